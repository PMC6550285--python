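import numpy as np
import pytest

import deeptag as dt


@pytest.fixture(scope="session")
def small_world():
    """A small synthetic study: 10 codes / 4 metas, 300 notes, splits, vocab."""
    gen = dt.GeneratorConfig(
        n_codes=10,
        n_metas=4,
        mean_labels_per_note=3.0,
        doc_length_mean=80.0,
        background_vocab_size=500,
        seed=11,
    )
    ontology, inventory = dt.generate_ontology(gen)
    notes = dt.generate_corpus(ontology, inventory, gen, n=700)
    train, val, test = dt.split_corpus(notes, dt.SplitSpec(seed=1))
    vocab = dt.build_vocabulary(train)
    return {
        "gen": gen,
        "ontology": ontology,
        "inventory": inventory,
        "notes": notes,
        "train": train,
        "val": val,
        "test": test,
        "vocab": vocab,
    }


@pytest.fixture(scope="session")
def tiny_model_config():
    return dt.TaggerConfig(
        embedding_dim=32,
        hidden_dim=32,
        batch_size=32,
        max_epochs=25,
        patience=6,
        learning_rate=1e-2,
        seed=0,
    )


@pytest.fixture(scope="session")
def trained_small(small_world, tiny_model_config):
    """One trained tiny tagger shared by the model/abstention tests."""
    model = dt.TaggerModel(
        tiny_model_config, small_world["vocab"], small_world["ontology"]
    )
    log = dt.train(model, small_world["train"], small_world["val"])
    return model, log
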