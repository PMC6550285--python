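"""Train the BLSTM tagger on a synthetic corpus and print its evaluation.

Splits the corpus 0.9/0.05/0.05, builds the vocabulary from the training
split only, trains with early stopping on validation weighted F1, and
prints the per-code table plus the aggregate block (exact match, unweighted
and weighted precision/recall/F1).
"""

import numpy as np

import deeptag as dt

gen = dt.GeneratorConfig(
    n_codes=10, n_metas=4, mean_labels_per_note=3.0,
    doc_length_mean=80.0, background_vocab_size=500, seed=11,
)
ontology, inventory = dt.generate_ontology(gen)
notes = dt.generate_corpus(ontology, inventory, gen, n=700)
train, val, test = dt.split_corpus(notes, dt.SplitSpec(seed=1))
vocab = dt.build_vocabulary(train)

config = dt.TaggerConfig(
    embedding_dim=32, hidden_dim=32, learning_rate=1e-2,
    max_epochs=25, patience=6, seed=0,
)
model = dt.TaggerModel(config, vocab, ontology)
log = dt.train(model, train, val)
print(f"stopped after epoch {len(log.epoch_losses) - 1}, "
      f"best validation weighted F1 {max(log.val_weighted_f1):.3f} "
      f"at epoch {log.best_epoch}")

labels = np.stack([n.labels for n in test])
report = dt.evaluate(model.predict_proba(test), labels)
print("\nper-code metrics on the held-out test split:")
print(report.per_code.round(3).to_string())
print("\naggregates:")
for k, v in report.aggregates.items():
    print(f"  {k}: {v:.3f}")
# exact_match is the fraction of notes whose full predicted code set is
# exactly right; weighted aggregates weight codes by positive count.
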