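"""Synthetic corpus generator: planted structure and the domain-shift transform."""

import dataclasses

import numpy as np
import pytest

import deeptag as dt


class TestGenerateOntology:
    def test_default_scale_passes_strict_invariants(self):
        onto, inv = dt.generate_ontology(dt.GeneratorConfig(seed=0))
        assert onto.n_diseases == 42 and onto.n_metas == 18
        assert onto.strict_cardinality
        onto.validate()
        assert all(len(subs) >= 1 for subs in inv.code_subtypes.values())

    def test_minimal_ontology(self):
        onto, _ = dt.generate_ontology(dt.GeneratorConfig(n_codes=2, n_metas=1, seed=0))
        assert onto.n_diseases == 2 and onto.n_metas == 1

    def test_same_seed_identical(self):
        a_onto, a_inv = dt.generate_ontology(dt.GeneratorConfig(seed=3))
        b_onto, b_inv = dt.generate_ontology(dt.GeneratorConfig(seed=3))
        assert a_onto.subtype_to_disease == b_onto.subtype_to_disease
        assert a_onto.disease_to_meta == b_onto.disease_to_meta
        assert a_inv.keywords == b_inv.keywords

    def test_keywords_disjoint_from_background(self):
        _, inv = dt.generate_ontology(dt.GeneratorConfig(n_codes=6, n_metas=2, seed=1))
        bg = set(inv.background)
        for kws in inv.keywords.values():
            assert not bg & set(kws)

    def test_same_meta_codes_share_theme_tokens(self):
        onto, inv = dt.generate_ontology(dt.GeneratorConfig(n_codes=8, n_metas=3, seed=2))
        for members in onto.meta_groups():
            kw_sets = [
                set(inv.keywords[inv.code_subtypes[d][0]]) for d in members
            ]
            shared = set.intersection(*kw_sets)
            assert shared  # the meta theme tokens

    def test_invalid_configs_rejected(self):
        with pytest.raises(ValueError):
            dt.GeneratorConfig(subtype_range=(0, 3))
        with pytest.raises(ValueError):
            dt.GeneratorConfig(n_codes=4, n_metas=6)
        with pytest.raises(ValueError):
            dt.GeneratorConfig(mean_labels_per_note=0.5)


@pytest.fixture(scope="module")
def gen_world():
    gen = dt.GeneratorConfig(
        n_codes=10, n_metas=4, mean_labels_per_note=3.0,
        doc_length_mean=60.0, background_vocab_size=300, seed=21,
    )
    onto, inv = dt.generate_ontology(gen)
    return gen, onto, inv


class TestGenerateCorpus:
    def test_labels_equal_rollup_of_planted_subtypes(self, gen_world):
        gen, onto, inv = gen_world
        notes = dt.generate_corpus(onto, inv, gen, n=100)
        for note in notes:
            assert (note.labels == dt.rollup(note.subtypes, onto)).all()
            assert note.labels.sum() >= 1

    def test_mean_labels_matches_config(self):
        gen = dt.GeneratorConfig(
            n_codes=42, n_metas=18, doc_length_mean=30.0, seed=5,
        )
        onto, inv = dt.generate_ontology(gen)
        notes = dt.generate_corpus(onto, inv, gen, n=4000)
        counts = np.array([n.labels.sum() for n in notes])
        # code-set size is 1 + Poisson(mean-1); duplicates collapse slightly
        se = counts.std() / np.sqrt(len(counts))
        assert abs(counts.mean() - gen.mean_labels_per_note) < max(3 * se, 0.4)

    def test_keywords_present_in_document(self, gen_world):
        gen, onto, inv = gen_world
        notes = dt.generate_corpus(onto, inv, gen, n=20)
        for note in notes:
            toks = set(note.tokens)
            for sid in note.subtypes:
                assert set(inv.keywords[sid]) <= toks

    def test_label_flip_noise_changes_labels(self, gen_world):
        gen, onto, inv = gen_world
        noisy = dataclasses.replace(gen, label_flip_noise=0.3)
        notes = dt.generate_corpus(onto, inv, noisy, n=200, seed=9)
        mismatch = sum(
            (n.labels != dt.rollup(n.subtypes, onto)).any() for n in notes
        )
        assert mismatch > 0

    def test_determinism_and_distinct_seeds(self, gen_world):
        gen, onto, inv = gen_world
        a = dt.generate_corpus(onto, inv, gen, n=30, seed=1)
        b = dt.generate_corpus(onto, inv, gen, n=30, seed=1)
        c = dt.generate_corpus(onto, inv, gen, n=30, seed=2)
        assert [n.text for n in a] == [n.text for n in b]
        assert [n.text for n in a] != [n.text for n in c]

    def test_long_tailed_code_frequencies(self):
        gen = dt.GeneratorConfig(
            n_codes=20, n_metas=5, mean_labels_per_note=2.0,
            doc_length_mean=20.0, freq_exponent=1.5, seed=6,
        )
        onto, inv = dt.generate_ontology(gen)
        notes = dt.generate_corpus(onto, inv, gen, n=2000)
        counts = np.stack([n.labels for n in notes]).sum(axis=0)
        assert counts[0] > 5 * counts[-1]  # head code much more frequent than tail


class TestDomainShift:
    def test_all_zero_shift_is_identity(self, gen_world):
        gen, onto, inv = gen_world
        notes = dt.generate_corpus(onto, inv, gen, n=40)
        shift = dt.ShiftConfig(
            oov_prob=0.0, length_scale=1.0, subtype_replacement_rate=0.0, seed=0
        )
        result = dt.apply_domain_shift(notes, shift, onto, inv)
        for a, b in zip(notes, result.notes):
            assert a.tokens == b.tokens
            assert a.subtypes == b.subtypes
            assert (a.labels == b.labels).all()

    def test_labels_preserved_under_full_shift(self, gen_world):
        gen, onto, inv = gen_world
        notes = dt.generate_corpus(onto, inv, gen, n=60)
        result = dt.apply_domain_shift(notes, dt.ShiftConfig(seed=1), onto, inv)
        assert len(result.notes) == len(notes)
        for a, b in zip(notes, result.notes):
            assert (a.labels == b.labels).all()

    def test_oov_rate_matches_injection_probability(self, gen_world):
        gen, onto, inv = gen_world
        notes = dt.generate_corpus(onto, inv, gen, n=400)
        vocab = dt.build_vocabulary(notes)
        shift = dt.ShiftConfig(
            oov_prob=0.154, length_scale=1.0, subtype_replacement_rate=0.0, seed=2
        )
        result = dt.apply_domain_shift(notes, shift, onto, inv)
        rate = dt.oov_rate(result.notes, vocab)["occurrence"]
        assert 0.14 <= rate <= 0.17

    def test_novel_subtypes_roll_up_to_same_codes(self, gen_world):
        gen, onto, inv = gen_world
        notes = dt.generate_corpus(onto, inv, gen, n=60)
        shift = dt.ShiftConfig(subtype_replacement_rate=1.0, oov_prob=0.0,
                               length_scale=1.0, seed=3)
        result = dt.apply_domain_shift(notes, shift, onto, inv)
        novel = {
            s for n in result.notes for s in n.subtypes
        } - set(onto.subtype_to_disease)
        assert novel  # the shifted domain has subtypes of its own
        for n in result.notes:
            assert (dt.rollup(n.subtypes, result.ontology) == n.labels).all()

    def test_length_scaling_shortens_documents(self, gen_world):
        gen, onto, inv = gen_world
        notes = dt.generate_corpus(onto, inv, gen, n=200)
        shift = dt.ShiftConfig(oov_prob=0.0, subtype_replacement_rate=0.0,
                               length_scale=191.0 / 325.0, seed=4)
        result = dt.apply_domain_shift(notes, shift, onto, inv)
        before = np.mean([len(n.tokens) for n in notes])
        after = np.mean([len(n.tokens) for n in result.notes])
        assert after / before == pytest.approx(191.0 / 325.0, abs=0.03)

    def test_invalid_shift_probabilities_rejected(self):
        with pytest.raises(ValueError):
            dt.ShiftConfig(oov_prob=1.3)
        with pytest.raises(ValueError):
            dt.ShiftConfig(length_scale=0.0)


def test_trained_model_degrades_on_shifted_domain(small_world, trained_small):
    """Cross-hospital pattern: held-out source beats shifted-domain scoring."""
    model, _ = trained_small
    gen, onto, inv = small_world["gen"], small_world["ontology"], small_world["inventory"]
    test = small_world["test"]
    result = dt.apply_domain_shift(test, dt.ShiftConfig(seed=5), onto, inv)
    y = np.stack([n.labels for n in test])
    f1_src = dt.evaluate(model.predict_proba(test), y).aggregates["weighted_f1"]
    f1_shift = dt.evaluate(model.predict_proba(result.notes), y).aggregates["weighted_f1"]
    assert f1_shift < f1_src
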