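"""Reproducible synthetic studies exercising the whole pipeline.

Each function here sets up one self-contained experiment on generated data —
learnability, the effect of the cluster penalty on embedding geometry, the
benefit of the hierarchical losses under domain shift, the subtype-diversity
regression, the OOV calibration of the shift transform, and abstention —
and returns plain dictionaries of measured quantities.  They are shared by
the test suite and by ``scripts/acceptance.py``.

Problem sizes are deliberately desk-scale (thousands of notes, hidden
dimensions in the tens); the study *conditions* — label-space shape, label
density, shift rates — mirror the full-scale setting.
"""

from __future__ import annotations

import dataclasses

import numpy as np

from . import abstention as ab
from . import corpus as cp
from . import evaluation as ev
from . import model as md
from . import synthgen as sg
from .ontology import CodeOntology


def _train_on(
    notes, ontology, config: md.TaggerConfig
) -> tuple[md.TaggerModel, list, list, "cp.Vocabulary"]:
    train, val, test = cp.split_corpus(notes, cp.SplitSpec(seed=config.seed))
    train = cp.training_eligible(train)
    vocab = cp.build_vocabulary(train)
    model = md.TaggerModel(dataclasses.replace(config), vocab, ontology)
    md.train(model, train, val)
    return model, val, test, vocab


def _f1(model: md.TaggerModel, notes) -> dict[str, float]:
    labels = np.stack([n.labels for n in notes])
    return ev.evaluate(model.predict_proba(notes), labels).aggregates


def learnability_study(seed: int, n: int = 2000) -> dict[str, float]:
    """Train the tagger on a clean 10-code / 4-meta corpus; score held-out.

    The corpus is a density-preserving scale-down of the full setting: the
    label space shrinks 42 -> 10, and mean labels per note (8 -> 3) and mean
    document length (325 -> 80) shrink with it, keeping label density and
    the keyword-to-background token ratio at full-scale values.  Noise is
    zero, so the planted lexical signal fully determines the labels.
    """
    gen = sg.GeneratorConfig(label_flip_noise=0.0, seed=seed, **SMALL_STUDY_GEN)
    ontology, inventory = sg.generate_ontology(gen)
    notes = sg.generate_corpus(ontology, inventory, gen, n=n)
    cfg = md.TaggerConfig(
        embedding_dim=32, hidden_dim=32, learning_rate=1e-2,
        max_epochs=25, patience=6, seed=seed,
    )
    model, _, test, _ = _train_on(notes, ontology, cfg)
    aggs = _f1(model, test)
    return {
        "unweighted_f1": aggs["unweighted_f1"],
        "weighted_f1": aggs["weighted_f1"],
        "exact_match": aggs["exact_match"],
        "n": n,
    }


SMALL_STUDY_GEN = dict(
    n_codes=10, n_metas=4, mean_labels_per_note=3.0,
    doc_length_mean=80.0, background_vocab_size=500,
)

SMALL_STUDY_CFG = dict(
    embedding_dim=32, hidden_dim=24, learning_rate=1e-2,
    max_epochs=8, patience=8, batch_size=32,
)


def embedding_distance_ratio(model: md.TaggerModel) -> float:
    """Mean intra-meta / mean inter-meta distance of the code embeddings."""
    E = model.label_embeddings.data
    groups = model.ontology.meta_groups()
    group_of = np.empty(E.shape[0], dtype=int)
    for g, members in enumerate(groups):
        group_of[members] = g
    ii, jj = np.triu_indices(E.shape[0], k=1)
    d = np.linalg.norm(E[ii] - E[jj], axis=1)
    same = group_of[ii] == group_of[jj]
    return float(d[same].mean() / d[~same].mean())


def cluster_effect_study(seed: int, n: int = 400) -> dict[str, float]:
    """Embedding geometry with and without the cluster penalty, same data."""
    gen = sg.GeneratorConfig(seed=seed, **SMALL_STUDY_GEN)
    ontology, inventory = sg.generate_ontology(gen)
    notes = sg.generate_corpus(ontology, inventory, gen, n=n)
    ratios = {}
    for name, lam in (("baseline", 0.0), ("regularized", 0.1)):
        cfg = md.TaggerConfig(lambda_cluster=lam, seed=seed, **SMALL_STUDY_CFG)
        model, _, _, _ = _train_on(notes, ontology, cfg)
        ratios[name] = embedding_distance_ratio(model)
    return ratios


def shift_benefit_study(seed: int, n: int = 600) -> dict[str, float]:
    """Weighted F1 of the three model variants on a shifted test corpus.

    All variants train on the same source split; the test split is passed
    through the domain-shift transform (OOV 0.15, subtype swap 0.3) before
    scoring, mirroring the cross-hospital evaluation.
    """
    gen = sg.GeneratorConfig(seed=seed, **SMALL_STUDY_GEN)
    ontology, inventory = sg.generate_ontology(gen)
    notes = sg.generate_corpus(ontology, inventory, gen, n=n)
    train, val, test = cp.split_corpus(notes, cp.SplitSpec(seed=seed))
    train = cp.training_eligible(train)
    vocab = cp.build_vocabulary(train)
    shift = sg.ShiftConfig(
        oov_prob=0.15, subtype_replacement_rate=0.3, seed=seed + 1
    )
    shifted_test = sg.apply_domain_shift(test, shift, ontology, inventory).notes
    labels = np.stack([nt.labels for nt in test])
    out = {}
    variants = {
        "baseline": dict(),
        "cluster": dict(lambda_cluster=0.1),
        "meta": dict(beta_meta=0.1),
    }
    for name, extra in variants.items():
        cfg = md.TaggerConfig(seed=seed, **SMALL_STUDY_CFG, **extra)
        model = md.TaggerModel(cfg, vocab, ontology)
        md.train(model, train, val)
        probs = model.predict_proba(shifted_test)
        out[name] = ev.evaluate(probs, labels).aggregates["weighted_f1"]
    return out


def subtype_diversity_study(
    seed: int, n: int = 800, counts=(1, 1, 1, 5, 5, 5, 25, 25, 25)
) -> dict[str, float]:
    """Does planted subtype diversity degrade per-code F1?

    Nine codes with planted subtype counts spanning {1, 5, 25}; code- and
    meta-level shared tokens are disabled so a code is recognizable only
    through its subtype keywords, making diversity the treatment.  Returns
    the subtype coefficient of the F1 ~ log N + subtypes regression.
    """
    gen = sg.GeneratorConfig(
        n_codes=len(counts), n_metas=3, subtype_counts=tuple(counts),
        code_tokens=0, meta_theme_tokens=0,
        mean_labels_per_note=3.0, doc_length_mean=80.0,
        background_vocab_size=500, seed=seed,
    )
    ontology, inventory = sg.generate_ontology(gen)
    notes = sg.generate_corpus(ontology, inventory, gen, n=n)
    cfg = md.TaggerConfig(seed=seed, **SMALL_STUDY_CFG)
    model, _, test, _ = _train_on(notes, ontology, cfg)
    train_notes = cp.training_eligible(
        cp.split_corpus(notes, cp.SplitSpec(seed=seed))[0]
    )
    n_train = np.stack([nt.labels for nt in train_notes]).sum(axis=0)
    labels = np.stack([nt.labels for nt in test])
    table = ev.per_code_metrics(model.predict_proba(test), labels)
    planted = inventory.subtype_counts(ontology.n_diseases)
    keep = n_train > 0
    res = ev.performance_regression(
        table["f1"].to_numpy()[keep], n_train[keep], planted[keep]
    )
    return {
        "subtype_coef": float(res.loc["subtypes", "coef"]),
        "subtype_pvalue": float(res.loc["subtypes", "pvalue"]),
        "log_n_coef": float(res.loc["log_n", "coef"]),
    }


def oov_calibration_study(seed: int, n: int = 1000) -> dict[str, float]:
    """Measured OOV rate of the shift transform at the nominal 15.4%.

    Full-scale generator defaults (42 codes, mean length 325); only the OOV
    injection channel of the shift is active so the measurement isolates it.
    """
    gen = sg.GeneratorConfig(seed=seed)
    ontology, inventory = sg.generate_ontology(gen)
    notes = sg.generate_corpus(ontology, inventory, gen, n=n)
    vocab = cp.build_vocabulary(notes)
    shift = sg.ShiftConfig(oov_prob=0.154, subtype_replacement_rate=0.0, seed=seed + 1)
    shifted = sg.apply_domain_shift(notes, shift, ontology, inventory).notes
    rates = cp.oov_rate(shifted, vocab, drop_numeric=True)
    return {
        "occurrence_rate": rates["occurrence"],
        "type_rate": rates["type"],
        "n": n,
    }


def abstention_world(seed: int, n: int = 400, d: int = 42):
    """Confidence vectors with injected per-document noise and overconfidence.

    Two document regimes emulate a tagger whose raw confidence margins
    mislead a fixed-threshold abstention rule:

    * clean documents — every code predicted correctly, most confidently
      (0.1 / 0.9), but a random handful of codes carry uninformative
      near-boundary confidences (0.45 / 0.55 on the *correct* side), so low
      margins do not imply errors;
    * noisy documents — the model is systematically overconfident: its
      general confidence profile is slightly compressed (0.2 / 0.8) and a
      random subset of codes is predicted on the *wrong* side at high
      confidence, so errors hide behind large margins.

    A margin-based priority ranks the clean-but-hedged documents as risky
    and keeps the overconfident erroneous ones; the error signature (the
    compressed profile) is nevertheless recoverable from the confidence
    vector, which is what the learned abstainer exploits.
    """
    rng = np.random.default_rng(seed)
    labels = rng.integers(0, 2, size=(n, d))
    conf = np.where(labels == 1, 0.9, 0.1).astype(float)
    # overconfidence traps: a fixed subset of codes is overpredicted — when
    # absent, the model still fires at 0.9 half of the time (an error hidden
    # behind a large margin)
    traps = np.arange(d // 5)
    for i in range(n):
        for j in traps:
            if labels[i, j] == 0 and rng.random() < 0.5:
                conf[i, j] = 0.9
        # hedging: near-boundary confidences on the correct side only
        k = rng.integers(0, d // 4 + 1)
        if k:
            idx = rng.choice(d, size=k, replace=False)
            hedged = np.where(labels[i, idx] == 1, 0.55, 0.45)
            correct = (conf[i, idx] >= 0.5) == (labels[i, idx] == 1)
            conf[i, idx] = np.where(correct, hedged, conf[i, idx])
    return conf, labels


def abstention_study(seed: int, n_fit: int = 800, n_eval: int = 400) -> dict:
    """Retention curves of the learned abstainer vs the fixed baseline."""
    conf_fit, y_fit = abstention_world(seed * 2 + 1, n=n_fit)
    conf_ev, y_ev = abstention_world(seed * 2 + 2, n=n_eval)
    est = ab.fit_abstainer(conf_fit, y_fit, seed=seed)
    learned = ab.retention_curve(est.priority(conf_ev), conf_ev, y_ev)
    baseline = ab.retention_curve(ab.baseline_priority(conf_ev), conf_ev, y_ev)
    oracle = ab.retention_curve(
        ab.per_document_error(conf_ev, y_ev), conf_ev, y_ev
    )
    return {
        "fractions": learned["fraction"].tolist(),
        "learned_f1": learned["weighted_f1"].to_numpy(),
        "baseline_f1": baseline["weighted_f1"].to_numpy(),
        "oracle_exact_match": oracle["exact_match"].to_numpy(),
    }


def pipeline_run(seed: int, n: int = 700) -> dict:
    """One deterministic end-to-end pass: simulate, train, evaluate, abstain.

    Returns a flat summary of every stage — used both for the determinism
    check (two runs with the same seed must agree exactly) and as the
    package's headline demonstration.
    """
    gen = sg.GeneratorConfig(seed=seed, **SMALL_STUDY_GEN)
    ontology, inventory = sg.generate_ontology(gen)
    notes = sg.generate_corpus(ontology, inventory, gen, n=n)
    cfg = md.TaggerConfig(lambda_cluster=0.1, seed=seed, **SMALL_STUDY_CFG)
    model, val, test, vocab = _train_on(notes, ontology, cfg)
    aggs = _f1(model, test)
    shift = sg.ShiftConfig(seed=seed + 1)
    shifted = sg.apply_domain_shift(test, shift, ontology, inventory)
    labels = np.stack([nt.labels for nt in test])
    shifted_aggs = ev.evaluate(model.predict_proba(shifted.notes), labels).aggregates
    conf_fit = model.predict_proba(val)
    conf_ev = model.predict_proba(test)
    est = ab.fit_abstainer(conf_fit, np.stack([nt.labels for nt in val]), seed=seed)
    learned = ab.retention_curve(est.priority(conf_ev), conf_ev, labels)
    baseline = ab.retention_curve(ab.baseline_priority(conf_ev), conf_ev, labels)
    oov = cp.oov_rate(shifted.notes, vocab, drop_numeric=True)["occurrence"]
    return {
        "heldout_weighted_f1": aggs["weighted_f1"],
        "heldout_unweighted_f1": aggs["unweighted_f1"],
        "heldout_exact_match": aggs["exact_match"],
        "shifted_weighted_f1": shifted_aggs["weighted_f1"],
        "shifted_oov_rate": oov,
        "embedding_distance_ratio": embedding_distance_ratio(model),
        "abstain_learned_mean_f1": float(learned["weighted_f1"].mean()),
        "abstain_baseline_mean_f1": float(baseline["weighted_f1"].mean()),
        "n": n,
    }
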