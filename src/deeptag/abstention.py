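"""Selective prediction: abstain on documents the tagger is unsure about.

Two ways to rank documents for deferral to a human coder:

* a fixed-confidence baseline — the mean distance of the 42 per-code
  probabilities from the decision threshold, with no learning;
* a learned estimator — a small feed-forward regressor that maps the 42-dim
  confidence vector to the document's expected per-code error rate, fit on a
  held-out split (the validation split, never the final evaluation split).

Either produces an abstention *priority* (higher = dropped earlier).  Quality
is read off the retention curve: weighted F1 and exact match of the retained
documents as the dropped fraction sweeps 0 to 0.9.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from sklearn.neural_network import MLPRegressor

from .evaluation import evaluate

FRACTION_GRID = tuple(np.round(np.arange(0.0, 0.91, 0.1), 10))


def baseline_priority(confidences: np.ndarray) -> np.ndarray:
    """Unlearned priority from per-code confidence margins.

    Per document: 1 minus the mean over codes of the rescaled margin
    ``2 * |p_d - 0.5|``.  All probabilities at 0 or 1 give priority 0
    (maximally confident, kept longest); all at 0.5 give priority 1.
    """
    conf = np.atleast_2d(np.asarray(confidences, dtype=float))
    return 1.0 - (2.0 * np.abs(conf - 0.5)).mean(axis=1)


def per_document_error(
    confidences: np.ndarray, labels: np.ndarray, threshold: float = 0.5
) -> np.ndarray:
    """Fraction of codes mispredicted per document at the given threshold."""
    preds = np.asarray(confidences) >= threshold
    return (preds != np.asarray(labels).astype(bool)).mean(axis=1)


@dataclass
class AbstentionEstimator:
    """Learned priority scorer: confidence vector -> predicted error rate."""

    regressor: MLPRegressor
    n_codes: int
    seed: int

    def priority(self, confidences: np.ndarray) -> np.ndarray:
        conf = np.atleast_2d(np.asarray(confidences, dtype=float))
        if conf.shape[1] != self.n_codes:
            raise ValueError(f"expected {self.n_codes}-dim confidence vectors")
        return np.clip(self.regressor.predict(conf), 0.0, 1.0)


def fit_abstainer(
    confidences: np.ndarray,
    labels: np.ndarray,
    seed: int = 0,
    hidden: int = 64,
    max_iter: int = 500,
    threshold: float = 0.5,
) -> AbstentionEstimator:
    """Fit the learned abstainer on a held-out fit split.

    The regression target is the per-document error rate (1 minus the
    per-document accuracy over the codes); its prediction is used directly
    as the abstention priority.  Deterministic given the seed.  The fit
    split must be disjoint from the split the retention curve is read on.
    """
    conf = np.asarray(confidences, dtype=float)
    if len(conf) < 50:
        import warnings

        warnings.warn(f"abstainer fit split has only {len(conf)} documents")
    target = per_document_error(conf, labels, threshold)
    # L-BFGS: full-batch quasi-Newton fits the small fit splits reliably
    reg = MLPRegressor(
        hidden_layer_sizes=(hidden,),
        random_state=seed,
        max_iter=max_iter,
        solver="lbfgs",
    )
    reg.fit(conf, target)
    return AbstentionEstimator(regressor=reg, n_codes=conf.shape[1], seed=seed)


def retention_curve(
    priorities: np.ndarray,
    confidences: np.ndarray,
    labels: np.ndarray,
    fractions=FRACTION_GRID,
    threshold: float = 0.5,
) -> pd.DataFrame:
    """Metrics on retained documents as the dropped fraction sweeps up.

    At each fraction f the ceil(f * n) highest-priority documents are
    removed (ties broken by document order: earlier documents dropped first)
    and weighted F1 plus exact match are computed on the remainder.
    """
    priorities = np.asarray(priorities, dtype=float)
    confidences = np.asarray(confidences, dtype=float)
    labels = np.asarray(labels)
    n = len(priorities)
    if not (len(confidences) == len(labels) == n):
        raise ValueError("length mismatch")
    fractions = sorted(set(float(f) for f in fractions))
    if any(f < 0 or f >= 1 for f in fractions):
        raise ValueError("fractions must lie in [0, 1)")
    # stable sort, descending priority: ties drop earlier documents first
    order = np.argsort(-priorities, kind="stable")
    rows = []
    for f in fractions:
        dropped = order[: int(np.ceil(f * n))]
        keep = np.ones(n, dtype=bool)
        keep[dropped] = False
        report = evaluate(confidences[keep], labels[keep], threshold)
        rows.append(
            {
                "fraction": f,
                "weighted_f1": report.aggregates["weighted_f1"],
                "exact_match": report.aggregates["exact_match"],
                "n_retained": int(keep.sum()),
            }
        )
    return pd.DataFrame(rows)
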