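"""Multilabel evaluation protocol.

Per-code precision / recall / F1 / ROC AUC, the exact-match ratio over
documents, unweighted and weighted aggregates across the label space, and an
OLS regression explaining per-code F1 heterogeneity by training-set size and
subtype diversity.

Conventions (stated explicitly because they are rarely written down): precision, recall
and F1 are 0 when their denominator is 0; AUC is NaN — and excluded from
aggregates — for a code whose evaluation column is single-class; weighted
aggregates weight each code by its positive-example count in the evaluation
split; a predicted probability exactly at threshold counts as positive.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
import statsmodels.api as sm
from sklearn.metrics import roc_auc_score


@dataclass
class EvalReport:
    per_code: pd.DataFrame        # index = code; columns n_pos, precision, recall, f1, auc
    aggregates: dict[str, float]  # exact_match + {unweighted,weighted}_{precision,recall,f1}

    def to_tsv(self, path) -> None:
        self.per_code.to_csv(path, sep="\t", index_label="code")


def per_code_metrics(
    probs: np.ndarray, labels: np.ndarray, threshold: float = 0.5
) -> pd.DataFrame:
    """Per-code precision/recall/F1/AUC table from a probability matrix.

    ``probs`` and ``labels`` are (n_documents, n_codes); AUC uses the raw
    scores (midrank ties), the other metrics the thresholded predictions.
    """
    probs = np.asarray(probs, dtype=float)
    labels = np.asarray(labels)
    if probs.shape != labels.shape:
        raise ValueError(f"shape mismatch: {probs.shape} vs {labels.shape}")
    if probs.ndim != 2 or probs.shape[0] < 1:
        raise ValueError("need a (documents, codes) matrix with >= 1 document")
    if not 0 < threshold < 1:
        raise ValueError("threshold must be in (0, 1)")
    preds = (probs >= threshold).astype(int)
    tp = ((preds == 1) & (labels == 1)).sum(axis=0).astype(float)
    fp = ((preds == 1) & (labels == 0)).sum(axis=0).astype(float)
    fn = ((preds == 0) & (labels == 1)).sum(axis=0).astype(float)
    with np.errstate(divide="ignore", invalid="ignore"):
        prec = np.where(tp + fp > 0, tp / (tp + fp), 0.0)
        rec = np.where(tp + fn > 0, tp / (tp + fn), 0.0)
        f1 = np.where(prec + rec > 0, 2 * prec * rec / (prec + rec), 0.0)
    n_codes = probs.shape[1]
    auc = np.full(n_codes, np.nan)
    for d in range(n_codes):
        col = labels[:, d]
        if 0 < col.sum() < len(col):  # AUC undefined for single-class columns
            auc[d] = roc_auc_score(col, probs[:, d])
    return pd.DataFrame(
        {
            "n_pos": labels.sum(axis=0).astype(int),
            "precision": prec,
            "recall": rec,
            "f1": f1,
            "auc": auc,
        }
    )


def exact_match(preds: np.ndarray, labels: np.ndarray) -> float:
    """Fraction of documents whose predicted label SET equals the true set.

    A document with true codes {a, b, c} predicted {a, b} contributes 0:
    the match must be exact, no more and no less.
    """
    preds = np.asarray(preds)
    labels = np.asarray(labels)
    if preds.shape != labels.shape:
        raise ValueError("shape mismatch")
    return float((preds == labels).all(axis=1).mean())


def aggregate(per_code: pd.DataFrame) -> dict[str, float]:
    """Unweighted (plain mean) and weighted (by per-code positive counts)
    averages of precision, recall and F1 across codes."""
    weights = per_code["n_pos"].to_numpy(dtype=float)
    out: dict[str, float] = {}
    for metric in ("precision", "recall", "f1"):
        vals = per_code[metric].to_numpy(dtype=float)
        out[f"unweighted_{metric}"] = float(vals.mean())
        if weights.sum() > 0:
            out[f"weighted_{metric}"] = float((vals * weights).sum() / weights.sum())
        else:
            out[f"weighted_{metric}"] = float(vals.mean())
    auc = per_code["auc"].to_numpy(dtype=float)
    valid = ~np.isnan(auc)
    out["unweighted_auc"] = float(auc[valid].mean()) if valid.any() else float("nan")
    return out


def evaluate(
    probs: np.ndarray, labels: np.ndarray, threshold: float = 0.5
) -> EvalReport:
    """Full report: per-code table plus exact match and aggregate averages."""
    table = per_code_metrics(probs, labels, threshold)
    aggs = aggregate(table)
    preds = (np.asarray(probs) >= threshold).astype(int)
    aggs["exact_match"] = exact_match(preds, labels)
    return EvalReport(per_code=table, aggregates=aggs)


def performance_regression(
    f1: np.ndarray,
    n_train: np.ndarray,
    subtype_counts: np.ndarray,
    log_base: float = 10.0,
) -> pd.DataFrame:
    """OLS of per-code F1 on log(training examples) and subtype count.

    Tests whether code diversity (proxied by the number of distinct subtypes
    binned into the code) degrades performance beyond what sample size
    explains — a negative subtype coefficient means more diverse codes are
    harder to tag.  Returns a coefficient table with standard errors and
    p-values; raises on perfectly collinear covariates.
    """
    f1 = np.asarray(f1, dtype=float)
    n_train = np.asarray(n_train, dtype=float)
    subtype_counts = np.asarray(subtype_counts, dtype=float)
    if len(f1) < 3:
        raise ValueError("need at least 3 codes for the regression")
    if np.any(n_train <= 0):
        raise ValueError("n_train must be positive (log transform)")
    X = np.column_stack([np.log(n_train) / np.log(log_base), subtype_counts])
    if np.linalg.matrix_rank(np.column_stack([np.ones(len(f1)), X])) < 3:
        raise ValueError("collinear covariates")
    res = sm.OLS(f1, sm.add_constant(X)).fit()
    return pd.DataFrame(
        {"coef": res.params, "stderr": res.bse, "pvalue": res.pvalues},
        index=["intercept", "log_n", "subtypes"],
    )
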