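"""Per-sgRNA evaluation, threshold metrics and exact paired significance.

Off-target validation is done one guide at a time, so ranking quality is
measured per sgRNA and then averaged: for every sgRNA with at least one true
off-target site in the test set, AUPRC (step-wise precision-recall
integration) and AUROC (midrank tie handling) are computed over its own
candidate sites, and the dataset-level score is the unweighted mean across
those sgRNAs.  Precision/recall/F1/MCC at a fixed probability threshold are
reported the same way.  Seed-wise method comparisons use the one-sided exact
Wilcoxon signed-rank test (enumeration of all sign assignments, zeros
dropped).
"""

from __future__ import annotations

from dataclasses import dataclass
from itertools import product as _iterproduct

import numpy as np
import pandas as pd
from sklearn.metrics import average_precision_score, roc_auc_score

__all__ = [
    "SgMetricRecord",
    "DatasetMetrics",
    "sg_curve_metrics",
    "threshold_metrics",
    "evaluate_dataset",
    "wilcoxon_one_sided",
]


class UndefinedMetricError(ValueError):
    """Raised when a curve or test statistic is undefined for the input."""


def _check_binary(labels: np.ndarray) -> np.ndarray:
    labels = np.asarray(labels)
    if not np.isin(labels, (0, 1)).all():
        raise ValueError("labels must be binary 0/1")
    return labels.astype(int)


def sg_curve_metrics(scores, labels) -> tuple[float, float]:
    """(AUPRC, AUROC) for one sgRNA's scored candidate sites.

    Requires both classes present.  AUPRC is the step-function
    precision-recall summary (precision at each achieved recall level);
    AUROC uses the midrank convention for tied scores.
    """
    scores = np.asarray(scores, dtype=float)
    labels = _check_binary(labels)
    if labels.size != scores.size or labels.size == 0:
        raise ValueError("scores and labels must be equal-length and non-empty")
    n_pos = int(labels.sum())
    if n_pos == 0 or n_pos == labels.size:
        raise UndefinedMetricError("both classes are required for curve metrics")
    return (
        float(average_precision_score(labels, scores)),
        float(roc_auc_score(labels, scores)),
    )


def threshold_metrics(scores, labels, threshold: float = 0.5) -> dict[str, float]:
    """Precision/recall/F1/MCC at a fixed score threshold.

    Division-by-zero cases return 0.0 and are flagged in the ``degenerate``
    entry rather than raising.
    """
    scores = np.asarray(scores, dtype=float)
    labels = _check_binary(labels)
    pred = (scores >= threshold).astype(int)
    tp = int(((pred == 1) & (labels == 1)).sum())
    fp = int(((pred == 1) & (labels == 0)).sum())
    fn = int(((pred == 0) & (labels == 1)).sum())
    tn = int(((pred == 0) & (labels == 0)).sum())
    degenerate = []
    if tp + fp == 0:
        precision = 0.0
        degenerate.append("precision")
    else:
        precision = tp / (tp + fp)
    if tp + fn == 0:
        recall = 0.0
        degenerate.append("recall")
    else:
        recall = tp / (tp + fn)
    if precision + recall == 0:
        f1 = 0.0
        degenerate.append("f1")
    else:
        f1 = 2 * precision * recall / (precision + recall)
    denom = (tp + fp) * (tp + fn) * (tn + fp) * (tn + fn)
    if denom == 0:
        mcc = 0.0
        degenerate.append("mcc")
    else:
        mcc = (tp * tn - fp * fn) / np.sqrt(denom)
    return {
        "precision": float(precision),
        "recall": float(recall),
        "f1": float(f1),
        "mcc": float(mcc),
        "degenerate": ",".join(degenerate),
    }


@dataclass(frozen=True)
class SgMetricRecord:
    sgrna_id: str
    n_pos: int
    n_neg: int
    sg_auprc: float
    sg_auroc: float
    precision: float
    recall: float
    f1: float
    mcc: float
    degenerate: str = ""


@dataclass(frozen=True)
class DatasetMetrics:
    """Per-sgRNA records plus their unweighted dataset-level means."""

    records: tuple[SgMetricRecord, ...]
    threshold: float

    @property
    def N(self) -> int:
        return len(self.records)

    @property
    def auprc(self) -> float:
        return float(np.mean([r.sg_auprc for r in self.records]))

    @property
    def auroc(self) -> float:
        return float(np.mean([r.sg_auroc for r in self.records]))

    def aggregate(self, field: str) -> float:
        return float(np.mean([getattr(r, field) for r in self.records]))

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame([r.__dict__ for r in self.records])


def evaluate_dataset(
    predictions: pd.DataFrame,
    score_col: str = "p_ensemble",
    threshold: float = 0.5,
) -> DatasetMetrics:
    """Score a predictions table per sgRNA and average.

    ``predictions`` needs columns ``sgrna_id``, ``label`` and *score_col*.
    sgRNAs with no true off-target site (or no negative, where the curves
    are equally undefined) are excluded from the average.
    """
    if not 0 < threshold < 1:
        raise ValueError("threshold must lie in (0, 1)")
    records = []
    for sg, grp in predictions.groupby("sgrna_id", sort=True):
        labels = _check_binary(grp["label"].to_numpy())
        n_pos = int(labels.sum())
        n_neg = int(labels.size - n_pos)
        if n_pos == 0 or n_neg == 0:
            continue
        scores = grp[score_col].to_numpy(dtype=float)
        auprc, auroc = sg_curve_metrics(scores, labels)
        thr = threshold_metrics(scores, labels, threshold)
        records.append(
            SgMetricRecord(
                sgrna_id=str(sg), n_pos=n_pos, n_neg=n_neg,
                sg_auprc=auprc, sg_auroc=auroc,
                precision=thr["precision"], recall=thr["recall"],
                f1=thr["f1"], mcc=thr["mcc"], degenerate=thr["degenerate"],
            )
        )
    if not records:
        raise UndefinedMetricError("no sgRNA with both classes present")
    return DatasetMetrics(records=tuple(records), threshold=threshold)


def wilcoxon_one_sided(x, y) -> float:
    """Exact one-sided Wilcoxon signed-rank p-value for paired samples.

    Tests the alternative ``median(x - y) > 0``.  Zero differences are
    dropped (signed-rank convention); ranks of tied |differences| are
    midranks.  The p-value is P(W+ >= observed) under enumeration of all
    2^n sign assignments, exact for n <= 20 (beyond that a normal
    approximation with tie correction is used).
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape or x.ndim != 1 or x.size == 0:
        raise ValueError("x and y must be equal-length non-empty 1-D arrays")
    d = x - y
    d = d[d != 0.0]
    n = d.size
    if n == 0:
        raise UndefinedMetricError("all paired differences are zero; test undefined")
    ranks = pd.Series(np.abs(d)).rank(method="average").to_numpy()
    w_obs = float(ranks[d > 0].sum())
    if n <= 20:
        # enumerate all sign assignments of the ranked |differences|
        sums = np.zeros(1)
        for r in ranks:
            sums = np.concatenate([sums, sums + r])
        return float(np.mean(sums >= w_obs - 1e-12))
    mu = ranks.sum() / 2.0
    sigma2 = float(np.sum(ranks**2)) / 4.0
    from scipy.stats import norm

    z = (w_obs - mu - 0.5) / np.sqrt(sigma2)
    return float(norm.sf(z))
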