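"""The metric suite over bag predictions and continuous labels.

Classification metrics derive the binary groups from the normalized labels
(<= 0.5 -> high risk); predictions are on the same [0, 1] scale, so the
prediction itself scores the low-risk class and ``1 - prediction`` the
high-risk class.  Area under the precision-recall curve is reported in both
modes (low-as-positive and high-as-positive) via step-wise average
precision; AUROC uses rank statistics with tie correction; balanced
accuracy is the mean of per-class recalls at the 0.5 threshold; association
between the two continuous variables is the Spearman rank correlation
(exact-permutation p-value for n <= 10, t-approximation above).
"""

from __future__ import annotations

from dataclasses import dataclass, asdict
from itertools import permutations
from typing import Sequence

import numpy as np
from scipy import stats
from sklearn.metrics import (
    average_precision_score,
    balanced_accuracy_score,
    precision_recall_fscore_support,
    roc_auc_score,
)

from .training import assign_risk_group

__all__ = ["MetricReport", "compute_metrics", "spearman_exact_p"]

UNDEFINED = float("nan")


@dataclass
class MetricReport:
    auroc: float
    balanced_accuracy: float
    auprc_low_positive: float
    auprc_high_positive: float
    spearman_r: float
    spearman_p: float
    n: int
    # "average" precision/recall/F1 in both common weightings
    f1_macro: float = UNDEFINED
    f1_weighted: float = UNDEFINED
    precision_weighted: float = UNDEFINED
    recall_weighted: float = UNDEFINED

    def to_dict(self) -> dict:
        return asdict(self)


def spearman_exact_p(x: np.ndarray, y: np.ndarray) -> float:
    """Two-sided exact permutation p-value for the Spearman correlation."""
    n = len(x)
    rx = stats.rankdata(x)
    ry = stats.rankdata(y)
    observed = abs(np.corrcoef(rx, ry)[0, 1])
    rx_c = rx - rx.mean()
    count = 0
    total = 0
    chunk: list[tuple] = []

    def flush(chunk: list[tuple]) -> int:
        perm = np.array(chunk, dtype=np.int16)
        ry_c = ry[perm] - ry[perm].mean(axis=1, keepdims=True)
        r = np.abs(ry_c @ rx_c / np.sqrt((rx_c**2).sum() * (ry_c**2).sum(axis=1)))
        return int((r >= observed - 1e-12).sum())

    for perm in permutations(range(n)):
        chunk.append(perm)
        total += 1
        if len(chunk) == 100_000:
            count += flush(chunk)
            chunk = []
    if chunk:
        count += flush(chunk)
    return count / total


def compute_metrics(
    predictions: Sequence[float], labels_normalized: Sequence[float]
) -> MetricReport:
    """Full metric report for paired predictions and normalized labels."""
    p = np.asarray(predictions, dtype=float)
    y = np.asarray(labels_normalized, dtype=float)
    if p.shape != y.shape or p.ndim != 1:
        raise ValueError("predictions and labels must be equal-length 1-D")
    n = len(p)
    if n < 2:
        raise ValueError("need at least 2 samples")

    rho, p_t = stats.spearmanr(p, y)
    if n <= 10:
        sp_p = spearman_exact_p(p, y)
    else:
        sp_p = float(p_t)
    sp_p = min(max(sp_p, np.nextafter(0, 1)), 1.0)

    groups = np.array([assign_risk_group(v, "normalized") for v in y])
    low = (groups == "low").astype(int)  # positive = low risk
    pred_groups = np.where(p <= 0.5, "high", "low")
    pred_low = (pred_groups == "low").astype(int)

    if low.min() == low.max():  # single-class labels: classification undefined
        return MetricReport(
            auroc=UNDEFINED,
            balanced_accuracy=UNDEFINED,
            auprc_low_positive=UNDEFINED,
            auprc_high_positive=UNDEFINED,
            spearman_r=float(rho),
            spearman_p=sp_p,
            n=n,
        )

    prec_w, rec_w, f1_w, _ = precision_recall_fscore_support(
        low, pred_low, average="weighted", zero_division=0
    )
    _, _, f1_m, _ = precision_recall_fscore_support(
        low, pred_low, average="macro", zero_division=0
    )
    return MetricReport(
        auroc=float(roc_auc_score(low, p)),
        balanced_accuracy=float(balanced_accuracy_score(low, pred_low)),
        auprc_low_positive=float(average_precision_score(low, p)),
        auprc_high_positive=float(average_precision_score(1 - low, 1.0 - p)),
        spearman_r=float(rho),
        spearman_p=sp_p,
        n=n,
        f1_macro=float(f1_m),
        f1_weighted=float(f1_w),
        precision_weighted=float(prec_w),
        recall_weighted=float(rec_w),
    )
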