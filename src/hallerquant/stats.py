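"""Cohort-level statistics for per-eye vessel metrics.

Nonparametric throughout, matching common ophthalmic-cohort practice:
Mann-Whitney U for two-group metric comparisons, Yates-corrected chi-square
for the 2x2 sex table, Spearman rank correlation against central choroidal
thickness, and an ROC/Youden-index cutoff for separating diseased from
normal eyes on mean vessel diameter.  All p-values are two-sided.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, List, Optional, Sequence, Tuple

import numpy as np
import pandas as pd
from scipy import stats as sps


@dataclass(frozen=True)
class GroupComparison:
    metric: str
    group_a: str
    group_b: str
    mean_a: float
    sd_a: float
    mean_b: float
    sd_b: float
    u_statistic: float
    p_value: float


@dataclass(frozen=True)
class RocResult:
    """ROC curve with the Youden-index operating point.

    ``cutoffs`` are the sorted unique observed values; an eye is called
    positive when its value is strictly greater than the cutoff.  The Youden
    cutoff maximizes J = sensitivity + specificity - 1; ties are broken
    toward the larger cutoff (higher specificity).
    """

    cutoffs: np.ndarray
    sensitivity: np.ndarray
    specificity: np.ndarray
    auc: float
    youden_cutoff: float
    youden_j: float
    sensitivity_at_cutoff: float
    specificity_at_cutoff: float


@dataclass(frozen=True)
class ConfusionTable:
    """Counts of a 2x2 diagnostic quadrant (positive = diseased call)."""

    tp: int
    fp: int
    tn: int
    fn: int

    def __post_init__(self) -> None:
        for name in ("tp", "fp", "tn", "fn"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be nonnegative")


@dataclass(frozen=True)
class ConfusionMetrics:
    """Percentages as printed in clinical tables (one decimal)."""

    sensitivity_pct: float
    specificity_pct: float
    tp_pct: float
    fp_pct: float
    tn_pct: float
    fn_pct: float


def mann_whitney_u(sample_a: Sequence[float], sample_b: Sequence[float]
                   ) -> Tuple[float, float]:
    """Two-sided Mann-Whitney U test (U of the first sample, midrank ties).

    Uses exact enumeration when the pooled size is <= 16 with no ties, and
    the tie-corrected normal approximation otherwise.
    """
    a = np.asarray(sample_a, dtype=float)
    b = np.asarray(sample_b, dtype=float)
    if a.size == 0 or b.size == 0:
        raise ValueError("both samples must be nonempty")
    pooled = np.concatenate([a, b])
    no_ties = np.unique(pooled).size == pooled.size
    method = "exact" if (pooled.size <= 16 and no_ties) else "asymptotic"
    res = sps.mannwhitneyu(a, b, alternative="two-sided", method=method)
    return float(res.statistic), float(res.pvalue)


def chi_square_2x2(table: Sequence[Sequence[int]]) -> Tuple[float, float]:
    """Yates-continuity-corrected chi-square on a 2x2 count table (df = 1)."""
    t = np.asarray(table, dtype=float)
    if t.shape != (2, 2) or (t < 0).any():
        raise ValueError("table must be 2x2 with nonnegative counts")
    if (t.sum(axis=0) == 0).any() or (t.sum(axis=1) == 0).any():
        raise ValueError("all row and column margins must be positive")
    res = sps.chi2_contingency(t, correction=True)
    return float(res.statistic), float(res.pvalue)


def spearman_corr(x: Sequence[float], y: Sequence[float]) -> Tuple[float, float]:
    """Spearman rank correlation with midranks; p from the t approximation."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.size != y.size or x.size < 3:
        raise ValueError("need paired samples with n >= 3")
    if np.unique(x).size == 1 or np.unique(y).size == 1:
        raise ValueError("correlation undefined for a constant input vector")
    res = sps.spearmanr(x, y)
    return float(res.statistic), float(res.pvalue)


def roc_youden(values: Sequence[float], labels: Sequence[int]) -> RocResult:
    """ROC curve over all observed cutoffs and the Youden operating point.

    ``labels`` are 1 for the diseased (positive) class.  Every unique
    observed value is evaluated as a cutoff with the strictly-greater
    positivity rule; AUC is the trapezoid area under the (FPR, TPR) curve
    extended to the all-positive corner.
    """
    v = np.asarray(values, dtype=float)
    y = np.asarray(labels, dtype=int)
    if v.size != y.size or v.size == 0:
        raise ValueError("values and labels must be nonempty and paired")
    if not (np.any(y == 1) and np.any(y == 0)):
        raise ValueError("both classes must be present")
    n_pos = int((y == 1).sum())
    n_neg = int((y == 0).sum())
    cutoffs = np.unique(v)
    # positive call: value > cutoff
    sens = np.array([(v[y == 1] > c).sum() / n_pos for c in cutoffs])
    spec = np.array([(v[y == 0] <= c).sum() / n_neg for c in cutoffs])
    j = sens + spec - 1.0
    # tolerance absorbs float noise so mathematical ties are real ties
    best = np.flatnonzero(j >= j.max() - 1e-12)[-1]  # ties -> larger cutoff
    # trapezoid AUC over (FPR, TPR), adding the all-positive corner (cutoff -inf);
    # with ascending cutoffs FPR/TPR descend, so reverse for ascending FPR
    fpr = np.concatenate([[1.0], 1.0 - spec])[::-1]
    tpr = np.concatenate([[1.0], sens])[::-1]
    auc = float(np.trapezoid(tpr, fpr))
    return RocResult(
        cutoffs=cutoffs,
        sensitivity=sens,
        specificity=spec,
        auc=auc,
        youden_cutoff=float(cutoffs[best]),
        youden_j=float(j[best]),
        sensitivity_at_cutoff=float(sens[best]),
        specificity_at_cutoff=float(spec[best]),
    )


def confusion_metrics(table: ConfusionTable) -> ConfusionMetrics:
    """Sensitivity/specificity and per-cell column percentages, 1 decimal."""
    pos_total = table.tp + table.fn
    neg_total = table.tn + table.fp
    if pos_total == 0 or neg_total == 0:
        raise ValueError("both the diseased and normal columns must be nonempty")
    return ConfusionMetrics(
        sensitivity_pct=round(100.0 * table.tp / pos_total, 1),
        specificity_pct=round(100.0 * table.tn / neg_total, 1),
        tp_pct=round(100.0 * table.tp / pos_total, 1),
        fn_pct=round(100.0 * table.fn / pos_total, 1),
        tn_pct=round(100.0 * table.tn / neg_total, 1),
        fp_pct=round(100.0 * table.fp / neg_total, 1),
    )


def confusion_at_cutoff(values: Sequence[float], labels: Sequence[int],
                        cutoff: float) -> ConfusionTable:
    """Quadrant counts at a given cutoff (positive iff value > cutoff)."""
    v = np.asarray(values, dtype=float)
    y = np.asarray(labels, dtype=int)
    pos = v > cutoff
    return ConfusionTable(
        tp=int((pos & (y == 1)).sum()),
        fp=int((pos & (y == 0)).sum()),
        tn=int((~pos & (y == 0)).sum()),
        fn=int((~pos & (y == 1)).sum()),
    )


def compare_groups(cohort: pd.DataFrame,
                   metrics: Sequence[str],
                   pairs: Optional[Sequence[Tuple[str, str]]] = None,
                   group_col: str = "group") -> pd.DataFrame:
    """Pairwise Mann-Whitney comparisons of metrics across groups.

    Returns one row per (metric, group pair) with per-group mean ± SD, the
    U statistic and the two-sided p-value, mirroring a published
    three-column comparison table.
    """
    if group_col not in cohort.columns:
        raise ValueError(f"missing group column {group_col!r}")
    for m in metrics:
        if m not in cohort.columns:
            raise ValueError(f"missing metric column {m!r}")
    groups = list(dict.fromkeys(cohort[group_col]))
    if len(groups) < 2:
        raise ValueError("need at least two groups")
    if pairs is None:
        pairs = [(groups[i], groups[j])
                 for i in range(len(groups)) for j in range(i + 1, len(groups))]
    rows: List[GroupComparison] = []
    for metric in metrics:
        for ga, gb in pairs:
            xa = cohort.loc[cohort[group_col] == ga, metric].to_numpy(float)
            xb = cohort.loc[cohort[group_col] == gb, metric].to_numpy(float)
            u, p = mann_whitney_u(xa, xb)
            rows.append(GroupComparison(
                metric=metric, group_a=ga, group_b=gb,
                mean_a=float(xa.mean()), sd_a=float(xa.std(ddof=1)),
                mean_b=float(xb.mean()), sd_b=float(xb.std(ddof=1)),
                u_statistic=u, p_value=p,
            ))
    return pd.DataFrame([r.__dict__ for r in rows])
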