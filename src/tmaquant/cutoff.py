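"""Dichotomization of continuous densities: median split, ROC exploration,
and distribution-shape diagnostics.

The primary cut-off is the sample median (high iff strictly above it; ties
sit in the low group so the rule is reproducible).  ROC analysis over all
empirical thresholds reports the AUC and the Youden-optimal candidate
cut-off, together with whether that candidate actually improves Youden's J
over the median split by more than a margin.  Skewness and excess kurtosis
use the small-sample-adjusted moment formulas conventional in clinical
statistics packages.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import stats
from sklearn.metrics import roc_auc_score, roc_curve


@dataclass
class CutoffResult:
    variable: str
    cutoff_value: float
    rule: str  # "median" or "roc_youden"
    labels: np.ndarray = field(repr=False)  # "high"/"low" per non-missing value
    n_high: int = 0
    n_low: int = 0
    skewness: float = float("nan")
    excess_kurtosis: float = float("nan")
    roc_auc: float = float("nan")
    youden_j: float = float("nan")
    median_j: float = float("nan")
    improves_over_median: bool | None = None


def _labels(values: np.ndarray, cutoff: float) -> np.ndarray:
    return np.where(values > cutoff, "high", "low")


def median_dichotomize(values, variable: str = "value") -> CutoffResult:
    """Split at the sample median; high iff value > median, ties are low."""
    v = np.asarray(values, dtype=float)
    v = v[np.isfinite(v)]
    if v.size < 2:
        raise ValueError("need at least 2 non-missing values")
    if np.ptp(v) == 0:
        raise ValueError("all values identical; no split possible")
    med = float(np.median(v))
    labels = _labels(v, med)
    sk, ku = shape_stats(v) if v.size >= 4 else (float("nan"), float("nan"))
    return CutoffResult(
        variable=variable,
        cutoff_value=med,
        rule="median",
        labels=labels,
        n_high=int((labels == "high").sum()),
        n_low=int((labels == "low").sum()),
        skewness=sk,
        excess_kurtosis=ku,
    )


def roc_optimal_cutoff(
    values, outcome, variable: str = "value", margin: float = 0.05
) -> CutoffResult:
    """Youden-optimal cut-off from the empirical ROC curve.

    Scans every distinct threshold, maximizes J = sensitivity +
    specificity - 1, and reports whether the candidate beats the median
    split's J by more than ``margin`` (if not, the median remains the
    preferred, unbiased cut-off).
    """
    v = np.asarray(values, dtype=float)
    y = np.asarray(outcome).astype(int)
    keep = np.isfinite(v)
    v, y = v[keep], y[keep]
    if len(np.unique(y)) < 2:
        raise ValueError("outcome must contain both classes")
    fpr, tpr, thr = roc_curve(y, v)
    j = tpr - fpr
    best = int(np.argmax(j))
    # sklearn thresholds are ">= thr"; shift to the midpoint below so the
    # package-wide strict ">" convention selects the same cells
    distinct = np.unique(v)
    t = thr[best]
    below = distinct[distinct < t]
    cutoff = float((t + below.max()) / 2.0) if below.size else float(distinct[0] - 1.0)
    auc = float(roc_auc_score(y, v))

    med = float(np.median(v))
    med_pred = v > med
    med_j = float(
        med_pred[y == 1].mean() + (~med_pred[y == 0]).mean() - 1.0
        if (y == 1).any() and (y == 0).any()
        else np.nan
    )
    labels = _labels(v, cutoff)
    return CutoffResult(
        variable=variable,
        cutoff_value=cutoff,
        rule="roc_youden",
        labels=labels,
        n_high=int((labels == "high").sum()),
        n_low=int((labels == "low").sum()),
        roc_auc=auc,
        youden_j=float(j[best]),
        median_j=med_j,
        improves_over_median=bool(j[best] > med_j + margin),
    )


def shape_stats(values) -> tuple[float, float]:
    """Sample-size-adjusted skewness and excess kurtosis (G1, G2)."""
    v = np.asarray(values, dtype=float)
    v = v[np.isfinite(v)]
    if v.size < 4:
        raise ValueError("adjusted kurtosis needs at least 4 values")
    g1 = float(stats.skew(v, bias=False))
    g2 = float(stats.kurtosis(v, fisher=True, bias=False))
    return g1, g2
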