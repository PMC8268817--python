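"""Relapse-risk association statistics.

Cross-tabulates a dichotomized cell density against a binary relapse
outcome and estimates the odds ratio with a Woolf (log-scale Wald)
confidence interval, the uncorrected Pearson chi-square test, Fisher's
exact test, and univariate/multivariate binary logistic regression with
detection of separation (covariate patterns that perfectly predict the
outcome, for which the Wald machinery is meaningless and the odds ratio
is reported as undefined).

Table layout convention for the 2x2 table: rows are exposure (low, high),
columns are outcome (no event, event):

    a = low  & no event     b = low  & event
    c = high & no event     d = high & event

so the cross-product odds ratio is (d*a)/(b*c) — the odds of the event in
the high group relative to the low group.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy import stats

logger = logging.getLogger(__name__)

Z95 = 1.959963984540054  # normal 97.5% quantile

SEPARATION_COEF = 10.0
SEPARATION_SE = 50.0


@dataclass(frozen=True)
class ContingencyTable2x2:
    """Counts: rows (low, high) exposure x columns (no event, event)."""

    a: int  # low, no event
    b: int  # low, event
    c: int  # high, no event
    d: int  # high, event

    def __post_init__(self):
        for v in (self.a, self.b, self.c, self.d):
            if v < 0 or v != int(v):
                raise ValueError("counts must be non-negative integers")
        if self.total == 0:
            raise ValueError("empty table")

    @property
    def total(self) -> int:
        return self.a + self.b + self.c + self.d

    def as_array(self) -> np.ndarray:
        return np.array([[self.a, self.b], [self.c, self.d]], dtype=float)

    @classmethod
    def from_labels(cls, exposure_high, outcome) -> "ContingencyTable2x2":
        hi = np.asarray(exposure_high, dtype=bool)
        y = np.asarray(outcome, dtype=bool)
        return cls(
            a=int((~hi & ~y).sum()),
            b=int((~hi & y).sum()),
            c=int((hi & ~y).sum()),
            d=int((hi & y).sum()),
        )


@dataclass
class ORResult:
    or_: float
    ci_low: float
    ci_high: float
    log_or_se: float
    method: str  # "woolf" or "haldane_corrected"


def odds_ratio(table: ContingencyTable2x2) -> ORResult:
    """Cross-product odds ratio with a 95% Woolf confidence interval.

    Any zero cell triggers the Haldane–Anscombe correction (+0.5 to every
    cell).  Two zero cells in the same row or column leave the odds ratio
    undefined and raise.
    """
    arr = table.as_array()
    if ((arr == 0).sum(axis=0) == 2).any() or ((arr == 0).sum(axis=1) == 2).any():
        raise ValueError("zero row or column margin; odds ratio undefined")
    method = "woolf"
    if (arr == 0).any():
        arr = arr + 0.5
        method = "haldane_corrected"
    (a, b), (c, d) = arr
    or_ = (d * a) / (b * c)
    se = float(np.sqrt((1.0 / arr).sum()))
    lo, hi = np.exp(np.log(or_) + np.array([-Z95, Z95]) * se)
    return ORResult(float(or_), float(lo), float(hi), se, method)


def pearson_chi2(table: ContingencyTable2x2) -> tuple[float, float]:
    """Uncorrected Pearson chi-square test of independence on the 2x2 table."""
    arr = table.as_array()
    rows, cols = arr.sum(axis=1), arr.sum(axis=0)
    if (rows == 0).any() or (cols == 0).any():
        raise ValueError("zero margin; chi-square undefined")
    stat, p, _, _ = stats.chi2_contingency(arr, correction=False)
    return float(stat), float(p)


def fisher_exact(table: ContingencyTable2x2) -> float:
    """Two-sided Fisher exact p (minimum-likelihood method)."""
    _, p = stats.fisher_exact(table.as_array(), alternative="two-sided")
    return float(p)


@dataclass
class LogisticFit:
    params: pd.Series
    bse: pd.Series
    or_: pd.Series
    ci_low: pd.Series
    ci_high: pd.Series
    pvalues: pd.Series
    loglik: float
    converged: bool
    separation_flags: pd.Series

    def summary_frame(self) -> pd.DataFrame:
        df = pd.DataFrame(
            {
                "coef": self.params,
                "se": self.bse,
                "odds_ratio": self.or_,
                "ci_low": self.ci_low,
                "ci_high": self.ci_high,
                "p": self.pvalues,
                "separated": self.separation_flags,
            }
        )
        df.loc[df["separated"], ["odds_ratio", "ci_low", "ci_high"]] = np.nan
        return df


def logistic_fit(
    design: pd.DataFrame, outcome, max_iter: int = 100, tol: float = 1e-8
) -> LogisticFit:
    """Binary logistic regression by iteratively reweighted least squares.

    An intercept is always added.  Coefficients whose magnitude exceeds 10
    with a standard error above 50 are flagged as separated; their odds
    ratios are reported as undefined in :meth:`LogisticFit.summary_frame`
    (the Wald p-value near 1 is kept, mirroring how statistical packages
    print unresolved separation).
    """
    y = np.asarray(outcome).astype(float)
    if len(np.unique(y)) < 2:
        raise ValueError("outcome must contain both classes")
    X = sm.add_constant(design.astype(float), has_constant="add")
    model = sm.GLM(y, X, family=sm.families.Binomial())
    with np.errstate(all="ignore"):
        res = model.fit(maxiter=max_iter, tol=tol)
    params = res.params
    bse = res.bse
    flags = (params.abs() > SEPARATION_COEF) & (bse > SEPARATION_SE)
    converged = bool(getattr(res, "converged", True))
    if not converged:
        logger.warning("logistic regression did not converge")
    with np.errstate(over="ignore"):
        or_ = np.exp(params)
        ci_low = np.exp(params - Z95 * bse)
        ci_high = np.exp(params + Z95 * bse)
    return LogisticFit(
        params=params,
        bse=bse,
        or_=or_,
        ci_low=ci_low,
        ci_high=ci_high,
        pvalues=pd.Series(res.pvalues, index=params.index),
        loglik=float(res.llf),
        converged=converged,
        separation_flags=flags,
    )


STAGE_LEVELS = ["IA", "IB", "IIA", "IIB", "IIIA", "IIIB"]


def _design_columns(clinical: pd.DataFrame, variables: list[str]) -> pd.DataFrame:
    """Expand the named clinical variables into a numeric design matrix.

    Age is continuous; sex, histology (adenocarcinoma vs. rest) are single
    indicators; stage expands to indicators against reference level IA.
    """
    cols = {}
    for var in variables:
        if var == "age":
            cols["age"] = clinical["age"].astype(float)
        elif var == "sex":
            cols["sex_female"] = (clinical["sex"] == "female").astype(float)
        elif var == "histology":
            cols["adenocarcinoma"] = (
                clinical["histology"] == "adenocarcinoma"
            ).astype(float)
        elif var == "stage":
            for lev in STAGE_LEVELS[1:]:
                cols[f"stage_{lev}"] = (clinical["stage"] == lev).astype(float)
        elif var == "ps":
            cols["ps"] = clinical["ps"].astype(float)
        else:
            cols[var] = clinical[var].astype(float)
    return pd.DataFrame(cols, index=clinical.index)


DENSITY_VARIABLES = [
    "nrf2_ck_density_whole",
    "nrf2_ck_density_tumor",
    "nrf2_ck_density_stroma",
    "trxr1_ck_density_whole",
    "trxr1_ck_density_tumor",
    "trxr1_ck_density_stroma",
]
CLINICAL_VARIABLES = ["age", "sex", "histology", "stage"]

OUTCOMES = {
    "any_relapse": lambda s: s != "none",
    "cns_relapse": lambda s: s == "CNS",
    "non_cns_relapse": lambda s: ~s.isin(["none", "CNS"]),
}


def relapse_screens(
    density_labels: pd.DataFrame,
    clinical: pd.DataFrame,
    multivariate_density: str = "nrf2_ck_density_whole",
) -> dict:
    """Univariate screen plus the multivariate CNS-relapse model.

    ``density_labels`` holds per-patient boolean high/low indicators (one
    column per dichotomized density variable).  Patients with missing
    relapse site are excluded.  For each outcome, every density indicator
    and clinical covariate is screened univariately; the multivariate model
    combines the chosen density with age, histology and stage.

    Returns a dict with a tidy univariate report (one row per variable per
    outcome: OR, CI, p) and the multivariate :class:`LogisticFit`.
    """
    clin = clinical.dropna(subset=["relapse_site"]).copy()
    labels = density_labels.reindex(clin.index)
    rows = []
    fits: dict[str, dict[str, LogisticFit]] = {}
    avail_ps = ["ps"] if "ps" in clin.columns else []
    for outcome_name, fn in OUTCOMES.items():
        y = fn(clin["relapse_site"]).astype(int)
        fits[outcome_name] = {}
        for var in list(labels.columns) + CLINICAL_VARIABLES + avail_ps:
            if var in labels.columns:
                X = labels[[var]].astype(float)
            else:
                X = _design_columns(clin, [var])
            try:
                fit = logistic_fit(X, y)
            except ValueError as exc:
                logger.warning("skipping %s vs %s: %s", var, outcome_name, exc)
                continue
            fits[outcome_name][var] = fit
            frame = fit.summary_frame().drop(index="const")
            for coef, r in frame.iterrows():
                rows.append(
                    {
                        "outcome": outcome_name,
                        "variable": var,
                        "term": coef,
                        "odds_ratio": r["odds_ratio"],
                        "ci_low": r["ci_low"],
                        "ci_high": r["ci_high"],
                        "p": r["p"],
                        "separated": bool(r["separated"]),
                    }
                )
    univariate = pd.DataFrame(rows)

    y_cns = OUTCOMES["cns_relapse"](clin["relapse_site"]).astype(int)
    X_multi = _design_columns(clin, ["age", "histology", "stage"])
    X_multi.insert(0, multivariate_density, labels[multivariate_density].astype(float))
    multivariate = logistic_fit(X_multi, y_cns)
    return {
        "univariate": univariate,
        "multivariate": multivariate,
        "fits": fits,
    }
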