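"""Overall-survival estimation and group comparison.

Kaplan–Meier product-limit curves per group and the two-group log-rank
test, as used to compare overall survival of patients whose first relapse
was in the central nervous system against everyone else (non-relapsed and
otherwise-relapsed patients pooled).  Estimation is delegated to
``lifelines``; this module fixes the tie convention (events before
censorings at equal times, which lifelines shares) and the reporting style
(p-values below 1e-4 render as "<0.0001" while full precision is kept in
structured output).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from lifelines import KaplanMeierFitter
from lifelines.statistics import multivariate_logrank_test


@dataclass
class SurvivalCurve:
    group: str
    times: np.ndarray  # ordered event times (months)
    survival: np.ndarray  # S(t) just after each time
    at_risk: np.ndarray

    def as_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "group": self.group,
                "time_months": self.times,
                "survival": self.survival,
                "at_risk": self.at_risk,
            }
        )


def km_estimate(times, events, group) -> dict[str, SurvivalCurve]:
    """Product-limit survival curve for each group label."""
    t = np.asarray(times, dtype=float)
    e = np.asarray(events, dtype=bool)
    g = np.asarray(group)
    if t.size == 0:
        raise ValueError("no subjects")
    if (t < 0).any():
        raise ValueError("negative survival times")
    curves = {}
    for label in pd.unique(g):
        mask = g == label
        if not mask.any():
            raise ValueError(f"empty group {label!r}")
        kmf = KaplanMeierFitter()
        kmf.fit(t[mask], e[mask])
        ev_times = kmf.event_table.index.values.astype(float)
        surv = kmf.survival_function_["KM_estimate"].values
        at_risk = kmf.event_table["at_risk"].values
        # drop the t=0 anchor row unless an event occurred at 0
        keep = (ev_times > 0) | (kmf.event_table["observed"].values > 0)
        curves[str(label)] = SurvivalCurve(
            group=str(label),
            times=ev_times[keep],
            survival=surv[keep],
            at_risk=at_risk[keep],
        )
    return curves


def logrank_test(times, events, group) -> tuple[float, float]:
    """Two-group log-rank chi-squared statistic and p-value."""
    t = np.asarray(times, dtype=float)
    e = np.asarray(events, dtype=bool)
    g = np.asarray(group)
    if len(pd.unique(g)) < 2:
        raise ValueError("log-rank test needs at least two groups")
    res = multivariate_logrank_test(t, g, e)
    return float(res.test_statistic), float(res.p_value)


def format_p(p: float) -> str:
    """Render a p-value the way clinical reports print it."""
    return "<0.0001" if p < 1e-4 else f"{p:.4g}"
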