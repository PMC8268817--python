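"""Two-component intensity mixture: chi-squared noise plus normal signal.

Marker positivity in multiplexed immunofluorescence is decided per marker by
pooling every segmented cell's mean intensity and fitting a two-component
mixture in which the marker-negative (noise) population follows a scaled
chi-squared distribution and the marker-positive population is normal.  The
positivity threshold is placed at the intersection of the two weighted
component densities — the intensity at which a cell becomes more likely to
have come from the signal component than from the noise component.

The scaled chi-squared with ``df`` degrees of freedom and scale ``s`` is the
gamma distribution with shape ``df/2`` and scale ``2 s``; that equivalence is
used throughout so the M-step can exploit the closed-form gamma likelihood in
its sufficient statistics.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, asdict, field

import numpy as np
from scipy import optimize, special, stats

logger = logging.getLogger(__name__)

_MIN_CELLS = 100


class InsufficientDataError(ValueError):
    """Fewer cells than the minimum required for a stable mixture fit."""


class DegenerateInputError(ValueError):
    """Input carries no information to separate two components."""


@dataclass
class MixtureFit:
    """Fitted noise/signal mixture for one marker.

    Attributes
    ----------
    pi_noise : float
        Mixing weight of the chi-squared noise component, in (0, 1).
    chi2_df, chi2_scale : float
        Degrees of freedom (continuous) and scale of the noise component.
    mu_pos, sigma_pos : float
        Mean and standard deviation of the normal signal component.
    threshold : float
        Positivity threshold (crossing of the weighted densities); filled
        by :func:`find_threshold`.
    loglik : float
        Final observed-data log-likelihood.
    n_iter : int
        EM iterations performed.
    converged : bool
        Whether the log-likelihood change fell below tolerance.
    threshold_fallback : bool
        True when no density crossing existed and the threshold fell back
        to the noise component's upper 1e-4 tail quantile.
    """

    pi_noise: float
    chi2_df: float
    chi2_scale: float
    mu_pos: float
    sigma_pos: float
    threshold: float = float("nan")
    loglik: float = float("nan")
    n_iter: int = 0
    converged: bool = False
    threshold_fallback: bool = False

    @property
    def pi_pos(self) -> float:
        return 1.0 - self.pi_noise

    def noise_pdf(self, x):
        a, theta = self.chi2_df / 2.0, 2.0 * self.chi2_scale
        return stats.gamma.pdf(x, a, scale=theta)

    def signal_pdf(self, x):
        return stats.norm.pdf(x, self.mu_pos, self.sigma_pos)

    def mixture_pdf(self, x):
        return self.pi_noise * self.noise_pdf(x) + self.pi_pos * self.signal_pdf(x)

    def to_json(self) -> str:
        d = asdict(self)
        d["pi_pos"] = self.pi_pos
        return json.dumps(d, indent=2)

    @classmethod
    def from_json(cls, text: str) -> "MixtureFit":
        d = json.loads(text)
        d.pop("pi_pos", None)
        return cls(**d)


def _gamma_mle(w: np.ndarray, x: np.ndarray, logx: np.ndarray) -> tuple[float, float]:
    """Weighted gamma MLE via the profile equation log(a) - psi(a) = c.

    Returns (shape, scale).  Falls back to moment matching when the
    weighted log-moment constraint is degenerate.
    """
    W = w.sum()
    mean = float(w @ x) / W
    c = np.log(mean) - float(w @ logx) / W
    if not np.isfinite(c) or c <= 0:
        var = float(w @ (x - mean) ** 2) / W
        a = mean**2 / max(var, 1e-12)
        return a, mean / a

    def f(a):
        return np.log(a) - special.digamma(a) - c

    # log(a) - psi(a) is decreasing from +inf to 0; bracket around 1/(2c)
    lo, hi = 1e-8, max(1.0, 1.0 / c)
    while f(hi) > 0:
        hi *= 2.0
        if hi > 1e12:
            break
    a = optimize.brentq(f, lo, hi, xtol=1e-12, rtol=1e-12)
    return a, mean / a


def _initialize(x: np.ndarray) -> MixtureFit:
    """Deterministic data-driven start.

    Mixing weight from the fraction below the 75th percentile; noise
    moments from the lower half, signal moments from the upper quartile.
    """
    q75 = np.quantile(x, 0.75)
    pi_noise = float(np.clip(np.mean(x < q75), 0.05, 0.95))
    lower = x[x <= np.median(x)]
    upper = x[x > q75]
    m, v = float(lower.mean()), float(lower.var())
    v = max(v, 1e-8)
    a = max(m**2 / v, 0.05)
    theta = m / a if a > 0 else 1.0
    return MixtureFit(
        pi_noise=pi_noise,
        chi2_df=2.0 * a,
        chi2_scale=theta / 2.0,
        mu_pos=float(upper.mean()),
        sigma_pos=max(float(upper.std()), 1e-6),
    )


def _em(x, init, tol, max_iter):
    logx = np.log(np.maximum(x, 1e-300))
    pi_n = init.pi_noise
    a, theta = init.chi2_df / 2.0, 2.0 * init.chi2_scale
    mu, sigma = init.mu_pos, init.sigma_pos

    loglik_prev = -np.inf
    trace = []
    converged = False
    it = 0
    for it in range(1, max_iter + 1):
        log_noise = np.log(pi_n) + stats.gamma.logpdf(x, a, scale=theta)
        log_sig = np.log1p(-pi_n) + stats.norm.logpdf(x, mu, sigma)
        both = np.column_stack([log_noise, log_sig])
        log_tot = special.logsumexp(both, axis=1)
        loglik = float(log_tot.sum())
        trace.append(loglik)
        if abs(loglik - loglik_prev) < tol:
            converged = True
            break
        loglik_prev = loglik

        r_noise = np.exp(log_noise - log_tot)  # responsibility of noise
        r_sig = 1.0 - r_noise

        w_n, w_s = r_noise.sum(), r_sig.sum()
        pi_n = float(np.clip(w_n / x.size, 1e-6, 1 - 1e-6))
        mu = float(r_sig @ x / w_s)
        sigma = float(np.sqrt(max(r_sig @ (x - mu) ** 2 / w_s, 1e-12)))
        if w_n > 1e-8:
            a, theta = _gamma_mle(r_noise, x, logx)

    fit = MixtureFit(
        pi_noise=float(pi_n),
        chi2_df=float(2.0 * a),
        chi2_scale=float(theta / 2.0),
        mu_pos=float(mu),
        sigma_pos=float(sigma),
        loglik=trace[-1],
        n_iter=it,
        converged=converged,
    )
    return fit, trace


def fit_mixture(
    intensities,
    init: MixtureFit | None = None,
    tol: float = 1e-8,
    max_iter: int = 500,
    return_trace: bool = False,
):
    """Fit the chi-squared + normal mixture by EM over pooled cells.

    The E-step assigns each cell a posterior responsibility for the noise
    component; the M-step updates the normal parameters in closed form and
    the scaled chi-squared (gamma-form) parameters by solving the weighted
    gamma likelihood equation.  Iteration stops when the observed-data
    log-likelihood changes by less than ``tol``.

    Parameters
    ----------
    intensities : array-like
        Non-negative per-cell intensities, pooled over all samples; at
        least 100 finite values required.
    init : MixtureFit, optional
        Starting parameters; defaults to a deterministic moment-based start.
    return_trace : bool
        Also return the per-iteration log-likelihood trace.

    Raises
    ------
    InsufficientDataError, DegenerateInputError
    """
    x = np.asarray(intensities, dtype=float)
    x = x[np.isfinite(x)]
    if x.size < _MIN_CELLS:
        raise InsufficientDataError(
            f"mixture fit needs at least {_MIN_CELLS} cells, got {x.size}"
        )
    if np.any(x < 0):
        raise ValueError("intensities must be non-negative")
    if np.ptp(x) == 0:
        raise DegenerateInputError("all intensities identical; mixture undefined")
    if tol <= 0:
        raise ValueError("tol must be positive")
    # strictly zero intensities carry no gamma likelihood; nudge them
    x = np.maximum(x, 1e-12)

    start = init if init is not None else _initialize(x)
    fit, trace = _em(x, start, tol, max_iter)
    if not fit.converged and init is None:
        # fixed fallback restarts: a more separated configuration, and a
        # near-degenerate one for data with (almost) no noise component
        alt = _initialize(x)
        alt.pi_noise = 0.5
        alt.mu_pos = float(np.quantile(x, 0.9))
        degen = MixtureFit(
            pi_noise=0.05,
            chi2_df=2.0,
            chi2_scale=max(float(np.quantile(x, 0.1)) / 2.0, 1e-6),
            mu_pos=float(x.mean()),
            sigma_pos=max(float(x.std()), 1e-6),
        )
        for cand in (alt, degen):
            fit2, trace2 = _em(x, cand, tol, max_iter)
            if fit2.loglik > fit.loglik:
                fit, trace = fit2, trace2
    return (fit, trace) if return_trace else fit


def density_crossing(
    noise_pdf,
    signal_pdf,
    pi_noise: float,
    interval: tuple[float, float],
    signal_mode: float,
    xtol: float = 1e-8,
):
    """Largest root of ``pi_noise*noise_pdf - (1-pi_noise)*signal_pdf`` below
    ``signal_mode`` in ``interval``, by bracketing plus bisection.

    Returns None when no sign change exists in the interval.
    """
    lo, hi = interval
    hi = min(hi, signal_mode)
    if hi <= lo:
        return None

    def g(x):
        return pi_noise * noise_pdf(x) - (1.0 - pi_noise) * signal_pdf(x)

    grid = np.linspace(lo, hi, 2048)
    vals = g(grid)
    sign = np.sign(vals)
    idx = np.nonzero(np.diff(sign) != 0)[0]
    if idx.size == 0:
        return None
    i = idx[-1]  # largest crossing below the signal mode
    return float(optimize.bisect(g, grid[i], grid[i + 1], xtol=xtol))


def find_threshold(
    fit: MixtureFit, search_interval: tuple[float, float] | None = None
) -> float:
    """Positivity threshold at the intersection of the weighted densities.

    Searches between the noise component's mode and the signal mean for the
    crossing where the weighted signal density overtakes the weighted noise
    density (the largest root below ``mu_pos``).  When the components never
    cross — one fully dominates — falls back to the intensity whose noise
    upper-tail probability is 1e-4 and flags the fit.

    The returned threshold is also stored on ``fit``.
    """
    if not (0.0 < fit.pi_noise < 1.0):
        raise ValueError("pi_noise must be strictly inside (0, 1)")
    a, theta = fit.chi2_df / 2.0, 2.0 * fit.chi2_scale
    noise_mode = (a - 1.0) * theta if a > 1.0 else 0.0
    if search_interval is None:
        search_interval = (noise_mode + 1e-9, fit.mu_pos)
    root = density_crossing(
        fit.noise_pdf, fit.signal_pdf, fit.pi_noise, search_interval, fit.mu_pos
    )
    if root is None:
        root = float(stats.gamma.isf(1e-4, a, scale=theta))
        fit.threshold_fallback = True
        logger.warning(
            "no density crossing in (%.4g, %.4g); falling back to noise "
            "upper-tail quantile %.4g",
            search_interval[0],
            search_interval[1],
            root,
        )
    fit.threshold = root
    return root


def classify_cells(intensities, threshold: float) -> np.ndarray:
    """Boolean positivity call per cell: positive iff intensity > threshold.

    The boundary is negative by convention.  Non-finite intensities are
    classified negative and their count logged; callers that must drop such
    rows should filter beforehand.
    """
    if not np.isfinite(threshold):
        raise ValueError("threshold must be finite")
    x = np.asarray(intensities, dtype=float)
    finite = np.isfinite(x)
    n_bad = int((~finite).size - finite.sum())
    if n_bad:
        logger.warning("%d non-finite intensities classified negative", n_bad)
    out = np.zeros(x.shape, dtype=bool)
    out[finite] = x[finite] > threshold
    return out
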