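import numpy as np
import pytest

from tmaquant import mixture as mix

RECOVERY_TRUTH = dict(pi_noise=0.7, chi2_df=2.0, chi2_scale=1.0, mu_pos=8.0,
                      sigma_pos=1.5)


def draw_recovery_sample(seed: int, n: int = 50_000):
    """Sample from the canonical recovery mixture, returning intensities and
    the generating component labels (True = signal)."""
    rng = np.random.default_rng(seed)
    t = RECOVERY_TRUTH
    signal = rng.random(n) >= t["pi_noise"]
    x = np.where(
        signal,
        rng.normal(t["mu_pos"], t["sigma_pos"], n),
        t["chi2_scale"] * rng.chisquare(t["chi2_df"], n),
    )
    return np.maximum(x, 0.0), signal


def grid_scan_threshold(fit, lo, hi, n=10**6):
    """Brute-force density-crossing oracle: largest sign change of the
    weighted density difference on an n-point grid."""
    x = np.linspace(lo, hi, n)
    g = fit.pi_noise * fit.noise_pdf(x) - fit.pi_pos * fit.signal_pdf(x)
    idx = np.nonzero(np.diff(np.sign(g)) != 0)[0]
    return None if idx.size == 0 else float(x[idx[-1]])


@pytest.fixture(scope="session")
def recovery_fit():
    """One EM fit of the canonical recovery sample, shared across tests."""
    x, signal = draw_recovery_sample(seed=20240901)
    fit, trace = mix.fit_mixture(x, return_trace=True)
    mix.find_threshold(fit)
    return {"x": x, "signal": signal, "fit": fit, "trace": trace}
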