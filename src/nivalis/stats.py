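"""Posterior summary helpers shared across the package.

Point estimates are posterior modes from a Gaussian-kernel density
estimate; intervals are highest-posterior-density (HPD) intervals; tail
probabilities follow the usual MCMC convention
``p = 2 min(Pr(x > v), Pr(x < v))`` bounded below by ``1 / n_samples``.
"""

from __future__ import annotations

import numpy as np
from scipy.stats import gaussian_kde

__all__ = [
    "posterior_mode",
    "hpd_interval",
    "pmcmc",
    "tail_prob",
    "lag1_autocorr",
    "split_rhat",
]


def split_rhat(chains: np.ndarray) -> float:
    """Split-chain potential scale reduction factor (R-hat).

    ``chains`` has shape (n_chains, n_draws); each chain is split in two
    before the usual between/within variance comparison.
    """
    x = np.asarray(chains, dtype=float)
    if x.ndim != 2:
        raise ValueError("chains must be (n_chains, n_draws)")
    half = x.shape[1] // 2
    if half < 2:
        return float("nan")
    xs = x[:, : 2 * half].reshape(x.shape[0] * 2, half)
    W = xs.var(axis=1, ddof=1).mean()
    B = half * xs.mean(axis=1).var(ddof=1)
    if W <= 0:
        return 1.0
    var_plus = (half - 1) / half * W + B / half
    return float(np.sqrt(var_plus / W))


def posterior_mode(samples, n_grid: int = 512, strict: bool = False) -> float:
    """Mode of a kernel density estimate over posterior draws.

    Uses a Gaussian KDE with Scott's bandwidth evaluated on a regular
    grid spanning the sample range; the grid argmax is returned.  With
    fewer than 100 draws the KDE mode is imprecise: a warning is issued,
    escalated to an error when ``strict``.
    """
    x = np.asarray(samples, dtype=float).ravel()
    x = x[np.isfinite(x)]
    if x.size == 0:
        raise ValueError("no finite samples")
    if x.size < 100:
        msg = f"posterior_mode called with only {x.size} draws"
        if strict:
            raise ValueError(msg)
        import warnings

        warnings.warn(msg, stacklevel=2)
    if np.ptp(x) == 0:
        return float(x[0])
    kde = gaussian_kde(x)
    grid = np.linspace(x.min(), x.max(), n_grid)
    return float(grid[np.argmax(kde(grid))])


def hpd_interval(samples, prob: float = 0.95) -> tuple[float, float]:
    """Narrowest interval containing ``prob`` of the draws."""
    x = np.sort(np.asarray(samples, dtype=float).ravel())
    n = x.size
    if n == 0:
        raise ValueError("no samples")
    m = max(int(np.ceil(prob * n)), 1)
    if m >= n:
        return float(x[0]), float(x[-1])
    widths = x[m:] - x[: n - m]
    j = int(np.argmin(widths))
    return float(x[j]), float(x[j + m])


def tail_prob(samples, value: float = 0.0, direction: str = "less") -> float:
    """One-sided posterior probability of being below/above ``value``."""
    x = np.asarray(samples, dtype=float).ravel()
    p = np.mean(x < value) if direction == "less" else np.mean(x > value)
    return float(p)


def pmcmc(samples, value: float = 0.0) -> float:
    """Two-sided MCMC p-value against ``value``."""
    x = np.asarray(samples, dtype=float).ravel()
    p = 2.0 * min(np.mean(x > value), np.mean(x < value))
    return float(max(p, 1.0 / x.size))


def lag1_autocorr(chain) -> float:
    x = np.asarray(chain, dtype=float).ravel()
    if x.size < 3 or np.std(x) == 0:
        return 0.0
    a = x[:-1] - x[:-1].mean()
    b = x[1:] - x[1:].mean()
    denom = np.sqrt((a**2).sum() * (b**2).sum())
    return float((a * b).sum() / denom) if denom > 0 else 0.0
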