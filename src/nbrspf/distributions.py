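"""NB2 / NB1 distribution helpers.

The NB2 parameterization used throughout the package is the ecologists'
(mu, theta) form: a count Y has mean ``u`` and variance ``u + u**2/theta``,
so smaller ``theta`` means more overdispersion and ``theta -> inf`` recovers
the Poisson.  scipy's :class:`~scipy.stats.nbinom` uses (n, p); the mapping
is ``n = theta``, ``p = theta / (theta + u)``.
"""

from __future__ import annotations

import numpy as np
from scipy import stats

__all__ = [
    "nb2_pmf",
    "nb2_logpmf",
    "nb2_cdf",
    "nb2_tail",
    "nb2_rvs",
    "nb2_variance",
    "nb1_variance",
]


def _check_theta(theta) -> None:
    if not np.all(np.asarray(theta) > 0):
        raise ValueError("dispersion theta must be > 0")


def nb2_pmf(y, u, theta):
    """P(Y = y) for an NB2 count with mean ``u`` and dispersion ``theta``.

    The zero probability has the closed form ``(theta/(theta+u))**theta``;
    at ``u == 0`` the distribution is degenerate at zero.
    """
    _check_theta(theta)
    y = np.asarray(y)
    u = np.asarray(u, dtype=float)
    if np.any(u < 0):
        raise ValueError("mean u must be >= 0")
    p = theta / (theta + u)
    out = stats.nbinom.pmf(y, theta, p)
    # degenerate mean-zero case: point mass at y = 0
    out = np.where(u == 0, np.where(y == 0, 1.0, 0.0), out)
    return out[()] if out.ndim == 0 else out


def nb2_logpmf(y, u, theta):
    _check_theta(theta)
    p = theta / (theta + np.asarray(u, dtype=float))
    return stats.nbinom.logpmf(y, theta, p)


def nb2_cdf(y, u, theta):
    _check_theta(theta)
    p = theta / (theta + np.asarray(u, dtype=float))
    return stats.nbinom.cdf(y, theta, p)


def nb2_tail(y_min, u, theta):
    """P(Y > y_min), via the stable survival function."""
    _check_theta(theta)
    u = np.asarray(u, dtype=float)
    if np.any(u < 0):
        raise ValueError("mean u must be >= 0")
    p = theta / (theta + u)
    out = stats.nbinom.sf(y_min, theta, p)
    out = np.where(u == 0, 0.0, out)
    return out[()] if np.ndim(out) == 0 else out


def nb2_rvs(u, theta, size=None, rng=None):
    """Seeded NB2 draws (``rng`` is a numpy Generator or a seed)."""
    _check_theta(theta)
    rng = np.random.default_rng(rng)
    u = np.asarray(u, dtype=float)
    p = theta / (theta + u)
    if size is None:
        size = u.shape if u.shape else None
    return rng.negative_binomial(theta, p, size=size)


def nb2_variance(u, theta):
    """var[Y] = u + u^2/theta (NB2: overdispersion grows with the mean squared)."""
    _check_theta(theta)
    u = np.asarray(u, dtype=float)
    return (u + u**2 / theta)[()]


def nb1_variance(u, theta):
    """var[Y] = u + u/theta (NB1: overdispersion proportional to the mean).

    Provided for comparison only; fitting uses NB2 throughout.
    """
    _check_theta(theta)
    u = np.asarray(u, dtype=float)
    return (u + u / theta)[()]
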