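"""Inverse-Gaussian first-passage-time density for a drifting accumulator.

A linear stochastic accumulator with drift ``v * D``, noise ``sigma`` and
absorbing boundary ``b`` first crosses the boundary at a time distributed
Inverse-Gaussian with ``mu = b / (v * D)`` and ``lam = b**2 / sigma**2``
(time in ms throughout).

The density and distribution function are written out from the model
equations; sampling goes through scipy's generator (Michael-Schucany-Haas
transform) so simulator and likelihood remain independent code routes.

Convention for ``D = 0`` (``mu`` undefined): the accumulator never finishes
-- density and CDF are identically zero, survival is one.
"""

from __future__ import annotations

import numpy as np
from scipy import stats
from scipy.special import log_ndtr, ndtr

__all__ = [
    "invgauss_logpdf",
    "invgauss_pdf",
    "invgauss_cdf",
    "invgauss_logsf",
    "invgauss_rvs",
]

_LOG_2PI = np.log(2.0 * np.pi)


def _prepare(t, mu, lam):
    t = np.asarray(t, dtype=float)
    mu = np.asarray(mu, dtype=float)
    lam = np.asarray(lam, dtype=float)
    if np.any(lam <= 0):
        raise ValueError("lam must be > 0")
    if np.any(mu < 0):
        raise ValueError("mu must be >= 0 (np.inf encodes a never-finishing accumulator)")
    return t, mu, lam


def invgauss_logpdf(t, mu, lam):
    """Log density of the first-passage time at ``t`` (per ms)."""
    t, mu, lam = _prepare(t, mu, lam)
    ok = (t > 0) & np.isfinite(mu) & (mu > 0)
    ts = np.where(ok, t, 1.0)
    mus = np.where(np.isfinite(mu) & (mu > 0), mu, 1.0)
    out = 0.5 * (np.log(lam) - _LOG_2PI - 3.0 * np.log(ts)) - lam * (ts - mus) ** 2 / (
        2.0 * mus**2 * ts
    )
    return np.where(ok, out, -np.inf)


def invgauss_pdf(t, mu, lam):
    return np.exp(invgauss_logpdf(t, mu, lam))


def invgauss_cdf(t, mu, lam):
    """Distribution function; monotone to 1 (0 for ``t <= 0`` or ``mu`` infinite)."""
    t, mu, lam = _prepare(t, mu, lam)
    ok = (t > 0) & np.isfinite(mu) & (mu > 0)
    ts = np.where(ok, t, 1.0)
    mus = np.where(np.isfinite(mu) & (mu > 0), mu, 1.0)
    rt = np.sqrt(lam / ts)
    # second term computed in log space: exp(2*lam/mu) overflows on its own
    out = ndtr(rt * (ts / mus - 1.0)) + np.exp(2.0 * lam / mus + log_ndtr(-rt * (ts / mus + 1.0)))
    return np.where(ok, np.clip(out, 0.0, 1.0), 0.0)


def invgauss_logsf(t, mu, lam):
    """Log survival function ``log(1 - F(t))`` (0 where the accumulator
    cannot finish)."""
    t, mu, lam = _prepare(t, mu, lam)
    sf = 1.0 - invgauss_cdf(t, mu, lam)
    with np.errstate(divide="ignore"):
        return np.log(np.clip(sf, 0.0, 1.0))


def invgauss_rvs_crn(mu, lam, chi, u):
    """Michael-Schucany-Haas draw from fixed auxiliary randomness.

    ``chi`` is a chi-square(1) draw and ``u`` a uniform draw per variate;
    holding them fixed makes the sample a deterministic, smooth function of
    ``(mu, lam)`` (common random numbers), which fixed-point constructions
    rely on. Infinite ``mu`` yields an infinite passage time.
    """
    mu = np.asarray(mu, dtype=float)
    lam = np.asarray(lam, dtype=float)
    chi = np.asarray(chi, dtype=float)
    u = np.asarray(u, dtype=float)
    fin = np.isfinite(mu) & (mu > 0)
    mus = np.where(fin, mu, 1.0)
    w = mus * chi
    x1 = mus + (w * mus - mus * np.sqrt(w * (4.0 * lam + w))) / (2.0 * lam)
    x1 = np.maximum(x1, 1e-300)
    out = np.where(u <= mus / (mus + x1), x1, mus**2 / x1)
    return np.where(fin, out, np.inf)


def invgauss_rvs(mu, lam, size=None, rng=None):
    """Draw first-passage times (scipy generator; independent of the
    closed-form density above)."""
    mu = np.asarray(mu, dtype=float)
    lam = np.asarray(lam, dtype=float)
    rng = np.random.default_rng(rng)
    return stats.invgauss.rvs(mu / lam, scale=lam, size=size, random_state=rng)
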