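"""Gaze-weighted linear accumulator model (GLAM, relative accumulation).

All seen items race from trial onset to a common boundary ``b = 1``. Each
item's *absolute* decision signal is its gaze-weighted value

    ``A_i = g_i * (l_i + zeta) + (1 - g_i) * gamma * l_i``

with ``g_i`` the item's share of total trial time. The *relative* signal
``R_i = A_i - max_{j != i} A_j`` is squashed through a logistic with
sensitivity ``tau``, ``D_i = 1 / (1 + exp(-tau * R_i))``, which keeps every
drift positive while concentrating discrimination near ``R = 0``.
First-passage times are Inverse-Gaussian (``mu_i = b / (v * D_i)``,
``lam = b**2 / sigma**2``) and the winner's density is corrected for the
survival of the other seen accumulators. Passive gaze is ``gamma = 1,
zeta = 0``.

Parameters: ``v`` in [1e-7, 0.005], ``sigma`` in [1e-7, 0.05], ``tau`` in
[0, 10], ``gamma`` in [0, 1], ``zeta`` in [0, 10].
"""

from __future__ import annotations

import numpy as np

from ..data import ValidationError
from .base import TrialBatch, TrialModelInput, mix_loglik
from .iam import _ig_params
from .invgauss import invgauss_logpdf, invgauss_logsf, invgauss_rvs

__all__ = [
    "GLAM_PARAM_NAMES",
    "GLAM_PRIOR_BOX",
    "glam_signals",
    "glam_batch_loglik",
    "glam_trial_loglik",
    "glam_simulate",
]

GLAM_PARAM_NAMES = ("v", "sigma", "tau", "gamma", "zeta")
GLAM_PRIOR_BOX = {
    "v": (1e-7, 0.005),
    "sigma": (1e-7, 0.05),
    "tau": (0.0, 10.0),
    "gamma": (0.0, 1.0),
    "zeta": (0.0, 10.0),
}


def glam_signals(g, values, gamma, zeta, tau, seen=None):
    """Absolute (``A``), relative (``R``) and drift (``D``) decision signals.

    Works on 1-D per-item arrays or batched 2-D arrays (trials x items).
    Unseen items get ``A = R = D = 0`` and are excluded from the other
    items' maxima. A trial with a single seen item has ``R = 0``
    (``D = 1/2``): the max over no other item is taken as the item's own
    signal, keeping the trial usable.
    """
    one_d = np.asarray(g).ndim == 1
    g = np.atleast_2d(np.asarray(g, dtype=float))
    values = np.atleast_2d(np.asarray(values, dtype=float))
    seen_m = (
        np.ones(g.shape, dtype=bool) if seen is None else np.atleast_2d(np.asarray(seen, bool))
    )
    if g.shape[1] < 2:
        raise ValidationError("glam_signals needs at least two items")
    A = np.where(seen_m, g * (values + zeta) + (1.0 - g) * gamma * values, -np.inf)
    order = np.argsort(A, axis=1, kind="stable")
    rows = np.arange(A.shape[0])
    top = A[rows, order[:, -1]]
    second = A[rows, order[:, -2]]
    max_others = np.broadcast_to(top[:, None], A.shape).copy()
    max_others[rows, order[:, -1]] = second
    # a single seen item has no competitor: R := 0 (drift 1/2)
    R = np.where(seen_m & np.isfinite(max_others), A - max_others, 0.0)
    A = np.where(seen_m, A, 0.0)
    D = np.where(seen_m, 1.0 / (1.0 + np.exp(-tau * R)), 0.0)
    if one_d:
        return A[0], R[0], D[0]
    return A, R, D


def glam_batch_loglik(batch: TrialBatch, params: dict) -> np.ndarray:
    """Per-trial log mixture likelihood, vectorized over a batch."""
    v, sigma = params["v"], params["sigma"]
    _, _, D = glam_signals(
        batch.g_total, batch.values, params["gamma"], params["zeta"], params["tau"],
        seen=batch.seen,
    )
    mu, lam = _ig_params(D, v, sigma)
    x = np.broadcast_to(batch.rt[:, None], mu.shape)  # all accumulators start at t = 0
    rows = np.arange(batch.n_trials)
    logf = invgauss_logpdf(x, mu, lam)[rows, batch.choice]
    logsf = np.where(batch.seen, invgauss_logsf(x, mu, lam), 0.0)
    logsf[rows, batch.choice] = 0.0
    p = np.exp(logf + logsf.sum(axis=1))
    return mix_loglik(p, batch.u)


def glam_trial_loglik(
    trial: TrialModelInput, params: dict, rt_range_ms: float = None
) -> float:
    return float(glam_batch_loglik(TrialBatch([trial], rt_range_ms), params)[0])


def glam_simulate(trial: TrialModelInput, params: dict, rng, n_sims: int = 1):
    """Race simulation: draw an Inverse-Gaussian first-passage time per seen
    item (no onset offsets -- all accumulators start at trial onset); the
    shortest FPT determines choice and RT. Returns ``(choices, rts)``."""
    rng = np.random.default_rng(rng)
    _, _, D = glam_signals(
        trial.g_total, trial.values, params["gamma"], params["zeta"], params["tau"],
        seen=trial.seen,
    )
    racers = np.flatnonzero(trial.seen & (D > 0))
    if not len(racers):
        raise ValidationError("no accumulator can finish (all drifts zero)")
    mu, lam = _ig_params(D[racers], params["v"], params["sigma"])
    fpt = invgauss_rvs(mu[None, :], lam, size=(n_sims, len(racers)), rng=rng)
    win = fpt.argmin(axis=1)
    choices = racers[win]
    # round to the nearest ms: integer RTs then match the density evaluated
    # on the integer grid (midpoint rule)
    rts = np.maximum(np.round(fpt[np.arange(n_sims), win]), 1).astype(np.int64)
    return choices, rts


def glam_joint_density(trial: TrialModelInput, params: dict, t: np.ndarray) -> np.ndarray:
    """Per-ms joint density ``p_i(t)`` (numeric reference for the simulator
    oracle). Shape ``(n_items, len(t))``."""
    _, _, D = glam_signals(
        trial.g_total, trial.values, params["gamma"], params["zeta"], params["tau"],
        seen=trial.seen,
    )
    mu, lam = _ig_params(D, params["v"], params["sigma"])
    x = np.broadcast_to(t[None, :], (trial.n_items, len(t))).astype(float)
    logf = invgauss_logpdf(x, mu[:, None], lam)
    logsf = np.where(trial.seen[:, None], invgauss_logsf(x, mu[:, None], lam), 0.0)
    out = np.zeros((trial.n_items, len(t)))
    for i in np.flatnonzero(trial.seen):
        others = trial.seen.copy()
        others[i] = False
        out[i] = np.exp(logf[i] + logsf[others].sum(axis=0))
    return out
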