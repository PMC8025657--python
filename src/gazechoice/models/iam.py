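"""Independent evidence accumulation model (IAM).

One accumulator per item, started the moment the item is first looked at
(``t0_i``) and racing independently to a common boundary ``b = 1``. The
drift of accumulator *i* is ``v * D_i`` with gaze-weighted decision signal

    ``D_i = g_i * (l_i + zeta) + (1 - g_i) * gamma * l_i``

where ``g_i`` is the fraction of the trial time *remaining after* ``t0_i``
that was spent looking at item *i*. First-passage times are
Inverse-Gaussian with ``mu_i = b / (v * D_i)`` and ``lam = b**2 / sigma**2``;
the trial likelihood is the winner's density at ``rt - t0_i`` times every
other seen accumulator's survival. Unseen items never accumulate and drop
out entirely. Passive gaze is ``gamma = 1, zeta = 0``.

Parameters: ``v`` in [1e-7, 0.005] (1/ms), ``sigma`` in [1e-7, 0.05],
``gamma`` in [0, 1], ``zeta`` in [0, 10].
"""

from __future__ import annotations

import numpy as np

from ..data import ValidationError
from .base import BOUNDARY, TrialBatch, TrialModelInput, mix_loglik
from .invgauss import invgauss_logpdf, invgauss_logsf, invgauss_rvs

__all__ = [
    "IAM_PARAM_NAMES",
    "IAM_PRIOR_BOX",
    "iam_drift",
    "iam_batch_loglik",
    "iam_trial_loglik",
    "iam_simulate",
]

IAM_PARAM_NAMES = ("v", "sigma", "gamma", "zeta")
IAM_PRIOR_BOX = {
    "v": (1e-7, 0.005),
    "sigma": (1e-7, 0.05),
    "gamma": (0.0, 1.0),
    "zeta": (0.0, 10.0),
}


def iam_drift(g_rem, values, gamma, zeta, seen=None):
    """Gaze-weighted decision signals ``D_i``; 0 for unseen items (their
    accumulators never start)."""
    g = np.asarray(g_rem, dtype=float)
    values = np.asarray(values, dtype=float)
    D = g * (values + zeta) + (1.0 - g) * gamma * values
    if seen is None:
        return D
    return np.where(np.asarray(seen, dtype=bool), D, 0.0)


def _ig_params(D, v, sigma):
    with np.errstate(divide="ignore"):
        mu = np.where(D > 0, BOUNDARY / (v * np.maximum(D, 1e-300)), np.inf)
    lam = BOUNDARY**2 / sigma**2
    return mu, lam


def iam_batch_loglik(batch: TrialBatch, params: dict) -> np.ndarray:
    """Per-trial log mixture likelihood, vectorized over a batch."""
    v, sigma = params["v"], params["sigma"]
    D = iam_drift(batch.g_rem, batch.values, params["gamma"], params["zeta"], seen=batch.seen)
    mu, lam = _ig_params(D, v, sigma)
    x = batch.rt[:, None] - batch.t0  # time each accumulator has been running
    rows = np.arange(batch.n_trials)
    logf = invgauss_logpdf(x, mu, lam)[rows, batch.choice]
    logsf = np.where(batch.seen, invgauss_logsf(x, mu, lam), 0.0)
    logsf[rows, batch.choice] = 0.0
    p = np.exp(logf + logsf.sum(axis=1))
    return mix_loglik(p, batch.u)


def iam_trial_loglik(
    trial: TrialModelInput, params: dict, rt_range_ms: float = None
) -> float:
    return float(iam_batch_loglik(TrialBatch([trial], rt_range_ms), params)[0])


def iam_simulate(trial: TrialModelInput, params: dict, rng, n_sims: int = 1):
    """Race simulation: per seen item draw an Inverse-Gaussian first-passage
    time, add the item's observed first-gaze onset ``t0_i``; the smallest
    ``FPT_i + t0_i`` wins (ties to the lowest item index). Items with zero
    drift never finish. Returns ``(choices, rts)``."""
    rng = np.random.default_rng(rng)
    D = iam_drift(trial.g_rem, trial.values, params["gamma"], params["zeta"], seen=trial.seen)
    racers = np.flatnonzero(trial.seen & (D > 0))
    if not len(racers):
        raise ValidationError("no accumulator can finish (all drifts zero)")
    mu, lam = _ig_params(D[racers], params["v"], params["sigma"])
    fpt = invgauss_rvs(mu[None, :], lam, size=(n_sims, len(racers)), rng=rng)
    arrival = fpt + trial.t0[racers][None, :]
    win = arrival.argmin(axis=1)
    choices = racers[win]
    # round to the nearest ms: integer RTs then match the density evaluated
    # on the integer grid (midpoint rule)
    rts = np.maximum(np.round(arrival[np.arange(n_sims), win]), 1).astype(np.int64)
    return choices, rts


def iam_joint_density(trial: TrialModelInput, params: dict, t: np.ndarray) -> np.ndarray:
    """Per-ms joint density ``p_i(t)`` of item *i* winning at time ``t``
    (numeric reference for the simulator oracle). Shape ``(n_items, len(t))``."""
    v, sigma = params["v"], params["sigma"]
    D = iam_drift(trial.g_rem, trial.values, params["gamma"], params["zeta"], seen=trial.seen)
    mu, lam = _ig_params(D, v, sigma)
    x = t[None, :] - trial.t0[:, None]
    logf = invgauss_logpdf(x, mu[:, None], lam)
    logsf = np.where(trial.seen[:, None], invgauss_logsf(x, mu[:, None], lam), 0.0)
    out = np.zeros((trial.n_items, len(t)))
    for i in np.flatnonzero(trial.seen):
        others = trial.seen.copy()
        others[i] = False
        out[i] = np.exp(logf[i] + logsf[others].sum(axis=0))
    return out
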