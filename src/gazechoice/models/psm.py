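"""Probabilistic satisficing model (PSM) with gaze-weighted cached value.

The searcher holds a *cached value* ``C(t)``: the best gaze-weighted value
among the items seen so far. At every millisecond the search stops with
probability ``q(t) = min(alpha * C(t) + v * t, 1)``; on stopping, a choice
is drawn from a softmax (sensitivity ``tau``) over the seen items' cached
values. Gaze enters each item's cached value

    ``c_i(t) = g_i(t) * (l_i + zeta) + (1 - g_i(t)) * gamma * l_i``

through the fraction ``g_i(t)`` of elapsed time spent on the item: the
currently-accrued gaze share boosts an item additively (``zeta``) while the
unattended share discounts it multiplicatively (``gamma``). Items not yet
seen carry ``c_i = 0``. The passive-gaze variant is exactly ``gamma = 1,
zeta = 0``.

Parameters: ``v`` (1/ms), ``alpha`` (1/(value unit * ms)), ``tau``
(softmax sensitivity), ``gamma`` in [0, 1], ``zeta`` in [0, 10].
"""

from __future__ import annotations

import numpy as np
from scipy.special import logsumexp

from ..data import ValidationError
from .base import TrialBatch, TrialModelInput, mix_loglik

__all__ = [
    "PSM_PARAM_NAMES",
    "PSM_PRIOR_BOX",
    "psm_cached_value",
    "psm_choice_prob",
    "psm_stop_density",
    "psm_batch_loglik",
    "psm_trial_loglik",
    "psm_simulate",
]

PSM_PARAM_NAMES = ("v", "alpha", "tau", "gamma", "zeta")
PSM_PRIOR_BOX = {
    "v": (0.0, 0.001),
    "alpha": (0.0, 0.001),
    "tau": (0.0, 10.0),
    "gamma": (0.0, 1.0),
    "zeta": (0.0, 10.0),
}

# q is floored just below 1 inside likelihood evaluations so the per-ms
# density at the response time stays well defined on coarse grids
_Q_CEIL = 1.0 - 1e-12


def psm_cached_value(g_t, values, gamma, zeta, seen=None):
    """Gaze-weighted cached item values; 0 for items not yet seen.

    ``seen`` defaults to ``g_t > 0`` (an item joins the seen set once it has
    accrued any gaze time).
    """
    g_t = np.asarray(g_t, dtype=float)
    values = np.asarray(values, dtype=float)
    c = g_t * (values + zeta) + (1.0 - g_t) * gamma * values
    if seen is None:
        seen = g_t > 0
    return np.where(seen, c, 0.0)


def psm_choice_prob(c_t, tau, seen):
    """Softmax choice probabilities over the seen set (0 for unseen)."""
    seen = np.asarray(seen, dtype=bool)
    if not seen.any():
        raise ValidationError("softmax choice needs a nonempty seen set")
    logits = np.where(seen, tau * np.asarray(c_t, dtype=float), -np.inf)
    logits = logits - logsumexp(logits, axis=-1, keepdims=True)
    return np.where(seen, np.exp(logits), 0.0)


def _unpack(params: dict) -> tuple[float, float, float, float, float]:
    return (params["v"], params["alpha"], params["tau"], params["gamma"], params["zeta"])


def psm_stop_density(
    trial: TrialModelInput, params: dict, dt_ms: int = 1, horizon_ms: int | None = None
):
    """Stopping hazard ``q``, survivor ``Q`` and stop mass ``f`` on the grid.

    The grid runs past the observed response time with gaze fractions frozen
    at their final values, up to the first time the hazard saturates at 1
    (finite whenever ``v > 0``) or ``horizon_ms``. On the 1 ms grid ``f``
    sums to 1 over its finite support when the hazard saturates.

    Returns ``(t, q, Q, f)``; at ``dt_ms > 1`` each ``f`` entry is the stop
    mass of the whole grid step.
    """
    v, alpha, tau, gamma, zeta = _unpack(params)
    t_obs, G = trial.gaze_frac_grid(dt_ms)
    c = psm_cached_value(G, trial.values[:, None], gamma, zeta)
    C_obs = c.max(axis=0)
    C_end = C_obs[-1]

    # support ends where the hazard saturates or residual survival is
    # negligible (past rt the hazard is at least alpha*C_end + v*rt per ms)
    if v > 0 and alpha * C_end + v * trial.rt < 1.0:
        t_star = int(np.ceil((1.0 - alpha * C_end) / v))
    elif v > 0 or alpha * C_end >= 1.0:
        t_star = trial.rt
    else:  # v = 0 and hazard plateau < 1: never certain to stop
        t_star = horizon_ms if horizon_ms is not None else 10 * trial.rt
    h0 = alpha * C_end + v * trial.rt
    if 0.0 < h0 < 1.0:
        t_eps = trial.rt + int(np.ceil(-np.log(1e-16) / h0))
        t_star = min(t_star, t_eps)
    t_end = max(t_star, trial.rt)
    if horizon_ms is not None:
        t_end = min(t_end, max(horizon_ms, trial.rt))

    t_ext = np.arange(t_obs[-1] + dt_ms, t_end + 1, dt_ms, dtype=np.int64)
    if len(t_ext) and t_ext[-1] != t_end:
        t_ext = np.append(t_ext, t_end)
    elif not len(t_ext) and t_end > t_obs[-1]:
        t_ext = np.array([t_end], dtype=np.int64)
    t = np.concatenate([t_obs, t_ext])
    C = np.concatenate([C_obs, np.full(len(t_ext), C_end)])
    q = np.clip(alpha * C + v * t, 0.0, 1.0)
    w = np.diff(t, prepend=0)
    with np.errstate(divide="ignore"):
        step_log_surv = w * np.log1p(-np.minimum(q, _Q_CEIL))
    step_log_surv = np.where(q >= 1.0, -np.inf, step_log_surv)
    logQ = np.cumsum(step_log_surv)
    Q = np.exp(logQ)
    Q_prev = np.concatenate([[1.0], Q[:-1]])
    f = (1.0 - np.exp(step_log_surv)) * Q_prev
    return t, q, Q, f


def psm_batch_loglik(batch: TrialBatch, params: dict, dt_ms: int = 1) -> np.ndarray:
    """Per-trial log of the 95/5 mixture on ``p(choice, rt) = f(rt) *
    softmax_choice(rt)`` (density per ms), vectorized over the batch.

    Large batches are evaluated in RT-sorted buckets to keep the padded
    hazard grids tight."""
    buckets = batch.psm_buckets(dt_ms)
    if len(buckets) > 1:
        out = np.empty(batch.n_trials)
        for idx, sub in buckets:
            out[idx] = _psm_batch_loglik_dense(sub, params, dt_ms)
        return out
    return _psm_batch_loglik_dense(batch, params, dt_ms)


def _psm_batch_loglik_dense(batch: TrialBatch, params: dict, dt_ms: int) -> np.ndarray:
    v, alpha, tau, gamma, zeta = _unpack(params)
    t_grid, widths, wlog, k_last, Gm, LG, LG1 = batch.psm_value_grids(dt_ms)
    # c = gamma * l * (1 - g) + zeta * g + l * g, masked before first gaze
    c3 = np.float32(gamma) * LG1
    c3 += np.float32(zeta) * Gm
    c3 += LG
    C = c3.max(axis=1)
    q = np.minimum(np.clip(alpha * C + v * t_grid, 0.0, 1.0), _Q_CEIL)
    log1mq = np.log1p(-q)
    S = (wlog * log1mq).cumsum(axis=1)
    rows = np.arange(batch.n_trials)
    # survival through every ms before rt, stop hazard at rt itself
    with np.errstate(divide="ignore"):
        logf = np.log(q[rows, k_last]) + S[rows, k_last] - log1mq[rows, k_last]

    c_rt = psm_cached_value(batch.g_total, batch.values, gamma, zeta, seen=batch.seen)
    logits = np.where(batch.seen, tau * c_rt, -np.inf)
    logsig = logits[rows, batch.choice] - logsumexp(logits, axis=1)

    p = np.exp(logf + logsig)
    return mix_loglik(p, batch.u)


def psm_trial_loglik(
    trial: TrialModelInput, params: dict, dt_ms: int = 1, rt_range_ms: float = None
) -> float:
    """Single-trial convenience wrapper (requires an explicit RT range for
    the contaminant density)."""
    return float(psm_batch_loglik(TrialBatch([trial], rt_range_ms), params, dt_ms)[0])


def psm_simulate(
    trial: TrialModelInput,
    params: dict,
    rng,
    n_sims: int = 1,
    dt_ms: int = 1,
    horizon_ms: int = 2_000_000,
):
    """Simulate (choice, RT) pairs by running the stopping process forward.

    The per-ms stopping hazard is evaluated sequentially (a Bernoulli draw
    per millisecond, vectorized over simulations); past the observed gaze
    stream the gaze fractions stay frozen at their final values. Raises if
    the hazard cannot reach 1 within ``horizon_ms``.

    Returns ``(choices, rts)`` integer arrays of length ``n_sims``.
    """
    rng = np.random.default_rng(rng)
    v, alpha, tau, gamma, zeta = _unpack(params)
    t, q, Q, f = psm_stop_density(trial, params, dt_ms=1, horizon_ms=horizon_ms)
    if q[-1] < 1.0 and Q[-1] > 1e-9:
        raise ValidationError(
            "stopping probability does not concentrate within the horizon "
            "(v and alpha too small)"
        )

    rts = np.empty(n_sims, dtype=np.int64)
    sim_chunk, block = 16384, 1024  # bound the uniform-draw buffers
    for lo in range(0, n_sims, sim_chunk):
        alive = np.arange(lo, min(lo + sim_chunk, n_sims))
        for start in range(0, len(t), block):
            if not len(alive):
                break
            qb = q[start : start + block]
            hit = rng.random((len(alive), len(qb))) < qb[None, :]
            any_hit = hit.any(axis=1)
            first = hit.argmax(axis=1)
            rts[alive[any_hit]] = t[start + first[any_hit]]
            alive = alive[~any_hit]
        if len(alive):  # residual survival below 1e-9: censor at support end
            rts[alive] = t[-1]

    # cached values at the stop time (frozen at the end of the gaze stream)
    t_obs, G = trial.gaze_frac_grid(1)
    c_grid = psm_cached_value(G, trial.values[:, None], gamma, zeta)  # (N, rt)
    c_frozen = psm_cached_value(trial.g_total, trial.values, gamma, zeta, seen=trial.seen)
    cols = np.minimum(rts, trial.rt) - 1
    c_sim = np.where(
        (rts <= trial.rt)[:, None], c_grid[:, cols].T, c_frozen[None, :]
    )
    seen_at = np.where(
        (rts <= trial.rt)[:, None], G[:, cols].T > 0, trial.seen[None, :]
    )
    # degenerate stop before the first gaze: choice uniform over the set
    seen_at[~seen_at.any(axis=1)] = True
    gumbel = rng.gumbel(size=c_sim.shape)
    scores = np.where(seen_at, tau * c_sim + gumbel, -np.inf)
    choices = scores.argmax(axis=1)
    return choices, rts


def psm_joint_density(trial: TrialModelInput, params: dict, horizon_ms: int = 2_000_000):
    """Joint per-ms probability ``p_i(t) = f(t) * sigma_i(t)`` on the 1 ms
    grid over the model's finite support (gaze frozen past the stream; a
    stop before the first gaze yields a uniform choice, mirroring the
    simulator). Returns ``(t, P)`` with ``P`` of shape ``(n_items, len(t))``;
    ``P`` sums to 1 when the hazard saturates within the horizon."""
    v, alpha, tau, gamma, zeta = _unpack(params)
    t, q, Q, f = psm_stop_density(trial, params, dt_ms=1, horizon_ms=horizon_ms)
    t_obs, G = trial.gaze_frac_grid(1)
    n = trial.n_items
    c = np.empty((n, len(t)))
    seen = np.empty((n, len(t)), dtype=bool)
    k = len(t_obs)
    c[:, :k] = psm_cached_value(G, trial.values[:, None], gamma, zeta)
    seen[:, :k] = G > 0
    c_frozen = psm_cached_value(trial.g_total, trial.values, gamma, zeta, seen=trial.seen)
    c[:, k:] = c_frozen[:, None]
    seen[:, k:] = trial.seen[:, None]
    empty = ~seen.any(axis=0)
    seen[:, empty] = True
    logits = np.where(seen, tau * c, -np.inf)
    sigma = np.exp(logits - logsumexp(logits, axis=0, keepdims=True))
    return t, sigma * f[None, :]
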