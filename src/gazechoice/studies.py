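"""Validation studies: the package checking its own internal consistency.

These are the simulation studies a modelling paper runs before trusting its
fits: simulator-vs-likelihood agreement for every model family, passive =
active degeneracy, normalization of every density, calibration of the
gaze-influence measure on null data, and the recovery harnesses (which live
in :mod:`gazechoice.inference`). Both the test suite and the reproduction
script drive these functions, so the study conditions are defined once.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from scipy import integrate, stats

from .data import ItemInfo
from .metrics import gaze_influence
from .models import (
    FAMILIES,
    PASSIVE_FIXED,
    TrialBatch,
    TrialModelInput,
    build_inputs,
    glam_joint_density,
    iam_joint_density,
    invgauss_pdf,
    psm_joint_density,
    psm_stop_density,
)
from .synth import (
    GazeProcessConfig,
    SyntheticConfig,
    _scaffold_input,
    gen_gaze_sequence,
    gen_null_gaze_subject,
    gen_subject,
)

__all__ = [
    "probe_trial",
    "equivalence_study",
    "passive_active_study",
    "normalization_study",
    "gaze_influence_null_study",
    "gaze_influence_positive_study",
]

#: Parameter points used by the consistency studies (mid-magnitude values
#: producing the experiment's RT scale).
STUDY_PARAMS = {
    "psm": {"v": 2e-7, "alpha": 6e-5, "tau": 1.0, "gamma": 0.5, "zeta": 1.5},
    "iam": {"v": 3e-4, "sigma": 0.01, "gamma": 0.5, "zeta": 1.5},
    "glam": {"v": 1e-3, "sigma": 0.01, "tau": 1.0, "gamma": 0.5, "zeta": 1.5},
}


def probe_trial(seed: int = 7, set_size: int = 9) -> TrialModelInput:
    """A fixed synthetic trial (items + gaze scaffold) for density checks."""
    rng = np.random.default_rng(seed)
    n = int(np.sqrt(set_size))
    ratings = [-3, -1, 0, 1, 2, 3, 2, 0, -2][:set_size]
    items = [ItemInfo(f"i{k}", r, k // n, k % n, 0.6) for k, r in enumerate(ratings)]
    segs = gen_gaze_sequence(items, GazeProcessConfig(scaffold_ms=4000), rng)
    return _scaffold_input(items, segs, segs[-1].end_ms)


def _joint_density(family: str, trial: TrialModelInput, params: dict):
    if family == "psm":
        return psm_joint_density(trial, params)
    t = np.arange(1, 150_001)
    dens = iam_joint_density if family == "iam" else glam_joint_density
    return t, dens(trial, params, t)


def equivalence_study(
    seed: int, n_sims: int = 100_000, families=("psm", "iam", "glam"),
    variants=("active", "passive"),
) -> pd.DataFrame:
    """Simulator-vs-likelihood agreement on the fixed probe trial.

    For each family and gaze variant, ``n_sims`` forward-simulated
    (choice, RT) pairs are tested against the closed-form/numeric joint
    density: a chi-square on choice counts and a chi-square on decile-binned
    RTs. Returns one row per family x variant with the p-values and the
    total numeric mass of the density.
    """
    rng = np.random.default_rng(seed)
    trial = probe_trial()
    rows = []
    for family in families:
        for variant in variants:
            params = dict(STUDY_PARAMS[family])
            if variant == "passive":
                params.update(PASSIVE_FIXED)
            t, P = _joint_density(family, trial, params)
            choices, rts = FAMILIES[family].simulate(trial, params, rng, n_sims=n_sims)

            p_choice = P.sum(axis=1)
            mass = p_choice.sum()
            p_choice = p_choice / mass
            obs = np.bincount(choices, minlength=trial.n_items)
            keep = p_choice > 0
            choice_p = stats.chisquare(
                obs[keep], n_sims * p_choice[keep] / p_choice[keep].sum()
            ).pvalue

            f_t = P.sum(axis=0)
            F_t = np.cumsum(f_t) / f_t.sum()
            edges = t[np.searchsorted(F_t, np.linspace(0.1, 0.9, 9))]
            # half-integer bin edges so bin k counts edge_{k-1} < RT <= edge_k,
            # matching the integer-grid CDF differences exactly
            bins = np.concatenate([[0.5], edges + 0.5, [np.inf]])
            obs_rt = np.histogram(rts, bins=bins)[0]
            exp_rt = np.diff(np.concatenate([[0.0], F_t[np.searchsorted(t, edges)], [1.0]]))
            rt_p = stats.chisquare(obs_rt, n_sims * exp_rt / exp_rt.sum()).pvalue

            rows.append(
                {
                    "family": family,
                    "variant": variant,
                    "n_sims": n_sims,
                    "choice_chi2_p": float(choice_p),
                    "rt_chi2_p": float(rt_p),
                    "density_mass": float(mass),
                }
            )
    return pd.DataFrame(rows)


def _random_trial_batch(seed: int, n_trials: int) -> TrialBatch:
    cfg = SyntheticConfig(
        set_sizes=(9,), trials_per_cond=n_trials, contaminant_rate=0.0
    ).with_generator("glam", "active", STUDY_PARAMS["glam"])
    ds, _ = gen_subject(cfg, np.random.default_rng(seed))
    return TrialBatch(build_inputs(ds.valid_trials()))


def passive_active_study(seed: int, n_trials: int = 1000) -> dict[str, float]:
    """Max |difference| between the passive variant's log-likelihood and the
    active code path evaluated at gamma = 1, zeta = 0, over random trials.
    Exact zero is the contract: passive IS that parameter restriction."""
    batch = _random_trial_batch(seed, n_trials)
    out = {}
    for family, spec in FAMILIES.items():
        params = dict(STUDY_PARAMS[family])
        active_at_fixed = {**params, **PASSIVE_FIXED}
        ll_active = spec.loglik(batch, active_at_fixed, 5)
        # the passive fitting path: free params merged with the fixed pair
        free = {k: v for k, v in params.items() if k not in PASSIVE_FIXED}
        ll_passive = spec.loglik(batch, {**free, **PASSIVE_FIXED}, 5)
        out[family] = float(np.max(np.abs(ll_active - ll_passive)))
    return out


def normalization_study(seed: int, n_trials: int = 5) -> dict[str, float]:
    """Probability-mass checks: the satisficing stop density sums to 1 over
    its finite support, each race's win probabilities integrate to 1, and
    the Inverse-Gaussian density integrates to 1."""
    cfg = SyntheticConfig(
        set_sizes=(9,), trials_per_cond=n_trials, contaminant_rate=0.0
    ).with_generator("glam", "active", STUDY_PARAMS["glam"])
    ds, _ = gen_subject(cfg, np.random.default_rng(seed))
    inputs = build_inputs(ds.valid_trials())

    psm_err = max(
        abs(psm_stop_density(inp, STUDY_PARAMS["psm"], dt_ms=1)[3].sum() - 1.0)
        for inp in inputs
    )
    t = np.arange(1, 150_001)
    iam_err = max(
        abs(iam_joint_density(inp, STUDY_PARAMS["iam"], t).sum() - 1.0) for inp in inputs
    )
    glam_err = max(
        abs(glam_joint_density(inp, STUDY_PARAMS["glam"], t).sum() - 1.0) for inp in inputs
    )
    ig_mass, _ = integrate.quad(
        lambda x: invgauss_pdf(x, 800.0, 5000.0), 0, np.inf, limit=200
    )
    return {
        "psm_stop_mass_err": float(psm_err),
        "iam_win_mass_err": float(iam_err),
        "glam_win_mass_err": float(glam_err),
        "invgauss_integral_err": float(abs(ig_mass - 1.0)),
    }


def gaze_influence_null_study(
    seed: int, n_seeds: int = 20, trials: int = 200, set_size: int = 9
) -> np.ndarray:
    """Gaze-influence values for rating-only (gaze-independent) choosers;
    the measure should be centred on zero."""
    root = np.random.default_rng(seed)
    cfg = SyntheticConfig(set_sizes=(set_size,), trials_per_cond=trials)
    vals = []
    for _ in range(n_seeds):
        ds = gen_null_gaze_subject(cfg, root, softmax_tau=0.8)
        vals.append(gaze_influence(ds.valid_trials()))
    return np.asarray(vals)


def gaze_influence_positive_study(
    seed: int, n_subjects: int = 20, trials: int = 150, set_size: int = 9
) -> np.ndarray:
    """Gaze-influence values for subjects generated by the relative-race
    model with a strong active gaze bias (gamma = 0.3, zeta = 3); the
    measure should be positive for nearly all of them."""
    root = np.random.default_rng(seed)
    params = {"v": 1e-3, "sigma": 0.01, "tau": 1.0, "gamma": 0.3, "zeta": 3.0}
    cfg = SyntheticConfig(
        set_sizes=(set_size,), trials_per_cond=trials, contaminant_rate=0.0
    ).with_generator("glam", "active", params)
    vals = []
    for s in range(n_subjects):
        ds, _ = gen_subject(cfg, root, subject_id=f"g{s:02d}")
        vals.append(gaze_influence(ds.valid_trials()))
    return np.asarray(vals)
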