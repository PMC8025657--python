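"""sklearn-style estimators wrapping the likelihood models.

Each estimator holds the sampler settings as constructor parameters
(``get_params``/``set_params`` compose with sklearn model selection), fits
one subject-condition's trials with Metropolis sampling, and exposes the
posterior, MAP, convergence diagnostics and WAIC as fitted attributes.
"""

from __future__ import annotations

import numpy as np
from sklearn.base import BaseEstimator
from sklearn.utils.validation import check_is_fitted

from ..data import TrialRecord


class ChoiceModelEstimator(BaseEstimator):
    """Base class for the gaze-dependent choice/RT model estimators.

    Parameters
    ----------
    variant : "active" or "passive"
        Passive fixes ``gamma = 1`` and ``zeta = 0`` instead of sampling
        them (two fewer free parameters).
    n_tune, n_draws : int
        Discarded burn-in samples and retained posterior draws.
    dt_ms : int
        Time step of the satisficing likelihood grid (1 ms reproduces the
        model definition exactly; coarser steps trade accuracy for speed).
    max_retries : int
        Extra sampling attempts with extended burn-in on non-convergence.
    min_trials : int
        Floor on the number of valid trials.
    rt_range_ms : float or None
        Explicit contaminant RT range (defaults to the fitted batch's own).
    seed : int or None
        Sampler seed.

    Attributes (after ``fit``)
    --------------------------
    result_ : FitResult            full fit object
    draws_ : ndarray               posterior draws (n_draws, n_free)
    map_ : dict                    MAP parameter estimates (free + fixed)
    pointwise_loglik_ : ndarray    (n_draws, n_trials)
    rhat_, ess_ : dict             per-parameter diagnostics
    converged_ : bool
    waic_ : WAICResult
    """

    family: str | None = None

    def __init__(
        self,
        variant: str = "active",
        n_tune: int = 5000,
        n_draws: int = 5000,
        dt_ms: int = 1,
        max_retries: int = 2,
        min_trials: int = 20,
        rt_range_ms: float | None = None,
        seed: int | None = None,
    ):
        self.variant = variant
        self.n_tune = n_tune
        self.n_draws = n_draws
        self.dt_ms = dt_ms
        self.max_retries = max_retries
        self.min_trials = min_trials
        self.rt_range_ms = rt_range_ms
        self.seed = seed

    def _config(self):
        from ..inference import FitConfig

        return FitConfig(
            n_tune=self.n_tune,
            n_draws=self.n_draws,
            max_retries=self.max_retries,
            min_trials=self.min_trials,
            dt_ms=self.dt_ms,
            seed=self.seed,
            rt_range_ms=self.rt_range_ms,
        )

    def fit(self, X: list[TrialRecord], y=None):
        """Fit the model to one subject-condition's valid trials."""
        from ..inference import fit_subject

        result = fit_subject(self.family, self.variant, X, config=self._config())
        self.result_ = result
        self.draws_ = result.draws
        self.map_ = result.map_params
        self.pointwise_loglik_ = result.pointwise_loglik
        self.rhat_ = result.rhat
        self.ess_ = result.ess
        self.converged_ = result.converged
        self.waic_ = result.waic()
        self.param_names_ = result.param_names
        return self

    def loglik(self, X: list[TrialRecord], params: dict | None = None) -> np.ndarray:
        """Per-trial log-likelihood at ``params`` (default: the fitted MAP)."""
        from . import FAMILIES
        from .base import TrialBatch, build_inputs

        if params is None:
            check_is_fitted(self, "map_")
            params = self.map_
        family = FAMILIES[self.family]
        batch = TrialBatch(build_inputs(X), self.rt_range_ms)
        return family.loglik(batch, params, self.dt_ms)

    def score(self, X: list[TrialRecord], y=None) -> float:
        """Summed MAP log-likelihood of ``X`` (sklearn scoring contract)."""
        return float(self.loglik(X).sum())

    def simulate(
        self,
        X: list[TrialRecord],
        reps: int = 50,
        rng=None,
        contaminant_rate: float = 0.05,
        params: dict | None = None,
    ):
        """Forward-simulate the 95/5 protocol over observed trials using the
        fitted MAP (or explicit ``params``)."""
        from .simulate import simulate_experiment

        if params is None:
            check_is_fitted(self, "map_")
            params = self.map_
        return simulate_experiment(
            self.family, params, X, reps=reps, rng=rng, contaminant_rate=contaminant_rate
        )


class PSM(ChoiceModelEstimator):
    """Probabilistic satisficing model estimator."""

    family = "psm"


class IAM(ChoiceModelEstimator):
    """Independent evidence accumulation (race) model estimator."""

    family = "iam"


class GLAM(ChoiceModelEstimator):
    """Gaze-weighted linear accumulator (relative race) model estimator."""

    family = "glam"
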