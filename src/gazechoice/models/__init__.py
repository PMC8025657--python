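"""Likelihood models, forward simulators, and sklearn-style estimators."""

from __future__ import annotations

from dataclasses import dataclass
from typing import Callable

from .base import (
    BOUNDARY,
    CONTAMINANT_RATE,
    TrialBatch,
    TrialModelInput,
    TrialOutcome,
    build_inputs,
    contaminant_density,
    mix_loglik,
    trial_model_input,
)
from .glam import (
    GLAM_PARAM_NAMES,
    GLAM_PRIOR_BOX,
    glam_batch_loglik,
    glam_joint_density,
    glam_signals,
    glam_simulate,
    glam_trial_loglik,
)
from .iam import (
    IAM_PARAM_NAMES,
    IAM_PRIOR_BOX,
    iam_batch_loglik,
    iam_drift,
    iam_joint_density,
    iam_simulate,
    iam_trial_loglik,
)
from .invgauss import invgauss_cdf, invgauss_logpdf, invgauss_logsf, invgauss_pdf, invgauss_rvs
from .psm import (
    PSM_PARAM_NAMES,
    PSM_PRIOR_BOX,
    psm_batch_loglik,
    psm_cached_value,
    psm_choice_prob,
    psm_joint_density,
    psm_simulate,
    psm_stop_density,
    psm_trial_loglik,
)

#: Fixed values that turn an active-gaze model into its passive variant.
PASSIVE_FIXED = {"gamma": 1.0, "zeta": 0.0}


@dataclass(frozen=True)
class FamilySpec:
    """Registry entry tying a model family to its likelihood and simulator."""

    name: str
    param_names: tuple[str, ...]
    prior_box: dict[str, tuple[float, float]]
    batch_loglik: Callable  # (batch, params[, dt_ms]) -> per-trial loglik
    simulate: Callable      # (trial, params, rng, n_sims) -> (choices, rts)
    uses_time_grid: bool = False

    def loglik(self, batch: TrialBatch, params: dict, dt_ms: int = 1):
        if self.uses_time_grid:
            return self.batch_loglik(batch, params, dt_ms)
        return self.batch_loglik(batch, params)


FAMILIES: dict[str, FamilySpec] = {
    "psm": FamilySpec("psm", PSM_PARAM_NAMES, PSM_PRIOR_BOX, psm_batch_loglik,
                      psm_simulate, uses_time_grid=True),
    "iam": FamilySpec("iam", IAM_PARAM_NAMES, IAM_PRIOR_BOX, iam_batch_loglik, iam_simulate),
    "glam": FamilySpec("glam", GLAM_PARAM_NAMES, GLAM_PRIOR_BOX, glam_batch_loglik, glam_simulate),
}

from .estimators import GLAM, IAM, PSM, ChoiceModelEstimator  # noqa: E402
from .simulate import simulate_experiment  # noqa: E402

__all__ = [
    "BOUNDARY",
    "CONTAMINANT_RATE",
    "PASSIVE_FIXED",
    "FAMILIES",
    "FamilySpec",
    "TrialBatch",
    "TrialModelInput",
    "TrialOutcome",
    "build_inputs",
    "trial_model_input",
    "contaminant_density",
    "mix_loglik",
    "simulate_experiment",
    "ChoiceModelEstimator",
    "PSM",
    "IAM",
    "GLAM",
    # family surfaces
    "PSM_PARAM_NAMES", "PSM_PRIOR_BOX", "psm_cached_value", "psm_choice_prob",
    "psm_stop_density", "psm_joint_density", "psm_batch_loglik", "psm_trial_loglik",
    "psm_simulate",
    "IAM_PARAM_NAMES", "IAM_PRIOR_BOX", "iam_drift", "iam_batch_loglik",
    "iam_trial_loglik", "iam_simulate", "iam_joint_density",
    "GLAM_PARAM_NAMES", "GLAM_PRIOR_BOX", "glam_signals", "glam_batch_loglik",
    "glam_trial_loglik", "glam_simulate", "glam_joint_density",
    "invgauss_pdf", "invgauss_logpdf", "invgauss_cdf", "invgauss_logsf", "invgauss_rvs",
]
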