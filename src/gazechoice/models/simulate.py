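"""Forward simulation of fitted models over an observed dataset.

Mirrors the study's simulation protocol: every observed trial is repeated
``reps`` times (default 50); each repetition is a model draw with
probability 95% and a spurious outcome (uniform item among all N, uniform
RT within the subject-condition's observed range) with probability 5%.
Simulated outcomes keep the observed trial's gaze statistics -- the models
generate choices and response times, not gaze -- so the result is a
per-item table ready for :func:`gazechoice.metrics.summarize_table`.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from ..data import TrialRecord
from ..metrics import trial_table
from .base import CONTAMINANT_RATE, build_inputs


def simulate_experiment(
    model: str,
    params: dict,
    trials: list[TrialRecord],
    reps: int = 50,
    rng=None,
    contaminant_rate: float = CONTAMINANT_RATE,
) -> pd.DataFrame:
    """Simulate ``reps`` (choice, RT) outcomes per valid observed trial.

    ``model`` is a family name (``"psm"``, ``"iam"``, ``"glam"``); passive
    variants are simulated by passing ``gamma=1, zeta=0`` in ``params``.
    Returns the per-item table with ``rep`` and ``contaminant`` columns;
    ``chosen`` and ``rt_ms`` are the simulated outcome while the gaze
    columns describe the observed trial.
    """
    from . import FAMILIES  # late import: registry lives in the package root

    family = FAMILIES[model]
    rng = np.random.default_rng(rng)
    valid = [t for t in trials if t.valid]
    inputs = build_inputs(valid)
    base_table = trial_table(valid)

    # observed RT range per subject x set size for the spurious component
    rt_bounds: dict[tuple, tuple[int, int]] = {}
    for t in valid:
        key = (t.subject_id, t.set_size)
        lo, hi = rt_bounds.get(key, (t.rt_ms, t.rt_ms))
        rt_bounds[key] = (min(lo, t.rt_ms), max(hi, t.rt_ms))

    frames = []
    for t, inp in zip(valid, inputs):
        choices, rts = family.simulate(inp, params, rng, n_sims=reps)
        contam = rng.random(reps) < contaminant_rate
        if contam.any():
            lo, hi = rt_bounds[(t.subject_id, t.set_size)]
            k = int(contam.sum())
            choices = choices.copy()
            rts = rts.copy()
            choices[contam] = rng.integers(0, t.set_size, size=k)
            rts[contam] = rng.integers(lo, max(hi, lo + 1), size=k)
        obs = base_table[
            (base_table["subject"] == t.subject_id) & (base_table["trial"] == t.trial_id)
        ]
        for rep in range(reps):
            sim = obs.copy()
            sim["rep"] = rep
            sim["chosen"] = (sim["item"] == choices[rep]).astype(int)
            sim["rt_ms"] = rts[rep]
            sim["contaminant"] = contam[rep]
            frames.append(sim)
    return pd.concat(frames, ignore_index=True)
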