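"""Shared model-input plumbing: per-trial gaze/value summaries, padded
batches for vectorized likelihoods, and the contaminant mixture.

Every likelihood model consumes a :class:`TrialModelInput`: liking ratings
rescaled to 1..7, the seen set, cumulative gaze fractions (full-trial and
remaining-time variants), first-gaze onsets, the response time and the
choice. A :class:`TrialBatch` pads a list of inputs into rectangular arrays
so a whole subject-condition likelihood is one vectorized evaluation.

Spurious trials are handled by a fixed 5% contaminant mixture: a uniformly
random item at a uniformly random time within the subject's observed
response-time range, ``u = 1 / (N * (max RT - min RT))`` per item and ms.
The mixture floor keeps every trial log-likelihood finite for any in-box
parameter vector.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from ..data import TrialRecord, ValidationError, rescale_rating
from ..preprocess import clean_gaze_stream, gaze_statistics

__all__ = [
    "CONTAMINANT_RATE",
    "TrialModelInput",
    "TrialBatch",
    "TrialOutcome",
    "contaminant_density",
    "mix_loglik",
    "build_inputs",
]

#: Fixed rate of spurious trials in the likelihood mixture.
CONTAMINANT_RATE = 0.05

#: Common decision boundary of the accumulator models.
BOUNDARY = 1.0


@dataclass(frozen=True)
class TrialOutcome:
    """A simulated trial outcome."""

    choice_index: int
    rt_ms: int
    contaminant: bool = False


@dataclass
class TrialModelInput:
    """Per-trial quantities every likelihood model reads."""

    values: np.ndarray      # rescaled ratings, 1..7
    seen: np.ndarray        # bool
    g_total: np.ndarray     # gaze time / rt
    g_rem: np.ndarray       # gaze time / (rt - t0), in [0, 1]; 0 where unseen
    t0: np.ndarray          # first-gaze onset (ms); -1 where unseen
    rt: int
    choice: int
    n_items: int
    segments: list[tuple[int, int, int]]  # cleaned (item, onset, dur), truncated at rt
    _grids: dict = field(default_factory=dict, repr=False)

    def gaze_frac_grid(self, dt_ms: int = 1) -> tuple[np.ndarray, np.ndarray]:
        """Running gaze fraction ``g_i(t)`` on the grid t = dt, 2dt, ..., rt
        (final step partial if ``dt_ms`` does not divide ``rt``). Cached."""
        if dt_ms not in self._grids:
            t_grid = np.arange(dt_ms, self.rt + 1, dt_ms, dtype=np.int64)
            if len(t_grid) == 0 or t_grid[-1] != self.rt:
                t_grid = np.append(t_grid, self.rt)
            cum = np.zeros((self.n_items, len(t_grid)))
            for item, onset, dur in self.segments:
                cum[item] += np.clip(t_grid - onset, 0, dur)
            self._grids[dt_ms] = (t_grid, (cum / t_grid).astype(np.float32))
        return self._grids[dt_ms]


def trial_model_input(trial: TrialRecord) -> TrialModelInput:
    """Summarize a valid trial for the likelihood models."""
    if not trial.valid:
        raise ValidationError("model input requires a valid trial")
    stats = gaze_statistics(trial)
    rt = trial.rt_ms
    values = np.array([rescale_rating(i.rating) for i in trial.items], dtype=float)
    remaining = np.where(stats.t0_ms >= 0, rt - stats.t0_ms, 1).astype(float)
    # first seen at the response itself: all remaining time was gaze
    g_rem = np.where(
        remaining > 0, stats.total_gaze_ms / np.maximum(remaining, 1e-12), 1.0
    )
    g_rem = np.clip(np.where(stats.seen, g_rem, 0.0), 0.0, 1.0)
    segments = [
        (s.item_index, s.onset_ms, min(s.end_ms, rt) - s.onset_ms)
        for s in clean_gaze_stream(trial.gaze)
        if s.onset_ms < rt
    ]
    return TrialModelInput(
        values=values,
        seen=stats.seen.copy(),
        g_total=stats.cum_gaze_frac.copy(),
        g_rem=g_rem,
        t0=stats.t0_ms.copy(),
        rt=rt,
        choice=trial.choice_index,
        n_items=trial.set_size,
        segments=segments,
    )


def build_inputs(trials: list[TrialRecord]) -> list[TrialModelInput]:
    return [trial_model_input(t) for t in trials if t.valid]


def contaminant_density(n_items: int, rt_range_ms: float) -> float:
    """Uniform spurious-trial density over items x response times
    (per item and ms)."""
    if rt_range_ms <= 0:
        raise ValidationError(
            "contaminant density needs a positive RT range; supply an explicit "
            "range when fitting fewer than two distinct response times"
        )
    return 1.0 / (n_items * rt_range_ms)


def mix_loglik(p_model: np.ndarray, u: np.ndarray | float) -> np.ndarray:
    """Log of the 95/5 model-contaminant mixture."""
    return np.log((1.0 - CONTAMINANT_RATE) * p_model + CONTAMINANT_RATE * np.asarray(u))


class TrialBatch:
    """Rectangular, padded view of a list of trial inputs.

    Padding items have ``item_mask`` False, value 0 and are never seen;
    every likelihood implementation masks on ``seen``/``item_mask``.
    ``u`` is the contaminant density from the batch's own RT range (a
    shared explicit range may be passed for cross-condition sensitivity
    checks).
    """

    def __init__(self, inputs: list[TrialModelInput], rt_range_ms: float | None = None):
        if not inputs:
            raise ValidationError("empty trial batch")
        self.inputs = inputs
        n = len(inputs)
        nmax = max(inp.n_items for inp in inputs)
        self.n_trials, self.n_items_max = n, nmax
        self.values = np.zeros((n, nmax))
        self.seen = np.zeros((n, nmax), dtype=bool)
        self.item_mask = np.zeros((n, nmax), dtype=bool)
        self.g_total = np.zeros((n, nmax))
        self.g_rem = np.zeros((n, nmax))
        self.t0 = np.full((n, nmax), -1, dtype=np.int64)
        self.rt = np.array([inp.rt for inp in inputs], dtype=np.int64)
        self.choice = np.array([inp.choice for inp in inputs], dtype=np.int64)
        self.n_items = np.array([inp.n_items for inp in inputs], dtype=np.int64)
        for k, inp in enumerate(inputs):
            m = inp.n_items
            self.values[k, :m] = inp.values
            self.seen[k, :m] = inp.seen
            self.item_mask[k, :m] = True
            self.g_total[k, :m] = inp.g_total
            self.g_rem[k, :m] = inp.g_rem
            self.t0[k, :m] = inp.t0
        if rt_range_ms is None:
            rt_range_ms = float(self.rt.max() - self.rt.min())
        self.rt_range_ms = rt_range_ms
        self.u = np.array(
            [contaminant_density(inp.n_items, rt_range_ms) for inp in inputs]
        )
        self._psm_cache: dict = {}

    def psm_grids(self, dt_ms: int) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
        """Padded per-ms gaze-fraction grids for the satisficing likelihood.

        Returns ``(t_grid, G, widths)``: ``t_grid`` of shape (n, Kmax) holding
        each trial's time grid (its last in-range point is exactly ``rt``,
        padding repeats the final point with zero width), ``G`` of shape
        (n, Nmax, Kmax) with running gaze fractions, and ``widths`` (n, Kmax)
        with the ms width of each grid step.
        """
        if dt_ms in self._psm_cache:
            return self._psm_cache[dt_ms]
        grids = [inp.gaze_frac_grid(dt_ms) for inp in self.inputs]
        kmax = max(len(t) for t, _ in grids)
        n = self.n_trials
        t_grid = np.zeros((n, kmax), dtype=np.int64)
        G = np.zeros((n, self.n_items_max, kmax), dtype=np.float32)
        widths = np.zeros((n, kmax))
        for k, (t, g) in enumerate(grids):
            kk = len(t)
            t_grid[k, :kk] = t
            t_grid[k, kk:] = t[-1]
            G[k, : g.shape[0], :kk] = g
            G[k, : g.shape[0], kk:] = g[:, -1:]
            widths[k, :kk] = np.diff(t, prepend=0)
        self._psm_cache[dt_ms] = (t_grid, G, widths)
        return self._psm_cache[dt_ms]

    def psm_buckets(self, dt_ms: int, n_buckets: int = 3, min_size: int = 40):
        """Sub-batches grouped by response-time length.

        Padding every trial's hazard grid to the longest response time
        wastes most of the work on short trials; grouping by RT keeps the
        padded grids tight. Returns ``[(orig_indices, sub_batch), ...]``;
        sub-batches share this batch's contaminant RT range.
        """
        key = ("buckets", dt_ms)
        if key not in self._psm_cache:
            if self.n_trials < min_size * 2:
                self._psm_cache[key] = [(np.arange(self.n_trials), self)]
            else:
                order = np.argsort(self.rt)
                parts = np.array_split(order, n_buckets)
                self._psm_cache[key] = [
                    (idx, TrialBatch([self.inputs[i] for i in idx], self.rt_range_ms))
                    for idx in parts
                    if len(idx)
                ]
        return self._psm_cache[key]

    def psm_value_grids(self, dt_ms: int):
        """Precomputed gaze-weighted value components for the satisficing
        hazard: cached values decompose as ``c = gamma * LG1 + zeta * Gm +
        LG`` with ``LG1 = l * (1 - g)``, ``Gm = g`` and ``LG = l * g``, all
        masked to zero before an item's first gaze, so each likelihood
        evaluation is two scaled additions and a max."""
        key = ("values", dt_ms)
        if key not in self._psm_cache:
            t_grid, G, widths = self.psm_grids(dt_ms)
            mask = G > 0
            L = self.values[:, :, None].astype(np.float32)
            Gm = np.where(mask, G, np.float32(0))
            LG = np.where(mask, L * G, np.float32(0))
            LG1 = np.where(mask, L * (np.float32(1) - G), np.float32(0))
            with np.errstate(invalid="ignore"):
                wlog = np.where(widths > 0, widths, 0.0)
            k_last = (widths > 0).sum(axis=1) - 1
            self._psm_cache[key] = (t_grid, widths, wlog, k_last, Gm, LG, LG1)
        return self._psm_cache[key]
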