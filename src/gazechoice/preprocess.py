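"""Gaze-stream cleaning, trial exclusion rules, and per-trial gaze statistics.

Cleaning follows the experiment's rules for turning labelled fixation runs
into item gazes:

1. missing segments flanked by gazes to the same item are relabelled to that
   item (a blink inside a gaze does not split it);
2. non-item and missing segments before the first and after the last item
   gaze are discarded;
3. non-item or missing segments between gazes to *different* items are
   discarded (their time counts toward the trial but toward no item);
4. temporally contiguous same-item segments are merged into single gazes.

Step 1 runs before step 2 so the stated rules compose deterministically.
All "fraction of trial time" quantities use the response time as the
denominator, so time on empty screen dilutes every item's share.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .data import MISSING, GazeSegment, TrialRecord, ValidationError, _check_ordered

__all__ = [
    "GazeStatistics",
    "clean_gaze_stream",
    "apply_trial_exclusions",
    "gaze_statistics",
    "gaze_timecourse",
    "gaze_advantage",
]


def clean_gaze_stream(raw: list[GazeSegment]) -> list[GazeSegment]:
    """Reduce a labelled gaze stream to item-only gazes (rules above)."""
    _check_ordered(raw, "gaze stream")
    segs = list(raw)

    # 1. missing runs flanked by the same item -> that item
    relabelled: list[GazeSegment] = []
    i = 0
    while i < len(segs):
        s = segs[i]
        if s.item_index == MISSING:
            j = i
            while j < len(segs) and segs[j].item_index == MISSING:
                j += 1
            prev = relabelled[-1].item_index if relabelled else None
            nxt = segs[j].item_index if j < len(segs) else None
            if prev is not None and prev >= 0 and prev == nxt:
                relabelled.extend(
                    GazeSegment(prev, m.onset_ms, m.duration_ms) for m in segs[i:j]
                )
            else:
                relabelled.extend(segs[i:j])
            i = j
        else:
            relabelled.append(s)
            i += 1

    # 2./3. keep only item segments (leading/trailing and between-item
    # non-item/missing time is dropped from gaze totals either way)
    items_only = [s for s in relabelled if s.item_index >= 0]

    # 4. merge temporally contiguous same-item segments
    merged: list[GazeSegment] = []
    for s in items_only:
        if merged and merged[-1].item_index == s.item_index and merged[-1].end_ms == s.onset_ms:
            prev = merged.pop()
            merged.append(GazeSegment(prev.item_index, prev.onset_ms, prev.duration_ms + s.duration_ms))
        else:
            merged.append(s)
    return merged


def apply_trial_exclusions(trial: TrialRecord) -> TrialRecord:
    """Flag a trial invalid if it timed out, the choice was never gazed, or
    the click landed between items; otherwise mark it valid."""
    out = trial.copy()
    clean = clean_gaze_stream(trial.gaze)
    if trial.choice_index is None:
        out.valid = False
        out.exclusion_reason = "timeout" if trial.rt_ms is None else "clicked_empty"
        return out
    if trial.rt_ms is None:
        out.valid = False
        out.exclusion_reason = "timeout"
        return out
    seen_before_rt = any(
        s.item_index == trial.choice_index and s.onset_ms < trial.rt_ms for s in clean
    )
    if not seen_before_rt:
        out.valid = False
        out.exclusion_reason = "chose_unseen"
        return out
    out.valid = True
    out.exclusion_reason = "none"
    return out


@dataclass
class GazeStatistics:
    """Per-trial derived gaze quantities (arrays indexed by item)."""

    seen: np.ndarray           # bool
    total_gaze_ms: np.ndarray  # int, per item
    cum_gaze_frac: np.ndarray  # total_gaze_ms / rt_ms
    t0_ms: np.ndarray          # first-gaze onset; -1 where never seen
    n_gazes: np.ndarray        # int
    last_gazed_item: int
    rt_ms: int


def gaze_statistics(trial: TrialRecord) -> GazeStatistics:
    """Seen set, cumulative gaze, first-gaze onsets and gaze counts.

    Gaze is truncated at the response time: a segment straddling ``rt_ms``
    contributes only its portion before the response.
    """
    if trial.rt_ms is None:
        raise ValidationError("gaze_statistics requires a response time")
    rt = trial.rt_ms
    clean = [s for s in clean_gaze_stream(trial.gaze) if s.onset_ms < rt]
    if not clean:
        raise ValidationError(
            f"trial {trial.subject_id}/{trial.trial_id}: no item gaze before the response"
        )
    n = trial.set_size
    total = np.zeros(n, dtype=np.int64)
    t0 = np.full(n, -1, dtype=np.int64)
    counts = np.zeros(n, dtype=np.int64)
    for s in clean:
        dur = min(s.end_ms, rt) - s.onset_ms
        total[s.item_index] += dur
        counts[s.item_index] += 1
        if t0[s.item_index] < 0:
            t0[s.item_index] = s.onset_ms
    if total.sum() > rt:
        raise ValidationError(
            f"trial {trial.subject_id}/{trial.trial_id}: gaze time exceeds the response time"
        )
    return GazeStatistics(
        seen=total > 0,
        total_gaze_ms=total,
        cum_gaze_frac=total / rt,
        t0_ms=t0,
        n_gazes=counts,
        last_gazed_item=clean[-1].item_index,
        rt_ms=rt,
    )


def gaze_timecourse(trial: TrialRecord, dt_ms: int = 1) -> tuple[np.ndarray, np.ndarray]:
    """Per-item running gaze fraction ``g_i(t)`` on the grid t = dt, 2dt, ... .

    ``g_i(t)`` is the gaze time item *i* accrued in ``[0, t)`` divided by
    ``t``. If ``dt_ms`` does not divide the response time the final step is
    evaluated at ``t = rt`` (a partial step), so the last column always
    matches the trial-level cumulative gaze fractions.

    Returns ``(t_grid, g)`` with ``g`` of shape ``(set_size, len(t_grid))``.
    """
    if dt_ms < 1:
        raise ValidationError("dt_ms must be >= 1")
    if trial.rt_ms is None:
        raise ValidationError("gaze_timecourse requires a response time")
    rt = trial.rt_ms
    t_grid = np.arange(dt_ms, rt + 1, dt_ms, dtype=np.int64)
    if len(t_grid) == 0 or t_grid[-1] != rt:
        t_grid = np.append(t_grid, rt)
    clean = [s for s in clean_gaze_stream(trial.gaze) if s.onset_ms < rt]
    cum = np.zeros((trial.set_size, len(t_grid)))
    for s in clean:
        # overlap of [onset, end) with [0, t)
        cum[s.item_index] += np.clip(t_grid - s.onset_ms, 0, min(s.end_ms, rt) - s.onset_ms)
    return t_grid, cum / t_grid


def gaze_advantage(stats: GazeStatistics) -> np.ndarray:
    """Each item's cumulative gaze minus the maximum cumulative gaze of any
    other item; at most one item (the uniquely longest-gazed) is positive."""
    frac = np.asarray(stats.cum_gaze_frac, dtype=float)
    if frac.size < 2:
        raise ValidationError("gaze_advantage needs at least two items")
    order = np.argsort(frac)
    top, second = frac[order[-1]], frac[order[-2]]
    adv = frac - top
    adv[order[-1]] = top - second
    return adv
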