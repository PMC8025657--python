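"""Domain types and CSV I/O for many-alternative choice experiments.

The experiment this package models presents square grids of 9, 16, 25 or 36
snack-food items. On each trial the subject freely inspects the grid while
their gaze is tracked, and presses a key when they have decided; each item
carries a 7-point liking rating (-3 "not at all" .. 3 "very much") collected
in a separate rating phase.

Conventions
-----------
* Item grid positions are 0-based, row-major (row 0 = top, col 0 = left).
* Time is integer milliseconds from choice-screen onset; gaze segments are
  half-open intervals ``[onset, onset + duration)``.
* Ratings are stored raw (-3..3); model code rescales them to 1..7 via
  :func:`rescale_rating`.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from pathlib import Path

import pandas as pd

__all__ = [
    "NON_ITEM",
    "MISSING",
    "SET_SIZES",
    "ItemInfo",
    "GazeSegment",
    "TrialRecord",
    "SubjectDataset",
    "DataFormatError",
    "ValidationError",
    "rescale_rating",
    "read_dataset",
    "write_dataset",
    "validate_dataset",
]

#: Sentinel item indices for gaze segments off any item / lost signal.
NON_ITEM = -1
MISSING = -2

#: Set sizes used in the experiment (square grids).
SET_SIZES = (9, 16, 25, 36)

RATING_MIN, RATING_MAX = -3, 3


class DataFormatError(ValueError):
    """A file does not conform to the declared CSV dialect/columns."""


class ValidationError(ValueError):
    """Structurally well-formed data violating a domain invariant."""


def rescale_rating(rating: int) -> int:
    """Map a raw liking rating in -3..3 onto the strictly positive 1..7 scale.

    The affine shift ``rating + 4`` preserves order and makes every item
    value positive, which the stopping/accumulation rules require.
    """
    r = int(rating)
    if r != rating or not RATING_MIN <= r <= RATING_MAX:
        raise ValidationError(f"rating must be an integer in [-3, 3], got {rating!r}")
    return r + 4


@dataclass(frozen=True)
class ItemInfo:
    """One item of a choice set: identity, liking rating, grid cell, size."""

    item_id: str
    rating: int
    row: int
    col: int
    size_frac: float = 0.6

    def validate(self, set_size: int) -> None:
        n = int(math.isqrt(set_size))
        if not RATING_MIN <= self.rating <= RATING_MAX:
            raise ValidationError(f"item {self.item_id}: rating {self.rating} outside [-3, 3]")
        if not (0 <= self.row < n and 0 <= self.col < n):
            raise ValidationError(
                f"item {self.item_id}: grid position ({self.row}, {self.col}) "
                f"outside a {n}x{n} grid"
            )
        if not 0 < self.size_frac <= 1:
            raise ValidationError(f"item {self.item_id}: size_frac {self.size_frac} not in (0, 1]")


@dataclass(frozen=True)
class GazeSegment:
    """A maximal run of consecutive fixations with a single label.

    ``item_index >= 0`` is a gaze to that item; :data:`NON_ITEM` is a fixation
    on empty screen, :data:`MISSING` a signal loss (e.g. a blink).
    """

    item_index: int
    onset_ms: int
    duration_ms: int

    def __post_init__(self) -> None:
        if self.item_index < MISSING:
            raise ValidationError(f"unknown gaze label {self.item_index}")
        if self.onset_ms < 0 or self.duration_ms <= 0:
            raise ValidationError(
                f"gaze segment needs onset >= 0 and duration > 0, "
                f"got onset={self.onset_ms}, duration={self.duration_ms}"
            )

    @property
    def end_ms(self) -> int:
        return self.onset_ms + self.duration_ms


@dataclass
class TrialRecord:
    """One choice trial: item set, gaze stream, choice and response time."""

    subject_id: str
    trial_id: int
    set_size: int
    items: list[ItemInfo]
    gaze: list[GazeSegment]
    choice_index: int | None
    rt_ms: int | None
    valid: bool = True
    exclusion_reason: str = "none"

    def validate(self) -> None:
        if self.set_size not in SET_SIZES:
            raise ValidationError(
                f"trial {self.subject_id}/{self.trial_id}: set_size {self.set_size} "
                f"not one of {SET_SIZES}"
            )
        if len(self.items) != self.set_size:
            raise ValidationError(
                f"trial {self.subject_id}/{self.trial_id}: {len(self.items)} items "
                f"for set_size {self.set_size}"
            )
        for item in self.items:
            item.validate(self.set_size)
        _check_ordered(self.gaze, f"trial {self.subject_id}/{self.trial_id}")
        if self.rt_ms is not None and self.rt_ms <= 0:
            raise ValidationError(f"trial {self.subject_id}/{self.trial_id}: rt_ms must be > 0")
        if self.valid:
            if self.choice_index is None or self.rt_ms is None:
                raise ValidationError(
                    f"trial {self.subject_id}/{self.trial_id}: valid trial needs choice and rt"
                )
            if not 0 <= self.choice_index < self.set_size:
                raise ValidationError(
                    f"trial {self.subject_id}/{self.trial_id}: choice_index "
                    f"{self.choice_index} outside the choice set"
                )
            if not any(
                s.item_index == self.choice_index and s.onset_ms < self.rt_ms
                for s in self.gaze
            ):
                raise ValidationError(
                    f"trial {self.subject_id}/{self.trial_id}: chosen item "
                    f"{self.choice_index} never gazed before the response"
                )

    def copy(self, **changes) -> "TrialRecord":
        out = replace(self, **changes)
        out.items = list(out.items)
        out.gaze = list(out.gaze)
        return out


@dataclass
class SubjectDataset:
    """All trials of one subject plus their item-rating table."""

    subject_id: str
    trials: list[TrialRecord]
    ratings_table: dict[str, int] = field(default_factory=dict)

    def valid_trials(self, set_size: int | None = None) -> list[TrialRecord]:
        return [
            t
            for t in self.trials
            if t.valid and (set_size is None or t.set_size == set_size)
        ]

    def validate(self) -> None:
        for trial in self.trials:
            trial.validate()
            for item in trial.items:
                if item.item_id not in self.ratings_table:
                    raise ValidationError(
                        f"subject {self.subject_id}: item {item.item_id} has no rating"
                    )
                if self.ratings_table[item.item_id] != item.rating:
                    raise ValidationError(
                        f"subject {self.subject_id}: trial {trial.trial_id} rating for "
                        f"{item.item_id} disagrees with the ratings table"
                    )


def _check_ordered(gaze: list[GazeSegment], where: str) -> None:
    for a, b in zip(gaze, gaze[1:]):
        if b.onset_ms < a.end_ms:
            raise ValidationError(f"{where}: gaze segments unordered or overlapping at {b.onset_ms}")


def validate_dataset(datasets: list[SubjectDataset]) -> None:
    for ds in datasets:
        ds.validate()


# ---------------------------------------------------------------------------
# CSV round trip
#
# trials.csv  : subject, trial, setsize, item_ids, rows, cols, size_fracs,
#               choice, rt_ms, valid, exclusion_reason
#               (per-item fields are ';'-joined in item-index order, so one
#                row fully describes the composition of a trial)
# gaze.csv    : subject, trial, item, onset_ms, dur_ms   (item -1 = non-item,
#               -2 = missing)
# ratings.csv : subject, item_id, rating
# ---------------------------------------------------------------------------

TRIALS_COLUMNS = [
    "subject",
    "trial",
    "setsize",
    "item_ids",
    "rows",
    "cols",
    "size_fracs",
    "choice",
    "rt_ms",
    "valid",
    "exclusion_reason",
]
GAZE_COLUMNS = ["subject", "trial", "item", "onset_ms", "dur_ms"]
RATINGS_COLUMNS = ["subject", "item_id", "rating"]


def _require_columns(df: pd.DataFrame, required: list[str], path) -> None:
    missing = [c for c in required if c not in df.columns]
    if missing:
        raise DataFormatError(f"{path}: missing required column(s) {missing}")


def write_dataset(datasets: list[SubjectDataset], out_dir) -> dict[str, Path]:
    """Write ``trials.csv``, ``gaze.csv`` and ``ratings.csv`` under ``out_dir``.

    Rows are emitted in deterministic (subject, trial, onset) order.
    """
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)

    trial_rows, gaze_rows, rating_rows = [], [], []
    for ds in sorted(datasets, key=lambda d: d.subject_id):
        for item_id in sorted(ds.ratings_table):
            rating_rows.append(
                {"subject": ds.subject_id, "item_id": item_id, "rating": ds.ratings_table[item_id]}
            )
        for t in sorted(ds.trials, key=lambda t: t.trial_id):
            trial_rows.append(
                {
                    "subject": ds.subject_id,
                    "trial": t.trial_id,
                    "setsize": t.set_size,
                    "item_ids": ";".join(i.item_id for i in t.items),
                    "rows": ";".join(str(i.row) for i in t.items),
                    "cols": ";".join(str(i.col) for i in t.items),
                    "size_fracs": ";".join(repr(float(i.size_frac)) for i in t.items),
                    "choice": "" if t.choice_index is None else t.choice_index,
                    "rt_ms": "" if t.rt_ms is None else t.rt_ms,
                    "valid": int(t.valid),
                    "exclusion_reason": t.exclusion_reason,
                }
            )
            for s in sorted(t.gaze, key=lambda s: s.onset_ms):
                gaze_rows.append(
                    {
                        "subject": ds.subject_id,
                        "trial": t.trial_id,
                        "item": s.item_index,
                        "onset_ms": s.onset_ms,
                        "dur_ms": s.duration_ms,
                    }
                )

    paths = {
        "trials": out_dir / "trials.csv",
        "gaze": out_dir / "gaze.csv",
        "ratings": out_dir / "ratings.csv",
    }
    pd.DataFrame(trial_rows, columns=TRIALS_COLUMNS).to_csv(paths["trials"], index=False)
    pd.DataFrame(gaze_rows, columns=GAZE_COLUMNS).to_csv(paths["gaze"], index=False)
    pd.DataFrame(rating_rows, columns=RATINGS_COLUMNS).to_csv(paths["ratings"], index=False)
    return paths


def _opt_int(x) -> int | None:
    if pd.isna(x) or x == "":
        return None
    return int(x)


def read_dataset(trials_path, gaze_path, ratings_path) -> list[SubjectDataset]:
    """Assemble :class:`SubjectDataset` objects from the three CSV files.

    Gaze rows whose (subject, trial) key does not appear in the trials file
    are rejected with a :class:`ValidationError` listing the orphan keys.
    """
    trials_df = pd.read_csv(trials_path, dtype={"subject": str})
    gaze_df = pd.read_csv(gaze_path, dtype={"subject": str})
    ratings_df = pd.read_csv(ratings_path, dtype={"subject": str, "item_id": str})
    _require_columns(trials_df, TRIALS_COLUMNS, trials_path)
    _require_columns(gaze_df, GAZE_COLUMNS, gaze_path)
    _require_columns(ratings_df, RATINGS_COLUMNS, ratings_path)

    bad = ratings_df[(ratings_df["rating"] < RATING_MIN) | (ratings_df["rating"] > RATING_MAX)]
    if len(bad):
        raise ValidationError(
            f"{ratings_path}: ratings outside [-3, 3] for "
            f"{bad[['subject', 'item_id']].to_records(index=False).tolist()}"
        )

    known_keys = set(zip(trials_df["subject"], trials_df["trial"]))
    orphans = sorted(
        {k for k in zip(gaze_df["subject"], gaze_df["trial"]) if k not in known_keys}
    )
    if orphans:
        raise ValidationError(f"{gaze_path}: gaze rows reference unknown trials: {orphans}")

    ratings: dict[str, dict[str, int]] = {}
    for r in ratings_df.itertuples(index=False):
        ratings.setdefault(r.subject, {})[r.item_id] = int(r.rating)

    gaze_by_key: dict[tuple, list[GazeSegment]] = {}
    for g in gaze_df.sort_values(["subject", "trial", "onset_ms"]).itertuples(index=False):
        gaze_by_key.setdefault((g.subject, g.trial), []).append(
            GazeSegment(int(g.item), int(g.onset_ms), int(g.dur_ms))
        )

    datasets: dict[str, SubjectDataset] = {}
    for row in trials_df.sort_values(["subject", "trial"]).itertuples(index=False):
        subject = row.subject
        table = ratings.get(subject, {})
        ids = str(row.item_ids).split(";")
        rows_ = [int(x) for x in str(row.rows).split(";")]
        cols_ = [int(x) for x in str(row.cols).split(";")]
        sizes = [float(x) for x in str(row.size_fracs).split(";")]
        if not len(ids) == len(rows_) == len(cols_) == len(sizes):
            raise DataFormatError(
                f"{trials_path}: trial {subject}/{row.trial} has ragged per-item fields"
            )
        items = []
        for item_id, r_, c_, s_ in zip(ids, rows_, cols_, sizes):
            if item_id not in table:
                raise ValidationError(f"subject {subject}: item {item_id} has no rating")
            items.append(ItemInfo(item_id, table[item_id], r_, c_, s_))
        trial = TrialRecord(
            subject_id=subject,
            trial_id=int(row.trial),
            set_size=int(row.setsize),
            items=items,
            gaze=gaze_by_key.get((subject, row.trial), []),
            choice_index=_opt_int(row.choice),
            rt_ms=_opt_int(row.rt_ms),
            valid=bool(int(row.valid)),
            exclusion_reason=str(row.exclusion_reason),
        )
        datasets.setdefault(subject, SubjectDataset(subject, [], table)).trials.append(trial)

    out = [datasets[s] for s in sorted(datasets)]
    validate_dataset(out)
    return out
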