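"""Synthetic many-alternative choice experiments.

Generates complete subjects -- liking ratings, gaze trajectories over
square item grids, and choices/response times produced by one of the
likelihood models -- with the statistical structure the analysis assumes:
square grids of 9/16/25/36 items drawn from an 80-item universe, 7-point
ratings, sequential gaze with shorter initial visits, growing revisit
probability, rating/size-weighted item selection with spatial-neighbour
preference, and a seen-set fraction that shrinks with set size.

The gaze process is a stylized emulator of the qualitative search
regularities such experiments exhibit (centre start, top-left drift,
rating-weighted looking, ~44 ms shorter first visits) — not a generative
gaze model fitted to data; only those regularities are contracted here.

Generation runs in two stages: a *gaze scaffold* long enough to outlast
the decision, then the configured model simulates a (choice, RT) on that
scaffold. The emitted trial is reconciled with the simulated RT per
family: satisficing trials truncate the scaffold at the RT (the running
gaze fractions the likelihood reads are unchanged by truncation, so the
emitted trial is exactly the generating process); the independent race
truncates too (first-gaze onsets are preserved exactly, remaining-time
gaze shares approximately); the relative race rescales the scaffold's
time axis onto the RT so the full-trial gaze fractions the GLAM reads are
preserved exactly.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np

from .data import GazeSegment, ItemInfo, SubjectDataset, TrialRecord, ValidationError
from .models import FAMILIES, TrialModelInput
from .preprocess import apply_trial_exclusions, gaze_statistics

__all__ = [
    "GazeProcessConfig",
    "SyntheticConfig",
    "GroundTruth",
    "gen_ratings",
    "gen_gaze_sequence",
    "gen_subject",
    "gen_null_gaze_subject",
    "gen_experiment",
    "default_recovery_params",
]

#: Default 7-point rating distribution over -3..3: Binomial(6, 1/2), a
#: symmetric bell like the empirical rating histograms.
DEFAULT_RATING_DIST = np.array([1, 6, 15, 20, 15, 6, 1]) / 64.0


@dataclass(frozen=True)
class GazeProcessConfig:
    """Knobs of the gaze-scaffold emulator (durations in ms)."""

    frac_seen_base: float = 1.0          # seen fraction at set size 0 ...
    frac_seen_slope_per_item: float = -0.012  # ... minus this per item
    gaze_dur_mean_ms: float = 400.0
    gaze_dur_shape: float = 2.0
    initial_gaze_shortening_ms: float = 44.0
    min_gaze_ms: int = 50
    return_prob_base: float = 0.10
    return_prob_growth: float = 0.02     # per completed gaze
    return_prob_max: float = 0.75
    rating_weight: float = 0.25          # per raw rating unit
    size_weight: float = 1.0             # per unit size fraction
    spatial_decay: float = 0.35          # per Chebyshev grid step
    start_bias: str = "center_topleft"   # or "uniform"
    scaffold_ms: int = 8000


@dataclass(frozen=True)
class SyntheticConfig:
    """Settings for a full synthetic experiment."""

    n_subjects: int = 1
    set_sizes: tuple[int, ...] = (9, 16, 25, 36)
    trials_per_cond: int = 50
    rating_dist: np.ndarray = field(default_factory=lambda: DEFAULT_RATING_DIST.copy())
    n_items_universe: int = 80
    gaze: GazeProcessConfig = field(default_factory=GazeProcessConfig)
    generator_model: str = "glam"
    generator_variant: str = "active"
    generator_params: dict | None = None
    contaminant_rate: float = 0.05
    seed: int | None = None

    def with_generator(self, model: str, variant: str, params: dict) -> "SyntheticConfig":
        if variant == "passive":
            params = {**params, "gamma": 1.0, "zeta": 0.0}
        return replace(
            self, generator_model=model, generator_variant=variant, generator_params=params
        )


@dataclass
class GroundTruth:
    """Generating model, parameters and per-trial contaminant flags."""

    subject_id: str
    model: str
    variant: str
    params: dict
    contaminant: dict[int, bool] = field(default_factory=dict)  # trial_id -> flag


def gen_ratings(config: SyntheticConfig, rng) -> dict[str, int]:
    """Draw one subject's -3..3 liking ratings over the item universe."""
    rng = np.random.default_rng(rng)
    dist = np.asarray(config.rating_dist, dtype=float)
    if dist.sum() <= 0 or (dist < 0).any() or len(dist) != 7:
        raise ValidationError("rating_dist must be 7 nonnegative weights with positive sum")
    dist = dist / dist.sum()
    levels = np.arange(-3, 4)
    return {
        f"item{i:02d}": int(rng.choice(levels, p=dist))
        for i in range(config.n_items_universe)
    }


def _grid_positions(set_size: int, rng) -> list[tuple[int, int]]:
    n = int(np.sqrt(set_size))
    cells = [(r, c) for r in range(n) for c in range(n)]
    order = rng.permutation(len(cells))
    return [cells[i] for i in order]


def gen_gaze_sequence(
    items: list[ItemInfo], cfg: GazeProcessConfig, rng, horizon_ms: int | None = None
) -> list[GazeSegment]:
    """Generate a contiguous item-gaze scaffold over ``items``.

    The walk starts near the grid centre (or uniformly), moves to unvisited
    items with probability falling as gazes accumulate, prefers highly
    rated, larger and spatially close items, and revisits otherwise. The
    number of distinct items visited targets ``frac_seen_base +
    frac_seen_slope_per_item * set_size`` of the set. Durations are
    gamma-distributed; first visits are shortened. Segments are contiguous
    from t = 0 (the stream is already clean).
    """
    if cfg.gaze_dur_mean_ms <= 0 or cfg.gaze_dur_shape <= 0 or cfg.min_gaze_ms <= 0:
        raise ValidationError("gaze durations must be positive")
    rng = np.random.default_rng(rng)
    horizon = horizon_ms if horizon_ms is not None else cfg.scaffold_ms
    n = len(items)
    ratings = np.array([i.rating for i in items], dtype=float)
    sizes = np.array([i.size_frac for i in items], dtype=float)
    pos = np.array([[i.row, i.col] for i in items], dtype=float)
    target_frac = np.clip(cfg.frac_seen_base + cfg.frac_seen_slope_per_item * n, 0.0, 1.0)
    n_target = int(np.clip(round(target_frac * n), 1, n))

    if cfg.start_bias == "center_topleft":
        center = (np.sqrt(n) - 1) / 2.0
        d = np.abs(pos - center).max(axis=1)
        current = int(rng.choice(np.flatnonzero(d == d.min())))
    elif cfg.start_bias == "uniform":
        current = int(rng.integers(n))
    else:
        raise ValidationError(f"unknown start_bias {cfg.start_bias!r}")

    segs: list[GazeSegment] = []
    visited: list[int] = []
    t = 0
    k = 0
    while t < horizon:
        first_visit = current not in visited
        if first_visit:
            visited.append(current)
        mean = cfg.gaze_dur_mean_ms - (cfg.initial_gaze_shortening_ms if first_visit else 0.0)
        mean = max(mean, float(cfg.min_gaze_ms))
        dur = int(
            max(cfg.min_gaze_ms, round(rng.gamma(cfg.gaze_dur_shape, mean / cfg.gaze_dur_shape)))
        )
        segs.append(GazeSegment(current, t, dur))
        t += dur
        k += 1

        p_ret = min(cfg.return_prob_base + cfg.return_prob_growth * k, cfg.return_prob_max)
        revisit = len(visited) >= n_target or (len(visited) > 1 and rng.random() < p_ret)
        if revisit and len(visited) > 1:
            cands = [i for i in visited if i != current]
        else:
            cands = [i for i in range(n) if i not in visited]
            if not cands:
                cands = [i for i in visited if i != current] or [current]
        cands = np.asarray(cands)
        dist = np.abs(pos[cands] - pos[current]).max(axis=1)
        logits = (
            cfg.rating_weight * ratings[cands]
            + cfg.size_weight * sizes[cands]
            - cfg.spatial_decay * dist
        )
        logits -= logits.max()
        w = np.exp(logits)
        current = int(rng.choice(cands, p=w / w.sum()))
    return segs


def _scaffold_input(items: list[ItemInfo], segs: list[GazeSegment], rt: int) -> TrialModelInput:
    """Model input computed directly from a scaffold (no choice yet)."""
    from .data import rescale_rating

    probe = TrialRecord(
        subject_id="_scaffold",
        trial_id=0,
        set_size=len(items),
        items=list(items),
        gaze=list(segs),
        choice_index=None,
        rt_ms=rt,
        valid=False,
    )
    stats = gaze_statistics(probe)
    values = np.array([rescale_rating(i.rating) for i in items], dtype=float)
    remaining = np.where(stats.t0_ms >= 0, rt - stats.t0_ms, 1).astype(float)
    g_rem = np.where(remaining > 0, stats.total_gaze_ms / np.maximum(remaining, 1e-12), 1.0)
    g_rem = np.clip(np.where(stats.seen, g_rem, 0.0), 0.0, 1.0)
    segments = [
        (s.item_index, s.onset_ms, min(s.end_ms, rt) - s.onset_ms)
        for s in segs
        if s.onset_ms < rt
    ]
    return TrialModelInput(
        values=values,
        seen=stats.seen.copy(),
        g_total=stats.cum_gaze_frac.copy(),
        g_rem=g_rem,
        t0=stats.t0_ms.copy(),
        rt=rt,
        choice=-1,
        n_items=len(items),
        segments=segments,
    )


def _truncate(segs: list[GazeSegment], rt: int) -> list[GazeSegment]:
    out = []
    for s in segs:
        if s.onset_ms >= rt:
            break
        out.append(GazeSegment(s.item_index, s.onset_ms, min(s.end_ms, rt) - s.onset_ms))
    return out


def _rescale(segs: list[GazeSegment], rt: int) -> list[GazeSegment]:
    """Map a scaffold's time axis onto [0, rt], preserving gaze fractions."""
    total = segs[-1].end_ms
    bounds = np.round(
        np.array([0] + [s.end_ms for s in segs], dtype=float) * rt / total
    ).astype(np.int64)
    out = []
    for s, a, b in zip(segs, bounds[:-1], bounds[1:]):
        if b > a:
            out.append(GazeSegment(s.item_index, int(a), int(b - a)))
    return out


def _emit_trial(model, segs, rt, choice):
    if model == "glam":
        return _rescale(segs, rt), rt
    return _truncate(segs, rt), rt


def _simulate_iam_fixed_point(items, segs, params, rng, n_iter=12):
    """Self-consistent independent-race outcome on a gaze scaffold.

    The race's drifts read the *emitted* trial's remaining-time gaze shares,
    which depend on the response time being generated. With the auxiliary
    randomness held fixed (common random numbers) the map RT -> winner
    arrival time is iterated to a fixed point, so the emitted trial's
    statistics reproduce the generating drifts when refitted.
    """
    from .models.iam import _ig_params, iam_drift
    from .models.invgauss import invgauss_rvs_crn

    n = len(items)
    chi = rng.chisquare(1, size=n)
    u = rng.random(n)
    rt = segs[-1].end_ms
    choice = -1
    for _ in range(n_iter):
        inp = _scaffold_input(items, segs, rt)
        D = iam_drift(
            inp.g_rem, inp.values, params["gamma"], params["zeta"], seen=inp.seen
        )
        mu, lam = _ig_params(np.where(inp.seen, D, 0.0), params["v"], params["sigma"])
        fpt = invgauss_rvs_crn(mu, lam, chi, u)
        arrival = np.where(inp.seen & (D > 0), fpt + inp.t0, np.inf)
        if not np.isfinite(arrival).any():
            raise ValidationError("no accumulator can finish (all drifts zero)")
        w = int(np.argmin(arrival))
        rt_new = int(max(inp.t0[w] + 1, 1, round(arrival[w])))
        if rt_new == rt and w == choice:
            break
        choice, rt = w, rt_new
    return choice, rt


def gen_subject(
    config: SyntheticConfig, rng, subject_id: str = "s00"
) -> tuple[SubjectDataset, GroundTruth]:
    """Generate one subject: ratings, gaze scaffolds, model outcomes.

    Contaminant trials are injected at ``contaminant_rate`` per condition:
    a uniform item among all N and a uniform RT within the condition's
    realized model RT range.
    """
    rng = np.random.default_rng(rng)
    if config.generator_params is None:
        raise ValidationError("config.generator_params must be set (see with_generator)")
    params = dict(config.generator_params)
    if config.generator_variant == "passive":
        params.update({"gamma": 1.0, "zeta": 0.0})
    family = FAMILIES[config.generator_model]
    ratings = gen_ratings(config, rng)
    sizes = {k: float(rng.uniform(0.3, 0.95)) for k in ratings}
    truth = GroundTruth(subject_id, config.generator_model, config.generator_variant, params)

    trials: list[TrialRecord] = []
    trial_id = 0
    for set_size in config.set_sizes:
        cond: list[tuple[list[ItemInfo], list[GazeSegment], int, int]] = []
        for _ in range(config.trials_per_cond):
            ids = rng.choice(sorted(ratings), size=set_size, replace=False)
            cells = _grid_positions(set_size, rng)
            items = [
                ItemInfo(i, ratings[i], r, c, sizes[i]) for i, (r, c) in zip(ids, cells)
            ]
            horizon = config.gaze.scaffold_ms
            while True:
                segs = gen_gaze_sequence(items, config.gaze, rng, horizon_ms=horizon)
                if config.generator_model == "iam":
                    choice, rt = _simulate_iam_fixed_point(items, segs, params, rng)
                else:
                    inp = _scaffold_input(items, segs, segs[-1].end_ms)
                    choices, rts = family.simulate(inp, params, rng, n_sims=1)
                    choice, rt = int(choices[0]), int(rts[0])
                # a satisficing stop past the scaffold would freeze gaze
                # fractions the refit cannot see: regrow the scaffold instead
                if (
                    config.generator_model != "psm"
                    or rt <= segs[-1].end_ms
                    or horizon >= 64 * config.gaze.scaffold_ms
                ):
                    break
                horizon *= 2
            cond.append((items, segs, choice, rt))

        model_rts = [rt for *_, rt in cond]
        lo, hi = min(model_rts), max(model_rts)
        for items, segs, choice, rt in cond:
            contam = rng.random() < config.contaminant_rate
            if contam:
                choice = int(rng.integers(set_size))
                rt = int(rng.integers(lo, max(hi, lo + 1)))
                gaze, rt = _truncate(segs, rt), rt
            else:
                gaze, rt = _emit_trial(config.generator_model, segs, rt, choice)
            trial = TrialRecord(
                subject_id=subject_id,
                trial_id=trial_id,
                set_size=set_size,
                items=items,
                gaze=gaze,
                choice_index=choice,
                rt_ms=rt,
                valid=True,
            )
            trial = apply_trial_exclusions(trial)
            truth.contaminant[trial_id] = contam
            trials.append(trial)
            trial_id += 1
    return SubjectDataset(subject_id, trials, ratings), truth


def gen_null_gaze_subject(
    config: SyntheticConfig,
    rng,
    subject_id: str = "null00",
    softmax_tau: float = 0.5,
) -> SubjectDataset:
    """Negative control: choices from a rating-only softmax, independent of
    gaze.

    The gaze process covers the whole set (every item seen) with
    rating-independent selection, so the only path from gaze to choice --
    the consideration set -- is severed and the gaze-influence measure
    should be centred on zero.
    """
    from .data import rescale_rating

    rng = np.random.default_rng(rng)
    gaze_cfg = replace(
        config.gaze,
        frac_seen_base=1.0,
        frac_seen_slope_per_item=0.0,
        rating_weight=0.0,
        size_weight=0.0,
    )
    ratings = gen_ratings(config, rng)
    sizes = {k: float(rng.uniform(0.3, 0.95)) for k in ratings}
    trials = []
    trial_id = 0
    for set_size in config.set_sizes:
        for _ in range(config.trials_per_cond):
            ids = rng.choice(sorted(ratings), size=set_size, replace=False)
            cells = _grid_positions(set_size, rng)
            items = [
                ItemInfo(i, ratings[i], r, c, sizes[i]) for i, (r, c) in zip(ids, cells)
            ]
            horizon = gaze_cfg.scaffold_ms
            while True:
                segs = gen_gaze_sequence(items, gaze_cfg, rng, horizon_ms=horizon)
                if len({s.item_index for s in segs}) == set_size:
                    break
                horizon *= 2
            # response after every item has been seen at least once
            first_seen_end = max(
                next(s.end_ms for s in segs if s.item_index == i) for i in range(set_size)
            )
            rt = int(rng.integers(first_seen_end, segs[-1].end_ms + 1))
            values = np.array([rescale_rating(i.rating) for i in items], dtype=float)
            w = np.exp(softmax_tau * (values - values.max()))
            choice = int(rng.choice(set_size, p=w / w.sum()))
            trial = apply_trial_exclusions(
                TrialRecord(
                    subject_id=subject_id,
                    trial_id=trial_id,
                    set_size=set_size,
                    items=items,
                    gaze=_truncate(segs, rt),
                    choice_index=choice,
                    rt_ms=rt,
                    valid=True,
                )
            )
            trials.append(trial)
            trial_id += 1
    return SubjectDataset(subject_id, trials, ratings)


def gen_experiment(
    config: SyntheticConfig, seed=None
) -> tuple[list[SubjectDataset], list[GroundTruth]]:
    """Generate ``config.n_subjects`` subjects (seeded, reproducible)."""
    root = np.random.default_rng(config.seed if seed is None else seed)
    datasets, truths = [], []
    for s in range(config.n_subjects):
        ds, gt = gen_subject(config, root, subject_id=f"s{s:02d}")
        datasets.append(ds)
        truths.append(gt)
    return datasets, truths


#: Gaze process used by the recovery studies: concentrated, revisit-heavy
#: search whose cumulative-gaze spread across items makes the additive and
#: multiplicative gaze biases separately identifiable from 150 trials.
RECOVERY_GAZE = GazeProcessConfig(
    return_prob_base=0.35,
    return_prob_growth=0.05,
    return_prob_max=0.9,
    spatial_decay=0.6,
    rating_weight=0.1,
    gaze_dur_shape=1.2,
    scaffold_ms=10_000,
)


def recovery_config(
    set_sizes: tuple[int, ...] = (25,), trials_per_cond: int = 150
) -> SyntheticConfig:
    """Study conditions for simulate-then-refit validation runs: one
    mid-range set size, no contaminants, concentrated gaze."""
    return SyntheticConfig(
        set_sizes=set_sizes,
        trials_per_cond=trials_per_cond,
        contaminant_rate=0.0,
        gaze=RECOVERY_GAZE,
    )


def default_recovery_params(model: str, rng, strong_gaze_bias: bool = False) -> dict:
    """Sample generating parameters for recovery studies.

    Ranges sit inside the prior boxes at magnitudes that give the
    experiment's RT scale (roughly 0.5-4 s) and, for the gaze biases, the
    magnitudes typical of fitted subjects (gamma well below 1, zeta of a
    few value units). Softmax/logistic sensitivities stay high enough that
    choices carry value information (subjects pick the best seen item at
    high rates). ``strong_gaze_bias`` narrows gamma/zeta to a strong
    active-gaze regime for model-recovery runs.
    """
    rng = np.random.default_rng(rng)
    if strong_gaze_bias:
        gamma = float(rng.uniform(0.2, 0.45))
        zeta = float(rng.uniform(2.0, 4.0))
    else:
        gamma = float(rng.uniform(0.15, 0.95))
        # the range individual fitted additive biases span across subjects
        zeta = float(rng.uniform(0.0, 8.0))
    if model == "psm":
        return {
            "v": float(rng.uniform(5e-8, 3e-7)),
            "alpha": float(rng.uniform(2e-5, 1.2e-4)),
            "tau": float(rng.uniform(0.8, 2.5)),
            "gamma": gamma,
            "zeta": zeta,
        }
    if model == "iam":
        return {
            "v": float(rng.uniform(1.5e-4, 6e-4)),
            "sigma": float(rng.uniform(0.004, 0.015)),
            "gamma": gamma,
            "zeta": zeta,
        }
    if model == "glam":
        return {
            "v": float(rng.uniform(6e-4, 2e-3)),
            "sigma": float(rng.uniform(0.004, 0.015)),
            "tau": float(rng.uniform(0.3, 2.0)),
            "gamma": gamma,
            "zeta": zeta,
        }
    raise ValidationError(f"unknown model {model!r}")
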