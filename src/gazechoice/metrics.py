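"""Behavioural summary measures for observed or simulated choice data.

The same code path serves observed trials and model simulations: both are
first flattened into a per-trial table (choice, response time, per-item
ratings and cumulative gaze), so a simulated outcome can reuse an observed
trial's gaze statistics (the models generate choices and response times,
not gaze).

The headline statistic is the *gaze influence* measure: after regressing a
binary per-item choice indicator on rating-based predictors (the item's
rating relative to the mean of the others, and the mean and range of the
other items' ratings), the mean residual choice probability of items with a
positive cumulative-gaze advantage minus that of all other items, in
percentage points. It quantifies the extra choice probability earned by the
longest-gazed item once the rating distribution of the set is accounted for.
"""

from __future__ import annotations

import warnings

import numpy as np
import pandas as pd
import statsmodels.api as sm
from sklearn.linear_model import LogisticRegression

from .data import SubjectDataset, TrialRecord
from .preprocess import gaze_advantage, gaze_statistics

__all__ = [
    "trial_table",
    "p_choose_best_seen",
    "p_choose_last_seen",
    "frac_items_seen",
    "gaze_influence",
    "summarize",
]


def trial_table(trials: list[TrialRecord]) -> pd.DataFrame:
    """Flatten valid trials to one row per item per trial."""
    rows = []
    for t in trials:
        if not t.valid:
            continue
        stats = gaze_statistics(t)
        adv = gaze_advantage(stats)
        ratings = np.array([i.rating for i in t.items], dtype=float)
        for i in range(t.set_size):
            rows.append(
                {
                    "subject": t.subject_id,
                    "trial": t.trial_id,
                    "setsize": t.set_size,
                    "item": i,
                    "rating": ratings[i],
                    "chosen": int(i == t.choice_index),
                    "seen": bool(stats.seen[i]),
                    "cum_gaze_frac": stats.cum_gaze_frac[i],
                    "gaze_advantage": adv[i],
                    "last_gazed": int(i == stats.last_gazed_item),
                    "rt_ms": t.rt_ms,
                }
            )
    return pd.DataFrame(rows)


def p_choose_best_seen(trials: list[TrialRecord]) -> float:
    """Fraction of valid trials whose chosen item has the maximum rating
    among the items the subject looked at (rating ties count as success)."""
    hits, n = 0, 0
    for t in trials:
        if not t.valid:
            continue
        stats = gaze_statistics(t)
        ratings = np.array([i.rating for i in t.items], dtype=float)
        best_seen = ratings[stats.seen].max()
        hits += ratings[t.choice_index] == best_seen
        n += 1
    return hits / n if n else float("nan")


def p_choose_last_seen(trials: list[TrialRecord]) -> float:
    """Fraction of valid trials where the chosen item is the last one gazed."""
    hits, n = 0, 0
    for t in trials:
        if not t.valid:
            continue
        hits += gaze_statistics(t).last_gazed_item == t.choice_index
        n += 1
    return hits / n if n else float("nan")


def frac_items_seen(trial: TrialRecord) -> float:
    """Fraction of the choice set the subject looked at during the trial."""
    stats = gaze_statistics(trial)
    return stats.seen.sum() / trial.set_size


def _rating_predictors(df: pd.DataFrame) -> pd.DataFrame:
    """Per-item rating predictors within each trial: relative rating, and
    mean and range of the *other* items' ratings."""
    out = []
    for _, g in df.groupby(["subject", "trial"], sort=False):
        r = g["rating"].to_numpy()
        n = len(r)
        total = r.sum()
        mean_others = (total - r) / (n - 1)
        rng_others = np.empty(n)
        order = np.argsort(r)
        lo, lo2 = r[order[0]], r[order[1]]
        hi, hi2 = r[order[-1]], r[order[-2]]
        for i in range(n):
            mx = hi2 if i == order[-1] else hi
            mn = lo2 if i == order[0] else lo
            rng_others[i] = mx - mn
        out.append(
            pd.DataFrame(
                {
                    "rel_rating": r - mean_others,
                    "mean_others": mean_others,
                    "range_others": rng_others,
                },
                index=g.index,
            )
        )
    return pd.concat(out)


def gaze_influence(
    trials: list[TrialRecord] | pd.DataFrame,
    *,
    seen_only: bool = False,
    method: str = "logistic",
) -> float:
    """Gaze-influence statistic (percentage points) for one subject/condition.

    Fits a per-subject regression of the binary choice indicator on the
    rating predictors, and contrasts mean residuals between items with
    positive and non-positive cumulative-gaze advantage. ``method`` is
    ``"logistic"`` (default) or ``"linear"`` (linear-probability sensitivity
    check). On complete separation the logistic fit falls back to a weakly
    L2-regularized fit.

    Returns NaN when the predictors or outcome are degenerate.
    """
    df = trials if isinstance(trials, pd.DataFrame) else trial_table(trials)
    if seen_only:
        df = df[df["seen"]]
    if df.empty or df["chosen"].nunique() < 2:
        return float("nan")
    X = _rating_predictors(df)
    if (X.std(ddof=0) < 1e-12).all():
        return float("nan")
    y = df["chosen"].to_numpy()
    Xc = sm.add_constant(X.to_numpy(), has_constant="add")

    if method == "linear":
        fitted = sm.OLS(y, Xc).fit().fittedvalues
    elif method == "logistic":
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            try:
                res = sm.Logit(y, Xc).fit(disp=0, maxiter=200)
                if not res.mle_retvals.get("converged", False) or not np.all(
                    np.isfinite(res.params)
                ):
                    raise np.linalg.LinAlgError
                fitted = res.predict(Xc)
            except Exception:
                # complete separation (or a singular Hessian): weakly
                # regularized fallback keeps the statistic defined
                clf = LogisticRegression(C=100.0, max_iter=1000)
                clf.fit(X.to_numpy(), y)
                fitted = clf.predict_proba(X.to_numpy())[:, 1]
    else:
        raise ValueError(f"unknown method {method!r}")

    resid = y - fitted
    pos = df["gaze_advantage"].to_numpy() > 0
    if pos.sum() == 0 or (~pos).sum() == 0:
        return float("nan")
    return 100.0 * (resid[pos].mean() - resid[~pos].mean())


def summarize_table(df: pd.DataFrame, **influence_kwargs) -> pd.DataFrame:
    """Behaviour summary from a per-item trial table (see :func:`trial_table`).

    This is the code path shared by observed and simulated data; simulated
    tables carry the observed gaze columns with model-generated ``chosen``
    and ``rt_ms`` values (and optionally a ``rep`` column distinguishing
    simulation repetitions of the same trial).
    """
    trial_keys = ["trial"] + (["rep"] if "rep" in df.columns else [])
    rows = []
    for (subject, setsize), g in df.groupby(["subject", "setsize"], sort=True):
        per_trial = []
        for _, tg in g.groupby(trial_keys, sort=False):
            chosen = tg[tg["chosen"] == 1]
            if len(chosen) != 1:
                continue
            ratings = tg["rating"].to_numpy()
            seen = tg["seen"].to_numpy()
            per_trial.append(
                {
                    "rt_ms": chosen["rt_ms"].iloc[0],
                    "best_seen": float(chosen["rating"].iloc[0]) >= ratings[seen].max(),
                    "last_seen": bool(chosen["last_gazed"].iloc[0]),
                    "frac_seen": seen.mean(),
                }
            )
        pt = pd.DataFrame(per_trial)
        rows.append(
            {
                "subject": subject,
                "setsize": setsize,
                "n_trials": len(pt),
                "mean_rt_ms": float(pt["rt_ms"].mean()),
                "p_choose_best_seen": float(pt["best_seen"].mean()),
                "p_choose_last_seen": float(pt["last_seen"].mean()),
                "frac_items_seen": float(pt["frac_seen"].mean()),
                "gaze_influence": gaze_influence(g, **influence_kwargs),
            }
        )
    return pd.DataFrame(rows)


def summarize(
    dataset: SubjectDataset | list[TrialRecord] | pd.DataFrame, **influence_kwargs
) -> pd.DataFrame:
    """Behaviour summary per set size: mean RT, P(choose best seen),
    P(choose last seen), fraction of items seen, and gaze influence."""
    if isinstance(dataset, pd.DataFrame):
        return summarize_table(dataset, **influence_kwargs)
    trials = dataset.trials if isinstance(dataset, SubjectDataset) else list(dataset)
    rows = []
    by_cond: dict[tuple, list[TrialRecord]] = {}
    for t in trials:
        if t.valid:
            by_cond.setdefault((t.subject_id, t.set_size), []).append(t)
    for (subject, setsize), ts in sorted(by_cond.items()):
        rows.append(
            {
                "subject": subject,
                "setsize": setsize,
                "n_trials": len(ts),
                "mean_rt_ms": float(np.mean([t.rt_ms for t in ts])),
                "p_choose_best_seen": p_choose_best_seen(ts),
                "p_choose_last_seen": p_choose_last_seen(ts),
                "frac_items_seen": float(np.mean([frac_items_seen(t) for t in ts])),
                "gaze_influence": gaze_influence(ts, **influence_kwargs),
            }
        )
    return pd.DataFrame(rows)
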