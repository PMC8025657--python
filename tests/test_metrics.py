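import numpy as np
import pytest

from gazechoice.data import GazeSegment, ItemInfo, TrialRecord
from gazechoice.metrics import (
    frac_items_seen,
    gaze_influence,
    p_choose_best_seen,
    p_choose_last_seen,
    summarize,
    summarize_table,
    trial_table,
)
from gazechoice.synth import SyntheticConfig, gen_null_gaze_subject, gen_subject

from .conftest import make_trial


def trials_with_choices(choices, last_items=None, rng_seed=0):
    """Trials where item `choices[k]` is chosen; optionally force the last
    gazed item."""
    out = []
    for k, ch in enumerate(choices):
        last = last_items[k] if last_items else ch
        # item 5 (top rating) is always seen, so "best seen" is unambiguous
        gaze = [(5, 0, 300), (ch, 300, 300), (last, 600, 300)]
        out.append(make_trial(trial=k, gaze=tuple(gaze), choice=ch, rt=1000))
    return out


class TestSimpleRates:
    def test_p_choose_best_seen_counts_hits(self):
        # ratings: item5 has rating 3 (max); choose it 3 of 4 times
        trials = trials_with_choices([5, 5, 5, 4])
        assert p_choose_best_seen(trials) == pytest.approx(0.75)

    def test_all_tied_ratings_always_best(self):
        trials = [
            make_trial(ratings=(1,) * 9, gaze=((0, 0, 300), (4, 300, 300)), choice=4, trial=k)
            for k in range(3)
        ]
        assert p_choose_best_seen(trials) == 1.0

    def test_argmax_chooser_scores_one(self):
        cfg = SyntheticConfig(set_sizes=(9,), trials_per_cond=40)
        ds = gen_null_gaze_subject(cfg, np.random.default_rng(0), softmax_tau=100.0)
        assert p_choose_best_seen(ds.valid_trials()) == 1.0

    def test_p_choose_last_seen_fraction(self):
        trials = trials_with_choices([1, 2, 3, 4, 5], last_items=[1, 2, 0, 0, 0])
        assert p_choose_last_seen(trials) == pytest.approx(0.4)

    def test_p_choose_last_seen_uniform_generator(self):
        # choice independent of gaze, uniform over items whose last gaze is
        # uniform -> hit rate ~ 1/N
        rng = np.random.default_rng(1)
        n, hits, total = 9, 0, 0
        for _ in range(10_000):
            last = rng.integers(n)
            choice = rng.integers(n)
            hits += last == choice
            total += 1
        assert hits / total == pytest.approx(1 / n, abs=0.01)

    def test_frac_items_seen(self):
        t = make_trial(
            gaze=tuple((i, 200 * i, 200) for i in range(6)), choice=5, rt=1400
        )
        assert frac_items_seen(t) == pytest.approx(6 / 9)
        t_all = make_trial(gaze=tuple((i, 150 * i, 150) for i in range(9)), choice=8, rt=1400)
        assert frac_items_seen(t_all) == 1.0


class TestGazeInfluence:
    def test_null_choices_centered_on_zero(self):
        cfg = SyntheticConfig(set_sizes=(9,), trials_per_cond=200)
        vals = []
        for seed in range(6):
            ds = gen_null_gaze_subject(cfg, np.random.default_rng(seed), softmax_tau=0.8)
            vals.append(gaze_influence(ds.valid_trials()))
        assert abs(np.mean(vals)) < 2.0

    def test_longest_gaze_chooser_is_strongly_positive(self):
        rng = np.random.default_rng(2)
        trials = []
        for k in range(120):
            ratings = tuple(int(r) for r in rng.integers(-3, 4, size=9))
            items = list(rng.permutation(9)[:4])
            durs = rng.integers(100, 500, size=4)
            gaze, t = [], 0
            for i, d in zip(items, durs):
                gaze.append((int(i), t, int(d)))
                t += int(d)
            longest = items[int(np.argmax(durs))]
            trials.append(
                make_trial(trial=k, ratings=ratings, gaze=tuple(gaze), choice=int(longest), rt=t + 100)
            )
        assert gaze_influence(trials) > 20.0

    def test_residuals_sum_to_zero(self):
        cfg = SyntheticConfig(set_sizes=(9,), trials_per_cond=150)
        ds = gen_null_gaze_subject(cfg, np.random.default_rng(3), softmax_tau=0.8)
        df = trial_table(ds.valid_trials())
        import statsmodels.api as sm

        from gazechoice.metrics import _rating_predictors

        X = sm.add_constant(_rating_predictors(df).to_numpy())
        y = df["chosen"].to_numpy()
        res = sm.Logit(y, X).fit(disp=0)
        assert abs((y - res.predict(X)).sum()) < 1e-6

    def test_invariant_to_constant_rating_shift(self):
        rng = np.random.default_rng(4)
        trials, shifted = [], []
        for k in range(60):
            ratings = tuple(int(r) for r in rng.integers(-3, 2, size=9))
            gaze = ((0, 0, 300), (3, 300, 400), (5, 700, 200))
            choice = int(rng.choice([0, 3, 5]))
            trials.append(make_trial(trial=k, ratings=ratings, gaze=gaze, choice=choice))
            shifted.append(
                make_trial(trial=k, ratings=tuple(r + 1 for r in ratings), gaze=gaze, choice=choice)
            )
        a = gaze_influence(trials)
        b = gaze_influence(shifted)
        assert a == pytest.approx(b, abs=1e-6)

    def test_degenerate_predictors_return_nan(self):
        trials = [
            make_trial(ratings=(0,) * 9, gaze=((0, 0, 300), (1, 300, 300)), choice=1, trial=k)
            for k in range(10)
        ]
        assert np.isnan(gaze_influence(trials))

    def test_linear_method_agrees_in_sign(self):
        cfg = SyntheticConfig(set_sizes=(9,), trials_per_cond=150).with_generator(
            "glam", "active", {"v": 1e-3, "sigma": 0.01, "tau": 1.0, "gamma": 0.3, "zeta": 3.0}
        )
        ds, _ = gen_subject(cfg, np.random.default_rng(5))
        a = gaze_influence(ds.valid_trials(), method="logistic")
        b = gaze_influence(ds.valid_trials(), method="linear")
        assert a > 0 and b > 0


class TestSummaries:
    def test_one_row_per_set_size(self):
        cfg = SyntheticConfig(set_sizes=(9, 16), trials_per_cond=30).with_generator(
            "glam", "active", {"v": 1e-3, "sigma": 0.01, "tau": 1.0, "gamma": 0.5, "zeta": 1.0}
        )
        ds, _ = gen_subject(cfg, np.random.default_rng(6))
        table = summarize(ds)
        assert sorted(table["setsize"]) == [9, 16]
        assert set(table.columns) >= {
            "mean_rt_ms",
            "p_choose_best_seen",
            "p_choose_last_seen",
            "frac_items_seen",
            "gaze_influence",
        }
        assert ((table["p_choose_best_seen"] >= 0) & (table["p_choose_best_seen"] <= 1)).all()

    def test_table_path_matches_trialrecord_path(self):
        cfg = SyntheticConfig(set_sizes=(9,), trials_per_cond=60).with_generator(
            "glam", "active", {"v": 1e-3, "sigma": 0.01, "tau": 1.0, "gamma": 0.5, "zeta": 1.0}
        )
        ds, _ = gen_subject(cfg, np.random.default_rng(7))
        direct = summarize(ds)
        via_table = summarize_table(trial_table(ds.valid_trials()))
        for col in ["mean_rt_ms", "p_choose_best_seen", "p_choose_last_seen", "frac_items_seen"]:
            np.testing.assert_allclose(direct[col], via_table[col], err_msg=col)

    def test_independent_oracle_on_simulated_data(self):
        """Summary measures agree with a from-scratch pandas-free recount."""
        cfg = SyntheticConfig(set_sizes=(9,), trials_per_cond=50).with_generator(
            "iam", "active", {"v": 3e-4, "sigma": 0.01, "gamma": 0.5, "zeta": 1.0}
        )
        ds, _ = gen_subject(cfg, np.random.default_rng(8))
        row = summarize(ds).iloc[0]
        from gazechoice.preprocess import gaze_statistics

        valid = ds.valid_trials()
        rts, best, last, seen = [], [], [], []
        for t in valid:
            st = gaze_statistics(t)
            ratings = [i.rating for i in t.items]
            rts.append(t.rt_ms)
            best.append(
                ratings[t.choice_index]
                == max(r for r, s in zip(ratings, st.seen) if s)
            )
            last.append(st.last_gazed_item == t.choice_index)
            seen.append(st.seen.sum() / t.set_size)
        assert row["mean_rt_ms"] == pytest.approx(np.mean(rts))
        assert row["p_choose_best_seen"] == pytest.approx(np.mean(best))
        assert row["p_choose_last_seen"] == pytest.approx(np.mean(last))
        assert row["frac_items_seen"] == pytest.approx(np.mean(seen))
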