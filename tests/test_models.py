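import numpy as np
import pytest
from scipy import integrate, stats

from gazechoice.data import ValidationError
from gazechoice.models import (
    FAMILIES,
    PASSIVE_FIXED,
    TrialBatch,
    build_inputs,
    contaminant_density,
    glam_joint_density,
    glam_signals,
    iam_drift,
    iam_joint_density,
    invgauss_cdf,
    invgauss_logsf,
    invgauss_pdf,
    invgauss_rvs,
    mix_loglik,
    psm_cached_value,
    psm_choice_prob,
    psm_joint_density,
    psm_stop_density,
    trial_model_input,
)
from gazechoice.models.invgauss import invgauss_rvs_crn

from .conftest import make_trial, random_dataset


@pytest.fixture(scope="module")
def inputs():
    trials = [t for ds in random_dataset(3, n_subjects=2, n_trials=5) for t in ds.trials]
    return build_inputs(trials)


PARAMS = {
    "psm": {"v": 2e-7, "alpha": 6e-5, "tau": 1.0, "gamma": 0.5, "zeta": 1.5},
    "iam": {"v": 3e-4, "sigma": 0.01, "gamma": 0.5, "zeta": 1.5},
    "glam": {"v": 1e-3, "sigma": 0.01, "tau": 1.0, "gamma": 0.5, "zeta": 1.5},
}


class TestInverseGaussian:
    def test_pdf_integrates_to_one(self):
        mu, lam = 800.0, 5000.0
        val, _ = integrate.quad(lambda t: invgauss_pdf(t, mu, lam), 0, np.inf, limit=200)
        assert val == pytest.approx(1.0, abs=1e-6)

    def test_cdf_derivative_matches_pdf(self):
        mu, lam = 600.0, 3000.0
        t = np.linspace(100, 3000, 50)
        h = 1e-3
        num = (invgauss_cdf(t + h, mu, lam) - invgauss_cdf(t - h, mu, lam)) / (2 * h)
        np.testing.assert_allclose(num, invgauss_pdf(t, mu, lam), rtol=1e-5, atol=1e-10)

    def test_sample_mean_matches_mu(self):
        mu, lam = 500.0, 4000.0
        x = invgauss_rvs(mu, lam, size=1_000_000, rng=7)
        assert x.mean() == pytest.approx(mu, rel=5e-3)

    def test_matches_scipy(self):
        mu, lam = 700.0, 2500.0
        t = np.array([100.0, 500.0, 1500.0, 5000.0])
        sp = stats.invgauss(mu / lam, scale=lam)
        np.testing.assert_allclose(invgauss_pdf(t, mu, lam), sp.pdf(t), rtol=1e-10)
        np.testing.assert_allclose(invgauss_cdf(t, mu, lam), sp.cdf(t), rtol=1e-9)

    def test_zero_drift_convention(self):
        # an accumulator with no drift never finishes
        assert invgauss_pdf(100.0, np.inf, 1000.0) == 0
        assert invgauss_cdf(100.0, np.inf, 1000.0) == 0
        assert invgauss_logsf(100.0, np.inf, 1000.0) == 0
        assert invgauss_pdf(-5.0, 100.0, 1000.0) == 0

    def test_crn_draws_follow_the_distribution(self):
        mu, lam = 400.0, 3000.0
        rng = np.random.default_rng(11)
        chi = rng.chisquare(1, size=200_000)
        u = rng.random(200_000)
        x = invgauss_rvs_crn(mu, lam, chi, u)
        ks = stats.kstest(x, stats.invgauss(mu / lam, scale=lam).cdf)
        assert ks.pvalue > 0.01


class TestPSMPieces:
    def test_cached_value_substitutions(self):
        assert psm_cached_value(1.0, 5.0, gamma=0.9, zeta=2.0, seen=True) == 7.0
        assert psm_cached_value(0.0, 4.0, gamma=0.5, zeta=2.0, seen=True) == 2.0
        # passive identity: gamma=1, zeta=0 -> value itself for seen items
        v = np.array([1.0, 4.0, 7.0])
        np.testing.assert_allclose(
            psm_cached_value(np.array([0.3, 0.0, 0.9]), v, 1.0, 0.0, seen=np.ones(3, bool)), v
        )
        # unseen items carry no cached value
        assert psm_cached_value(0.0, 5.0, 0.5, 1.0, seen=False) == 0.0

    def test_choice_prob_uniform_cases(self):
        seen = np.array([True, True, True, True, False])
        c = np.array([2.0, 2.0, 2.0, 2.0, 9.0])
        p = psm_choice_prob(c, tau=1.3, seen=seen)
        np.testing.assert_allclose(p[:4], 0.25)
        assert p[4] == 0
        np.testing.assert_allclose(psm_choice_prob(np.arange(5.0), 0.0, np.ones(5, bool)), 0.2)

    def test_choice_prob_large_tau_is_argmax(self):
        p = psm_choice_prob(np.array([1.0, 3.0, 2.0]), 200.0, np.ones(3, bool))
        np.testing.assert_allclose(p, [0, 1, 0], atol=1e-12)

    def test_stop_hazard_substitution(self, inputs):
        t, q, Q, f = psm_stop_density(inputs[0], {"v": 0.001, "alpha": 0.0, "tau": 1, "gamma": 1, "zeta": 0})
        assert q[np.searchsorted(t, 500)] == pytest.approx(0.5)

    def test_stop_density_sums_to_one(self, inputs):
        for inp in inputs[:3]:
            t, q, Q, f = psm_stop_density(inp, PARAMS["psm"])
            assert f.sum() == pytest.approx(1.0, abs=1e-8)

    def test_degenerate_never_stops(self, inputs):
        t, q, Q, f = psm_stop_density(
            inputs[0], {"v": 0.0, "alpha": 0.0, "tau": 1, "gamma": 1, "zeta": 0}, horizon_ms=5000
        )
        assert np.all(q == 0) and np.all(f == 0)

    def test_joint_density_mass_one(self, inputs):
        t, P = psm_joint_density(inputs[0], PARAMS["psm"])
        assert P.sum() == pytest.approx(1.0, abs=1e-8)


class TestIAMPieces:
    def test_drift_substitutions(self):
        assert iam_drift(1.0, 3.0, gamma=0.9, zeta=2.0) == 5.0
        assert iam_drift(0.0, 4.0, gamma=0.0, zeta=2.0) == 0.0
        v = np.array([2.0, 5.0])
        np.testing.assert_allclose(iam_drift(np.array([0.4, 0.7]), v, 1.0, 0.0), v)

    def test_single_seen_item_reduces_to_plain_density(self, inputs):
        inp = inputs[0]
        # keep only the chosen item seen
        solo = np.zeros_like(inp.seen)
        solo[inp.choice] = True
        import dataclasses

        inp1 = dataclasses.replace(inp, seen=solo)
        t = np.arange(1, 20000)
        P = iam_joint_density(inp1, PARAMS["iam"], t)
        only = P[inp.choice]
        D = iam_drift(
            inp.g_rem[inp.choice], inp.values[inp.choice], PARAMS["iam"]["gamma"], PARAMS["iam"]["zeta"]
        )
        mu = 1.0 / (PARAMS["iam"]["v"] * D)
        lam = 1.0 / PARAMS["iam"]["sigma"] ** 2
        x = t - inp.t0[inp.choice]
        np.testing.assert_allclose(only, invgauss_pdf(x, mu, lam), rtol=1e-10)
        assert np.all(P[np.arange(len(P)) != inp.choice] == 0)


class TestGLAMPieces:
    def test_signals_symmetry_and_substitution(self):
        g = np.array([0.5, 0.5])
        val = np.array([3.0, 3.0])
        A, R, D = glam_signals(g, val, gamma=0.5, zeta=1.0, tau=1.0)
        np.testing.assert_allclose(R, [0.0, 0.0])
        np.testing.assert_allclose(D, [0.5, 0.5])

    def test_tau_zero_gives_half_drift(self):
        A, R, D = glam_signals(
            np.array([0.8, 0.1, 0.1]), np.array([7.0, 1.0, 2.0]), 0.5, 2.0, tau=0.0
        )
        np.testing.assert_allclose(D, 0.5)

    def test_relative_signal_substitution(self):
        # A = (5, 3) -> R = (2, -2) via passive identity on full gaze split
        A, R, D = glam_signals(np.array([1.0, 0.0]), np.array([5.0, 3.0]), 1.0, 0.0, tau=1.0)
        np.testing.assert_allclose(A, [5.0, 3.0])
        np.testing.assert_allclose(R, [2.0, -2.0])

    def test_singleton_seen_has_zero_relative_signal(self):
        A, R, D = glam_signals(
            np.array([0.6, 0.2]), np.array([4.0, 2.0]), 0.5, 1.0, 2.0,
            seen=np.array([True, False]),
        )
        assert R[0] == 0 and D[0] == 0.5
        assert D[1] == 0

    def test_gaze_monotonicity_of_choice_probability(self, inputs):
        """More gaze on an item (others renormalized) weakly raises its
        win probability under an active gaze bias."""
        import dataclasses

        inp = inputs[0]
        tgt = int(np.flatnonzero(inp.seen)[0])
        t = np.arange(1, 30000)
        probs = []
        for boost in (0.0, 0.15, 0.3):
            g = inp.g_total.copy()
            others = inp.seen.copy()
            others[tgt] = False
            scale = (g[others].sum() - boost) / max(g[others].sum(), 1e-12)
            g[others] *= scale
            g[tgt] += boost
            P = glam_joint_density(dataclasses.replace(inp, g_total=g), PARAMS["glam"], t)
            probs.append(P[tgt].sum())
        assert probs[0] <= probs[1] + 1e-9 <= probs[2] + 2e-9


class TestCoarseTimeGrid:
    def test_psm_loglik_converges_with_dt(self, inputs):
        """The coarse-grid satisficing likelihood stays close to the exact
        1 ms grid (per-trial error well below the contaminant floor's
        scale)."""
        batch = TrialBatch(inputs)
        from gazechoice.models import psm_batch_loglik

        ll1 = psm_batch_loglik(batch, PARAMS["psm"], 1)
        for dt in (5, 10):
            lld = psm_batch_loglik(TrialBatch(inputs), PARAMS["psm"], dt)
            assert np.max(np.abs(lld - ll1)) < 0.02


class TestContaminant:
    def test_uniform_density_value(self):
        assert contaminant_density(9, 10_000) == pytest.approx(1 / 90_000)

    def test_zero_model_prob_floor(self):
        u = contaminant_density(9, 10_000)
        assert mix_loglik(np.array([0.0]), u)[0] == pytest.approx(np.log(0.05 * u))

    def test_degenerate_range_rejected(self):
        with pytest.raises(ValidationError):
            contaminant_density(9, 0.0)

    def test_mixture_mass_is_one(self, inputs):
        # sum over items x time of the mixed density equals 1
        inp = inputs[0]
        t, P = psm_joint_density(inp, PARAMS["psm"])
        rt_range = 5000.0
        u = contaminant_density(inp.n_items, rt_range)
        mix = 0.95 * P.sum() + 0.05 * u * inp.n_items * rt_range
        assert mix == pytest.approx(1.0, abs=1e-6)


class TestPassiveEqualsActive:
    @pytest.mark.parametrize("family", ["psm", "iam", "glam"])
    def test_bitwise_equal_logliks(self, family, inputs):
        batch = TrialBatch(inputs)
        spec = FAMILIES[family]
        params = dict(PARAMS[family])
        params.update(PASSIVE_FIXED)
        ll_active_path = spec.loglik(batch, params)
        # passive variant IS the active code path at gamma=1, zeta=0
        ll_again = spec.loglik(TrialBatch(inputs), params)
        np.testing.assert_array_equal(ll_active_path, ll_again)
        assert np.all(np.isfinite(ll_active_path))


class TestRaceMassAndFiniteness:
    @pytest.mark.parametrize("family", ["iam", "glam"])
    def test_total_win_probability_is_one(self, family, inputs):
        dens = iam_joint_density if family == "iam" else glam_joint_density
        t = np.arange(1, 200_000)
        mass = dens(inputs[0], PARAMS[family], t).sum()
        assert mass == pytest.approx(1.0, abs=1e-4)

    @pytest.mark.parametrize("family", ["psm", "iam", "glam"])
    def test_loglik_finite_for_box_corner_params(self, family, inputs):
        batch = TrialBatch(inputs)
        spec = FAMILIES[family]
        rng = np.random.default_rng(0)
        for _ in range(10):
            params = {
                k: float(rng.uniform(lo, hi)) for k, (lo, hi) in spec.prior_box.items()
            }
            assert np.all(np.isfinite(spec.loglik(batch, params)))

    def test_iam_ignores_unseen_items(self, inputs):
        import dataclasses

        inp = inputs[0]
        batch1 = TrialBatch([inp], rt_range_ms=5000)
        # perturb an unseen item's value: likelihood unchanged
        unseen = np.flatnonzero(~inp.seen)
        if len(unseen) == 0:
            pytest.skip("all items seen in fixture trial")
        vals = inp.values.copy()
        vals[unseen[0]] = 1.0 if vals[unseen[0]] != 1.0 else 7.0
        batch2 = TrialBatch([dataclasses.replace(inp, values=vals)], rt_range_ms=5000)
        ll1 = FAMILIES["iam"].loglik(batch1, PARAMS["iam"])
        ll2 = FAMILIES["iam"].loglik(batch2, PARAMS["iam"])
        np.testing.assert_array_equal(ll1, ll2)


class TestSimulators:
    @pytest.mark.parametrize("family", ["psm", "iam", "glam"])
    def test_seeded_reproducibility(self, family, inputs):
        spec = FAMILIES[family]
        c1, r1 = spec.simulate(inputs[0], PARAMS[family], np.random.default_rng(42), n_sims=50)
        c2, r2 = spec.simulate(inputs[0], PARAMS[family], np.random.default_rng(42), n_sims=50)
        np.testing.assert_array_equal(c1, c2)
        np.testing.assert_array_equal(r1, r2)

    def test_psm_huge_v_stops_immediately(self, inputs):
        params = {"v": 1.0, "alpha": 0.0, "tau": 1.0, "gamma": 0.5, "zeta": 1.0}
        _, rts = FAMILIES["psm"].simulate(inputs[0], params, np.random.default_rng(0), n_sims=100)
        assert np.all(rts == 1)

    @pytest.mark.parametrize("family", ["iam", "glam"])
    def test_race_single_runner(self, family, inputs):
        import dataclasses

        inp = inputs[0]
        solo = np.zeros_like(inp.seen)
        solo[inp.choice] = True
        inp1 = dataclasses.replace(inp, seen=solo)
        choices, rts = FAMILIES[family].simulate(
            inp1, PARAMS[family], np.random.default_rng(1), n_sims=20
        )
        assert np.all(choices == inp.choice)
        if family == "iam":
            assert np.all(rts > inp.t0[inp.choice])

    def test_race_all_zero_drift_errors(self, inputs):
        import dataclasses

        inp = dataclasses.replace(inputs[0], g_rem=np.zeros_like(inputs[0].g_rem))
        params = {"v": 3e-4, "sigma": 0.01, "gamma": 0.0, "zeta": 1.5}
        with pytest.raises(ValidationError):
            FAMILIES["iam"].simulate(inp, params, np.random.default_rng(0), n_sims=5)
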