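import numpy as np
import pytest
from hypothesis import given, settings, strategies as st
from scipy.special import gammaln

import hybridscape as hs
from hybridscape.inference import DEFAULT_BOUNDS, aic


def _sfs(entries, sizes):
    return hs.JointSFS(np.asarray(entries, dtype=float), sizes)


class TestPoissonLoglik:
    def test_saturated_case(self):
        obs = _sfs([[0, 3, 1], [2, 5, 4], [1, 2, 0]], (2, 2))
        model = hs.JointSFS(obs.entries * 0.25, (2, 2))
        ll, theta = hs.poisson_loglik(obs, model)
        assert theta == pytest.approx(4.0)
        o = obs.entries[~obs.mask]
        saturated = float(np.sum(o[o > 0] * np.log(o[o > 0]) - o[o > 0]) - gammaln(o + 1).sum())
        assert ll == pytest.approx(saturated)

    def test_scale_invariance(self):
        rng = np.random.default_rng(0)
        obs = _sfs(rng.poisson(5, (4, 4)), (3, 3))
        model = hs.JointSFS(rng.random((4, 4)) + 0.1, (3, 3))
        ll1, th1 = hs.poisson_loglik(obs, model)
        ll2, th2 = hs.poisson_loglik(obs, hs.JointSFS(model.entries * 2, (3, 3)))
        assert ll1 == pytest.approx(ll2)
        assert th2 == pytest.approx(th1 / 2)

    def test_two_by_two_hand_sum(self):
        # n=(1,1): cells (0,1), (1,0), (1,1)... corners (0,0),(1,1) masked
        obs = _sfs([[0, 2], [3, 0]], (1, 1))
        model = _sfs([[0, 1.0], [2.0, 0]], (1, 1))
        ll, theta = hs.poisson_loglik(obs, model)
        assert theta == pytest.approx(5.0 / 3.0)
        lam01, lam10 = 5 / 3, 10 / 3
        hand = (2 * np.log(lam01) - lam01 - np.log(2)) + (
            3 * np.log(lam10) - lam10 - np.log(6)
        )
        assert ll == pytest.approx(hand)

    def test_shape_mismatch_errors(self):
        with pytest.raises(ValueError, match="mismatch"):
            hs.poisson_loglik(_sfs(np.ones((3, 3)), (2, 2)), _sfs(np.ones((4, 4)), (3, 3)))


class TestAic:
    def test_formula(self):
        assert aic(hs.FitResult("X", {}, loglik=0.0, theta=1.0, k=0)) == 0.0
        assert aic(hs.FitResult("X", {}, loglik=-10.0, theta=1.0, k=3)) == pytest.approx(26.0)


class TestModelSelection:
    def test_three_model_arithmetic(self):
        fits = [
            hs.FitResult("A", {}, loglik=-45.0, theta=1, k=5),   # AIC 100
            hs.FitResult("B", {}, loglik=-47.5, theta=1, k=5),   # AIC 105
            hs.FitResult("C", {}, loglik=-55.0, theta=1, k=5),   # AIC 120
        ]
        t = hs.model_selection(fits)
        np.testing.assert_allclose(t["AIC"], [100, 105, 120])
        np.testing.assert_allclose(t["score"], [1.0, 0.75, 0.0])
        w = np.array([1.0, np.exp(-2.5), np.exp(-10)])
        np.testing.assert_allclose(t["wAIC"], w / w.sum(), rtol=1e-12)
        assert t["retained"].tolist() == [True, True, False]

    def test_equal_aic_pair(self):
        fits = [
            hs.FitResult("A", {}, loglik=-10.0, theta=1, k=2),
            hs.FitResult("B", {}, loglik=-10.0, theta=1, k=2),
        ]
        with pytest.warns(UserWarning):
            t = hs.model_selection(fits)
        np.testing.assert_allclose(t["wAIC"], [0.5, 0.5])
        np.testing.assert_allclose(t["score"], [1.0, 1.0])

    def test_dominant_model_weight_rounds_to_one(self):
        fits = [
            hs.FitResult("best", {}, loglik=-10.0, theta=1, k=2),
            hs.FitResult("worse", {}, loglik=-40.0, theta=1, k=2),
        ]
        t = hs.model_selection(fits)
        assert t.loc["best", "wAIC"] == pytest.approx(1.0, abs=1e-6)
        assert not t.loc["worse", "retained"]

    @given(
        lls=st.lists(st.floats(-500, -1), min_size=2, max_size=8),
        ks=st.lists(st.integers(1, 12), min_size=8, max_size=8),
    )
    @settings(max_examples=50, deadline=None)
    def test_invariants_on_random_fit_collections(self, lls, ks):
        fits = [
            hs.FitResult(f"m{i}", {}, loglik=ll, theta=1.0, k=k)
            for i, (ll, k) in enumerate(zip(lls, ks))
        ]
        t = hs.model_selection(fits)
        assert abs(t["wAIC"].sum() - 1.0) < 1e-12
        assert (t["deltaAIC"] >= 0).all() and (t["deltaAIC"] == 0).sum() >= 1
        assert t["score"].between(0, 1).all()
        assert ((t["deltaAIC"] < 10) == t["retained"]).all()


class TestFitScenario:
    def test_same_seed_identical_result(self):
        p = hs.ScenarioParams(nu1=1, nu2=0.5, Ts=0.5)
        mdl = hs.expected_jafs(hs.compile_two_pop("SI", p), (10, 10), n_reps=2000, seed=2)
        obs = hs.JointSFS(
            np.random.default_rng(3).poisson(500 / mdl.unmasked_sum() * mdl.entries), (10, 10)
        )
        kw = dict(n_restarts=2, seed=5, n_reps=800, maxiter=60)
        a = hs.fit_scenario(obs, "SI", **kw)
        b = hs.fit_scenario(obs, "SI", **kw)
        assert a.params == b.params
        assert a.loglik == b.loglik

    def test_generating_model_beats_nested_restriction(self):
        # IM data: the generating model must not fit worse than SI (nested at M=0)
        p = hs.ScenarioParams(nu1=1, nu2=1, M12=4.0, M21=4.0, Ts=1.0)
        mdl = hs.expected_jafs(hs.compile_two_pop("IM", p), (10, 10), n_reps=4000, seed=6)
        obs = hs.JointSFS(
            np.random.default_rng(7).poisson(1500 / mdl.unmasked_sum() * mdl.entries), (10, 10)
        )
        fit_im = hs.fit_scenario(obs, "IM", n_restarts=2, seed=8, n_reps=1500, maxiter=150)
        fit_si = hs.fit_scenario(obs, "SI", n_restarts=2, seed=8, n_reps=1500, maxiter=150)
        assert fit_im.loglik >= fit_si.loglik - 1.0  # MC slack

    def test_restart_log_complete(self):
        p = hs.ScenarioParams(nu1=1, nu2=1, Ts=0.8)
        mdl = hs.expected_jafs(hs.compile_two_pop("SI", p), (8, 8), n_reps=1000, seed=9)
        obs = hs.JointSFS(
            np.random.default_rng(10).poisson(300 / mdl.unmasked_sum() * mdl.entries), (8, 8)
        )
        fit = hs.fit_scenario(obs, "SI", n_restarts=3, seed=11, n_reps=500, maxiter=40)
        assert len(fit.restarts) == 3
        assert all({"start", "end", "loglik", "sim_seed"} <= set(r) for r in fit.restarts)
        assert fit.loglik == pytest.approx(max(r["loglik"] for r in fit.restarts), abs=1e-6)

    def test_documented_free_parameter_counts(self):
        assert len(hs.free_params("IM2m")) == 9
        assert len(hs.free_params("AM2m")) == 10
        assert len(hs.free_params("SI")) == 3
        assert len(hs.free_params("HS")) == 6
        assert len(hs.free_params("SGF1")) == 9

    def test_model_results_summary(self):
        p = hs.ScenarioParams(nu1=1, nu2=1, Ts=0.8)
        mdl = hs.expected_jafs(hs.compile_two_pop("SI", p), (8, 8), n_reps=1000, seed=12)
        obs = hs.JointSFS(
            np.random.default_rng(13).poisson(300 / mdl.unmasked_sum() * mdl.entries), (8, 8)
        )
        res = hs.DemographicModel(obs, "SI", n_reps=500).fit(n_restarts=1, seed=1, maxiter=30)
        text = res.summary()
        assert "SI" in text and "AIC" in text and "nu1" in text
        comp = hs.ModelComparison([res.fit_result, hs.FitResult("IM", {}, res.loglik - 20, 1, 5)])
        assert comp.best_model == "SI"
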