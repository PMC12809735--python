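import numpy as np
import pandas as pd
import pytest
from scipy import stats

from forestfit.nls_fitting import FixedEffects, ModelSpec, PowerHeightModel
from forestfit.nlme_engine import (
    MixedEffectsHeightModel,
    RandomEffectsSpec,
    VarianceFunctionSpec,
    evaluate_variance_fn,
    fit_nlme,
    lrt_variance_functions,
    marginal_loglik,
    standardized_residuals,
)
from forestfit.synthetic_data import SimConfig, generate
from ._oracles import dense_marginal_loglik


def _re_frame(rng, n_plots=4, n_trees=6, plot_sd=(0.5,), placement=("beta0",),
              sigma=1.0, beta0=2.0, beta1=0.6):
    """Small hierarchical sample with plot effects drawn from the given SDs."""
    rows = []
    cov = np.diag(np.square(plot_sd))
    L = np.linalg.cholesky(cov + 1e-14 * np.eye(len(plot_sd)))
    for p in range(n_plots):
        bvec = L @ rng.normal(size=len(plot_sd))
        b0, e = beta0, beta1
        for v, nm in zip(bvec, placement):
            if nm == "beta0":
                b0 += v
            else:
                e += v
        d = rng.uniform(6, 40, n_trees)
        h = 1.3 + b0 * d**e + rng.normal(0, sigma, n_trees)
        for dd, hh in zip(d, h):
            rows.append({"plot_id": f"p{p}", "species": "A",
                         "dbh_cm": dd, "height_m": hh})
    return pd.DataFrame(rows)


class TestVarianceFunctions:
    @pytest.mark.parametrize("kind, params, expected_ratio", [
        ("none", {}, 1.0),
        ("exponential", {"gamma": 0.0}, 1.0),
        ("power", {"gamma": 0.0}, 1.0),
        ("constant_plus_power", {"gamma1": 1.0, "gamma2": 0.0}, 2.0),
    ])
    def test_reductions(self, kind, params, expected_ratio):
        spec = VarianceFunctionSpec(kind, **params)
        sd = evaluate_variance_fn(spec, np.array([5.0, 20.0, 60.0]), sigma=1.7)
        np.testing.assert_allclose(sd, 1.7 * expected_ratio)

    def test_exponential_grows_with_d(self):
        spec = VarianceFunctionSpec("exponential", gamma=0.02)
        sd = evaluate_variance_fn(spec, np.array([5.0, 30.0]), 1.0)
        assert sd[1] > sd[0]

    def test_rejects_unknown_kind(self):
        with pytest.raises(ValueError):
            VarianceFunctionSpec("cauchy")

    def test_rejects_nonpositive_d(self):
        with pytest.raises(ValueError):
            evaluate_variance_fn(VarianceFunctionSpec("power", gamma=0.5), -1.0, 1.0)


class TestMarginalLoglik:
    def test_zero_variance_equals_nls_loglik(self, rng):
        frame = _re_frame(rng, plot_sd=(0.0,))
        fe = FixedEffects(2.0, 0.6)
        re = RandomEffectsSpec(("beta0",), (), plot_cov=np.array([[0.0]]))
        ll = marginal_loglik(fe, re, VarianceFunctionSpec(), frame,
                             frame["height_m"], sigma=1.0, spec=ModelSpec(()))
        r = frame["height_m"].to_numpy() - (1.3 + 2.0 * frame["dbh_cm"].to_numpy()**0.6)
        assert ll == pytest.approx(float(np.sum(stats.norm.logpdf(r, 0, 1.0))), abs=1e-9)

    @pytest.mark.parametrize("placement, sds", [
        (("beta0",), (0.5,)),
        (("beta1",), (0.11,)),
        (("beta0", "beta1"), (0.736, 0.110)),
    ])
    def test_matches_dense_quadrature(self, rng, placement, sds):
        frame = _re_frame(rng, n_plots=2, n_trees=6, plot_sd=sds, placement=placement)
        fe = FixedEffects(2.0, 0.6)
        re = RandomEffectsSpec(placement, (), plot_cov=np.diag(np.square(sds)))
        var = VarianceFunctionSpec()
        ll = marginal_loglik(fe, re, var, frame, frame["height_m"], 1.0, ModelSpec(()))
        oracle = dense_marginal_loglik(fe, re, var, frame, 1.0)
        assert ll == pytest.approx(oracle, abs=1e-3)

    def test_gaussian_scaling_identity(self, rng):
        """For the no-random-effect Gaussian model, doubling sigma and the
        deviations shifts the log-likelihood by exactly -n log 2."""
        frame = _re_frame(rng, plot_sd=(0.0,))
        fe = FixedEffects(2.0, 0.6)
        re = RandomEffectsSpec((), ())
        pred = 1.3 + 2.0 * frame["dbh_cm"].to_numpy()**0.6
        y1 = frame["height_m"].to_numpy()
        y2 = pred + 2.0 * (y1 - pred)
        ll1 = marginal_loglik(fe, re, VarianceFunctionSpec(), frame, y1, 1.0, ModelSpec(()))
        ll2 = marginal_loglik(fe, re, VarianceFunctionSpec(), frame, y2, 2.0, ModelSpec(()))
        assert ll2 == pytest.approx(ll1 - len(frame) * np.log(2.0), abs=1e-9)

    def test_invariant_to_plot_relabelling_and_order(self, rng):
        frame = _re_frame(rng, n_plots=3, plot_sd=(0.4,))
        fe = FixedEffects(2.0, 0.6)
        re = RandomEffectsSpec(("beta0",), (), plot_cov=np.array([[0.16]]))
        ll = marginal_loglik(fe, re, VarianceFunctionSpec(), frame,
                             frame["height_m"], 1.0, ModelSpec(()))
        shuffled = frame.sample(frac=1.0, random_state=1).reset_index(drop=True)
        shuffled["plot_id"] = shuffled["plot_id"].map({"p0": "zz", "p1": "aa", "p2": "mm"})
        ll2 = marginal_loglik(fe, re, VarianceFunctionSpec(), shuffled,
                              shuffled["height_m"], 1.0, ModelSpec(()))
        assert ll2 == pytest.approx(ll, abs=1e-8)


class TestFitNlme:
    def test_zero_re_data_matches_nls(self, rng):
        frame = _re_frame(rng, n_plots=8, n_trees=20, plot_sd=(0.0,), sigma=1.0)
        nls = PowerHeightModel().fit(frame, frame["height_m"])
        res = fit_nlme(frame, frame["height_m"],
                       re_spec=RandomEffectsSpec(("beta0",), ()))
        assert res.fixed.beta0 == pytest.approx(nls.fixed_effects_.beta0,
                                                abs=2 * nls.se_.beta0)
        assert res.fixed.beta1 == pytest.approx(nls.fixed_effects_.beta1,
                                                abs=2 * nls.se_.beta1)

    def test_small_instance_beats_truth_loglik(self):
        cfg = SimConfig(n_plots=6, trees_per_plot=4, species_mix={"Lg": 1.0},
                        truth=FixedEffects(2.0, 0.6),
                        re_truth=RandomEffectsSpec(("beta0",), (),
                                                   plot_cov=np.array([[0.16]])),
                        sigma=0.5, seed=3)
        frame = generate(cfg).frame
        res = fit_nlme(frame, frame["height_m"],
                       re_spec=RandomEffectsSpec(("beta0",), ()))
        truth_ll = marginal_loglik(
            FixedEffects(2.0, 0.6), RandomEffectsSpec(("beta0",), (),
                                                      plot_cov=np.array([[0.16]])),
            VarianceFunctionSpec(), frame, frame["height_m"], 0.5,
            ModelSpec(()), method="linearized")
        assert res.loglik >= truth_ll - 1e-6

    def test_needs_five_plots(self, rng):
        frame = _re_frame(rng, n_plots=3)
        with pytest.raises(ValueError, match="5 plots"):
            fit_nlme(frame, frame["height_m"])

    def test_param_census(self, small_mixed_forest):
        frame = small_mixed_forest.frame
        res = fit_nlme(frame, frame["height_m"], ModelSpec(("QMD",)),
                       RandomEffectsSpec(("beta0", "beta1"), ("QMD",)),
                       VarianceFunctionSpec("power"))
        census = res.param_census
        # 3 fixed + 3 plot-cov (unstructured 2x2) + 1 species + 1 gamma + sigma
        assert census == {"fixed_effects": 3, "plot_cov_params": 3,
                          "species_var_params": 1, "variance_fn_params": 1,
                          "sigma": 1}
        assert res.n_params == 9
        assert res.aic == pytest.approx(-2 * res.loglik + 2 * 9)

    def test_fit_invariant_to_tree_order(self, rng):
        frame = _re_frame(rng, n_plots=6, n_trees=12, plot_sd=(0.4,))
        res = fit_nlme(frame, frame["height_m"],
                       re_spec=RandomEffectsSpec(("beta0",), ()))
        shuffled = frame.sample(frac=1.0, random_state=3).reset_index(drop=True)
        res2 = fit_nlme(shuffled, shuffled["height_m"],
                        re_spec=RandomEffectsSpec(("beta0",), ()))
        assert res2.loglik == pytest.approx(res.loglik, abs=1e-4)
        assert res2.fixed.beta0 == pytest.approx(res.fixed.beta0, rel=1e-4)


class TestStandardizedResiduals:
    def test_wellspecified_sd_near_one(self, small_mixed_forest):
        frame = small_mixed_forest.frame
        res = fit_nlme(frame, frame["height_m"],
                       ModelSpec(("SOC", "MAP", "SIM", "BAL", "QMD")),
                       RandomEffectsSpec(("beta0", "beta1"), ("QMD",)))
        sd = float(np.std(standardized_residuals(res)))
        assert 0.8 <= sd <= 1.2

    def test_by_species_summary(self, small_mixed_forest):
        frame = small_mixed_forest.frame
        res = fit_nlme(frame, frame["height_m"],
                       re_spec=RandomEffectsSpec(("beta0",), ()))
        tab = standardized_residuals(res, by_species=True)
        assert set(tab.columns) == {"species", "count", "mean", "std"}
        assert tab["count"].sum() == len(frame)

    def test_heteroscedastic_misfit_leaves_trend(self, rng):
        """Fitting a homoscedastic model to strongly D-dependent noise leaves
        |residual| positively rank-correlated with D."""
        n = 1500
        d = rng.uniform(5, 60, n)
        h = 1.3 + 2.0 * d**0.6 + rng.normal(0, 0.05 * d, n)
        frame = pd.DataFrame({"dbh_cm": d, "height_m": h,
                              "plot_id": np.repeat([f"p{i}" for i in range(10)], n // 10),
                              "species": "A"})
        res = fit_nlme(frame, frame["height_m"],
                       re_spec=RandomEffectsSpec(("beta0",), ()))
        rho, p = stats.spearmanr(np.abs(res.std_residuals), d)
        assert rho > 0 and p < 1e-6


class TestLrt:
    def test_identical_model_twice(self, rng):
        frame = _re_frame(rng, n_plots=6, n_trees=15, plot_sd=(0.4,))
        res = fit_nlme(frame, frame["height_m"],
                       re_spec=RandomEffectsSpec(("beta0",), ()))
        tab = lrt_variance_functions(res, [("same", res)])
        row = tab[tab.model == "same"].iloc[0]
        assert row.l_ratio == pytest.approx(0.0, abs=1e-9)
        assert row.p_value == 1.0

    def test_non_nested_rejected(self, rng):
        frame = _re_frame(rng, n_plots=6, n_trees=15, plot_sd=(0.4,))
        full = fit_nlme(frame, frame["height_m"],
                        re_spec=RandomEffectsSpec(("beta0",), ()),
                        var_spec=VarianceFunctionSpec("power"))
        base = fit_nlme(frame, frame["height_m"],
                        re_spec=RandomEffectsSpec(("beta0",), ()))
        with pytest.raises(ValueError, match="nested"):
            lrt_variance_functions(full, [("smaller", base)])

    def test_flags_minimal_aic(self, rng):
        frame = _re_frame(rng, n_plots=6, n_trees=15, plot_sd=(0.4,))
        base = fit_nlme(frame, frame["height_m"],
                        re_spec=RandomEffectsSpec(("beta0",), ()))
        ext = fit_nlme(frame, frame["height_m"],
                       re_spec=RandomEffectsSpec(("beta0",), ()),
                       var_spec=VarianceFunctionSpec("power"))
        tab = lrt_variance_functions(base, [("power", ext)])
        assert tab["best_aic"].sum() == 1


class TestConditionalPrediction:
    def test_conditional_beats_population_in_sample(self, rng):
        frame = _re_frame(rng, n_plots=8, n_trees=15, plot_sd=(0.6,), sigma=0.8)
        est = MixedEffectsHeightModel(plot_effects=("beta0",)).fit(
            frame, frame["height_m"])
        y = frame["height_m"].to_numpy()
        rmse_pop = np.sqrt(np.mean((y - est.predict(frame)) ** 2))
        rmse_cond = np.sqrt(np.mean((y - est.predict(frame, level="conditional")) ** 2))
        assert rmse_cond < rmse_pop

    def test_sklearn_get_params(self):
        est = MixedEffectsHeightModel(("QMD",), variance_function="power")
        p = est.get_params()
        assert p["variance_function"] == "power"
        est2 = MixedEffectsHeightModel().set_params(**p)
        assert est2.exponent_covariates == ("QMD",)
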