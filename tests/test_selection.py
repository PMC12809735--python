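import numpy as np
import pandas as pd
import pytest

from forestfit.selection import (
    CandidateSet,
    aic_ladder,
    select_covariates,
    stage1_correlations,
    stage1_species_fits,
    vif_filter,
)
from forestfit.nls_fitting import FixedEffects
from forestfit.nlme_engine import RandomEffectsSpec
from forestfit.synthetic_data import SimConfig, generate


class TestStage1Fits:
    def _frame(self, rng, b1_by_species):
        rows = []
        for sp, b1 in b1_by_species.items():
            d = rng.uniform(5, 40, 150)
            h = 1.3 + 2.0 * d**b1 + rng.normal(0, 0.5, 150)
            for dd, hh in zip(d, h):
                rows.append({"plot_id": "p1", "species": sp,
                             "dbh_cm": dd, "height_m": hh})
        return pd.DataFrame(rows)

    def test_exponent_ordering_recovered(self, rng):
        frame = self._frame(rng, {"fast": 0.9, "slow": 0.5})
        tab = stage1_species_fits(frame, min_species_n=100)
        b1 = tab.set_index("species")["beta1"]
        assert b1["fast"] > b1["slow"]
        assert b1["fast"] == pytest.approx(0.9, abs=0.05)

    def test_noiseless_recovery(self, rng):
        frame = self._frame(rng, {"a": 0.7})
        frame["height_m"] = 1.3 + 2.0 * frame["dbh_cm"] ** 0.7
        tab = stage1_species_fits(frame, min_species_n=100)
        assert tab.iloc[0]["beta1"] == pytest.approx(0.7, abs=1e-6)

    def test_small_species_excluded(self, rng):
        frame = self._frame(rng, {"big": 0.7})
        frame = pd.concat([frame, frame.iloc[:10].assign(species="rare")])
        tab = stage1_species_fits(frame, min_species_n=100)
        assert "rare" not in set(tab["species"])


class TestStage1Correlations:
    def test_affine_function_gives_unit_correlation(self):
        coefs = pd.DataFrame({"beta0": [2.0, 2.2, 1.9, 2.4, 2.1],
                              "beta1": [0.5, 0.6, 0.45, 0.7, 0.55]})
        cand = CandidateSet({"stand": ["X"]},
                            pd.DataFrame({"X": 3.0 * coefs["beta1"] - 1.0}))
        tab = stage1_correlations(coefs, cand)
        row = tab[(tab.coefficient == "beta1") & (tab.covariate == "X")].iloc[0]
        assert row.r == pytest.approx(1.0)
        assert row.p_value < 1e-6

    def test_constant_covariate_flagged(self):
        coefs = pd.DataFrame({"beta0": [2.0, 2.2, 1.9], "beta1": [0.5, 0.6, 0.45]})
        cand = CandidateSet({"site": ["C"]}, pd.DataFrame({"C": [1.0, 1.0, 1.0]}))
        tab = stage1_correlations(coefs, cand)
        assert not tab["defined"].any()

    def test_null_covariate_p_roughly_uniform(self):
        """Under independence the p-values should not pile up near zero."""
        rng = np.random.default_rng(0)
        pvals = []
        for _ in range(200):
            coefs = pd.DataFrame({"beta1": rng.normal(0.6, 0.1, 50)})
            cand = CandidateSet({"g": ["Z"]}, pd.DataFrame({"Z": rng.normal(size=50)}))
            tab = stage1_correlations(coefs, cand, coefficients=("beta1",))
            pvals.append(tab.iloc[0].p_value)
        assert 0.01 < np.mean(np.array(pvals) < 0.05) < 0.12
        assert abs(np.mean(pvals) - 0.5) < 0.08

    def test_affine_rescaling_invariance(self, rng):
        coefs = pd.DataFrame({"beta1": rng.normal(0.6, 0.1, 30)})
        z = rng.normal(size=30)
        t1 = stage1_correlations(coefs, CandidateSet({"g": ["Z"]}, pd.DataFrame({"Z": z})),
                                 coefficients=("beta1",))
        t2 = stage1_correlations(coefs, CandidateSet({"g": ["Z"]},
                                                     pd.DataFrame({"Z": 100 * z + 7})),
                                 coefficients=("beta1",))
        assert t1.iloc[0].r == pytest.approx(t2.iloc[0].r)


class TestVif:
    def test_orthogonal_covariates_kept(self, rng):
        n = 200
        X = pd.DataFrame(rng.normal(size=(n, 4)), columns=list("abcd"))
        kept, vifs = vif_filter(X)
        assert kept == list("abcd")
        assert all(v < 1.2 for v in vifs.values())

    def test_duplicate_column_dropped(self, rng):
        n = 100
        a = rng.normal(size=n)
        X = pd.DataFrame({"a": a, "b": a.copy(), "c": rng.normal(size=n)})
        kept, _ = vif_filter(X)
        assert len(kept) == 2 and "c" in kept

    def test_matches_statsmodels_oracle(self, rng):
        from statsmodels.stats.outliers_influence import variance_inflation_factor
        import statsmodels.api as sm
        n = 300
        z = rng.normal(size=(n, 2))
        X = pd.DataFrame({
            "x1": z[:, 0], "x2": 0.8 * z[:, 0] + 0.6 * rng.normal(size=n),
            "x3": z[:, 1], "x4": 0.5 * z[:, 1] + 0.5 * z[:, 0] + rng.normal(size=n),
            "x5": rng.normal(size=n)})
        _, vifs = vif_filter(X, threshold=np.inf)
        Xc = sm.add_constant(X.to_numpy())
        for j, name in enumerate(X.columns):
            want = variance_inflation_factor(Xc, j + 1)
            assert vifs[name] == pytest.approx(want, rel=1e-6)

    def test_deterministic_drop_order(self, rng):
        n = 150
        base = rng.normal(size=n)
        X = pd.DataFrame({"a": base + 0.01 * rng.normal(size=n),
                          "b": base + 0.01 * rng.normal(size=n),
                          "c": rng.normal(size=n)})
        k1, _ = vif_filter(X)
        k2, _ = vif_filter(X)
        assert k1 == k2


class TestAicLadder:
    def test_single_rung_order(self, norE_forest):
        frame = norE_forest.frame
        tab = aic_ladder(frame, order=[("developmental stage", "QMD")])
        assert list(tab["model"]) == ["basic", "M1"]
        assert tab.iloc[1]["variables"] == "D + QMD"

    def test_full_model_wins_when_data_generated_from_it(self, study_scale_ols_forest):
        frame = study_scale_ols_forest.frame
        tab = aic_ladder(frame)
        assert len(tab) == 6
        assert tab["aic"].idxmin() == len(tab) - 1
        # AIC is non-increasing along the build-up on full-model data
        assert all(np.diff(tab["aic"]) < 0)

    def test_base_competitive_under_null(self):
        """Data from the base model: the base rung stays within a few AIC of
        the best in most replicates."""
        hits = 0
        for seed in range(5):
            cfg = SimConfig(n_plots=25, trees_per_plot=25,
                            truth=FixedEffects(2.817, 0.545),
                            re_truth=RandomEffectsSpec((), ()),
                            sigma=2.65, seed=100 + seed)
            frame = generate(cfg).frame
            tab = aic_ladder(frame)
            if tab.iloc[0]["aic"] <= tab["aic"].min() + 2 * len(tab):
                hits += 1
        assert hits >= 3


class TestSelectCovariates:
    def test_end_to_end(self, norE_forest):
        frame = norE_forest.frame
        plot_table = (frame.groupby("plot_id")
                      .agg({"QMD": "first", "MD": "first", "SOC": "first",
                            "MAP": "first", "SIM": "first", "BAL": "mean"})
                      .reset_index())
        cand = CandidateSet({"stand": ["QMD", "MD", "BAL"],
                             "climate": ["MAP"], "soil": ["SOC"],
                             "diversity": ["SIM"]}, plot_table)
        res = select_covariates(frame, cand)
        assert all(v <= 5.0 + 1e-9 for v in res.vif_table.values())
        # QMD and MD are near-collinear by construction: one must go
        assert not {"QMD", "MD"} <= set(res.chosen)
        assert res.aic_ladder is not None
        payload = res.to_json()
        assert "vif_table" in payload
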