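import math

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from forestfit.data_model import ForestDataset, PlotRecord, TreeRecord
from forestfit.stand_metrics import (
    annual_heat_moisture,
    compute_bal,
    compute_qmd,
    compute_stand_metrics,
    de_martonne,
    dominant_height,
    shannon_index,
    simpson_index,
    stage_transforms,
    tree_basal_area,
)
from ._oracles import bal_double_loop

positive_dbh_lists = st.lists(st.floats(5.0, 80.0), min_size=1, max_size=40)


class TestBasalArea:
    def test_formula(self):
        assert tree_basal_area(20.0) == pytest.approx(math.pi * 0.1**2)

    def test_rejects_nonpositive(self):
        with pytest.raises(ValueError):
            tree_basal_area(0.0)

    def test_sum_matches_loop(self, rng):
        d = rng.uniform(5, 60, 100)
        assert sum(tree_basal_area(x) for x in d) == pytest.approx(
            np.sum(np.pi * (d / 200) ** 2))


class TestQmd:
    @pytest.mark.parametrize("dbh, expected", [([10.0], 10.0), ([3.0, 4.0], math.sqrt(12.5))])
    def test_values(self, dbh, expected):
        assert compute_qmd(dbh) == pytest.approx(expected)

    def test_empty_rejected(self):
        with pytest.raises(ValueError):
            compute_qmd([])

    def test_brute_force(self, rng):
        d = rng.uniform(5, 60, 1000)
        assert compute_qmd(d) == pytest.approx(math.sqrt(sum(x * x for x in d) / len(d)))


class TestBal:
    def test_single_tree_is_zero(self):
        assert compute_bal([17.0], 0.1)[0] == 0.0

    def test_two_trees(self):
        bal = compute_bal([10.0, 20.0], 0.1)
        assert bal[0] == pytest.approx(math.pi * 0.1**2 / 0.1)
        assert bal[1] == 0.0

    def test_ties_contribute_nothing(self):
        bal = compute_bal([15.0, 15.0, 10.0], 0.06)
        assert bal[0] == bal[1] == 0.0
        assert bal[2] > 0

    @settings(deadline=None, max_examples=25)
    @given(positive_dbh_lists)
    def test_matches_double_loop(self, dbh):
        got = compute_bal(dbh, 0.25)
        want = bal_double_loop(dbh, 0.25)
        np.testing.assert_allclose(got, want, atol=1e-12)

    @settings(deadline=None, max_examples=25)
    @given(positive_dbh_lists)
    def test_nonincreasing_in_diameter(self, dbh):
        bal = compute_bal(dbh, 0.1)
        order = np.argsort(dbh)
        assert np.all(np.diff(bal[order]) <= 1e-12)


class TestDiversity:
    def test_pure_stand_zero(self):
        assert simpson_index({"A": 30}) == 0.0
        assert shannon_index({"A": 10}) == 0.0

    def test_even_two_species(self):
        assert simpson_index({"A": 50, "B": 50}) == pytest.approx(0.5)
        assert shannon_index({"A": 1, "B": 1}) == pytest.approx(math.log(2))

    def test_uniform_maximises_shannon(self):
        assert shannon_index({s: 4 for s in "ABCDE"}) == pytest.approx(math.log(5))

    def test_simpson_brute_force(self, rng):
        counts = {f"s{i}": int(c) for i, c in enumerate(rng.integers(1, 50, 5))}
        total = sum(counts.values())
        want = 1 - sum((c / total) ** 2 for c in counts.values())
        assert simpson_index(counts) == pytest.approx(want)

    @settings(deadline=None, max_examples=25)
    @given(st.lists(st.integers(1, 100), min_size=1, max_size=8))
    def test_bounds_and_scale_invariance(self, counts):
        ab = {f"s{i}": c for i, c in enumerate(counts)}
        k = len(ab)
        sim = simpson_index(ab)
        shi = shannon_index(ab)
        assert 0 <= sim <= 1 - 1 / k + 1e-12
        assert -1e-12 <= shi <= math.log(k) + 1e-12
        doubled = {s: 2 * c for s, c in ab.items()}
        assert simpson_index(doubled) == pytest.approx(sim)
        assert shannon_index(doubled) == pytest.approx(shi)

    def test_all_zero_rejected(self):
        with pytest.raises(ValueError):
            simpson_index({"A": 0})


class TestSiteAndClimate:
    def test_stage_transform_limits(self):
        e = math.e
        assert stage_transforms(0.0, e) == pytest.approx((0.0, 1.0))
        assert stage_transforms(90.0, e) == pytest.approx((1.0, 0.0))

    def test_stage_transform_arithmetic(self):
        sie, cie = stage_transforms(47.0, 423.8)
        assert sie == pytest.approx(math.sin(math.radians(47)) * math.log(423.8))
        assert sie == pytest.approx(4.4240, abs=5e-4)

    def test_stage_transform_rejects_low_elevation(self):
        with pytest.raises(ValueError):
            stage_transforms(10.0, 0.5)

    @pytest.mark.parametrize("map_mm, mat, expected",
                             [(0.0, 5.0, 0.0), (400.0, 0.0, 40.0),
                              (454.10, -2.94, 64.32)])
    def test_de_martonne(self, map_mm, mat, expected):
        assert de_martonne(map_mm, mat) == pytest.approx(expected, abs=5e-3)

    def test_de_martonne_domain(self):
        with pytest.raises(ValueError):
            de_martonne(400.0, -10.0)

    @pytest.mark.parametrize("mat, map_mm, expected",
                             [(0.0, 1000.0, 10.0), (-2.94, 454.1, 15.55)])
    def test_ahm(self, mat, map_mm, expected):
        assert annual_heat_moisture(mat, map_mm) == pytest.approx(expected, abs=5e-3)

    def test_ahm_decreasing_in_map(self):
        vals = [annual_heat_moisture(0.0, m) for m in (300, 400, 500)]
        assert vals[0] > vals[1] > vals[2]


class TestDominantHeight:
    def test_single_species(self):
        trees = [TreeRecord("p", "A", 10, 10.0), TreeRecord("p", "A", 12, 15.0)]
        assert dominant_height(trees) == 15.0

    def test_mean_over_species_maxima(self):
        trees = [TreeRecord("p", "A", 10, 10.0), TreeRecord("p", "B", 12, 20.0)]
        assert dominant_height(trees) == 15.0

    def test_matches_loop_oracle(self, rng):
        trees = [TreeRecord("p", rng.choice(["A", "B", "C"]), float(d), float(h))
                 for d, h in zip(rng.uniform(5, 40, 30), rng.uniform(3, 25, 30))]
        maxima = {}
        for t in trees:
            maxima[t.species] = max(maxima.get(t.species, -1), t.height_m)
        assert dominant_height(trees) == pytest.approx(np.mean(list(maxima.values())))


class TestComputeStandMetrics:
    def _toy(self):
        trees = [TreeRecord("p1", "A", 10.0, 8.0), TreeRecord("p1", "B", 20.0, 14.0)]
        plots = {"p1": PlotRecord("p1", 0.1)}
        return ForestDataset(trees, plots)

    def test_hand_worked_two_tree_plot(self):
        m = compute_stand_metrics(self._toy(), "p1")
        assert m.qmd_cm == pytest.approx(math.sqrt((100 + 400) / 2))
        assert m.md_cm == pytest.approx(15.0)
        ba = math.pi * (0.05**2 + 0.1**2)
        assert m.ba_m2_ha == pytest.approx(ba / 0.1)
        assert m.n_per_ha == pytest.approx(20.0)
        assert m.dh_m == pytest.approx(11.0)
        assert m.sim == pytest.approx(0.5)
        assert m.bal_by_tree[0] == pytest.approx(math.pi * 0.1**2 / 0.1)
        assert m.bal_by_tree[1] == 0.0

    def test_pure_plot_zero_diversity(self):
        trees = [TreeRecord("p1", "A", d, None) for d in (10.0, 12.0, 14.0)]
        ds = ForestDataset(trees, {"p1": PlotRecord("p1", 0.06)})
        m = compute_stand_metrics(ds, "p1")
        assert m.sim == 0.0 and m.shi == 0.0

    def test_qmd_at_least_md_and_permutation_invariance(self, rng):
        for _ in range(20):
            d = rng.uniform(5, 60, rng.integers(2, 30))
            trees = [TreeRecord("p1", "A", float(x), None) for x in d]
            ds = ForestDataset(trees, {"p1": PlotRecord("p1", 0.1)})
            m = compute_stand_metrics(ds, "p1")
            assert m.qmd_cm >= m.md_cm - 1e-12
            perm = rng.permutation(len(d))
            trees2 = [trees[i] for i in perm]
            m2 = compute_stand_metrics(
                ForestDataset(trees2, {"p1": PlotRecord("p1", 0.1)}), "p1")
            assert m2.qmd_cm == pytest.approx(m.qmd_cm)
            assert m2.ba_m2_ha == pytest.approx(m.ba_m2_ha)
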