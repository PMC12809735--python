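import numpy as np
import pandas as pd
import pytest
from hypothesis import settings

settings.register_profile("repro", derandomize=True, deadline=None)
settings.load_profile("repro")

from forestfit.nls_fitting import FixedEffects
from forestfit.nlme_engine import RandomEffectsSpec, VarianceFunctionSpec
from forestfit.synthetic_data import SimConfig, generate


@pytest.fixture(scope="session")
def small_mixed_forest():
    """6 plots x 25 trees with both random-effect levels (NLME-capable)."""
    cfg = SimConfig(n_plots=6, trees_per_plot=25, seed=42)
    return generate(cfg)


@pytest.fixture(scope="session")
def norE_forest():
    """40-plot forest simulated without random effects (pure fixed-effects)."""
    cfg = SimConfig(
        n_plots=40, trees_per_plot=30,
        truth=FixedEffects(2.092, 0.802,
                           {"SOC": -6.07e-4, "MAP": -3.14e-4, "SIM": -2.80e-2,
                            "BAL": 1e-3, "QMD": -4e-3}),
        re_truth=RandomEffectsSpec((), ()),
        var_truth=VarianceFunctionSpec("none"), sigma=2.47, seed=7)
    return generate(cfg)


@pytest.fixture(scope="session")
def study_scale_ols_forest():
    """99 plots at survey density, full-covariate fixed-effects truth."""
    cfg = SimConfig(
        truth=FixedEffects(2.092, 0.802,
                           {"SOC": -6.07e-4, "MAP": -3.14e-4, "SIM": -2.80e-2,
                            "BAL": 1e-3, "QMD": -4e-3}),
        re_truth=RandomEffectsSpec((), ()),
        var_truth=VarianceFunctionSpec("none"), sigma=2.47, seed=11)
    return generate(cfg)


@pytest.fixture()
def rng():
    return np.random.default_rng(12345)


def power_law_frame(rng, n=200, beta0=2.0, beta1=0.5, sigma=0.0):
    d = rng.uniform(5, 50, n)
    h = 1.3 + beta0 * d**beta1 + (rng.normal(0, sigma, n) if sigma else 0.0)
    return pd.DataFrame({"dbh_cm": d, "height_m": h,
                         "plot_id": "P1", "species": "A"})
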