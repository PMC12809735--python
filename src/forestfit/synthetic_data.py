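"""Hierarchical synthetic-forest generator.

Emulates the statistical structure the estimators assume: plots with
environmental covariates drawn from truncated normals matched to the study
region's summary statistics (five mixed-forest species of the cold-temperate
Daxing'an range; mean annual precipitation 363-509 mm; soil organic carbon
37-159 g/kg; quadratic mean diameters 9-31 cm), per-species diameter
distributions, and heights generated from the two-level mixed-effects
allometry: plot effects on the scale and exponent, species-within-plot
effects on the QMD slope, and optionally heteroscedastic residual noise.

Stand covariates (QMD, BAL, SIM, ...) are *derived from the realized trees*,
never sampled independently — the model couples tree diameters and stand
structure, and independent sampling would destroy exactly the dependence the
mixed model exploits.  A single integer seed drives named substreams (plots,
trees, effects, noise), so enlarging one stage does not perturb the others.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field, replace
import numpy as np
import pandas as pd
from scipy import stats

from .data_model import ForestDataset, PlotRecord, TreeRecord
from .nls_fitting import BREAST_HEIGHT_M, FixedEffects
from .nlme_engine import RandomEffectsSpec, VarianceFunctionSpec
from .stand_metrics import attach_stand_metrics

logger = logging.getLogger(__name__)

#: per-species diameter laws: (mean, sd, min, max) cm, truncated normal
SPECIES_D_DISTRIBUTIONS: dict[str, tuple[float, float, float, float]] = {
    "Bp": (12.8, 4.9, 5.0, 40.0),
    "Qm": (11.9, 3.6, 5.2, 21.4),
    "Pd": (14.8, 4.9, 5.5, 30.9),
    "Lg": (15.2, 6.9, 5.0, 61.3),
    "Ps": (22.9, 8.7, 5.0, 59.0),
}
#: species mixing weights proportional to the study's stem counts
SPECIES_WEIGHTS: dict[str, float] = {
    "Bp": 2222 / 7786, "Qm": 166 / 7786, "Pd": 179 / 7786,
    "Lg": 4778 / 7786, "Ps": 440 / 7786,
}

#: plot-level covariates: (mean, sd, min, max)
PLOT_COVARIATE_MARGINALS: dict[str, tuple[float, float, float, float]] = {
    "SOC": (90.16, 34.47, 37.20, 159.30),
    "MAP": (454.10, 27.55, 363.40, 508.80),
    "MAT": (-2.94, 1.03, -4.57, -0.17),
    "EL": (791.10, 167.88, 423.80, 1135.0),
    "SL": (11.0, 9.0, 0.0, 47.0),
    "BD": (0.91, 0.12, 0.59, 1.20),
    "TN": (9.35, 3.14, 2.69, 14.40),
    "pH": (6.11, 0.30, 5.5, 7.0),
    "CD": (0.70, 0.11, 0.40, 0.90),
}
#: stem density, stems/ha
DENSITY_MARGINAL = (1197.0, 486.0, 290.0, 2667.0)

#: fixed-effect truth for the full covariate model (mixed-effects column)
DEFAULT_TRUTH = FixedEffects(
    beta0=1.784, beta1=0.823,
    exponent_coefs={"SOC": -1e-3, "MAP": 2e-4, "SIM": 1.044e-1,
                    "BAL": 2e-3, "QMD": -5e-3},
)
#: plot-level SDs on (beta0, beta1) and species-within-plot SD on the QMD slope
DEFAULT_PLOT_SD = (0.736, 0.110)
DEFAULT_SPECIES_SD = 1.6e-3
DEFAULT_SIGMA = 1.73

#: Dirichlet concentration for per-plot species mixing; at alpha ~ 0.64 the
#: expected realized Gini-Simpson index is ~0.21 with pure plots included
DEFAULT_DIRICHLET_ALPHA = 0.64


@dataclass
class SimConfig:
    """Everything that defines a simulated forest, including the truth."""

    n_plots: int = 99
    trees_per_plot: int | tuple[int, int] | None = None  # None: density x area
    species_mix: dict[str, float] = field(
        default_factory=lambda: dict(SPECIES_WEIGHTS))
    d_distributions: dict[str, tuple[float, float, float, float]] = field(
        default_factory=lambda: dict(SPECIES_D_DISTRIBUTIONS))
    covariate_marginals: dict[str, tuple[float, float, float, float]] = field(
        default_factory=lambda: dict(PLOT_COVARIATE_MARGINALS))
    area_choices: tuple[float, ...] = (0.06, 0.10)
    area_probs: tuple[float, ...] = (0.85, 0.15)
    dirichlet_alpha: float = DEFAULT_DIRICHLET_ALPHA
    #: SD of the per-plot developmental-stage factor multiplying the diameter
    #: law's mean and SD (truncated to [0.55, 1.7]); spreads quadratic mean
    #: diameter across plots the way real stands of different ages do
    plot_d_scale_sd: float = 0.22
    truth: FixedEffects = field(default_factory=lambda: replace(
        DEFAULT_TRUTH, exponent_coefs=dict(DEFAULT_TRUTH.exponent_coefs)))
    re_truth: RandomEffectsSpec = field(default_factory=lambda: RandomEffectsSpec(
        plot_level=("beta0", "beta1"), species_level=("QMD",),
        plot_cov=np.diag([DEFAULT_PLOT_SD[0] ** 2, DEFAULT_PLOT_SD[1] ** 2]),
        species_var=DEFAULT_SPECIES_SD**2))
    var_truth: VarianceFunctionSpec = field(default_factory=VarianceFunctionSpec)
    sigma: float = DEFAULT_SIGMA
    seed: int = 0

    def __post_init__(self) -> None:
        total = sum(self.species_mix.values())
        if not math.isclose(total, 1.0, abs_tol=1e-9):
            self.species_mix = {k: v / total for k, v in self.species_mix.items()}
        if not self.species_mix:
            raise ValueError("species_mix must not be empty")
        for name, (mu, sd, lo, hi) in self.covariate_marginals.items():
            if lo >= hi:
                raise ValueError(f"covariate {name!r}: min {lo} >= max {hi}")
        for name, (mu, sd, lo, hi) in self.d_distributions.items():
            if lo >= hi:
                raise ValueError(f"species {name!r}: d_min {lo} >= d_max {hi}")


@dataclass
class SyntheticForest:
    dataset: ForestDataset
    frame: pd.DataFrame          # modelling table: tree rows + covariates + BAL
    truth_record: dict

    @property
    def n_trees(self) -> int:
        return len(self.dataset.trees)


def _streams(cfg: SimConfig):
    """Named independent substreams from the single global seed."""
    ss = np.random.SeedSequence(cfg.seed)
    children = ss.spawn(4)
    return {name: np.random.default_rng(child)
            for name, child in zip(("plots", "trees", "effects", "noise"), children)}


def _truncnorm(rng, mu, sd, lo, hi, size):
    if sd <= 0:
        return np.full(size, float(np.clip(mu, lo, hi)))
    a, b = (lo - mu) / sd, (hi - mu) / sd
    return stats.truncnorm.rvs(a, b, loc=mu, scale=sd, size=size, random_state=rng)


def generate_plots(cfg: SimConfig, rng=None) -> pd.DataFrame:
    """Per-plot covariate table with areas and target stem densities."""
    rng = rng if rng is not None else _streams(cfg)["plots"]
    n = cfg.n_plots
    out = {"plot_id": [f"P{i+1:03d}" for i in range(n)]}
    out["area_ha"] = rng.choice(cfg.area_choices, size=n, p=cfg.area_probs)
    for name, (mu, sd, lo, hi) in cfg.covariate_marginals.items():
        out[name] = _truncnorm(rng, mu, sd, lo, hi, n)
    out["density"] = _truncnorm(rng, *DENSITY_MARGINAL, n)
    out["d_scale"] = _truncnorm(rng, 1.0, cfg.plot_d_scale_sd, 0.55, 1.7, n)
    return pd.DataFrame(out)


def generate_trees(cfg: SimConfig, plots: pd.DataFrame, rng=None) -> pd.DataFrame:
    """Tree table (plot, species, D) without heights.

    Species are drawn per plot from a Dirichlet-perturbed version of the
    global mixing weights (small concentrations yield near-pure plots, as in
    real mixed stands), and diameters from each species' truncated normal.
    """
    rng = rng if rng is not None else _streams(cfg)["trees"]
    species = list(cfg.species_mix)
    w = np.array([cfg.species_mix[s] for s in species])
    rows = []
    for _, plot in plots.iterrows():
        if cfg.trees_per_plot is None:
            count = max(2, int(round(plot["density"] * plot["area_ha"])))
        elif isinstance(cfg.trees_per_plot, tuple):
            count = int(rng.integers(cfg.trees_per_plot[0], cfg.trees_per_plot[1] + 1))
        else:
            count = int(cfg.trees_per_plot)
        if len(species) == 1:
            mix = np.array([1.0])
        else:
            mix = rng.dirichlet(np.maximum(cfg.dirichlet_alpha * w, 1e-3))
        sp_draw = rng.choice(len(species), size=count, p=mix)
        d_scale = float(plot.get("d_scale", 1.0))
        uniq, counts = np.unique(sp_draw, return_counts=True)
        for s_idx, c in zip(uniq, counts):
            sp = species[s_idx]
            mu, sd, lo, hi = cfg.d_distributions[sp]
            draws = _truncnorm(rng, mu * d_scale, sd * d_scale, lo, hi, int(c))
            for d in draws:
                rows.append({"plot_id": plot["plot_id"], "species": sp,
                             "dbh_cm": float(d)})
    return pd.DataFrame(rows)


def simulate_heights(cfg: SimConfig, trees: pd.DataFrame, plots: pd.DataFrame,
                     rng_effects=None, rng_noise=None) -> SyntheticForest:
    """Draw random effects and residual noise and emit heights.

    Heights at or below breast height after noise are redrawn (up to 10
    attempts) and finally clipped to 1.31 m with a logged count; the clip
    counter is stored in the truth record.
    """
    streams = _streams(cfg)
    rng_effects = rng_effects if rng_effects is not None else streams["effects"]
    rng_noise = rng_noise if rng_noise is not None else streams["noise"]

    # assemble the dataset so stand metrics come from the realized trees
    tree_records = [TreeRecord(str(r.plot_id), str(r.species), float(r.dbh_cm))
                    for r in trees.itertuples()]
    plot_records = {}
    for _, p in plots.iterrows():
        covs = {k: float(p[k]) for k in cfg.covariate_marginals}
        plot_records[str(p["plot_id"])] = PlotRecord(
            str(p["plot_id"]), float(p["area_ha"]), covs)
    ds = ForestDataset(tree_records, plot_records)
    frame = attach_stand_metrics(ds)

    truth = cfg.truth
    re = cfg.re_truth
    names = [c for c in truth.exponent_coefs]
    missing = [c for c in names if c not in frame.columns and c != "BAL"]
    if missing:
        raise KeyError(f"truth covariates missing from the frame: {missing}")

    plot_ids = frame["plot_id"].to_numpy()
    uniq_plots, plot_idx = np.unique(plot_ids, return_inverse=True)
    qp = re.n_plot
    psi = re.plot_cov if re.plot_cov is not None else np.zeros((qp, qp))
    if qp and np.any(np.linalg.eigvalsh(psi) < -1e-10):
        raise ValueError("plot covariance truth must be positive semi-definite")
    b = (rng_effects.multivariate_normal(np.zeros(qp), psi, size=len(uniq_plots),
                                         method="cholesky")
         if qp else np.zeros((len(uniq_plots), 0)))

    u_map: dict[tuple[str, str], float] = {}
    if re.n_species:
        sp_var = re.species_var or 0.0
        pairs = sorted(set(zip(frame["plot_id"].astype(str),
                               frame["species"].astype(str))))
        vals = rng_effects.normal(0.0, math.sqrt(sp_var), size=len(pairs))
        u_map = {pair: float(v) for pair, v in zip(pairs, vals)}

    d = frame["dbh_cm"].to_numpy(dtype=float)
    beta0 = np.full(len(d), truth.beta0)
    expo = np.full(len(d), truth.beta1)
    for name, coef in truth.exponent_coefs.items():
        expo = expo + coef * frame[name].to_numpy(dtype=float)
    for r, nm in enumerate(re.plot_level):
        vals = b[plot_idx, r]
        if nm == "beta0":
            beta0 = beta0 + vals
        elif nm == "beta1":
            expo = expo + vals
        else:
            expo = expo + vals * frame[nm].to_numpy(dtype=float)
    if re.n_species:
        nm = re.species_level[0]
        uvals = np.array([u_map[(p, s)] for p, s in
                          zip(frame["plot_id"].astype(str), frame["species"].astype(str))])
        if nm == "beta0":
            beta0 = beta0 + uvals
        elif nm == "beta1":
            expo = expo + uvals
        else:
            expo = expo + uvals * frame[nm].to_numpy(dtype=float)

    mean_h = BREAST_HEIGHT_M + beta0 * d**expo
    sd_h = cfg.sigma * cfg.var_truth.g(d)
    h = mean_h + rng_noise.normal(0.0, 1.0, size=len(d)) * sd_h
    n_clipped = 0
    bad = h <= BREAST_HEIGHT_M
    for _ in range(10):
        if not bad.any():
            break
        h[bad] = mean_h[bad] + rng_noise.normal(0.0, 1.0, size=int(bad.sum())) * sd_h[bad]
        bad = h <= BREAST_HEIGHT_M
    if bad.any():
        n_clipped = int(bad.sum())
        h[bad] = BREAST_HEIGHT_M + 0.01
        logger.info("clipped %d heights to %.2f m", n_clipped, BREAST_HEIGHT_M + 0.01)

    frame["height_m"] = h
    ds.trees = [replace(t, height_m=float(hv)) for t, hv in zip(ds.trees, h)]

    truth_record = {
        "config_seed": cfg.seed,
        "fixed": {"beta0": truth.beta0, "beta1": truth.beta1, **truth.exponent_coefs},
        "plot_cov": np.asarray(psi).tolist(),
        "species_var": re.species_var,
        "sigma": cfg.sigma,
        "variance_function": {"kind": cfg.var_truth.kind,
                              "params": cfg.var_truth.params().tolist()},
        "plot_effects": {str(p): b[i].tolist() for i, p in enumerate(uniq_plots)},
        "species_effects": {f"{p}|{s}": v for (p, s), v in u_map.items()},
        "n_clipped": n_clipped,
    }
    return SyntheticForest(ds, frame, truth_record)


def generate(cfg: SimConfig) -> SyntheticForest:
    """Full chain: plots -> trees -> stand metrics -> heights."""
    streams = _streams(cfg)
    plots = generate_plots(cfg, streams["plots"])
    trees = generate_trees(cfg, plots, streams["trees"])
    return simulate_heights(cfg, trees, plots, streams["effects"], streams["noise"])


def make_fixture(name: str, seed: int = 0) -> SyntheticForest:
    """Named presets.

    tiny
        3 plots x 5 trees, base allometry, one plot effect on the scale
        parameter — small enough for quadrature oracles.
    paper_like
        99 plots, ~7,800 trees, five species, the full covariate truth with
        both random-effect levels and homoscedastic noise.
    heteroscedastic
        like paper_like but with constant-plus-power residual noise.
    """
    if name == "tiny":
        cfg = SimConfig(
            n_plots=3, trees_per_plot=5,
            species_mix={"Lg": 0.7, "Bp": 0.3},
            truth=FixedEffects(2.0, 0.6),
            re_truth=RandomEffectsSpec(plot_level=("beta0",), species_level=(),
                                       plot_cov=np.array([[0.16]])),
            var_truth=VarianceFunctionSpec("none"), sigma=0.5, seed=seed)
    elif name == "paper_like":
        cfg = SimConfig(seed=seed)
    elif name == "heteroscedastic":
        # constant ~half of the SD at the median diameter: identifiable
        # against the pure power-of-D alternative at survey sample sizes
        cfg = SimConfig(
            var_truth=VarianceFunctionSpec("constant_plus_power",
                                           gamma1=60.0, gamma2=1.5),
            sigma=0.019, seed=seed)
    else:
        raise ValueError(f"unknown fixture preset {name!r}")
    return generate(cfg)
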