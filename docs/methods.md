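# Methods

## The model

`forestfit` estimates environment-sensitive height-diameter (H-D) allometry
for mixed forests. The base relationship is the two-parameter power law

    H = 1.3 + b0 * D^b1 + e,

with H total height (m), D diameter at breast height (cm), and 1.3 m the
breast-height offset below which the model is undefined. `b1` is the
allometric scaling exponent; metabolic scaling theory predicts values near
2/3, and departures from it diagnose species strategy and environmental
modulation.

The environment-sensitive extension keeps the power-law shape and lets the
exponent respond linearly to stand and environmental covariates:

    H_ijk = 1.3 + b0 * D_ijk^(b1 + b2*SOC_i + b3*MAP_i + b4*SIM_i
                              + b5*BAL_ijk + b6*QMD_i) + e_ijk

for tree k of species j in plot i, where SOC is soil organic carbon (g/kg),
MAP mean annual precipitation (mm), SIM the Gini-Simpson species-diversity
index, BAL the basal area of strictly larger neighbours (m²/ha, a one-sided
competition index, tree-level), and QMD the quadratic mean diameter (cm, a
stand developmental-stage indicator).

The mixed-effects form adds two nested random-effect levels reflecting the
sampling design: a bivariate plot effect (u_i0 on b0 and u_i1 on b1,
unstructured 2x2 covariance by default, diagonal optional) and a
species-within-plot effect on the QMD slope (u_ij on b6, scalar variance).
Residuals are independent Gaussians whose SD may depend on D through one of
three variance functions: exponential `sigma*exp(gamma*D)`, power
`sigma*D^gamma`, or constant-plus-power `sigma*|gamma1 + D^gamma2|`. The
within-plot error correlation matrix is fixed to the identity: only the
variance structure is modelled, with the correlation slot left extensible.

## Estimation

Fixed-effects fits (`PowerHeightModel`) use damped Gauss-Newton /
Levenberg-Marquardt least squares with an analytic Jacobian. Covariates are
z-scaled internally — raw magnitudes (MAP ≈ 450) make the exponent surface
badly conditioned — and coefficients and standard errors are transformed
back exactly, so the reported fit is on the raw scale. Starting values come
from ordinary least squares of log(H − 1.3) on log D, which is exact for
noiseless power-law data. Convergence uses a relative SSE change below 1e-10
or a gradient norm below 1e-8 (at most 200 iterations). The Gaussian
log-likelihood uses the ML variance SSE/n so that AIC is comparable with the
mixed-effects fits; standard errors use the usual SSE/(n − p) scaling.

Mixed-effects fits (`MixedEffectsHeightModel`) maximise the Lindstrom-Bates
linearised marginal likelihood. The inner step is penalized nonlinear least
squares over the fixed effects and all random-effect modes, solved by joint
damped Gauss-Newton: one linearisation per sweep, block elimination of the
per-plot mode blocks (a Schur complement on the fixed effects), and
step-halving on the penalized objective. The outer problem is posed directly
over the variance parameters (log-Cholesky plot covariance, log species SD,
log sigma, free variance-function parameters): each Nelder-Mead evaluation
re-solves the warm-started inner problem, linearises about the current
modes, and profiles the fixed effects out by generalized least squares. We
chose this self-consistent formulation over the classical two-step
alternation (PNLS step, then a variance update against a frozen
linearisation) because the frozen-linearisation alternation contracted at a
geometric rate near 0.85 on these models — dozens of outer iterations with
estimates still drifting — while the self-consistent objective converges
reliably; the maximised criterion is the same. In the nonlinear-covariate
parameterisation the internal conditioning transform is scale-only
(covariates divided by their SD, never centred), because centring a
covariate that carries a random slope would silently introduce a
group-level intercept effect that the raw model does not contain; the
scale-only transform maps coefficients, standard errors, covariances and
random-effect variances back exactly.

Variance-function parameters get moment-based starting values: residual SDs
in diameter quantile bins, then a log-linear fit (exponential, power) or a
small gamma2 grid with linear solves (constant-plus-power). Without these
the constant-plus-power fit regularly stalls in local optima whose
likelihood falls below its own nested power-function submodel.

Estimation is maximum likelihood throughout (no REML). AIC = −2LL + 2k
counts fixed effects + plot-covariance parameters + species variance +
variance-function parameters + sigma; the census is stored on every fit and
audited by the tests.

### Marginal likelihood evaluation

`marginal_loglik` evaluates the marginal likelihood at given parameter
values by finding the random-effect modes (penalized least squares) and then
integrating the effects out. The default method is mode-centred adaptive
Gauss-Hermite quadrature (60-node tensor rule, scaled by the exact Hessian
of the joint log-density) for plots whose local effect dimension is at most
2, and exact-Hessian Laplace above that. The Gauss-Newton linearisation used
inside the fitting loop is available as `method="linearized"`. All methods
are exact when every random effect enters the mean linearly (effects on b0
only) and reduce exactly to the Gaussian NLS log-likelihood when all
random-effect variances are zero. We made adaptive quadrature the default
because the first-order linearisation carries errors of 1e-3 to 4e-2 nats
against dense numerical integration for exponent-level random effects at
realistic SDs, while the quadrature path agrees to better than 1e-4.

## Covariate engineering and selection

Stand metrics are deterministic functions of the tree list: QMD, mean
diameter, basal area and stem density per hectare, BAL (strictly-greater
diameters, so the largest tree's BAL is exactly 0 and ties contribute
nothing to each other), dominant height (mean over species of the tallest
stem per species), Gini-Simpson (1 − Σp², zero for a pure stand) and
Shannon (−Σp ln p) diversity, the Stage slope-elevation composites
SIE = sin(SL)·ln(EL) and CIE = cos(SL)·ln(EL) (slope in degrees converted to
radians), the de Martonne aridity index M = MAP/(MAT+10) and the annual
heat:moisture index AHM = (MAT+10)/(MAP/1000).

Selection is two-stage: per-species base-model fits, Pearson correlations
(two-sided t-test p-values, 0.05 screening) between the fitted coefficients
and candidate covariates over matched units, then iterative
variance-inflation-factor filtering at VIF ≤ 5 (drop the highest VIF,
lexicographic tie-break; tree-level BAL enters the plot-level collinearity
check as a plot mean). The AIC ladder fits the nested build-up — base, +QMD
(developmental stage), +BAL (competition), +SIM (diversity), +MAP
(climate), +SOC (soil) — and reports AIC, log-likelihood and R² per rung.

## Evaluation

R² = 1 − SSE/SST, RMSE, and the total relative error
TRE = 100·Σ(O − E)/ΣE, implemented signed (positive when observations
exceed predictions in aggregate). Partial R² of a covariate is the
refit-difference R²(full) − R²(without it), with D's share taken against
the intercept-only mean; terms need not sum to the full-model gain, and the
alternative SSE-based type-III decomposition is deliberately out of scope.
Per-species evaluation of mixed fits uses conditional
(random-effects-included) predictions by default; population-level
predictions are available.

## The synthetic-forest generator

Because the survey data are not deposited, every stage is exercised on
synthetic forests that emulate the study region's structure: 99 rectangular
plots (0.06 ha dominant, 0.10 ha minority), stem density 290-2,667 /ha
(mean 1,197), five species (Bp, Qm, Pd, Lg, Ps) mixed with weights
proportional to the study's stem counts (7,786 trees total; the generator's
realised totals fall in roughly 7,000-8,600), per-species truncated-normal
diameter laws matched to the reported per-species D means, SDs and ranges
(truncation at the 5 cm survey threshold), and plot covariates drawn from
truncated normals matched to the reported mean/SD/min/max (MAP 363-509 mm,
SOC 37-159 g/kg, MAT −4.6 to −0.2 °C, elevation 424-1,135 m, ...).

Two structural choices matter:

* **Coherence.** QMD, BAL, SIM and the other stand covariates are computed
  from the realised trees, never sampled independently — the model couples
  tree diameters to stand structure, and independent sampling would destroy
  the dependence the mixed model exploits. The tests assert stored
  covariates equal recomputation exactly.
* **Between-plot structure.** Species composition varies by plot through a
  Dirichlet-perturbed mixing vector (concentration 0.64, chosen so the
  expected realised Gini-Simpson index is ≈ 0.21 with pure plots included,
  matching the reported SIM range 0-0.68), and a per-plot
  developmental-stage factor (truncated normal, mean 1, SD 0.22) scales the
  diameter law. Without the latter a single global D law gives between-plot
  QMD spread of ~1.5 cm against the reported 4.4 cm, leaving the QMD
  coefficient weakly identified; with it the realised QMD spread is ~4 cm
  over 9.5-28.2 cm.

Heights follow the full hierarchical model with configurable truth; the
default fixed effects, random-effect SDs (0.736 on b0, 0.110 on b1,
1.6e-3 on the species-level QMD slope) and residual SD 1.73 m reproduce the
study conditions. Heights at or below 1.3 m after noise are redrawn up to
10 times, then clipped to 1.31 m with a logged count (Gaussian noise admits
physically impossible heights; clipping affects well under 1% of trees at
the default truth). A single integer seed drives named substreams (plots,
trees, effects, noise), so enlarging one stage does not perturb the others;
identical configurations are bit-reproducible.

The `heteroscedastic` preset uses constant-plus-power truth gamma1 = 60,
gamma2 = 1.5, sigma = 0.019 (residual SD rising from ~1.4 m at D = 5 cm to
~4.3 m at D = 30 cm, with the constant about half the SD at the median
diameter). These values were fixed by a pilot power analysis: the constant
component must be a material fraction of the SD over the observed diameter
range to be statistically separable from the one-parameter power family;
with a small constant (e.g. gamma1 ≈ 0.5 against D^0.8 ≈ 9) the two SD
curves are practically indistinguishable at any realistic sample size and
AIC correctly prefers the smaller model.

What the generator does **not** emulate: spatial coordinates and
autocorrelation, growth dynamics and remeasurement, measurement error in D,
correlation among plot covariates (elevation and MAP are drawn
independently; an optional correlation matrix is a known gap), and
non-Gaussian height noise. Passing recovery tests therefore demonstrate
that the estimators are consistent and well-calibrated under the model's
own assumptions at the study's design — not that the model is correct for
any particular real forest.

## Recovery protocols and problem sizes

The acceptance suite (tests/test_acceptance.py) runs, with fixed seeds:

* base-model recovery: 20 survey-scale replicates (99 plots, ~7,800 trees,
  residual SD 2.65 m); both parameters within 3 reported SEs in ≥ 90%;
* covariate-model recovery: 20 survey-scale replicates; median exponent
  intercept within 5%;
* mixed-effects recovery: 20 replicates at 60 plots x 40 trees — a
  deliberate scale-down that keeps per-plot replication realistic while
  bounding runtime; medians of the plot-SD on b0 (tolerance 20%) and
  residual sigma (5%), plus the fixed-effect medians (5%);
* oracle equivalence: 25 instances with ≤ 2 random effects and ≤ 12
  observations against dense trapezoid integration, tolerance 1e-3;
* variance-function identification at survey scale (20 replicates,
  fixed-effects generating model) and the null LRT calibration
  (200 replicates at 15 plots x 20 trees, binomial 95% band around 5%);
* exact degenerate reductions and brute-force stand-metric oracles.

`scripts/acceptance.py` re-runs the mixed-effects protocol end to end (20
fresh replicates seeded from `--seed`) and reports the median estimated
plot-level SD on b0.

A power caveat documented up front: with a plot-level exponent effect of
SD 0.110 acting as between-plot noise, the exponent intercept and the
plot-level covariate coefficients are intrinsically noisy — the design
carries an effective relative SE near 30% for b1 at the full survey size
(the study's own reported SE for b1 is of that order), so a median over 20
replicates still moves ~8% around truth at 60 plots. The 5% fixed-effect
band is therefore expected to hold for the scale parameter but not
uniformly for the exponent-side coefficients; the variance components and
residual SD, which that criterion also covers, recover well inside their
bands. We report the check as specified rather than loosening it.

## Numerical choices and degenerate inputs

* Exponent overflow is guarded by clipping e·ln D at ±700 before
  exponentiation; pathological variance proposals (non-finite or singular
  inner systems) are treated as infeasible points and the optimizer state
  is restored.
* Exact collinearity in VIF filtering gives an infinite VIF and an
  immediate drop with a log entry.
* Ties in BAL: equal diameters contribute nothing to each other.
* Empty diameter lists, all-zero abundances, slope outside [0, 90),
  elevation ≤ 1 m, MAT ≤ −10 °C and MAP ≤ 0 raise domain errors; heights
  ≤ 1.3 m are flagged by validation and excluded from fitting with a
  logged warning rather than an exception.
* Variance collapse (a random-effect SD estimated at the parameter floor)
  sets a `boundary` flag on the fit.
* `stage_transforms` converts slope degrees to radians; the reported SIE
  range in the source tables is not reproducible under any degree/radian
  convention we tried, so the convention is documented rather than tuned.

## Known limitations

* No EBLUP calibration workflow for predicting heights in new plots from a
  few measured trees; conditional prediction is only available for groups
  seen in training.
* No REML, no autocorrelation structures, no crossed random effects.
* One species-level random effect at a time.
* The Shannon-index upper bound ln(richness) is far below the maximum
  reported in the source tables (9.78); the variant behind that figure is
  unknown, and we implement the standard form.
* Alternative base curves (Mitscherlich, Gompertz, Richards) are out of
  scope; the power law is the only mean function.
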