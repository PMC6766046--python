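# Methods

## Model

Indoor radon is described by a mass balance over three compartments: indoor
air (`Ci`), soil beneath the building (`Cs`) and radon-bearing building
materials (`Cbm`), all in Bq m⁻³. Soil exchanges radon with indoor air by
diffusion (coefficient `kd_s`, m h⁻¹) and delivers it one-way by
pressure-driven advection (`ka·ΔP`, m h⁻¹); building materials exchange by
diffusion (`kd_bm`); indoor air exchanges with outdoor air (`Co`) at the
ventilation rate `λv`; every compartment decays at `λ`. The soil and
building-material compartments are fed by the effective exhalation rates
`Es`, `Ebm` (Bq m⁻² h⁻¹) scaled by the ground-contact area `Sg` and interior
material surface `Sbm` over the indoor volume `V`. The source terms in the
soil and building-material equations are normalised by the indoor volume
`V`, keeping every compartment on a common per-indoor-volume concentration
scale.

The system is linear, `dx/dt = Ax + c`, with a strictly stable `A` (every
mode decays at least at rate `λ`), hence a unique globally attracting fixed
point obtained by a 3×3 linear solve. At that fixed point the indoor
concentration collapses to

    Ci = (S + λv·Co − λ(Cs + Cbm)) / (λ + λv),     S = Es·Sg/V + Ebm·Sbm/V

and, crucially, this relation is affinely invertible in `S`:

    S = Ci(λ + λv) + λ(Cs + Cbm) − λv·Co.

The inversion is what makes the statistical half of the chain possible: the
physical transfer coefficients (`kd`, `ka`, `ΔP`, `Es`, `Ebm`, areas,
volume) never need to be known per residence — they are exercised only by
the dynamic simulator, which exists to validate the closed form.

### Ventilation

`λv = (ft·|Ti − To| + fw·u²)·N` combines the stack effect (indoor–outdoor
temperature difference) and wind-driven infiltration, scaled by a
dimensionless habit multiplier `N`. A residence's `λv` is the mean of the
12 monthly rates computed from its province's temperature and wind normals
(monthly inputs, annual prediction target), times its habit multiplier;
averaging `λv` rather than monthly `Ci` is the package convention.

`ft` and `fw` are empirical fitting constants with no first-principles
value. The package defaults, `ft = 0.03 h⁻¹ °C⁻¹` and
`fw = 0.01 h⁻¹ s² m⁻²`, were chosen so that under the synthetic
meteorology (indoor temperature 20 °C, Korean-peninsula-like seasonal
cycle, ~2 m s⁻¹ winds) annual-mean ventilation rates span roughly 0.2–0.45
h⁻¹ with mean ≈ 0.33 h⁻¹, the band reported for residential air-exchange
estimates of this kind (≈ 0.24–0.73 h⁻¹, AM ≈ 0.34). Both are required,
config-exposed parameters in every interface.

The habit multiplier uses ordinal labels low/medium/high with defaults
0.8/1.0/1.2; the indoor temperature defaults to 20 °C. Both are
config-driven.

### Regional proxies

Soil radon varies with geology (granite zones run high) but is not
systematically measured, so district `Cs` is proxied as
`weight × soil_reference`, where the weight is the ratio of the district's
winter-survey geometric mean to the national geometric mean. Winter data
are used because low ventilation makes the regional contrast mostly a
source-term signal. Province outdoor radon `Co` is built the same way at
province level with `outdoor_reference`. The references (defaults: the
national survey GM 86.52 Bq m⁻³ for soil, 10 Bq m⁻³ for outdoor air) are
deliberate free constants: changing either shifts the inverted `S` by a
term the regression intercept absorbs, so predictions of `Ci` are
insensitive to them (the sensitivity is exercised in tests via the exact
noiseless round trip, which holds for any positive references).

### Preprocessing

Fixed order: geometric mean of the two in-residence measurement points →
seasonal correction (`annual = measured × factor(season)`, identity factors
unless configured) → natural-log transform → single-pass `|z| > 3` outlier
screen computed within stratum (sample sd, ddof = 1) → stratum assignment.
The screen is single-pass by design: re-screening the kept set would
re-estimate the spread on truncated data and remove points indefinitely.
Both the threshold and the within-stratum scope are configurable.

### Stratified infiltration regression

Four strata: residence type (detached vs other) × groundwater usage.
Groundwater-borne radon is not directly measurable at scale, so it enters
as a stratification variable rather than a covariate. Per stratum, OLS of
the inverted `S` on district greenery ratio (%, as-is, no centering),
district survey GM (Bq m⁻³, raw scale), and dummy-coded building traits
(material, reference concrete; cracks ≥2 vs 0–1; floors ≥2 vs ≤1). The
predictor sets are stratum-specific *metadata*, not code branches: the
groundwater-using "other residences" stratum (Type 3) carries only the
concrete/red-brick/cement-block material levels and no crack or floor
terms; Type 4 has no soil/wood levels. Standard errors and two-sided
p-values come from the t-distribution with residual degrees of freedom.
Reference coefficient columns for all four strata ship as a JSON fixture
and double as the generator's default ground truth.

Two open scale questions are resolved as follows and flagged here: the
district GM enters on the raw Bq m⁻³ scale (its reference slope magnitude
≈ 2.5–2.7 per Bq m⁻³ would also be consistent with a standardized or log
scale, but raw is what the fixture's intercepts imply), and the reference
coefficients are taken to be in Bq m⁻³ h⁻¹ per predictor unit.

## Synthetic-data generator

The generator runs the forward model: draw districts (greenery uniform on
a configurable interval, default 20–80%; survey GMs log-normal about the
national GM 86.52, between-district GSD 1.5, within-district GSD 1.8, 30
records per district), province meteorology (sinusoidal temperature coldest
in January, mean 12 °C, half-range 13 °C; winds ≈ 2 m s⁻¹), then
residences: stratum shares (0.25, 0.35, 0.08, 0.32 — the
groundwater-using "other residences" cell smallest, as in the survey the
stratum summaries describe), building traits, habits, measurement season;
compute true `S` from the reference coefficients plus N(0, 2) residual,
`λv`, `Cs`, `Co` exactly as the pipeline will recompute them from the
written CSVs, and annual `Ci` from the steady state. Measurements are
de-annualized by the inverse seasonal factor (defaults 0.85 / 1.0 / 1.25 /
1.05 for winter/spring/summer/autumn) and split into two points with
multiplicative log-normal error (GSD 1.1 per point). A configurable
fraction of gross outliers (±6 sd on the log scale) can be planted; the
default is zero so that the generated concentrations retain the calibrated
stratum distributions.

**Calibration.** The reference slopes at the national-survey covariate
scale put the raw linear predictor far above the stratum GM targets
(62.19 / 49.71 / 34.26 / 44.48 Bq m⁻³ with GSDs 1.68 / 1.78 / 1.25 /
1.53), and no intercept shift alone can also match the GSDs. The generator
therefore solves, per stratum, an affine map `S = a·(Xβ + ε) + b` by nested
bisection — inner loop: offset `b` to match the sample log-mean; outer
loop: scale `a` to match the sample log-sd — so the generated annual
concentrations hit the configured GM *and* GSD essentially exactly, while
`S` stays exactly linear in the design columns. Consequences to be aware
of: (i) a noiseless run is exactly identifiable end to end (the pipeline's
OLS recovers the effective coefficients `a·β`, `a·β0 + b` and reproduces
`Ci` to machine precision); (ii) coefficients fitted on generated data are
the *scaled* `a·β`, not `β` — coefficient-recovery studies at the
reference values use the bare design simulator `simulate_design_rows`,
which applies no calibration; (iii) the attainable GSD has a floor set by
the heterogeneity of `λv` and the regional terms (≈ 0.13 on the log scale
at defaults); a GSD target below that floor is rejected with a clear
error. The map `(a, b)` is recorded per stratum in `truth.json`.

**What the generator does not emulate.** Real geography and geology (no
spatial autocorrelation of district GMs, no granite-zone structure),
within-district covariate correlation (greenery is independent of the
survey GM), detector response and seasonal-factor misspecification
(pipeline and generator share the factor table), non-linearity of the true
entry process, and reporting errors in questionnaires. Passing tests
therefore demonstrate the estimation chain is correct and well-calibrated
under its own assumptions — not that those assumptions hold in any real
housing stock.

## Numerical choices

- ODE integration: LSODA via `scipy.integrate.solve_ivp`, rtol 1e-8,
  atol 1e-10, validated against the 3×3 linear solve to rtol 1e-6 at
  t = 10⁴ h across random parameter sets.
- A negative algebraic `Ci` or `S` (inconsistent inputs) is returned
  as-is with a `RuntimeWarning` — clamping would silently break the
  inversion identity.
- Outlier z-scores use the sample sd (ddof = 1); with zero variance
  nothing is removed.
- OLS via statsmodels (pinv-based); dummy columns that are identically
  zero (allowed level absent from the data) are dropped before fitting and
  excluded from the model's level set, while genuine collinearity raises
  an error naming the offending columns. Predicting for a level absent
  from a fitted model raises.
- Calibration bisection: 80 outer iterations on the scale, Brent's method
  for the inner offset solve (xtol 1e-12), positivity of every generated
  concentration enforced by the admissible-offset bound.
- All randomness flows from a single integer seed through
  `numpy.random.default_rng` spawn streams; generated CSVs are
  byte-identical under a fixed seed, and the pipeline itself is
  deterministic (re-running a config reproduces outputs byte for byte).

## Problem sizes

Tests run the chain at desk scale: 500–1,400 residences, 20–233 districts,
5–17 provinces, with the generator-calibration check at 10,000 residences
and coefficient-recovery studies at 20 × 500 rows per stratum. These sizes
make every sampling-error tolerance comfortable while keeping the full
suite in seconds.

## Known limitations

- The dose formula `E = Q·F·T·K` is provided as a terminal convenience;
  no occupancy or equilibrium-factor modelling is included.
- Single-zone buildings only; the scalar soil–indoor pressure difference
  stands in for any pressure field.
- No geostatistical interpolation between districts: regions are discrete
  constants, and a residence in a district absent from the survey is an
  error, not an extrapolation.
- The regression is fixed per-stratum OLS by design — no variable
  selection, regularization or mixed effects.
- Seasonal correction factors are exogenous configuration; the package
  ships identity defaults and the generator records the factors it used.
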