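# Methods

This note documents the models inside `paddysim`, the choices made where
the design was genuinely open, and what the synthetic study conditions do
and do not establish about real field systems.

## The surrogate crop model

The simulator is a deliberately small daily-timestep rice model that
carries the *semantics* of the eight CERES-Rice genotype coefficients
without attempting numeric agreement with DSSAT. It exists so that
calibration, scenario and response-modelling machinery can be exercised
end-to-end on a forward model with the right qualitative behaviour.

**Phenology.** Daily thermal time is `GDD = max(0, tavg − t_base)` with
`t_base = 10 °C` (the conventional rice base temperature; configurable).
The juvenile phase ends after P1 °C·day; panicle initiation follows after
an additional photoperiod-induced requirement `P2R · max(0, daylength −
P2O)` (daylength from the standard solar-declination formula at the
configured latitude, default 24° N); heading follows panicle initiation
after a fixed thermal lag of 450 °C·day (CERES resolves this internally;
any positive constant preserves every ordering property the analysis
needs); maturity follows heading after P5 °C·day. Development is
water-independent, so deficit treatments share the baseline's stage dates.

**Soil water.** A single bucket over the 300 mm managed depth with
volumetric fractions θ_wp = 0.15 < θ_fc = 0.33 < θ_sat = 0.45 (plant-
available capacity 54 mm). Each day: rain enters; water above field
capacity drains within the day; actual ET = Kc · ET₀ · Ks leaves
(Kc = 1.05; ET₀ is a Priestley–Taylor estimate, α = 1.26, net radiation
taken as 75% of incident shortwave — chosen because radiation and
temperature are the only forcings available); irrigation enters at the end
of the day. The stress index Ks is 1 while the plant-available fraction is
at least `p_threshold` and declines linearly to 0 at wilting point.
Evaluating the irrigation trigger on the day's *closing* storage (and
injecting all irrigation at day end) makes the refill arithmetic exact and
— deliberately — makes replaying a recorded schedule bit-identical to the
run that produced it, which the scenario engine relies on.

**Yield formation.** Biomass grows as `RUE · G3 · interception · srad ·
Ks^0.15 · T-penalty` with RUE = 1.1 g/MJ and a canopy interception term
saturating on a 350 °C·day scale. Spikelet number is fixed at heading,
proportional to `G1 · biomass` and damped by (mean Ks over the
panicle-initiation→heading window)²; grain yield is the sink `N · G2`
scaled by grain-fill completion and (mean Ks during fill)^0.2, capped by a
maximum harvest index of 0.58 on final biomass. G4 shifts the onset of a
high-temperature penalty. Fertiliser events (25/20/30/25% splits of
140 kg N/ha in spring, 100 in autumn, at the season-specific days) are
recorded but physiologically inert — the study design itself excludes
nutrient limitation, and a hook is left for a future nitrogen term.

**Stress partition (a design decision).** The exponents (2.0 on the
sensitive window, 0.2 on grain fill, 0.15 on assimilation) and the stress
onset `p_threshold = 0.6` encode the agronomic consensus that water
deficit between panicle initiation and heading is far more damaging per
millimetre than deficit elsewhere. They were set so the model reproduces
the qualitative behaviour the scenario analysis assumes: yield is monotone
in applied water; mild deficits (s ≤ 0.2) are nearly free; dry seasons
respond much more steeply than wet ones; and concentrating a fixed water
budget inside the sensitive window out-yields spreading it uniformly in
≥95% of dry seasons. An earlier, flatter parameterisation failed that last
property for a structural reason — moderate uniform deficits never entered
the stress zone inside the window, so protection bought nothing — which is
why the stress onset sits above the 50%-of-capacity irrigation trigger.

**Degenerate inputs.** Negative or non-finite forcing raises; a series
ending before heading raises; a series ending between heading and maturity
is treated as a harvest cap with partial grain fill (configurable to raise
instead). Zero radiation yields zero biomass and zero yield.

## GLUE calibration

Two stages, following DSSAT-GLUE practice: phenology coefficients first
(growth held at the starting set), then growth coefficients with stage-1
posterior means fixed; each stage draws its own pool (default 10,000) from
independent uniform priors, by default ±50% around the starting
coefficients. Weights come from the Gaussian likelihood of
observed-vs-simulated yields; everything is computed in log space with
log-sum-exp normalisation, stable across log-likelihood spreads of 10⁴ and
more. A draw on which the forward model fails (e.g. a coefficient set that
cannot reach heading inside the season) receives exactly zero weight and
is counted, not fatal. The posterior mean is always inside the prior box
(convexity), and a point prior returns its value exactly.

**σ₀².** The method leaves the model-error variance unspecified. The
default here is the sample variance of the observed yields — a
scale-matching convention common in GLUE practice — and a constant
override is exposed. Calibration-recovery experiments pass an explicit σ₀
(2% of the observation scale): with noise-free synthetic observations the
variance default would be meaningless. Note that σ₀² controls posterior
concentration; with the variance default and few observations the
posterior mean is a mildly informative compromise between prior centre and
truth, which is the honest behaviour of yield-only calibration.

## Scenario engine

Level 0 of the saving axis is the fully-irrigated reference
(demand-triggered refill to field capacity at 50% of capacity over 30 cm);
its event log is the recorded schedule. The saving proportion s scales
every recorded application to (1−s); the sensitive-stage treatment keeps
applications inside [panicle initiation, heading] at full amount. The
"80/60/40/20/0% of the full amount" treatment ladder therefore corresponds
to s = 0.2 … 1.0 — the two conventions run in opposite directions and this
package always reports s, the *saving*. Ratios are rounded half-up to two
decimals for reporting; full precision is kept internally and used for all
fitting.

## Yield-response model

Fitting uses yearly records, not across-year means. Records above 1000 mm
seasonal accumulated precipitation are removed first (at that rainfall the
simulations show no deficit response, so they carry no curve information),
the remainder split at 500 mm, with the boundary value assigned to the
500–1000 mm stratum. Within each of the 24 subsets four curves are fitted
by least squares: polynomials of degree 1–3 (OLS) and a decreasing
3-parameter logistic `a / (1 + exp(b(x − c)))` fitted by bounded nonlinear
least squares from starts a = max y, b = 5, c = 0.5 with a small restart
grid; a non-convergent logistic is excluded from selection and logged.

AIC uses the maximised Gaussian log-likelihood (σ̂² = RSS/n) and counts
p = curve coefficients + 1 variance term uniformly across forms, so
comparisons are internally consistent; ties break toward fewer parameters.
Two plausibility overrides mirror how an analyst reads the scatter plots:
a fitted value at s = 0 above 1 + ε (ε = 0.02, an operationalisation of
"clearly above 1") disqualifies, as does any increasing segment on [0, 1]
(checked on a 1001-point grid) — less water cannot raise yield. If every
candidate is disqualified the best-AIC fit is returned with an explicit
fallback flag and no recommendation is derived from it.

Prediction intervals are classical t-based OLS intervals for the
polynomial forms and delta-method-plus-residual-variance intervals
(t quantile, n − 3 df) for the logistic. The correction term
Δ = mean(observed) − mean(simulated fully-irrigated), computed per
cultivar × season on year-paired values, shifts the kg/ha-scale curve and
its band; the 90%-retention inversion operates on the *ratio*-scale curve
(retention is defined on ratios), by bisection to 10⁻⁶, returning 100%
when the curve never crosses the floor and flagging the subset infeasible
when even s = 0 sits below it.

## Synthetic study conditions

**Weather.** Seasonal temperature and radiation follow linear ramps with
Gaussian noise (spring: warming 23→32 °C tmax over 130 days from early
March; autumn: cooling 33→26 °C over 100 days from late July, Taichung-like
latitudes). Rainfall is a wet/dry Bernoulli process with gamma amounts and
a quadratic day-position weight concentrating mass late in spring and
early in autumn; autumn additionally draws Poisson typhoon-like bursts
(rate 1.5/season, mean 90 mm). Amounts are scaled so the season's
*expected* total equals the configured target exactly; the demonstration
bank fixes per-year targets spanning the dry (<500 mm), intermediate
(500–1000 mm) and excluded (>1000 mm) strata. What this generator does
not emulate: multi-day storm persistence, humidity/wind (the analysis
inputs carry none), spatial structure, or trend/autocorrelation across
years — so passing tests demonstrate the machinery under plausible
seasonal structure, not climatological realism.

**Observed yields.** Fully-irrigated simulated yields at the packaged
coefficients with 8% multiplicative Gaussian noise — year-to-year
variation around cultivar-specific means with the weather-driven component
shared with the experiments. Real observation error is not purely
multiplicative and not independent across years.

**Known-response records.** The end-to-end validation of
stratify→fit→select→recommend draws yield ratios from known monotone
quadratic truths per treatment × stratum (90%-retention points at 56.6,
47.6, 79.6 and 71.4% saving), 12 years, additive noise sd 0.008. The
truth slopes keep |dy/ds| ≥ 0.14 at the crossing and the noise level was
chosen by power analysis so that three standard errors of the estimated
crossing stay inside 5 percentage points — a shallower truth or noisier
data would make the crossing statistically unidentifiable at this sample
size, a property of the inversion itself worth knowing when reading the
real tables.

**Problem sizes.** The packaged demonstration uses 6 years × 2 seasons,
2,000 GLUE draws per stage, and the full 10,000-draw setting in the
calibration-recovery experiment; these sizes give stable results while
keeping the demo interactive.

## Known limitations

- The surrogate has no ponded-water layer (flood irrigation is refill to
  field capacity), no multi-layer soil, no nitrogen/phosphorus/potassium
  response, no pest/lodging/CO₂ effects, and water-independent phenology.
- Yield-only GLUE calibration identifies coefficient *combinations* more
  sharply than individual coefficients; phenology coefficients in
  particular are weakly constrained by yield alone.
- The correction term shifts the prediction band rather than re-deriving
  it on the corrected scale; the band's coverage statement applies to the
  ratio scale.
- Unadjusted p-values in the correlation profile (eleven tests per
  cultivar × season) are reported deliberately; treat significance stars
  as descriptive.
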