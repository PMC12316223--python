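# paddysim

Water-saving rice cultivation analysis: how much irrigation water can be
withheld from a paddy crop before yield drops below 90% of the
fully-irrigated level?

Irrigated rice is the largest agricultural water user in many East-Asian
growing regions, and increasingly erratic rainfall makes deficit-irrigation
planning a practical necessity. `paddysim` packages the full analysis chain
a crop-systems analyst would run to answer the question above for specific
cultivars and cropping seasons:

1. **Surrogate crop simulation** — a compact CERES-like daily rice model:
   growing-degree-day and photoperiod phenology driven by the standard
   eight genotype coefficients (P1, P2O, P2R, P5, G1–G4), a single-layer
   soil-water bucket over the 30 cm managed depth, and stress-modulated
   biomass/sink yield formation. Coefficient sets for the Taiwanese
   cultivars TK9, TNG67 and TCS10 are packaged.
2. **GLUE calibration** — Generalized Likelihood Uncertainty Estimation of
   the genotype coefficients against observed seasonal yields: 10,000
   uniform prior draws per stage, Gaussian likelihood
   `L(θᵢ|O) = ∏ⱼ (2πσ₀²)^(-1/2) exp(−(Oⱼ − Sⱼ(θᵢ))²/2σ₀²)`, normalised
   weights `p(θᵢ) = Lᵢ/ΣLᵢ`, estimate `û = Σ p(θᵢ)θᵢ`; two stages
   (phenology first, growth second), all weight arithmetic in log space.
3. **Deficit-irrigation scenarios** — a fully-irrigated baseline
   (refill-to-field-capacity flood irrigation triggered at 50% of capacity)
   is simulated per cultivar × season × year and its schedule is replayed
   at saving proportions s ∈ {0, 0.2, …, 1.0} under two treatments:
   whole-season deficit, and deficit with full irrigation kept inside the
   water-sensitive panicle-initiation→heading window.
4. **Yield-response modelling** — yield ratios y(s) are stratified by
   seasonal accumulated precipitation (years >1000 mm excluded, remainder
   split at 500 mm → 24 subsets), fitted with four candidate curves
   (linear, quadratic, cubic, decreasing logistic), selected by
   `AIC = −2 log L + 2p` with plausibility overrides (no intercept above
   1.02, no increasing segment on [0,1]), corrected to the observed-yield
   scale by Δ = mean(observed) − mean(simulated full), wrapped in 95%
   prediction intervals, and inverted by bisection for the largest saving
   percentage with predicted retention ≥ 90%.

## Worked example

```python
from paddysim import CULTIVARS, SPRING_DEFAULT, generate_season_weather, run_baseline
from paddysim.simulator import ScheduledFractionPolicy, run_simulation
from paddysim.scenarios import yield_ratio

weather = generate_season_weather(
    SPRING_DEFAULT.with_year(2001, target_precip_total=650.0), seed=7
)
tk9 = CULTIVARS["TK9"]
base = run_baseline(tk9, weather)
print(f"baseline yield {base.yield_kg_ha:.0f} kg/ha, "
      f"irrigation {base.total_irrigation:.0f} mm in {len(base.irrigation_events)} events")

window = (base.pi_day, base.heading_day)
for s in (0.2, 0.6, 1.0):
    deficit = run_simulation(weather, tk9,
        policy=ScheduledFractionPolicy(base.irrigation_events, s))
    protected = run_simulation(weather, tk9,
        policy=ScheduledFractionPolicy(base.irrigation_events, s, window))
    print(f"saving {s:.0%}: uniform {deficit.yield_kg_ha:.0f} "
          f"({yield_ratio(deficit.yield_kg_ha, base.yield_kg_ha):.2f})  "
          f"protected {protected.yield_kg_ha:.0f} "
          f"({yield_ratio(protected.yield_kg_ha, base.yield_kg_ha):.2f})")
```

prints

```
baseline yield 5451 kg/ha, irrigation 255 mm in 9 events
saving 20%: uniform 4853 (0.89)  protected 5445 (1.00)
saving 60%: uniform 2846 (0.52)  protected 5368 (0.98)
saving 100%: uniform 763 (0.14)  protected 4612 (0.85)
```

The bracketed numbers are yield ratios relative to full irrigation
(rounded half-up to 2 decimals). In this moderately rainy spring season a
uniform 60% cut costs nearly half the yield, while the same cut with the
panicle-initiation→heading window kept fully irrigated costs 2% — the
behaviour that motivates sensitive-stage irrigation.

The whole pipeline (synthetic weather bank → GLUE calibration of TK9 →
scenario grid → stratified response fits → recommendations) runs with

```bash
paddysim run-all --seed 0 --outdir paddysim_out
```

which writes weather series, the calibration summary, long/wide
yield-ratio tables, the per-subset AIC table, prediction-band CSVs and a
`recommended_saving.csv` giving, per cultivar × season × treatment ×
precipitation stratum, the maximum water-saving percentage that keeps
predicted yield at ≥ 90% of the fully-irrigated level.

As a library, the two fitted components follow the model/results pattern:
`GlueCalibration(...).fit()` and `YieldResponseModel(records).fit()` return
results objects with `summary()` tables.

## Layout

- `src/paddysim/weather.py` — synthetic season generator, imputation, GDD
  and stage-window climate summaries; `io.py` — CSV and DSSAT-style WTH I/O
- `src/paddysim/simulator.py` — the surrogate crop model and irrigation
  policies; `cultivars.py` — genotype coefficient sets
- `src/paddysim/glue.py` — two-stage GLUE calibration
- `src/paddysim/scenarios.py` — baseline recording and the treatment grid
- `src/paddysim/response.py` — stratified curve fits, AIC selection,
  prediction intervals, retention inversion
- `src/paddysim/correlate.py` — yield–climate correlation profile
- `src/paddysim/synthetic.py`, `pipeline.py`, `cli.py` — study-condition
  generators, the end-to-end driver and the `paddysim` command

See `docs/methods.md` for model assumptions, parameter choices and
limitations.
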