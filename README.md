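# ithim-pa

Physical-activity pathway of the Integrated Transport and Health Impact
Model (ITHIM), in Python: what would happen to population health in England
& Wales if people travelled the way the Swiss, the Dutch or Californians do?

The package is aimed at health-impact modellers and transport/health
researchers.  It takes stratified travel-survey summaries and background
physical activity, converts travel time into weekly *marginal MET-hours*
(activity intensity above rest x duration), pushes exposure through
non-linear disease-specific dose–response curves, and applies potential
impact fractions to a burden-of-disease table — with full Monte Carlo
propagation of parameter uncertainty and tornado-style sensitivity ranking.
A synthetic-data module generates every input (person-level surveys for the
four settings, background activity, MET intensities, dose–response
parameters, burden tables) with the statistical structure of the published
summary tables, so the whole pipeline runs with no external data.

## Model

For a person with exposure `x` (marginal MET·h/week) and a disease whose
published relative risk is `RR_ref` at reference dose `x_ref`, risk follows
a log-linear curve on a power-transformed dose axis:

    RR(x) = exp( ln(RR_ref) · xᵏ / x_refᵏ ),   k ∈ [0.25, 1]

pinned so that `RR(0) = 1` and `RR(x_ref) = RR_ref` for every exponent `k`;
small `k` concentrates benefit at low doses.  Within each sex x age-band
stratum the population exposure distribution is represented at equi-probable
quantile points, and a counterfactual travel pattern changes burden through
the potential impact fraction

    PIF = ( Σᵢ RR(xᵢ·base) − Σᵢ RR(xᵢ·scen) ) / Σᵢ RR(xᵢ·base)

applied per disease, sex and age band: `Δburden = −PIF × baseline burden`
(negative = prevented).  Two scenario constructions are supported: adopting
the comparison area's *absolute* walking and cycling minutes, or its mode
*shares* within the baseline's unchanged travel-time budget.  Uncertainty
in the reference relative risks (truncated normal), the dose–response shape
`k` (uniform, shared across diseases) and optionally the MET intensities
and background activity is propagated by Monte Carlo (default 50,000
iterations); outputs are empirical medians with 95% credible intervals.

## Worked example

```python
import ithim_pa as ip

records = {}
for setting, seed in (("ew", 7), ("ch", 8)):
    survey = ip.generate_travel_survey(ip.setting_profile(setting, 20_000, seed=seed))
    records[setting] = ip.summarize_travel(ip.filter_records(survey), setting=setting)

inputs = ip.ModelInputs(
    baseline=ip.baseline_scenario(records["ew"]),
    scenario=ip.build_absolute_scenario(records["ew"], records["ch"]),
    background=ip.generate_background_pa(seed=7),
    met_dists=ip.DEFAULT_MET_DISTRIBUTIONS,
    dr_specs=ip.DEFAULT_DOSE_RESPONSE_SPECS,
    burden=ip.generate_burden_table(),
)
result = ip.run_simulation(ip.SimulationConfig(n_iterations=2_000, seed=1), inputs)

for outcome in ("dalys", "deaths"):
    med, lo, hi = result.total(outcome)
    print(f"{outcome}: {med:,.0f} (95% CI {lo:,.0f} to {hi:,.0f})")
med, lo, hi = result.lookup("ihd", "male", "dalys")
print(f"male IHD DALYs: {med:,.0f} (95% CI {lo:,.0f} to {hi:,.0f})")
```

prints

```
dalys: -197,593 (95% CI -431,200 to -65,828)
deaths: -12,387 (95% CI -25,474 to -4,347)
male IHD DALYs: -46,412 (95% CI -102,841 to -14,413)
```

i.e. if the urban England & Wales adult population walked and cycled as much
as the Swiss, the model's median estimate is roughly 198,000 disability-
adjusted life years and 12,000 premature deaths prevented per year, with
ischemic heart disease in men the largest single contributor.  The wide
credible intervals reflect genuine uncertainty about the dose–response
shape and activity intensities.

## Analysis scripts

The `analysis/` directory holds the numbered drivers for the full study:

1. `01_build_inputs.py` — synthesise and summarise the four travel surveys,
   background activity, MET, dose–response and burden tables into `results/`.
2. `02_build_scenarios.py` — build the six counterfactuals (three
   comparison areas x absolute/relative).
3. `03_run_impacts.py` — 50,000-iteration Monte Carlo per scenario;
   per-disease impact tables plus `results/impact_totals.csv`.
4. `04_tornado.py` — one-at-a-time sensitivity ranking and tornado plots.

A thin CLI (`ithim-pa synth|summarize|scenario|simulate`) exposes the same
stages for ad-hoc use.

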