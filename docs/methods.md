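# Methods

## Scope

The package implements the physical-activity pathway of a comparative risk
assessment of travel patterns: changes in walking and cycling time change
weekly physical-activity exposure, which changes disease-specific relative
risks, which changes deaths, years of life lost (YLL), years lived with
disability (YLD) and DALYs relative to a baseline burden table.  Injury and
air-pollution pathways, behavioural mode-shift modelling and life-table
methods are out of scope.

## Exposure model

Exposure is measured in *marginal* MET-hours per week: intensity above the
1-MET resting rate times weekly duration, `min/day × 7/60 × (MET − 1)`.
Compendium activities under 1.5 MET are excluded from the accounting
(raising `IntensityBelowFloorError`), so every counted activity has a
marginal intensity of at least 0.5.

Within a sex × age-band stratum, per-mode daily travel minutes are treated
as lognormal across people with the stratum's population-based mean
(non-travellers included as zeros) and a configurable coefficient of
variation (`time_cv`, default 1.0 — a typical dispersion for daily travel
time; the surveys' true within-stratum dispersion is unknown).  Walking and
cycling are comonotonic — a person's rank in one mode applies to the other
— which is simpler than an explicit copula and conservative in the sense of
maximising exposure contrast across the population.  The distribution is
summarised at `n_quantiles` equi-probable quantile midpoints (default 5,
standard quintile practice in comparative risk assessment; accuracy of the
impact fraction improves with more points and converges to the
individual-level calculation — see the test suite's brute-force
comparisons).  Background activity (household work, sport, occupational
activity above the intensity floor) is added to every quantile point and is
identical between baseline and scenario.

### MET intensity variation

The intensity table gives lognormal spreads for each activity (walking:
arithmetic mean 2.5 marginal MET, arithmetic sd 1.6, moment-matched;
cycling: median 5.8, geometric sd 1.3).  Two interpretations of that spread
are implemented (`SimulationConfig.met_variation`):

- `"population"` (default): the spread is person-level heterogeneity (some
  people walk briskly, some stroll).  Each mode's exposure is then the
  product of two independent lognormals (time × intensity), itself
  lognormal with `1 + cv²` multiplying across factors; intensities enter
  the exposure mean at their arithmetic means.  Under this reading the
  Monte Carlo credible intervals reflect parameter uncertainty only (the
  reference relative risks and the dose–response shape), which matches the
  scale of uncertainty reported in the study this model emulates.
- `"uncertainty"`: one intensity draw per activity per iteration shifts the
  whole population coherently.  This treats the spread as our ignorance of
  the true average intensity and produces much wider intervals, because a
  single walking-intensity draw scales a walking-dominated impact almost
  linearly.

Both modes share the same tornado treatment: the intensity parameter is
swept across its distribution's 5th–95th percentiles, so "walking METs"
ranks as a sensitivity driver either way.

## Dose–response

Risk follows `RR(x) = exp(ln(RR_ref) · xᵏ / x_refᵏ)`: log-linear in the
power-transformed dose, pinned at `RR(0) = 1` and `RR(x_ref) = RR_ref` for
every `k`.  The transform exponent is drawn uniformly on [0.25, 1] — the
exact distribution used historically is not documented, and a uniform draw
spans the published range symmetrically — with one shared draw across
diseases per iteration (a per-disease independent option exists,
`shared_k=False`).  Reference relative risks are drawn from a normal with
the published mean and sd, truncated to (0, 1]: an RR above 1 would flip
the effect direction for outcomes where activity is protective, which we
treat as unphysical.  The pooled cardiovascular row (stroke, ischemic heart
disease, other cardiovascular diseases) shares a single draw per iteration
(`group="cvd"`); colon cancer has sex-specific parameters; breast cancer
applies to women only; depression contributes morbidity (YLD) but no
deaths.  Exposures beyond ~5× the reference dose are extrapolations; no cap
is applied.

An all-cause mortality curve with user-supplied parameters is available
(`all_cause_mortality_rr`) so alternative mortality analyses can be run,
but no default parameters are bundled — the disease-specific model is the
main analysis.

## Impact fraction and burden

The potential impact fraction compares population-mean relative risk across
quantile points, `PIF = (ΣRR_base − ΣRR_scen)/ΣRR_base`, per disease × sex
× age band; `Δ = −PIF × baseline` for each outcome the disease carries, and
the DALY delta is the sum of the YLL and YLD deltas.  Negative deltas are
prevented burden, matching the sign convention of the published impact
tables.  Totals are exact sums over strata and diseases, and the grand
credible interval is computed on the per-iteration sum (not a sum of
per-disease intervals).

## Scenarios

*Absolute* adoption sets each stratum's walking and cycling minutes to the
comparison area's values.  *Relative* adoption applies the comparison
area's mode shares to the baseline stratum's own total travel time,
conserving the travel-time budget exactly.  Shares are computed per
(sex, age-band) stratum by default because active travel has strong age
gradients; a sex-level-share mode reproduces the arithmetic of published
sex-level tables.  Comparison strata that are empty (sparse old-age survey
cells) inherit the nearest complete band of the same sex, preferring the
adjacent younger band.

## Monte Carlo and sensitivity

Per iteration the engine draws the stochastic parameters, evaluates the
full chain vectorised across iterations, and summarises each output as the
empirical 2.5th/50th/97.5th percentiles with linear interpolation (the
credible-interval convention is stated because conventions differ).
Everything is reproducible from a single integer seed.  Iteration counts
below 100 log a warning.  The default of 50,000 iterations matches standard
practice for stable 95% intervals of a heavily skewed output; 2,000
iterations already place the median within ~2%.

Tornado analysis fixes one parameter at its 5th and 95th percentile while
holding all others at central values (distribution medians; intensity means
in `"population"` mode), records the induced range of the total DALY
change, and ranks parameters by that range.  The one-at-a-time scheme is a
reconstruction — the original tornado configuration is not documented.

## Synthetic data

The generators define the study conditions; all tests and analyses run on
their output.

- **Travel surveys.**  Four setting profiles (England & Wales, Switzerland,
  Netherlands, California) target the published sex-level mode-time means
  exactly, split across six age bands (15–29, 30–44, 45–59, 60–69, 70–79,
  80+) by illustrative gradients that reproduce the published qualitative
  age patterns (walking declines with age in E&W/California and rises into
  old age in Switzerland/Netherlands; cycling collapses with age everywhere
  except the Netherlands, where it holds until ~70).  Gradient magnitudes
  are invented — the printed figures give shapes, not numbers.  Per
  stratum, a fixed non-traveller share (default 15%) gets no trips;
  travellers participate in each mode with a probability chosen to keep
  participant means realistic, and participant minutes follow a 3-minute-
  shifted lognormal rescaled so the stratum population mean hits its target
  (calibration error is rounding-level, well under the 5% tolerance the
  tests assert).  Under-age respondents, sub-10,000-inhabitant communities
  and sub-3-minute trips are added deliberately so the harmonisation filter
  is exercised; targets are defined for the post-filter population.
- **Burden table.**  Per-disease, per-sex annual DALY and death totals are
  anchored exactly to the published baselines (grand totals 2,775,854 DALYs
  and 167,423 deaths, up to the source's own printed rounding).  The age
  split across bands (default weights 0.02/0.05/0.13/0.18/0.27/0.35,
  skewed old) and the YLL share of DALYs (0.7 for fatal diseases, 0 for
  depression) are synthetic structure: the true age-resolved burden is not
  published.
- **Background activity.**  Per-stratum marginal MET·h/week with a
  declining age gradient; defaults 9.0 (men) and 7.5 (women) for young
  adults, falling to ~45% of that by 80+.  The level is calibrated so that
  baseline total exposure sits in the neighbourhood of the published
  reference doses (~5–25 mMET·h/week), which is the regime in which the
  model reproduces the scale of the published impact estimates; treating
  all self-reported household/sport/work activity at face value would put
  every stratum far into the extrapolated tail of the dose–response curves.
  Optional lognormal jitter (off by default) makes background stochastic
  per iteration.

What passing tests on synthetic data do *not* show: fidelity to any real
national survey's dispersion, weighting scheme or diary protocol; the true
age distribution of burden; or the magnitude of real-world impacts beyond
the anchored marginals.

## Numerical choices

- Quantile midpoints `(i + 0.5)/n` of the exact lognormal quantile
  function; degenerate cases (zero mean or zero CV) return constant points.
- Truncated-normal RR draws use inverse-CDF sampling (no rejection loops),
  so draw counts are deterministic and reproducible.
- Filtering drops trips below the duration threshold trip-wise, never
  person-wise: a person whose trips all disappear becomes a non-traveller
  and stays in every denominator.
- Empty survey strata are recorded as missing (NaN) and logged, never as
  zero; mode-share computation skips missing strata but errors on genuine
  zero-travel strata.
- Integer person allocation uses largest-remainder rounding so stratum
  counts are deterministic.
- Tornado ties are broken alphabetically by parameter name (stable sort),
  making rankings order-invariant.

## Limitations

- The burden age split and background-activity table are synthetic; per-age
  results should not be interpreted, only totals anchored to published
  marginals.
- The dose–response family is the single pinned power-transform curve; no
  disease-specific curve shapes beyond the exponent, and no cap on the
  protective effect at extreme exposures.
- Survey weighting is supported but defaults to 1; multi-day diary
  normalisation is not modelled.
- Deaths flow through disease-specific mortality only; the all-cause
  alternative requires user-supplied parameters.
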