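# Methods note

This note defines the models implemented in `heterotherm`, the parameters
and defaults, what the synthetic-data generator emulates (and deliberately
does not), the numerical conventions, and known limitations. It makes no
empirical claims beyond what the test suite computes.

## 1. Respirometry model

Open-flow, pull-mode respirometry: air is drawn through a chamber at a mass
flow `FR` (default 50 L h⁻¹, expressed as ml h⁻¹ at STPD in the equation),
dried, and analyzed for the O2 fraction at 10-s cadence. The analyzer cycles
55 min of chamber ("sample") air with 5 min of outside ("reference") air.

**Drift correction.** Electrochemical O2 sensors drift slowly. Each reference
segment — with the first and last 30 s dropped as washout — is summarised by
its median O2 fraction anchored at the segment's temporal midpoint. A
piecewise-linear baseline through the anchors (held constant before the first
and after the last anchor) estimates what the sensor reads for air of known
fraction `FiO2`; sample rows are shifted by `FiO2 − baseline` and reference
rows are dropped. The correction is idempotent. A linear drift is removed
exactly at interior samples (tested); curvature between anchors ~55 min apart
is the residual error mode.

**Flow equation.** For dried sample air with CO2 left in the stream and flow
measured downstream of the chamber,

```
V̇O2 = FR · (FiO2 − FeO2) / (1 − FeO2 · (1 − RQ))
```

with `FiO2 = 0.2095` and an assumed respiratory quotient `RQ = 0.85`
(defaults; both configurable per run). Mass-specific MR is V̇O2 divided by the
mean of pre- and post-run body mass. Transient negative rates are clipped to 0
and counted; > 5 % clipped raises a warning.

## 2. State classification

| Parameter | Default | Why |
|---|---|---|
| `torpor_fraction` | 0.5 | torpor = MR at or below 50 % of the RMR baseline (inclusive) |
| `rmr_quantile` | 0.5 | RMR baseline keeps the lowest half of resting-phase values per clock hour (floor rule) |
| `tmr_quantile` | 0.7 | TMR keeps the lowest 70 % of in-bout values per hour |
| `min_bout_min` | 5 min | shorter sub-threshold runs are indistinguishable from noise at this duty cycle |
| `micro_max_min` | 60 min | observed micro bouts top out near 36 min and extended bouts start near 1.7 h; 60 min splits the unobserved gap |
| `multiday_min_h` | 24 h | bouts spanning more than a day are multi-day (hibernation-like) |
| `merge_gap_samples` | 2 | sub-threshold runs separated by ≤ 2 supra-threshold samples (20 s) are one bout |
| `tskin_delta_c` | 1.5 °C | minimum \|ΔT_skin\| for an extended bout to count as T_skin-confirmed (sign-agnostic) |
| `slope_fraction_per_min` | 0.25 | entry/arousal samples: 1-min-smoothed \|dMR/dt\| above 25 % of baseline per minute |
| `rmr_min_hour_samples` | 6 | hours retaining fewer filtered samples are skipped in the baseline |
| `stress_window_min` | 30 min | the first half hour after chamber entry is excluded (handling stress) |
| `feeding_exclusion_h` | 3 h | samples within 3 h after a feeding event are excluded |

**Resting window.** Sunrise to 30 min before sunset, per day, from the NOAA
solar-geometry equations (zenith 90.833°, i.e. refraction plus solar radius)
at the site coordinates, or from explicit overrides. The NOAA implementation
agrees with an independent ephemeris to well under two minutes at tropical
and temperate latitudes (frozen oracle values in `tests/test_solar.py`);
polar day/night raises an error as out of scope.

**Baseline fixed point.** The RMR baseline must be estimated on euthermic
samples, but which samples are euthermic depends on the baseline. The
iteration is seeded with the 90th percentile of resting-phase MR (an
overshoot-safe starting threshold: an over-wide torpid mask is pruned on the
next pass), then alternates baseline re-estimation on non-torpid samples with
threshold re-detection until the torpid mask is stable (≤ 25 iterations).

**Entry/arousal.** Steep sub-threshold edges (slope criterion above) are
peeled off bout interiors so they never contribute to TMR, but the bout's
start/end still span the full sub-threshold run. This slope rule is a
reproducible stand-in for the visual transition inspection used in practice.

**Durations are wall-clock.** Reference-air windows leave holes in the sample
index, so durations are computed from timestamps (plus one cadence step), not
sample counts; a bout spanning a 5-min reference window is not shortened.

**Labels partition the run.** Every sample gets exactly one of REST, ACTIVE,
MICRO/EXTENDED/MULTIDAY_TORPOR, ENTRY, AROUSAL, EXCLUDED_FEEDING,
EXCLUDED_STRESS. Supra-threshold samples bridged inside a merged bout stay
REST, so every torpid-labelled sample truly lies at or below the threshold.

## 3. Timing statistics

Clock times map to angles θ = 2π·minutes/1440. Circular mean and SD
(√(−2 ln r)), Rayleigh test (z = n r² with the standard series p-value
approximation), and the Watson two-sample U² computed from weighted pooled
ECDFs (exactly the classical statistic without ties; the midrank convention
with ties). Tabulated critical values apply at n ≥ 8 per sample; below that a
seeded permutation p-value is available. U² is rotation-invariant (tested).

## 4. Energetics

**Oxycalorific equivalent.** RQ is interpreted as a carbohydrate/fat
oxidation mixture: w = (RQ − 0.7)/0.3 weights the pure-fuel equivalents
21.12 (carbohydrate) and 19.61 (fat) kJ per litre O2; RQ 0.85 → 20.37 kJ L⁻¹
(two-decimal convention).

**DREE.** Daytime resting energy expenditure integrates the per-minute MR
from sunrise to sunset: `Σ (mr/60) · oxycal / 1000` kJ g⁻¹. Missing minutes
are linearly interpolated; the budget is flagged invalid when more than 5 %
of minutes are missing *beyond* the instrument's designed reference gaps
(5 min per hour under the 55/5 duty cycle — counting those by-design blind
minutes against the budget would invalidate every run from the standard
protocol).

**Savings and reductions.** Percent saving = 100·(1 − strategy/reference),
reported rounded half-up. Group-level metabolic reductions average each
animal's own reduction percentage rather than taking the ratio of group
means; the two differ whenever animals vary in RMR.

**SMI.** Scaled mass index: SMI_i = BM_i · (L0/L_i)^b with b the
standardised-major-axis exponent (OLS slope of ln BM on ln L divided by
|Pearson r|) and L0 the arithmetic mean length. Invariant to a common
rescaling of the lengths (tested).

## 5. Group statistics

Welch's t (Welch–Satterthwaite df) and the paired t on differences, with
p-values from the t distribution; Bonferroni–Holm step-down adjustment
(multiply the i-th smallest p by m − i, enforce monotonicity, cap at 1); the
two-sided Fisher exact test by full hypergeometric enumeration under the
point-probability rule (sum probabilities of all margin-consistent tables no
more probable than the observed one, with a 1e-7 relative tie tolerance).
Degenerate margins give p = 1. Mixed models (site-season × Tₐ interactions,
Tukey-adjusted marginal means) are not re-implemented; `model_ready_table`
exports the tidy per-animal-per-bin data those models consume.

## 6. Synthetic-data generator

The generator emulates the full measurement chain so the pipeline can be
validated against exact ground truth:

- **Microclimates** per profile (`cave_dry`, `cave_wet`, `forest_wet`):
  near-constant cave Tₐ with clipped Gaussian noise; a forest sinusoid
  peaking at 14:00 with the configured daily amplitude; RH anti-correlated
  with Tₐ. Clipped to configured ranges.
- **Schedules**: per rest day a strategy is drawn (default animal-day mix
  5 euthermic : 42 micro-only : 35 micro+extended : 10 extended-only, or
  fixed). Bout depths and durations come from truncated normals
  (micro: 17 ± 8 min on [5, 36], depth 0.76 ± 0.06 on [0.63, 0.89];
  extended: 4.9 ± 0.97 h on [1.7, 8.3], depth 0.84 ± 0.05 on [0.70, 0.94]).
  Extended bouts anchor mid-morning; micro bouts scatter uniformly with a
  ≥ 5-min gap. No bout is scheduled in the first 45 min (`settle_min`):
  freshly handled animals are treated as stressed, and the classifier
  excludes that span anyway.
- **MR waveform**: euthermic floor (1.0 ml O2 g⁻¹ h⁻¹) plus a linear rise
  below a 32 °C lower critical temperature, bout depressions with exponential
  entry/arousal ramps (τ = 10 s), and a ×2 nocturnal activity block in the
  forest profile. The waveform is inverted through the flow equation to
  excurrent O2 fractions; linear sensor drift (2 × 10⁻⁵ fraction h⁻¹) and
  Gaussian noise (SD 10⁻⁵, the sensor's resolution scale) are added and the
  55/5 duty cycle imposed. T_skin (5-min cadence) sits at 36.5 °C with
  exponential excursions during extended bouts only — a drop in the cave,
  a rise in the hot forest roost; micro bouts leave no T_skin signature.
- **Ground truth**: the bout list, per-day strategies, and the per-day DREE
  as the 1-s analytic integral of the noiseless waveform.
- **Observability**: `detectable_bouts()` annotates which true bouts are
  physically observable under the duty cycle — a bout whose sub-threshold
  interval (entry lag τ·ln(d/(d−0.5)), arousal lag τ·ln(d/0.5)) is sampled
  for < 5 min of wall-clock span hides inside reference windows and cannot be
  recovered by any method. Recovery tests compare against detectable truth;
  `edges_sampled` marks bouts whose duration is measurable to within the
  threshold-crossing lag.

**Not emulated:** biophysical heat balance, evaporative water loss, RQ
dynamics during fasting, analyzer washout kinetics inside sample segments,
chamber mixing time constants, and behavioural feedback between Tₐ and bout
initiation. Bout timing beyond the mid-morning anchor is uniform, not fitted
to any observed timing distribution.

All randomness flows through `numpy.random.SeedSequence([seed, k])` with a
fixed stream index `k` per component, so the same seed and configuration give
byte-identical output files (tested).

## 7. Numerical conventions

- Rounding of reported percentages is half-up (`floor(x + 0.5)`), not
  banker's rounding.
- Quantile filters ("lowest 50 % / 70 % per hour") use the floor rule with
  stable-sort tie-breaking and keep at least one value per hour; baseline
  hours retaining fewer than 6 filtered samples are skipped with a warning.
- The torpor threshold is inclusive (MR ≤ 0.5 × baseline).
- Trace round-trips are written at 6-decimal precision (0.1 ppm of an O2
  fraction, far below sensor noise).

## 8. Limitations

- The RMR baseline assumes some euthermic resting samples exist each run;
  a run spent entirely torpid raises rather than guessing.
- Drift correction assumes drift is slow relative to the 1-h anchor spacing.
- The slope-based entry/arousal rule approximates expert visual scoring; on
  very noisy traces the peeled transition spans will differ from a human's.
- The Rayleigh p-value is the standard series approximation — accurate for
  n ≥ ~10; the Monte-Carlo calibration test bounds its small-sample type-I
  error rather than proving exactness.
- Watson U² table thresholds only bound p (reported as the smallest
  tabulated α exceeded); exact p-values require the permutation method.
- Mixed-model inference is out of scope by design.
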