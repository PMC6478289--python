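# Methods

This document describes the generative model behind
`larvagrowth.simulate`, the statistical machinery in
`larvagrowth.inference`, and the assumptions and limitations of both.

## 1. The generative model

### Scales and rationale

All growth is modelled on the **cube-root-of-mass scale**
(`c = m^(1/3)`, units mg^(1/3)). Larval growth is close to cubic in
time — linear body dimensions grow roughly linearly while mass tracks
volume — so a constant daily increment `g` on the `c` scale (`the
allometric differential growth rate`) produces realistic accelerating
mass curves and, crucially, is independent of current size. That makes
`g` the natural scale on which to impose sex differences and variance
components without entangling them with body size.

### Trajectory construction

For one larva with sex-specific parameters (subscripts dropped):

1. **Development time** to the last instar:
   `t5 ~ N(mean_time_to_instar5, sd_time_to_instar5)`.
2. **Initial mass** (day-0, intermolt stasis): drawn on the cube-root
   scale, `c0 ~ N(μc, sd_initial_cuberoot)`, where `μc` is chosen so
   that the *mass-scale* mean equals `mean_initial_mass` (the cube of a
   noisy cube-root is biased upward; `μc` solves the cubic moment
   equation exactly, see `simulate._mean_preserving_cuberoot_mean`).
3. **Individual rate**: `g_i = rate + b + u`, with a shared brood
   effect `b ~ N(0, sd_rate_brood)`, an individual effect
   `u ~ N(0, sd_rate_individual)` (both truncated at ±2.5 sd), plus
   `host_effect_on_rate` on the second host (0 by default).
4. **Day 1**: `c1 = c0 + gutfill_factor · g_i`. The first feeding day
   shows an inflated apparent gain because the gut fills after the
   moult; `gutfill_factor = 1.5` reproduces the large day-1 jump.
5. **Free growth** (days 2 to `taper_start − 1`):
   `c_d = c_{d−1} + g_i + ε_d`, `ε_d ~ N(0, sd_rate_day)` independent
   across days. This window (days 2–5 by default) is where growth-rate
   analyses operate.
6. **Taper** (days `taper_start` to the individual's peak day,
   `peak ~ N(peak_day, sd_peak_day)`): the increment shrinks linearly
   to zero at the peak, flattening the curve into a sigmoid plateau.
7. **Post-peak decline**: from the peak to the individual's last
   feeding day (`duration ~ N(instar_duration, sd_instar_duration)`)
   mass declines geometrically so that the final larval mass equals
   `max / max_over_final` — larvae void the gut and lose mass before
   wandering.
8. **Pupal mass**: `max / max_over_pupa`, with small log-normal noise
   (`sd_pupa_lognoise`).

Degenerate draws (non-positive rate `g_i < 0.005`, a trajectory whose
maximum falls below its initial mass, non-positive times) are rejected
and redrawn from the individual's own RNG stream, up to 20 times.

### Design and reproducibility

`simulate_population` generates `n_broods` broods of
`larvae_per_brood_host1 + larvae_per_brood_host2` larvae with random
sex (`sex_ratio`). RNG streams are spawned hierarchically with
`numpy.random.SeedSequence`: one child per brood, one grandchild per
larva. Consequently the same seed yields byte-identical output, and
enlarging the design leaves existing broods' trajectories unchanged.

### Calibration

Defaults are calibrated so that population summaries match a reference
set of descriptor means (`params.CALIBRATION_MEANS`) and rate
statistics for a geometrid moth with moderate female-biased SSD:

| parameter | F | M | anchored to |
|---|---|---|---|
| `mean_time_to_instar5` | 18.17 | 17.58 | mean days to instar 5 |
| `mean_initial_mass` | 29.18 | 25.30 | mean day-0 mass (mg) |
| `rate` | 0.279 | 0.270 | mean allometric rate, days 2–5 |
| `peak_day` | 9.75 | 8.67 | mean day of maximal mass |
| `instar_duration` | 11.46 | 10.10 | mean instar length (days) |
| `max_over_final` | 1.39 | 1.37 | maximal / final larval mass |
| `max_over_pupa` | 1.634 | 1.563 | maximal / pupal mass |

The split of rate variance (`sd_rate_day = 0.064`,
`sd_rate_brood = 0.09`, `sd_rate_individual = 0.02`) was chosen, before
any acceptance testing, to reproduce two precision anchors: the
standard error of the day-2 mass increment (total per-record sd on the
`c` scale ≈ 0.11) and the strength of the sex effect in the
repeated-measures ANOVA of the allometric rate (sex-contrast SE
≈ 0.0027, i.e. F ≈ 11 for the 0.009 rate difference).

### What the simulator does *not* emulate

* **Absolute maximal mass overshoots its anchor.** With free growth
  through day 5 and the calibrated rates, simulated maximal masses
  average ≈ 135 mg (F) / 112 mg (M) rather than 120 / 99. The
  free-growth window and the descriptor anchors are not jointly
  satisfiable under this model; we preserve the window, the rates and
  all *ratios* (max/final, max/pupa, F/M), so dimorphism statistics are
  faithful while absolute late-instar masses run ~12% high.
* **The relative-rate compensation is imperfect.** The sexes' initial
  mass ratio (1.153) slightly exceeds what the rate ratio alone would
  compensate on the log scale, so the true sex effect on the relative
  rate is a little below zero (≈ −1.3 residual sd) rather than exactly
  zero. It is non-significant in roughly three quarters of simulated
  default populations — a qualitative, not a guaranteed, masking.
* No mortality or measurement dropout by default (`dropout_rate = 0`),
  no host-plant effect on rate (`host_effect_on_rate = 0`), no
  rate–duration correlation within individuals, and no
  temperature/photoperiod covariates.

## 2. Growth-rate indices

For consecutive masses `m_{d−1}, m_d`:

* absolute: `m_d − m_{d−1}` (mg/day),
* relative: `log10(m_d / m_{d−1})` (per day; `base="ln"` available),
* allometric: `m_d^(1/3) − m_{d−1}^(1/3)` (mg^(1/3)/day).

`rate_table` emits one record per larva × day × measure over the
free-growth window, carrying `covariate_mass = m_{d−2}` (the mass
*before* the increment) for size-dependence analyses. Under exact
cubic growth the allometric rate is constant in size while the relative
rate declines with mass — the size artefact that makes the larger sex
look slower on the conventional scale.

## 3. Mixed-model ANOVA

`inference` fits a Gaussian mixed model with random brood intercepts
(feature layout: one value per larva) or random brood *and* larva
intercepts (repeated layout: one record per larva × day):

`V = σ² (I + λ_b Z_b Z_bᵀ + λ_i Z_i Z_iᵀ)`.

* Variance ratios `λ` are estimated by **profiled REML**: σ² and the
  fixed effects are profiled out analytically and the concentrated
  criterion is minimised with L-BFGS-B over `λ ∈ [0, 10⁴]`, with
  explicit evaluation of the zero-variance boundary corners. The
  brood-block structure makes each evaluation a set of small dense
  Cholesky solves.
* Fixed effects use **sum-to-zero codings** (sex, host plant, their
  interaction; in the repeated layout also centred day and sex×day),
  so single-df **Type III Wald F** statistics are invariant to cell
  imbalance.
* Denominator df follow the **containment** rule: for between-larva
  factors, `n_larvae − rank(between design)` (e.g. 1635 − 4 = 1631 in
  the default design); for within-larva factors,
  `n_obs − n_larvae − 2`.
* The reported `r2` is each factor's Type III sum of squares as a share
  of the total sum of squares from the corresponding fixed-effects OLS
  fit — a descriptive effect-size approximation, not a likelihood-based
  partition.
* If REML optimisation fails, a method-of-moments estimate of the
  variance ratios is used and flagged in the `method` column.

The engine is validated two ways in the test suite: against brute-force
fixed-effects Type III F on constructed designs whose variance
components are exactly zero (where the mixed F must agree to machine
precision), and against `statsmodels` MixedLM on designs with real
brood variance. A 500-replicate null simulation confirms the sex test's
type-I error is at the nominal 5%.

`size_dependence` complements the ANOVA with per-day, per-sex OLS
regressions (via statsmodels) of each rate measure on the previous
day's mass.

## 4. SSD decomposition

`decompose` projects final mass on the cubic scale,
`m(t) = (m0^(1/3) + g·t)³`, from a common initial mass under two
counterfactuals:

* **rate only** — both sexes grow for `days` days at their own rates:
  `ratio_from_rate_difference(25.30, 0.279, 0.270, 5) = 1.0318`;
* **duration only** — both grow at the male rate but one grows
  `extra_days` longer:
  `ratio_from_extra_day(25.30, 0.270, 5, 1) = 1.2012`.

The comparison shows that the statistically detectable rate dimorphism
projects to only ~3% of mass, an order of magnitude less than a single
extra growth day — growth duration is the dominant proximate source of
SSD in this system.

## 5. Numerical and engineering choices

* Text I/O only: wide (one row per larva, `day1..dayN` columns) and
  long (tidy mass table plus a `*_meta` companion) dialects, TSV or
  CSV, `%.8g` floats. Trailing blank day columns mean a shorter
  instar; internal blanks are preserved as missing measurements.
* All analyses are deterministic given their inputs; only `simulate`
  consumes randomness, always through an explicit seed.
* Invariants (positive masses, pupal ≤ maximal, known sexes/hosts,
  unique ids) are enforced at the `Trajectory`/`TrajectoryTable`
  boundary, so downstream code can assume clean data.
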