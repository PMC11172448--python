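# Methods

## Scope and data model

The package quantifies muscle aging in zebrafish from four kinds of input:
cohort biometry tables (weight g, total length cm, age group), open-field
tracking trajectories (time s, x cm, y cm), histology/TEM/confocal field
annotations (binary collagen masks, per-field myocyte tallies,
per-mitochondrion records, sarcomere band lengths, GFP/DAPI summaries),
and a synthetic generator that emulates the four-age-group study design
(2, 10, 30, 60 months). Units are fixed by schema — g, cm, s, µm, µm² —
and never inferred; the frailty index mixes variables whose units must not
drift. All readers validate and raise typed errors; nothing is silently
repaired (non-monotone trajectory timestamps are reported with the first
offending index, not re-sorted).

## Locomotor summaries

A recording session is a 3-minute adaptation stage followed by a 20-minute
scored window; `trim_adaptation` keeps the half-open window
[trim, trim + record) and re-bases time to zero. From the retained polyline:

* **total distance** = Σ Euclidean step lengths;
* **mean speed** = total distance / elapsed time. This definition (rather
  than the mean of per-step speeds) is invariant to the sampling rate for
  uniform sampling and matches the unit bookkeeping of reporting a distance
  and a duration;
* **maximum speed** = max per-step speed after a centered rolling median
  (default window 3, a config knob recorded in the run manifest). The
  median damps single-frame tracker jitter, which otherwise dominates the
  maximum. What smoothing, if any, commercial tracking software applies is
  generally undocumented, so the default is explicit rather than an
  imitation. With window 1 (no smoothing) `max ≥ mean` holds exactly; an
  aggressive window on a degenerate path consisting of one brief burst can
  pull the reported maximum below the mean, and the summary reports it
  as-is rather than clamping.

Missing frames appear as single long steps; no interpolation or imputation
is performed, since no imputation policy can be justified from the
protocol. Trajectories are assumed already calibrated to cm (a
`px_per_cm` config field documents upstream calibration; arena geometry is
unknown and not modeled).

## Morphometry formulas

All morphometry is arithmetic on upstream annotations:

* BMI = weight / length² (g/cm²);
* collagen area fraction = 100 · set pixels / total pixels on a binary
  mask (8-bit masks binarize by pixel > 0; multi-channel images are
  rejected — segmentation is upstream);
* myocyte density = count / field area (myocytes/µm²), widths aggregated
  as mean ± SD;
* TEM fields (default 5.15 µm × 5.15 µm) yield IFM/SSM counts, per-class
  mean cross-sectional area, and damaged % = 100 · damaged / total. A
  field with zero mitochondria reports a *flagged undefined* damage
  percentage, never 0: 0/0 must not pass as "no damage". Damage itself
  (swelling, vacuolation, depleted/disorganized cristae) is a human or
  synthetic annotation consumed as a boolean;
* sarcomere statistics are plain aggregation of the measured lengths. Only
  H ≤ A is enforced (the H band lies inside the A band); no further band
  arithmetic (such as sarcomere = A + I) is assumed, because measurement
  conventions differ between labs;
* confocal ratio = mean GFP intensity / DAPI count, undefined (error) at
  zero nuclei.

## Frailty index

Reference statistics are the sample mean and SD (n−1) of the youngest
group; a zero SD is an error because it leaves the bins undefined. The
literal reading of the published binning clauses is mutually consistent
only as half-open bins with an isolated point at 3:
|z| ≤ 1 → 0, (1, 2] → 0.25, (2, 3) → 0.5, exactly 3 → 0.75, (3, ∞) → 1.
This is the default (`bins="literal"`); `bins="practical"` collapses the
measure-zero band, giving (2, 3] → 0.5 and (3, ∞) → 1, for users who
regard the exact-3 clause as a boundary artifact. The choice is recorded
in the run manifest.

Two scoring modes are first-class because the published group-level
results cannot discriminate between them (see Limitations): **absolute**
(default; any deviation counts — "differed by ±1 SD" reads as two-sided)
and **directional** (only frail-direction deviations count: lower
distance/speeds, higher BMI). Missing variables error by default; an
`allow_missing` option renormalizes by the available count and flags the
result, mirroring clinical FI practice.

Scores are exact multiples of 0.25 and the index is their exact mean, so
tests compare FI values with exact arithmetic. The index is invariant to
any affine rescaling of a variable applied consistently to reference and
test values, is even in z (absolute mode), and is monotone in each |z|.

Dispersion convention: published group tables may print SD or SEM, and the
two are easy to conflate. Printed dispersions are taken as SD by default;
a `dispersion="sem"` flag with a group n converts (SD = SEM·√n).

Reference fish are themselves scored against their own group's statistics.
With spread in the reference group this generically yields small nonzero
scores; a group-mean FI of exactly 0 for the reference arises only if
every fish is within 1 SD of the mean on every variable.

## Group statistics

One-way ANOVA (F = MS_between/MS_within, df k−1 and N−k) with Tukey's HSD;
unequal group sizes use the Tukey–Kramer standard error
√(MSW/2 · (1/nᵢ + 1/nⱼ)). The F and q statistics are computed in-package
(which keeps the degrees-of-freedom bookkeeping and degenerate branches
explicit); tail probabilities come from scipy's F and studentized-range
distributions, accurate far beyond the 1e-4 absolute target relevant to
α = 0.05 decisions. Degenerate inputs are deliberate: all observations
identical → F = 0, p = 1; zero within-group variance with unequal means →
the analytic limit p = 0, flagged. No Welch correction is applied (plain
one-way ANOVA is the named procedure); the unpaired t test arises as the
k = 2 special case, where the Tukey decision coincides with the
pooled-variance t test. Stars follow the usual convention (* p < 0.05,
** p < 0.01, *** p < 0.001).

## Synthetic data

The generator exists so every pipeline stage is testable without animal
data; its defaults are the published group laws, not tunables.

* **Cohorts.** The four scored variables are drawn independently per fish
  from normal laws truncated at zero (negative draws are resampled, not
  clipped, preserving continuity near 0), using the packaged per-group
  (mean, SD) table. The 30-month maximum speed was never published and has
  no default: requesting it is an error, never an interpolation. True
  per-fish covariance is unknown, so independence is the default and a
  correlation-matrix hook supports sensitivity analyses. Lengths follow
  synthetic stand-in laws (means 2.9/3.4/3.7/4.2 cm at 2/10/30/60 months,
  ~8% CV) — chosen once as realistic adult zebrafish sizes increasing with
  age — and weight is derived as BMI · length², so BMI follows its
  published law. Each fish's locomotor summary uses the implied duration
  distance/mean-speed, keeping the summary internally consistent even
  though the drawn variables are independent.
* **Trajectories.** A correlated random walk whose per-step speed series
  is an AR(1) fluctuation (φ = 0.95, 25% relative amplitude) around the
  target mean, rescaled so the realized mean speed is exact, with a 3-step
  plateau at the target maximum so the median-3 smoother preserves it;
  other steps are capped at 90% of the maximum. Headings evolve by normal
  increments (SD 0.35 rad). The generator emulates the *summary structure*
  of tracked swimming, not tank geometry, wall-following, burst-glide
  kinetics or tracker noise — so passing tests demonstrate pipeline
  correctness, not behavioral realism.
* **Masks.** Exactly round(fraction·N) pixels set (by construction, via
  top-k selection on Gaussian-filtered noise with tie-breaking jitter),
  arranged as smooth blobs rather than salt-and-pepper noise.
* **TEM fields.** Exactly round(fraction·total) mitochondria flagged
  damaged; CSAs from a truncated normal law.

All generators are pure functions of (SimConfig, ids): the same seed gives
byte-identical CSV output. Child streams are derived per (seed, purpose)
so adding one generator call never shifts another's draws.

## Problem sizes and numerical choices

Default test and acceptance runs use cohorts of 10–30 fish per group
(n = 1000 for parameter-recovery checks), 20-minute trajectories at 10 Hz
(12 000 steps), 100×100 masks, and 2000-replicate Monte-Carlo nulls for
the ANOVA type-I check — sizes chosen so the full suite completes in a few
seconds while keeping binomial/SEM tolerances meaningful (3·SEM bands;
rejection rate within 3 binomial σ of α). Floating-point equalities on
summed quantities use relative tolerances ≤ 1e-10; FI comparisons are
exact.

## Limitations

* The published per-fish appendix data are unavailable, so the printed
  group frailty indices (e.g. 0.125 ± 0.144 at 30 months, 0.250 ± 0.000 at
  60 months) cannot be re-derived: per-fish scoring is nonlinear, group
  means do not determine it, and the SD-vs-SEM convention of the printed
  dispersions is ambiguous. Feeding printed group means through the scorer
  with dispersions-as-SD does not reproduce a zero 10-month FI under
  absolute scoring (the 10-month BMI trends high), which is why directional
  mode exists; neither mode is asserted as the original intent. The
  acceptance checks therefore test structure: old synthetic cohorts score
  strictly frailer than young ones under both modes, and the index is
  bounded and monotone.
* Printed myocyte densities cannot be re-derived from raw counts because
  absolute field areas at the magnification used are not stated; the
  module computes density from whatever field area the annotation carries.
* The package never touches raw video or micrographs: tracking,
  segmentation and damage calls are upstream.
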