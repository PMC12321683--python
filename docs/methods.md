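# Methods

## The estimand

The apparent diffusion coefficient (ADC) is defined operationally: fit
`ln S(b) = ln S0 − b · ADC · 10⁻³` by ordinary least squares over the
acquired b-values (b in s/mm², ADC in µm²/ms = 10⁻³ mm²/s) and report
−10³ × slope.  With two b-values this is the two-point ratio formula
`ln(S(b₀)/S(b₁))/(b₁−b₀)·10³`.  The estimator is deliberately the
plain unweighted log-linear normal-equation solve — the method used by
typical in-house ADC software — not a weighted or nonlinear variant,
because the package studies how *that* estimator responds to
acquisition choices.  Voxels with any non-positive signal are flagged
invalid and excluded from ROI statistics rather than clamped; clamping
would bias low-signal voxels.

## Synthetic cohort

### Signal mechanism

True tissue signal is a two-compartment bi-exponential
(intravoxel-incoherent-motion-like):

    S(b) = S0 · [ f · exp(−b·D*·10⁻³) + (1−f) · exp(−b·D·10⁻³) ]

with perfusion fraction `f`, tissue diffusivity `D` and
pseudo-diffusion `D* = 20 µm²/ms`.  This is the smallest mechanism
that makes the fitted mono-exponential ADC *decrease* as the highest
b-value in the fit grows: the fast compartment steepens the early
decay, so fits that stop at lower b-max sit on the steeper part of the
log-signal curve.  Muscle uses `f = 0` (no b-max trend), tumor uses
`f = 0.0675`.  The tumor value was set, once, by a forward-model
calibration: over ten representative noise-free scans with the 7-value
scheme {0, 50, 100, 200, 500, 800, 1000} s/mm², the log-linear slope
of group-mean ADC against highest b over [200, 1000] averages a 2.8%
decrease per 100 s/mm², the magnitude reported for soft-tissue tumors.

Per scan, `D` is solved by bracketing root search (bracket
0.01–4.0 µm²/ms, tolerance 10⁻⁹) so that the log-linear fit *over that
scan's own b-values* returns the patient's true ADC exactly.  The
alternative — calibrating only the two-point ADC at a fixed reference
b — would make the standard full-scheme ADC map systematically miss
the configured cohort ADC distribution by up to ~0.04 µm²/ms,
because the OLS fit of a convex log-signal differs from its chord.
Consequence: with zero noise, fitting a scan with its own scheme
recovers the true ADC to < 10⁻⁶ µm²/ms, and for two-point schemes this
reduces to the classic two-point calibration.

### Patient truths and moment matching

Per-patient "true" median ADCs are normal draws: tumor diagnosis
1.09 ± 0.30, response 1.58 ± 0.38 (correlation 0.5 within patient),
muscle 1.20 ± 0.14 / 1.24 ± 0.16, all clipped to (0.3, 2.8) µm²/ms
(bounds wide enough that clipping is negligible).  Timepoint patterns
are exact by construction: with 114 patients, 81 have both timepoints,
31 diagnosis only, 2 response only (195 scans, 112 + 83), and 16 of
the both-timepoint patients carry a muscle region.

Draws use *empirical moment matching* (the `empirical=TRUE` convention
of multivariate-normal simulators): the standard-normal deviates are
affinely rescaled so that the realized sample mean and SD over the
subset the study summarizes (diagnosis scans, response scans, muscle
subset) equal the configured values exactly, not just in expectation.
The same principle pins the spread of the 22 center means of echo
time / pixel spacing / slice thickness to the configured
between-center SD, and the cohort-wide b-scheme composition to the
configured weights (largest-remainder allocation, assigned to centers
by a weighted urn so schemes still cluster within centers).  Rationale:
the generator's contract is to reproduce a documented variability
table and ADC summary table at the documented cohort size; without
moment matching, a 22-center, 195-scan realization misses those
targets by several hundredths for many seeds purely through Monte
Carlo error.  Set `empirical_moments: false` for fully random
two-level sampling.

### Acquisition parameters

Echo time, pixel spacing and slice thickness follow a two-level normal
model: center means around 75 ms / 1.2 mm / 5.0 mm with between-center
SD derived as `mean·sqrt(cv_total² − cv_within²)`, within-center SD
`mean·cv_within`.  Defaults reproduce cohort-wide CVs of 0.18 / 0.31 /
0.22 with median within-center CVs near 0.13 / 0.22 / 0.14.  B-value
schemes come from a six-scheme catalog (2 to 7 b-values, highest b 800
or 1000 s/mm²) with weights calibrated so the cohort CV of the number
of b-values is 0.55 and of the highest b-value 0.09.  Each of the five
manifest fields is independently missing with probability 0.075,
emulating header-extraction failures (the volumes themselves remain).

### Geometry, noise, flags

Volumes are 32×32×8 voxels.  The tumor is an ellipsoid (semi-axes 5–9
in-plane, 1.2–2.2 slices); half the scans carry an interior exclusion
ellipsoid at 45% scale filled with high-diffusivity "necrotic" tissue
(D = 2.3); muscle is an in-plane block, background D = 1.6.  Rician
noise applies `sqrt((v+ε₁)² + ε₂²)` with ε ~ N(0, σ), σ = 20 against
S0 = 1000 (tumor), i.e. baseline SNR 50 — at this level the noise-floor
bias on ROI-median ADC is below 0.005 µm²/ms.  Inclusion-flow flags
(no measurable tumor, quality score 1, missing DWI, outside field of
view) have probability 0 by default — the default cohort is fully
analyzable — and are raised in configs that exercise the filter.

Determinism: one master seed; per-scan streams are keyed by the master
seed and a CRC-32 hash of the scan id, so manifests and volumes are
bit-reproducible and independent of generation order, and the manifest
is identical whether or not volumes are built.

## Analyses

* **CV**: sample SD (n−1) over mean, missing values dropped per
  parameter; within-center CVs only for centers with ≥ 2 non-missing
  values.  Sample (not population) SD is used throughout; at cohort
  sizes of interest the difference is well inside reported precision.
* **Median split**: records with value ≤ median go low, > median go
  high (deterministic tie rule); all-equal parameters raise a
  degenerate-split error.  Groups are compared by a two-sided
  Mann-Whitney U test — exact null distribution when `n_x·n_y ≤ 400`
  and the pooled sample is tie-free, otherwise normal approximation
  with tie and continuity correction — Bonferroni-corrected with
  m = 10 (5 parameters × 2 timepoints) by default.
* **Regressions**: per-parameter simple OLS of median ADC on the
  parameter, with the slope t-test; run separately per timepoint.
* **Timepoint comparison**: paired mode is the Wilcoxon signed-rank
  test on per-patient differences (patients with both scans); unpaired
  mode is Mann-Whitney.  Both are reported, since with 81 paired
  patients either supports the same conclusion (tumor ADC rises,
  muscle does not).
* **b-value combinations**: all subsets of a scan's b-values
  containing b = 0 (2^m − 1 subsets for m non-zero values); scans
  qualify for this analysis with ≥ 6 b-values ("more than five" read
  strictly).  Group means/SEs per highest b-value; the sensitivity
  slope is a log-linear fit of ln(group mean) vs highest b over
  [200, 1000] s/mm², reported as `100·(1 − exp(100·slope))` percent per
  100 s/mm² so the figure compounds consistently (a relative-linear
  variant is available via `slope_method: relative_linear`).
* **Longitudinal four combinations**: percent change
  `100·(ADC_resp − ADC_diag)/ADC_diag` for the 2×2 choices of
  highest vs second-highest b-max group at each timepoint.
  "Propagated uncertainty" is the first-order delta method,
  `se% = 100·sqrt(se_r²/a_d² + a_r²·se_d²/a_d⁴)`; the effective n per
  side is the mean of the two groups' combination counts; pairs of
  deltas are compared by a Welch t-test from these summaries
  (Welch–Satterthwaite degrees of freedom).

## Fixed demonstration subset

`simulate_bsens_scans` emulates the fixed handful of many-b
examinations on which the b-max sensitivity is quantified.  Its ten
target ADCs sit at the decile midpoints of the diagnosis distribution
rather than being drawn randomly: the subset is meant to be a
representative cross-section, and the averaged slope it yields is then
a property of the calibration, not of one random draw.  Signals are
noise-free because the analysis isolates the model-driven b-value
effect.

## What the synthetic cohort does and does not show

The generator reproduces the *statistical* structure of a multicenter
cohort: marginal ADC distributions, acquisition-parameter dispersion
within and between centers, scheme heterogeneity, missing metadata,
exclusion flow, and the bi-exponential b-max mechanism.  It does not
contain real anatomy, partial-volume or motion effects, vendor ADC
algorithms, field-strength/vendor clustering, or genuine biological
coupling between acquisition choices and tumor state; tumors are
homogeneous within the ROI apart from the exclusion region.  Passing
tests therefore validate the pipeline's statistics and the internal
consistency of the b-value analysis — they do not certify effect sizes
in real patients.  In particular, the null result of the median-split
tests on default cohorts is built in (acquisition parameters are
independent of true ADC by construction) and is used to check type-I
error, not to make a clinical claim.

## Numerical conventions

Scale-invariant fits (multiplying all signals by a constant leaves ADC
unchanged); subset fits are canonicalized by sorting b-values;
even-sized ROI medians are midpoints of the central pair; the 10³ unit
factor is applied exactly once, inside the fit; SDs use n−1
everywhere; Bonferroni caps at 1.  Degenerate inputs raise typed
errors (`InvalidSubsetError`, `NoEvaluableROIError`,
`DegenerateSplitError`, `InsufficientDataError`, `InfeasibleTargetError`)
rather than returning silent defaults; pipeline stages skip and log
per-scan degeneracies but conserve scan counts in the inclusion
report.

## Problem sizes

Default analyses run at the documented cohort scale (114 patients, 195
scans, 22 centers, 32×32×8 voxel grids), which completes in seconds;
the error-rate studies use 1,000 simulated 40-scan cohorts for type-I
error and 200 replicates for the timepoint tests.  These sizes were
chosen to keep the full study reproducible on a laptop while leaving
Monte Carlo error well below the tolerances of interest.
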