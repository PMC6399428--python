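# Methods

This note documents the models, parameter choices and numerical
decisions behind `sleepfc`, and what the synthetic cohorts do and do not
establish about real data.

## State segmentation from breathing rate

Breathing rate is the only physiological channel used to segment the
scan into REM-like and NREM-like states; the high-rate state is REM-like.

**Rate estimation.** Breath peaks are detected with prominence-based
peak picking (prominence 0.3 × signal SD, minimum inter-peak distance
0.2 s, i.e. a 300 breaths/min ceiling). Each BOLD volume gets
`60 × n_peaks / window` from a 30 s window centered on the volume's
midpoint; edge windows are truncated with proportional scaling. The
30 s default is a compromise: it spans ≥ 50 breath periods at rodent
rates (small counting quantization, 2 breaths/min per count) while
staying shorter than typical state dwells so transitions are not
smeared by more than ~15 s.

**Labeling.** The original workflow labeled states manually from the
rate trace; the automated stand-in is an exact 1-D two-means split
(every threshold between sorted rate values is evaluated against the
within-cluster sum of squares — deterministic, no initialization).
Two states are declared only if the cluster-mean gap exceeds **both**

* 3.0 × the pooled within-cluster SD, and
* an absolute floor of 10 breaths/min.

Both guards are needed. An optimal two-means split of a *unimodal*
normal sample always attains a gap ≈ 2.66 × within-SD (the two
half-normals have means ±0.80 σ and within-SD 0.60 σ), so any relative
threshold below that declares spurious bimodality on every
constant-state recording; 3.0 sits just above it. Separately, the
breaths-per-window quantization concentrates the rate values of a
steady recording on a few discrete levels, shrinking the within-SD
toward zero and defeating any purely relative rule; the 10 bpm floor is
far below the ~20–30 breaths/min separating the two real regimes, so it
cannot mask a genuine transition. A unimodal recording is assigned the
single state whose reference rate (defaults 128/100 bpm) is nearer its
mean — the choice is mostly moot, since single-state subjects are
excluded anyway.

Runs shorter than 15 volumes (30 s, half an analysis window) are merged
into their longer neighbor to suppress flicker at transitions.

**Inclusion.** A subject enters the state-resolved analysis iff it has
≥ 1 REM↔NREM transition and ≥ 90 volumes in *each* state (the threshold
is inclusive: exactly 90 passes). The 90-volume rule is applied per
state rather than summed across states because the windowed statistics
need at least 3 windows (3 × 30 volumes) per state to average; a summed
reading could admit a subject with a single analyzable state.

## Signal conditioning

* **Bandpass:** order-4 Butterworth, 0.01–0.08 Hz, applied
  forward-backward (`sosfiltfilt`) for zero phase; DC is removed.
  The filter family and order are conventional for resting-state BOLD;
  the flat Butterworth passband keeps within-band amplitudes within 5%.
* **Order of operations:** filtering is applied to extracted ROI series.
  Both filtering and ROI averaging are linear, so the order is
  immaterial up to numerical tolerance; the suite asserts the
  commutation explicitly.
* **Spatial smoothing** is slice-wise 2-D with a 2-voxel FWHM
  (σ = 2/2.3548 voxels), matching an in-plane kernel on thick-slice
  acquisitions; the through-slice axis is never mixed. Boundary
  handling is nearest-edge replication.

## Windowed partial correlation

"Partial correlation" means the Pearson correlation of two series after
both are regressed on the six motion parameters plus an intercept — not
a full partial correlation conditioning on the other ROIs. The
implementation residualizes all ROI columns of a window jointly against
the shared design (one least-squares solve) and correlates the
residuals, which is algebraically identical to the pairwise definition;
the suite verifies this against an explicit normal-equations oracle and
an independent library implementation.

Windowing: each maximal same-state run of length L contributes
⌊L/30⌋ consecutive non-overlapping 30-volume windows starting at the
run's first volume; remainders are discarded. Nuisance regression is
windowed (the design is subset to the window's rows), consistent with
per-window correlation. Fisher's z = atanh(r) is applied **per window**
before within-subject averaging, i.e. averaging happens on the
variance-stabilized scale; whole-scan mode z-transforms its single r.
Windows with |r| = 1 are clipped to atanh(0.999999) with a warning;
residuals that are numerically zero (below 1e-8 of the input scale)
make the edge undefined for that window, and such windows are excluded
pairwise from the average with per-edge counts recorded.

Seed-based maps run the identical windowed procedure per masked voxel
against the seed ROI's mean series. Windowed (rather than whole-state)
computation is used for consistency with the edgewise analysis.

## Group statistics

Edgewise inference is a two-tailed unpaired t test on the subjects'
z values, pooled-variance Student by default (a Welch flag exists);
Benjamini–Hochberg FDR is applied over all 136 upper-triangle edges of
the 17-ROI matrix, separately per state and per contrast, because the
two state contrasts are reported separately. Edges with zero pooled
variance have no defined t and are excluded from the FDR family with a
warning. The group difference is reported as control − lesion so that
positive values denote decreased connectivity in the lesion group.
Voxelwise maps use the same machinery within a supplied brain mask:
one-sample t against zero for group maps, two-sample t for difference
maps, both FDR-thresholded, with the mean z (or mean difference)
retained at surviving voxels.

The significant-edge graph maps |diff| linearly onto a line-width range
and classes edges by p band (p < 0.01 vs 0.01–0.05).

The concentration-ratio utility computes C_lesioned/C_intact and
100 × (1 − ratio) as percent change (positive = depletion), rounded to
whole percent for reporting.

## The synthetic cohort model

The generator emulates the acquisition and physiology the pipeline
targets; its defaults are the reference conditions used throughout the
tests.

* **Scan:** TR 2 s, 1200 volumes (40 min), 17 ROIs — seven bilateral
  pairs (AC, MC, SC, VC, HC, Str, ThVL) plus three midline structures
  (mPFC, CgC, RC).
* **State dynamics:** alternating dwell times are shifted exponentials
  with a 60 s (one-window) minimum and means 99 s (REM-like) / 78.6 s
  (NREM-like); the exponential is the maximum-entropy law for a
  positive duration with fixed mean, and the shift guarantees every run
  contains at least one analysis window. A configurable fraction of
  subjects never transitions (default 0 in the analysis-cohort
  defaults; roughly half of real recordings lack transitions, and such
  subjects are exactly what the inclusion rules remove).
* **Covariance:** per state, ROI samples are multivariate normal with a
  correlation matrix built from a latent-factor model (a shared
  cortical factor, one factor per hemisphere, one homotopic factor per
  bilateral pair), which is positive definite by construction. The
  loadings give ~0.45 same-side thalamocortical and
  striato/hippocampo-cortical correlations in the REM-like state
  against ~0.25–0.30 in NREM, and ~0.60 homotopic / ~0.30 heterotopic
  interhemispheric corticocortical correlations in NREM against
  ~0.45 / ~0.22 in REM. An AR(1) filter (coefficient 0.3, innovations
  scaled by √(1−φ²) so the stationary within-state correlation is
  preserved) adds temporal smoothness; the downstream bandpass dominates
  the spectrum, so no hemodynamic convolution is modeled.
* **Lesion effects:** deltas are subtracted from the control REM
  correlation entries (defaults: five edges, 0.30–0.41). If the result
  loses positive definiteness it is projected to the nearest
  correlation matrix, and generation aborts if the projection moves any
  entry by more than 0.01, keeping planted effects interpretable.
  Validity is asserted at configuration time.
* **Respiration:** a sinusoid whose instantaneous rate tracks the state
  (128 vs 100 breaths/min, near reported urethane physiology), plus a
  per-subject rate offset (SD 4 bpm), slow within-scan wander (SD
  2 bpm), amplitude modulation and additive noise, sampled at 50 Hz.
  The within-state rates are stated assumptions — real recordings
  report overall means, not per-state values — so only the high/low
  ordering, not the absolute rates, should be read as data-like.
* **Motion:** six independent smoothed Gaussian random walks scaled to
  SD 0.05 (sub-voxel translations / sub-degree rotations). They are
  nuisance regressors downstream; no motion is applied to images.
* **Voxel fixtures:** each voxel carries its ROI's latent series plus
  independent Gaussian noise (default SD 0.5); code-0 voxels are pure
  noise. Grids are kept small (tens of voxels per side).

**What passing tests show — and what they do not.** The synthetic data
are Gaussian, stationary within state, and noise-free at the ROI level;
real BOLD has hemodynamic autocorrelation, drift, motion artifacts
coupled to the signal, and imperfect atlas registration, none of which
are modeled. Recovery of planted effects here demonstrates the
*statistical machinery* (labeling, windowing, residualization,
z-averaging, FDR) is correct and adequately powered at the stated
design (8 vs 8, deltas ≥ 0.3); it does not certify sensitivity on real
recordings, where effective dof within windows are lower and nuisance
structure is richer.

## Numerical choices and degenerate inputs

* Bandpassed window correlations occasionally reach |r| = 1 only in
  contrived noise-free fixtures; the clip at 0.999999 (z ≈ 7.25) keeps
  the transform finite and is warned about.
* Rank-deficient nuisance designs are handled by least squares
  (`lstsq`), which projects onto the span; dependent columns change
  nothing and trigger a warning.
* The 1-D two-means split breaks ties toward the lower threshold
  (first minimizing split in sorted order); run-merging absorbs the
  shortest offending run first, preferring the longer neighbor.
* Empty masks, empty significant sets and single-state label vectors
  are valid inputs that produce empty (not error) outputs; genuinely
  malformed inputs (wrong column counts, unknown ROI codes, flat
  respiration) raise with the offending file, line or label named.

## Problem sizes used in the checks

The Monte-Carlo suites use cohorts of 8 + 8 subjects at the full scan
length (1200 volumes): 50 null cohorts for FDR calibration and 20
effect cohorts for recovery in the test suite; the acceptance script
uses 20 and 10. Dwell-time statistics use 2000–3000 simulated label
sequences; law-of-large-numbers covariance checks use a single 10^5-
volume series. These sizes put the Monte-Carlo error comfortably inside
the asserted margins while keeping a full run in the low minutes on one
core.

## Known limitations

* The labeling stand-in is a global two-cluster rule; drifting baseline
  rates within one state could defeat it where a human rater would not.
  Hand-edited label files are accepted downstream for exactly this
  case.
* No slice-timing, realignment or coregistration: the pipeline consumes
  already-realigned data plus motion parameters.
* No mixed-effects models, cluster-extent correction, network-based
  statistics or graph metrics; inference is strictly edgewise/voxelwise
  with BH-FDR.
* The generator's voxel fixtures use contiguous rectangular ROI blocks
  and an identity affine; they exercise the code paths, not anatomical
  realism.
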