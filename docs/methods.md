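# Methods

## The problem

When a visual stimulus is shown to one eye only, can the eye-of-origin be
read out — from cortical activity, and behaviorally by the observer?  In
primary visual cortex, neurons preferring the left or right eye are
organized into ocular dominance (OD) columns roughly 0.8 mm wide.  An fMRI
voxel of 1.5 mm cannot resolve single columns, but because the voxel grid
samples the columnar mosaic unevenly, each voxel inherits a small, stable
bias toward one eye.  A multivoxel pattern classifier can pool hundreds of
such biases into reliable eye-of-origin decoding, even though no single
voxel is informative and the mean regional signal carries almost nothing.
This package implements that full chain — a forward simulation of the
columnar sheet and its voxel sampling, the decoding procedure, permutation
inference, and the signal-detection analysis of the matching behavioral
task (utrocular discrimination: "which eye saw it?") — so that every stage
can be validated against ground truth.

## Forward model of the cortical sheet

The sheet is a flattened 2D patch (default 24 × 24 mm at 0.15 mm/pixel).

**Ocular dominance map.**  White Gaussian noise is band-pass filtered with
a log-Gaussian annulus (width 0.25 octaves) centered on spatial frequency
`1/od_period_mm` (default period 1.6 mm, i.e. two 0.8 mm columns), then
passed through `tanh(sharpness · x)`.  The DC term is zeroed, so the map
has exactly zero mean before saturation and near-zero mean after; values
lie in [−1, +1] (+1 fully left-eye).  `sharpness` (default 3.0) sets how
binary the columns are.  The radially averaged power spectrum peaks at the
columnar frequency within half an octave; this is asserted by tests over
many seeds.  This generation scheme is a standard minimal model for
stripe-like columnar layouts with a controlled period; nothing in it is
fit to data.

**Spatial-frequency preference map.**  `sf_pref ∈ [0, 1]` mixes a field
derived from `1 − |ocularity|` with independent band-passed noise, with
mixing weight `coupling_rho`.  At `rho = 1`, low-sf preference sits exactly
at OD column centers (where `|ocularity|` is high); at `rho = 0` the maps
are independent; the correlation between `1 − sf_pref` and `|ocularity|`
rises monotonically with `rho` in expectation.  This implements the
hypothesis that low-spatial-frequency domains coincide with OD column
centers, which is what makes the eye signal spatial-frequency specific.

**Response model.**  For stimulus (eye `e`, spatial frequency `s` on the
[0, 1] preference axis; the low and high gratings map to 0 and 1):

    response = base_gain · exp(−(s − sf_pref)² / (2·width²))
               · (1 + eye_selectivity · sign(e) · ocularity)
               + left_eye_offset_delta · [e = L]

with `sign(L) = +1`.  The multiplicative structure is the crux: the eye
modulation only matters where the sf tuning term is large, so with coupled
maps a low-sf stimulus drives exactly the territory with strong eye
preference, whereas a high-sf stimulus drives column borders where eye
preference is weak.  The additive left-eye offset models a small global
mean-signal advantage for one eye, deliberately separate from the pattern
signal (pattern correlation is invariant to it; univariate decoding sees
it).  `eye_selectivity` is constrained to [0, 1] so responses stay
non-negative.

**Voxel sampling.**  Each voxel (default 1.5 mm isotropic) averages the
sheet pixels in its footprint; the voxel image is then smoothed with a
Gaussian kernel (default FWHM 4 mm).  The order matters and is deliberate:
box-averaging a 1.6 mm-period pattern at a 1.5 mm pitch aliases the
columnar signal down to very low spatial frequencies, which survive the
subsequent smoothing — the "biased sampling" mechanism that makes
millimetre-scale decoding of sub-millimetre structure possible.  Smoothing
the *sheet* first would instead annihilate the columnar signal entirely.

**Runs.**  Each run starts with 19.2 s of fixation, then shows each of the
four conditions (eye × sf) once for 19.2 s (6 volumes at TR 3.2 s) in a
pseudo-random order, each followed by 19.2 s fixation — 54 volumes per
run, 12 runs per subject.  Block regressors are convolved with a canonical
double-gamma HRF (peak 6 s, undershoot 16 s, unit plateau); a pure boxcar
mode exists for exact algebraic tests.  Noise is per-voxel stationary
AR(1) Gaussian (marginal SD `noise_sd`, coefficient `ar1_phi`),
independent across voxels; spatially correlated noise is out of scope.

**Effect-size defaults.**  No quantitative voxel-level eye-bias effect
size is available to copy, so the defaults (`sharpness 3.0`,
`sf_tuning_width 0.3`, `eye_selectivity 0.8`, `noise_sd 0.3`,
`ar1_phi 0.3`, `coupling_rho 0.9`) were chosen once so the simulation
reproduces the qualitative regime of interest — low-sf eye decoding
clearly above chance (≈ 0.85 mean accuracy), high-sf near chance
(≈ 0.55), low > high in the large majority of subjects.  They are tunable
generator knobs, not estimates of cortical physiology, and all calibration
claims in the tests hold at these defaults.

## Preprocessing

Each voxel's time course is z-scored over the full run (population-SD
denominator; zero-variance voxels map to zeros).  The population-vs-sample
SD choice is immaterial to correlation-based decoding but is fixed for
bit-exact tests.  Per-voxel normalization is the default reading of
"normalize the run time course"; a per-volume (across-voxel) alternative
exists as an option with no fidelity claim.  Blocks are located from the
volume labels (the design is known; no onset estimation), the averaging
window is shifted forward by `lag_volumes` (default 1 volume = 3.2 s) to
absorb the hemodynamic lag, volumes shifted past the run end are dropped,
and each block's volumes are averaged into one pattern sample.

## Decoding

For a binary problem (e.g. left vs right eye at low sf), leave-one-run-out
cross-validation: 12 folds, 2 test samples each.  Within each fold,
**using training runs only**:

1. *Voxel selection.*  Pattern classifier: rank voxels by the absolute
   pooled-variance two-sample T between the two conditions, keep the top
   `n_voxels_cutoff` (default 100).  Zero-variance voxels follow a fixed
   convention (zero difference → |T| = 0, ranked last; nonzero difference
   → |T| = ∞, ranked first).  Univariate classifier: rank by mean response
   (the "most visually responsive" voxels).  Ties break deterministically
   to the lowest voxel index.
2. *Templates.*  Per-condition mean of the training samples over the
   selected voxels.
3. *Classification.*  Pattern: Pearson correlation of the test sample with
   each template; larger r wins ("linear correlation", so Pearson, not
   rank-based).  Univariate: samples and templates reduced to their mean
   across selected voxels; nearer scalar wins.  Exact ties resolve to the
   first condition in canonical order and are flagged.

Accuracy is the mean over folds of the fold's proportion correct.
Re-running selection inside every fold is what prevents circularity; the
acceptance suite verifies on 200 signal-free simulations that accuracy
stays at chance and the permutation test rejects at its nominal rate.
When only a mean-signal summary (not decoding) is needed, responsiveness
ranking may be computed on all data; inside cross-validation it is always
training-only.

## Inference

**Permutation test.**  The null is built by flipping the two problem
labels within each run independently (2^12 labellings respect the run
structure on which the folds are built), re-running the complete pipeline
per permutation, with the add-one estimator
`p = (1 + #{null ≥ observed}) / (1 + N)` (default N = 1000; the
calibration suites use 199 to resolve p ≤ 0.05 at lower cost).  The
scheme and the Bonferroni family size (default 3, one per ROI) are
documented defaults, configurable, with no claim that they match any
particular prior analysis.

**Analytic tests.**  One-sample and paired t (sample-SD convention),
Pearson r with `t = r·√((n−2)/(1−r²))` on n−2 df, all two-tailed via the
Student-t survival function; Bonferroni multiplies by the family size and
clips at 1.  Perfect correlations report the numerical floor rather than
p = 0.

## Behavioral analysis

The out-of-scanner task presents 624 brief (350 ms) monocular trials.
The generated sequences are balanced (156 per condition) with spatial
frequency strictly alternating, which simultaneously guarantees the two
ordering rules (no condition repeats; no adjacent sf repeats within any
8-trial window) — the stricter sliding-window reading of the 8-trial rule
is adopted, and every generated sequence is validated by exhaustive scan.

Responses come from an equal-variance Gaussian observer: evidence
`x ~ N(d'_sf, 1)` on dominant-eye trials, `N(0, 1)` otherwise, response
"dominant" when `x > criterion_sf + d'_sf/2`.  Analysis treats
dominant-eye stimulation as the signal class: `d' = z(H) − z(F)`,
`c = −(z(H) + z(F))/2` (positive c = conservative about reporting the
dominant eye).  The log-linear correction (+0.5 per cell, +1 per
denominator) is always applied so extreme rates stay finite; results flag
sessions where a raw rate was exactly 0 or 1.  The default generative
parameters (`d'` low −0.13, high 0.96; criterion low 0.07, high 0.16)
place simulated observers in the regime of interest: near-blind to
eye-of-origin at low sf, clearly sensitive at high sf.  Note the
dissociation this builds in by design: cortical decoding favors *low* sf
while behavior favors *high* sf.

With balanced classes, relabeling the dominant eye while swapping the
stimulus class tokens (responses untouched) negates d' exactly; this and
the unbiased-observer identity accuracy = Φ(d'/2) are property tests.

## Study orchestration

`run_study` simulates `n_subjects` (default 8) × 3 ROIs, with coupling and
eye selectivity falling off V1 (0.9 / 0.8) → V2 (0.6 / 0.5) → V3 (0 / 0)
so that only the earlier areas carry decodable eye signal; V1 additionally
carries the small left-eye mean offset.  Per subject it decodes both
spatial frequencies with both classifiers, attaches permutation p-values
(Bonferroni family 3), runs group one-sample t-tests of accuracy against
0.5, simulates behavioral sessions both in-scanner (one trial per block,
48 trials) and out-of-scanner (624 trials) from the same observer model,
and correlates the two accuracy measures over (subject × sf) pairs.  All
randomness derives from one master seed through seed-sequence spawning;
re-running a config yields a byte-identical report carrying the config
hash.

## Problem sizes and numerical choices

The calibration suites use 200 signal-free simulated sessions with 199
permutations each, 50 subjects for the spatial-frequency contrast, and
100 sessions × 624 trials for signal-detection recovery — sizes chosen so
Monte-Carlo intervals are tight enough to detect miscalibration while the
whole suite stays desk-scale.  Degenerate inputs are handled by explicit
conventions rather than NaNs: zero-variance voxels in z-scoring map to
zeros, zero-variance test patterns are classified by the tie-break rule
and flagged, and permutation tests refuse degenerate (single-run) spaces.

## Limitations

The sheet is 2D with independent voxel noise; spatially correlated noise,
3D folded anatomy, scanner physics, motion and physiological artifacts are
not modelled, so passing calibration here does not certify behavior on
real EPI data with structured noise.  ROIs are independent simulated
patches, not a shared retinotopic model.  The univariate analysis shares
the sf-independent mean offset across spatial frequencies, so it cannot
reproduce sf-specific mean-signal effects.  Repeated-measures ANOVA-style
group analyses are out of scope.
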