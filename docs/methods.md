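# Methods

This note documents the models, the defaults and why they were chosen,
the numerical conventions, and what the synthetic generators do and do
not emulate.

## Stimuli

A stimulus is an 8.68° square of dots (density 20 dots/deg², dot size
0.05°, random black/white polarity) with a 6.45° × 4.55° oval target
region. Depth is carried by binocular disparity: each dot's disparity d
(arcmin) is applied as a symmetric ±d/2 horizontal shift of its two
half-images (positive = crossed = near). Dots are positioned in
continuous degree coordinates (origin at the stimulus center, x
rightward, y upward) and rasterized last; dots shifted past the edge
wrap horizontally so dot count and density are preserved. Depth maps are
scaled linearly so the global |max| equals the spec's maximum disparity
(5.3 arcmin; 5.4 for the in-bore variant), which leaves the map's mean
disparity a property of its shape.

Signal-in-noise rendering assigns exactly ⌊snr·n_target⌋ signal dots
chosen without replacement — an exact-count rule rather than per-dot
Bernoulli draws, which removes trial-to-trial SNR variance. Noise dots
draw disparities uniformly (continuously) from ±max disparity; surround
dots sit in the fixation plane. The fine-feature task renders two
noise-free stimuli: a reference peaking at 7.8 arcmin crossed and a
target at the reference plus an offset of 0–150 arcsec.

Phase scrambling masks the depth map with its oval first, then replaces
the Fourier phases with those of a white-noise real image. Because the
phase field of a real image is Hermitian-symmetric (DC/Nyquist phases 0
or π), the inverse transform is exactly real and the amplitude spectrum
is conserved to machine precision (tests require < 1e-9 relative). The
scrambled surface is used unmasked within the target region.

The face-like generator is a stand-in for laser-scanned head models: a
heavily low-pass-filtered noise field (Gaussian kernel, σ = min(grid)/8,
which concentrates > 90% of power below a quarter of Nyquist) plus a few
localized Gaussian features in a loosely face-like arrangement, oval
masked and normalized to unit amplitude. It reproduces the smoothness
and bounded amplitude of face depth maps, not their identity structure;
passing tests therefore validate the machinery, not face-specific
perception.

## QUEST staircases

The observer model is a Weibull on log10 intensity,
ψ(x) = γ + (1−γ−λ)(1 − exp(−10^{β(x−T)})), defaults β = 3.5, γ = 0.5
(2-AFC), λ = 0.01. The threshold parameter α is defined as the log10
intensity at the 82%-correct criterion point, with the Weibull scale T
placed accordingly; this makes the posterior mean directly the quantity
of interest (the tracked criterion intensity). The prior is Gaussian on
log10 threshold (SD 2.0) centered at the initial test value (80% SNR or
120 arcsec), on a 201-point grid spanning ±3 prior SDs. Each trial
multiplies the posterior by the outcome likelihood and renormalizes;
timeouts are scored incorrect. The recommended intensity is the
criterion point at the posterior-mean threshold, clipped to the physical
range ([0, 1] SNR; [0, 150] arcsec); intensities are handled in log10
units internally and reported linearly. The practice-phase posterior is
carried into the test phase, so the first test value derives from the
practice threshold.

A session is 6 runs (3 conditions × 2 stimulus identities, random
order), each with two staircases in strict alternation (one per stimulus
gender); the per-condition threshold is the mean of its four estimates.
Strict (rather than random) alternation was chosen for determinism.

The scanner sampling rule takes the post-clipping intensities of the
last 30 test trials and returns mean ± 1 SD. A staircase is deemed
unreliable — mapping to the 80%-SNR fallback — when the OLS slope of
those 30 values is ≥ 0.005 intensity units/trial (no asymptote) or the
95% credible interval reaches the grid floor; these thresholds
operationalize qualitative reliability criteria that have no standard
quantitative form.

## Synthetic fMRI

A run is 25 blocks of 16 s: the 6 stimulus block types (3 conditions × 2
genders) each twice, order randomized without further counterbalancing,
strictly interleaved with 13 fixation blocks and fixation-bookended.
Each stimulus block holds 8 trials (500 ms + 1500 ms) with 4 near + 4
far. At TR = 2 s this yields 200 retained volumes (205 acquired, first 5
discarded as start-up transients; the dummies are metadata, not
simulated). The default of 8 runs per synthetic subject is a
configuration choice — examples and tests use 2–4 runs to keep problem
sizes small.

Voxel signals are baseline (default 100, so amplitudes read directly as
percent signal change) + Σ_condition (boxcar ⊛ two-gamma HRF) ×
amplitude + noise. Noise is white Gaussian (σ = 1 in signal units) or
AR(1) with ρ configurable; motion nuisances are smooth random walks.
The planted pattern model gives all voxels a common baseline response
(~0.5) and spreads the conditions on a signed amplitude ladder over the
informative voxels, so pairwise separations scale with one effect-size
knob. Voxel coordinates default to a 10×10×10 grid at 2-mm pitch. Not
emulated: physiological noise, distortions, motion artifacts requiring
correction, or any retinotopic structure — so passing tests show the
analysis machinery is correct, not that it is robust to real-scanner
artifacts.

## GLM

The HRF is the canonical two-gamma difference: gamma density with mode
at the 6-s peak delay minus 1/6 of a gamma density with mode at the 16-s
undershoot delay (shape = delay/dispersion + 1, scale = dispersion),
sampled at TR over 32 s and normalized to unit peak. The design matrix
has exactly 10 columns: 3 condition regressors (genders pooled; 16-s
boxcars convolved with the HRF, truncated to run length), 6 motion
regressors, and a constant. High-pass filtering is available as a
discrete-cosine nuisance set (3 cycles/run) appended to the design — an
equivalent regression formulation of a pre-filter — and is off by
default. Fitting is OLS with an explicit rank check that names collinear
columns. Percent signal change is 100·β/β_constant per voxel, computed
before ROI averaging; ROI analyses fit the ROI-mean time course rather
than averaging voxelwise fits.

## MVPA

Patterns are individual volumes: each voxel z-scored within run over the
full run time course, labels shifted by 2 TRs (4 s) for hemodynamic
delay, and volumes inside (shifted) blocks of the two target conditions
retained with their block ids. Zero-variance voxels are dropped with a
warning (configurable to error).

RFE, per leave-one-run-out fold: 20 resamples of 80% of the training
samples are drawn ignoring block boundaries; a linear SVM (libsvm via
scikit-learn, C = 1, no per-fold tuning) is trained per resample; voxels
are ranked by |mean signed weight| across resamples (configurable to
mean of |weights|); the 5 lowest-ranked are eliminated (ties broken
toward the lower voxel id); the surviving pattern is scored on the
held-out run. Elimination stops at exactly 250 voxels (the final step is
truncated if needed); the reported accuracy is the fold mean at the stop
size.

Permutation baselines shuffle labels at block level within run, which
preserves run/block structure and class balance, and re-run the decoder
per permutation. The default decoder inside permutations is a reduced
single-ranking-pass pipeline (train once, keep the top stop-size voxels
by |weight|, refit, score) for tractability at 1000 permutations; the
exact RFE pipeline is available via a flag. The baseline summary is the
95th percentile of the null. The searchlight decodes, for every voxel,
the sphere of voxels within 6 mm (123 voxels on a 2-mm grid at interior
centers) with plain leave-one-run-out SVM.

## Statistics

The RM-ANOVA uses the classic balanced within-subject decomposition; for
arbitrary fully-within factorials, effects are obtained by
inclusion–exclusion over marginal means and each effect's error term is
its interaction with subject. Sphericity corrections are deliberately
omitted (uncorrected dfs). Paired post hoc t tests use a Bonferroni
multiplier of 3 (the three condition pairs) capped at 1; Cohen's d for
the paired contrast is t/√n. Behavioral indices are per-subject
threshold differences; the non-upright variant subtracts the mean of the
inverted and random thresholds. Pearson correlations report the
two-sided p from the t transform with df = n−2 and a Bonferroni
correction across the 10-ROI family.

## Numerical conventions and edge cases

- Grids are row-major, 0-based, row 0 at top; degenerate posteriors
  (mass underflow) raise rather than renormalize silently.
- F is defined as 0 when both the effect and error mean squares vanish
  (identical condition means with zero interaction), and the paired t is
  0 for identical vectors.
- All randomness flows through `numpy.random.Generator` objects; the
  pipeline derives per-stage generators from a global seed via
  `SeedSequence` with a CRC-based stage tag, so stages can be re-run
  independently and reruns are bit-identical.
- Problem sizes in tests and examples (runs, voxels, permutation counts,
  replicate counts) are deliberately small synthetic-scale choices;
  every count that matters to the protocol (trials, blocks, volumes,
  staircase structure, elimination schedule) is kept at full scale.

## Known limitations

- The synthetic observers are stationary Weibull responders; no
  learning, lapses beyond a constant rate, or serial dependencies.
- The planted-pattern model is linearly separable by construction;
  decoding accuracies on it say nothing about real cortical geometry.
- The permutation null at small n (as used in examples) is noisy; the
  implementation warns below 100 permutations.
- Experiment-scale effect sizes for human data are not reproduced —
  acceptance focuses on protocol arithmetic, oracle equivalence, and
  calibration properties that are valid at desk scale.
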