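# Methods

## The generative model

The simulator emulates per-subject 2D putamen ROIs from a two-group MRI
texture study. Each (group ∈ {bipolar, control}) × (side ∈ {left, right})
cell is a two-level hierarchy:

1. **Between subjects.** Subject *i*'s central intensity
   `μ_i ~ Normal(μ_subject, σ_subject)`. The within-ROI contribution to the
   between-subject variance of the *mean* feature is `σ_within²/n_pix`
   (≈ 48²/948 ≈ 2.5 squared units here), negligible against
   `σ_subject² ≈ 107²`, so `σ_subject` is set equal to the printed
   between-subject SD directly rather than deconvolved.
2. **Within ROI.** Pixel intensities are i.i.d. skew-normal with population
   mean `μ_i`, SD `σ_within` and skewness `γ`. The skew-normal is the
   minimal location–scale–shape family that encodes the small nonzero
   printed skewness (−0.11/+0.11) a Gaussian cannot. The shape is obtained
   in closed form by inverting
   `γ = ((4−π)/2)·(δb)³/(1−δ²b²)^{3/2}`, `b = √(2/π)`,
   `α = δ/√(1−δ²)`; attainable range |γ| < 0.99527. Sampling uses the
   exact delta-representation `z = δ|u| + √(1−δ²)w` with `u, w` standard
   normal — identical in law to the textbook parameterization (tests
   cross-check against `scipy.stats.skewnorm` by KS test) and fast enough
   for the Monte-Carlo suites.
3. **Quantization.** Values are rounded to integers and clipped to a 12-bit
   range (0–4095), the typical stored MRI pixel depth; absolute T2-FSE
   units are scanner-relative, so the range choice is cosmetic. Rounding
   perturbs each pixel by at most 0.5, hence the ROI mean by at most 0.5.

**Calibration.** `σ_within = (P90 − P10)/(2 z_0.9)` with
`z_0.9 = Φ⁻¹(0.9) ≈ 1.2816` uses the 10th/90th percentile spread *only*.
For |γ| ≤ 0.11 the skew-normal's 10–90 spread differs from the normal one
by well under 1%, so the normal-quantile identification is adequate, and it
deliberately leaves the 25th/75th percentiles and the RMS level
(`≈ √(μ² + σ_within²)` per subject) as out-of-sample predictions: the
acceptance run checks them without having fitted them.

**Masks.** ROI outlines are ellipses (default major/minor ratio 2.2,
putamen-like elongation) whose boundary radius is modulated by three
low-frequency cosine harmonics with random amplitude (≤ the `roughness`
parameter, default 0.1) and phase. The mask takes exactly the
`target_pixcount` grid cells with the smallest normalized radius, so the
realized count is exact; if the discretized region is not a single
8-connected component the perturbation is halved and retried, falling back
to the pure ellipse. Pixel counts per subject are drawn from the printed
count distribution, floored at 16.

**Demographics.** Sex counts are fixed exactly to the configured values;
ages are normal draws clipped to the study's 18–65 inclusion band. Both
drive only the demographic rows of the results table.

**What the generator does not emulate.** Pixels are spatially independent
by default: there is no tissue autocorrelation, no bias field, no
partial-volume effect, and no anatomy beyond the mask outline. Two
consequences matter for interpretation. First, the Katz fractal dimension
of a raster waveform depends strongly on spatial autocorrelation, so the
simulator's FD values (~2 for i.i.d. noise) are implementation-relative and
are *not* matched to the printed ~1.25; FD is validated by its exact
formula, its invariances, and the direction "smoothing lowers FD" (an
optional per-cell `smooth_weight` knob blends each pixel with its 3×3
neighbourhood mean, variance-corrected, to inject that direction). Second,
passing recovery tests show that the *feature-level statistical structure*
of the reference cohort is reproduced — they say nothing about raw-image
realism.

## Texture features

Conventions, fixed for reproducibility where ecosystems differ:

* percentiles: linear interpolation at fractional rank `1+(q/100)(n−1)`
  (the numpy `linear` method);
* skewness: uncorrected Fisher–Pearson `g₁ = m₃/m₂^{3/2}`, defined as 0
  for zero-variance samples; at n ≈ 948 the n-adjusted variant differs
  negligibly;
* most frequent value: requires integer intensities (guaranteed by the
  image model); ties break to the smallest value;
* root-sum-of-squares: the Euclidean norm `√(Σx²) = RMS·√n`. The printed
  magnitudes force this reading — e.g. 513.58·√948.12 ≈ 15.6k matches the
  printed RSS, whereas a literal sum of squares would be ~2.5×10⁸;
* Katz FD: computed on the row-major raster scan of the masked pixels,
  z-scored (population SD) for amplitude-scale invariance, vertices at
  unit abscissa spacing; `D = log₁₀(m)/(log₁₀(m)+log₁₀(d/L))`. Constant
  and strictly linear waveforms return exactly 1. The raster-scan choice
  is the largest free implementation decision (a boundary contour or
  histogram curve would be equally defensible), which is why no numeric FD
  recovery target exists.

## Statistics

* Normality screen: Shapiro–Wilk per group (3 ≤ n ≤ 5000, non-constant);
  sample skewness and excess kurtosis are reported but do not gate — the
  study lists all three without a combining rule, and the Shapiro–Wilk
  p-value is the only unambiguous binary criterion.
* Gate: t-test iff both groups have Shapiro–Wilk p > 0.05, else
  Mann–Whitney U (two-sided, normal approximation with tie correction;
  scipy's default continuity correction is kept).
* t-test: Student's pooled-variance form ("independent samples t-test"
  with no Welch qualifier); a `welch=True` flag exposes the alternative.
* 2×2 tables: chi-square without continuity correction when every
  expected count exceeds 5, else Fisher's exact two-sided test. The strict
  inequality places the boundary case (all expected exactly 5) with
  Fisher, matching the worked enumeration example; identical constant
  groups short-circuit to p = 1.
* No multiplicity correction by default; `correction="bh"` adds
  Benjamini–Hochberg adjusted p-values over the 28 feature rows.

Monte-Carlo calibration (test suite): under a null configuration the
fraction of significant feature rows across 200 replicate cohorts must sit
in 0.05 ± 0.02; with the reference calibration (left-mean separation
d ≈ 0.67 at n = 33) the gated left-mean comparison's power over 500
replicates must lie in [0.60, 0.90]. The null sweep uses ~200-pixel ROIs —
test level does not depend on ROI size — to keep the suite quick; the
power sweep keeps the printed pixel counts.

## Reporting

The z-score signature standardizes each group's feature mean against the
pooled cohort (mean and ddof-1 SD over all subjects), so
`n_A z_A + n_B z_B = 0` identically; `reference="control"` switches to
control-referenced standardization, since the choice of reference is a
presentation decision. The percentile-shift series lines up the
10/25/50/75/90 levels (the median standing at 50) per hemisphere with each
group's across-subject mean and the bipolar-minus-control difference. Both
outputs are validated by direction and invariants only: the corresponding
published figures print no axis values.

## Determinism and problem sizes

Every run is a pure function of (config, seed): a root `SeedSequence`
spawns one substream per subject-side plus one for demographics, and all
writers are deterministic, so a rerun is byte-identical. Default problem
sizes — 33 subjects per group, ~800–1100-pixel ROIs — are the reference
study's own; a full simulate→extract→compare→report run takes well under a
second, and the acceptance computation regenerates everything from scratch
at those sizes.

## Known limitations

* Subject-level heterogeneity beyond the central intensity (e.g. the
  printed between-subject SDs of skewness or of the percentiles) is not
  separately modelled; recovery targets are across-subject means.
* The printed gender p-value (0.500) is not reproduced by any standard
  two-sided test on the printed counts (chi-square ≈ 0.80, Fisher ≈ 1.0);
  the categorical test is validated against exact enumeration instead.
* DICOM ingestion is single-frame, read-only, and applies only the
  rescale slope/intercept; no windowing, no volumes.
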