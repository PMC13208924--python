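# roitex

Histogram and fractal texture analysis of grayscale regions of interest
(ROIs), built around a reproducible synthetic-cohort simulator. The package
targets the study design used in putamen texture analysis of bipolar
disorder: two matched groups of subjects, one manually delineated 2D
putamen ROI per hemisphere on T2-weighted MRI, 14 first-order texture
parameters per ROI, and distribution-gated two-sample statistics per
parameter.

Because the underlying clinical images are controlled-access, the pipeline
ships with a calibrated generator: per (group, hemisphere) cell, a
subject's central intensity is drawn from
`Normal(μ_subject, σ_subject)`, within-ROI pixel intensities are i.i.d.
skew-normal with population mean equal to the subject's central intensity,
SD `σ_within` and skewness `γ`, and the ROI pixel count follows the printed
count distribution. Calibration maps published group summaries onto these
parameters; notably `σ_within = (P90 − P10) / (2 z_0.9)` uses only the
10th/90th percentile spread, leaving the 25th/75th percentiles and the RMS
level as out-of-sample predictions.

Per ROI the package computes: pixel count; mean; median; minimum; maximum;
most frequent value; skewness `g₁ = m₃/m₂^{3/2}`; root-mean-square level
`√(Σx²/n)`; root-sum-of-squares level `√(Σx²) = RMS·√n`; the 10th, 25th,
75th and 90th percentiles (linear interpolation at rank `1+(q/100)(n−1)`);
and the Katz fractal dimension of the z-scored raster-scan waveform,
`D = log₁₀(m) / (log₁₀(m) + log₁₀(d/L))` with `m` segments, total polyline
length `L` and maximal distance `d` from the first vertex.

Group comparison follows the study's rule: both groups are screened with
the Shapiro–Wilk test (skewness and excess kurtosis are reported
alongside); if both pass at 0.05 the pooled-variance t-test is used,
otherwise the two-sided Mann–Whitney U. 2×2 tables use chi-square, or
Fisher's exact test when expected counts are small. No multiplicity
correction is applied by default (a Benjamini–Hochberg flag exists).

## Worked example

```python
from roitex import (default_config, generate_cohort,
                    feature_table_from_subjects, build_results_table)

cfg = default_config(rng_seed=1)          # reference-calibrated, 33 per group
subjects, _ = generate_cohort(cfg)        # 66 subjects, 132 ROIs
features = feature_table_from_subjects(subjects)
results = build_results_table(features)
print(results[["feature", "side", "group1_mean", "group2_mean",
               "test_used", "p_value"]].head(5).to_string(index=False))
```

prints

```
      feature  side  group1_mean  group2_mean test_used  p_value
gender_female            19.0000      18.0000      chi2   0.8041
          age            35.4848      34.7909         t   0.8048
  pixel_count  left     957.0909     721.2727         t   0.0000
         mean  left     511.6204     438.8541         t   0.0042
       median  left     512.3333     437.7576         t   0.0034
```

The bipolar group's left-putamen mean intensity (511.6) sits about 0.7
pooled SD above the control group's (438.9) and the gated t-test flags the
difference (p ≈ 0.004), while the matched demographics are, correctly, not
significant. `zscore_signature` and `percentile_shift_series` produce the
derived profiles: group z-scores per feature against the pooled cohort, and
the per-percentile bipolar-minus-control differences (uniformly positive on
the left side under this calibration — a global intensity shift).

The `examples/` scripts walk through each capability; a thin CLI mirrors
the stages (`roitex simulate|extract|compare|run`), e.g.

```sh
roitex run --seed 1 --out runs/exp1/
```

writes `manifest.csv`, the ROI/mask PNG pairs, `features.csv`,
`results.csv`, `signature.csv`, `shift.csv` and `run.log`, byte-identically
reproducible per seed.

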