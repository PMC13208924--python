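"""Standardized texture signature and percentile-shift series.

The signature re-expresses every group mean as a z-score against the
pooled cohort, so the two groups mirror each other around zero.  The
shift series lines up the percentile-family features: a uniformly
positive bipolar-minus-control difference means the whole intensity
distribution is shifted upward, not just its center.
"""

from roitex import (
    default_config,
    feature_table_from_subjects,
    generate_cohort,
    percentile_shift_series,
    zscore_signature,
)

cfg = default_config(rng_seed=1)
subjects, _ = generate_cohort(cfg)
features = feature_table_from_subjects(subjects)

sig = zscore_signature(features)
left = sig[(sig["side"] == "left") & (sig["group"] == "bipolar")]
print("bipolar z-scores, left putamen (positive = above pooled mean):")
for _, row in left.iterrows():
    print(f"  {row['feature']:>20}: {row['z']:+6.3f}")

shift = percentile_shift_series(features)
print("\npercentile shift (bipolar - control), left putamen:")
print(shift[shift["side"] == "left"][["level", "feature", "difference"]]
      .to_string(index=False))
# Every level shifting by a similar positive amount is the signature of a
# global intensity offset between the groups.
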