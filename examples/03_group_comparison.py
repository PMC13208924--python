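"""Distribution-gated two-group comparison of a simulated cohort.

Per feature, both groups are screened with the Shapiro-Wilk test; when
both pass at 0.05 the pooled-variance t-test is used, otherwise the
Mann-Whitney U.  The table mirrors the study layout: a gender row, an age
row, then 14 features x 2 hemispheres.
"""

from roitex import (
    build_results_table,
    default_config,
    feature_table_from_subjects,
    generate_cohort,
)

cfg = default_config(rng_seed=1)
subjects, _ = generate_cohort(cfg)
features = feature_table_from_subjects(subjects)
results = build_results_table(features, alpha=0.05)

cols = ["feature", "side", "group1_mean", "group2_mean", "test_used", "p_value"]
print(results[cols].to_string(index=False,
                              float_format=lambda v: f"{v:9.4f}"))
n_sig = int(results["significant"].sum())
print(f"\n{n_sig} of {len(results)} rows significant at alpha = 0.05")
# With the calibrated group separation (~0.67 SD on left mean intensity at
# n = 33) the left-side intensity features are usually, not always,
# significant: single-cohort power is around 0.75.
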