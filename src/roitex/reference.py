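"""Reference cohort summary statistics used for default calibration.

These are the published group-level summaries (mean +/- between-subject SD
per texture parameter, per hemisphere) of a 33-per-group putamen texture
study comparing bipolar-disorder patients with healthy controls on
T2-weighted MRI. They are the *input* to the generator calibration: the
simulator is configured so that a synthetic cohort reproduces these
summaries in distribution.

Only the entries the calibration consumes are carried per group/side
(central tendency, dispersion, 10th/90th percentiles, skewness, pixel
counts); the remaining printed parameters (median, 25th/75th percentile,
RMS level, ...) are deliberately *not* fed to the generator so that they
remain out-of-sample predictions a recovered cohort can be checked against.
"""

from __future__ import annotations

from .config import CohortDemographics, SummaryRow

#: Per (group, side) calibration summaries.
REFERENCE_SUMMARIES: dict[tuple[str, str], SummaryRow] = {
    ("bipolar", "left"): SummaryRow(
        mean=511.19, between_sd=106.96, p10=447.64, p90=571.89,
        skewness=-0.11, pixcount_mean=948.12, pixcount_sd=186.43,
    ),
    ("control", "left"): SummaryRow(
        mean=440.68, between_sd=102.21, p10=380.29, p90=501.51,
        skewness=0.11, pixcount_mean=790.48, pixcount_sd=287.85,
    ),
    ("bipolar", "right"): SummaryRow(
        mean=476.33, between_sd=102.04, p10=423.84, p90=529.50,
        skewness=-0.09, pixcount_mean=1083.97, pixcount_sd=204.21,
    ),
    ("control", "right"): SummaryRow(
        mean=417.19, between_sd=98.46, p10=362.74, p90=472.50,
        skewness=-0.05, pixcount_mean=800.06, pixcount_sd=253.24,
    ),
}

#: Cohort size and demographics of the reference study.
REFERENCE_DEMOGRAPHICS = CohortDemographics(
    n_per_group=33,
    female_counts={"bipolar": 19, "control": 18},
    age_mean={"bipolar": 36.42, "control": 37.42},
    age_sd={"bipolar": 12.69, "control": 13.64},
)

#: Full per-feature group means from the reference study, used by tests and
#: the acceptance script as recovery targets (not consumed by calibration
#: except for the REFERENCE_SUMMARIES subset above).
REFERENCE_FEATURE_MEANS: dict[tuple[str, str, str], float] = {
    ("bipolar", "left", "mean"): 511.19,
    ("control", "left", "mean"): 440.68,
    ("bipolar", "left", "median"): 511.92,
    ("control", "left", "median"): 440.53,
    ("bipolar", "left", "p25"): 477.92,
    ("bipolar", "left", "p75"): 545.70,
    ("bipolar", "left", "rms_level"): 513.58,
    ("bipolar", "left", "skewness"): -0.11,
    ("control", "left", "skewness"): 0.11,
    ("bipolar", "right", "mean"): 476.33,
    ("control", "right", "mean"): 417.19,
}

#: Between-subject SDs paired with REFERENCE_FEATURE_MEANS (for sampling
#: tolerances of the form 3*SD/sqrt(n)).
REFERENCE_FEATURE_SDS: dict[tuple[str, str, str], float] = {
    ("bipolar", "left", "mean"): 106.96,
    ("control", "left", "mean"): 102.21,
    ("bipolar", "left", "median"): 106.71,
    ("control", "left", "median"): 102.74,
    ("bipolar", "left", "p25"): 97.50,
    ("bipolar", "left", "p75"): 117.31,
    ("bipolar", "left", "rms_level"): 107.82,
    ("bipolar", "left", "skewness"): 0.23,
    ("control", "left", "skewness"): 0.39,
    ("bipolar", "right", "mean"): 102.04,
    ("control", "right", "mean"): 98.46,
}
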