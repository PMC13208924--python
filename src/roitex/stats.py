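"""Distribution-gated two-group comparison of texture features.

Per feature, both groups' distributions are assessed with skewness,
excess kurtosis and the Shapiro-Wilk test; the Shapiro-Wilk p-value gates
the choice between the independent-samples (pooled-variance) t-test and
the Mann-Whitney U test.  Categorical 2x2 tables use chi-square without
continuity correction when all expected counts are at least 5, otherwise
Fisher's exact test.  All tests are two-sided; no multiplicity correction
is applied by default (a Benjamini-Hochberg flag is available).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .types import FEATURE_NAMES

ALPHA_NORMALITY = 0.05


@dataclass
class NormalityReport:
    """Distribution assessment of one group's feature values."""

    n: int
    skewness: float
    excess_kurtosis: float
    shapiro_w: float
    shapiro_p: float


@dataclass
class ComparisonRow:
    """One feature's two-group comparison."""

    feature: str
    side: str
    group1_mean: float
    group1_sd: float
    group2_mean: float
    group2_sd: float
    test_used: str  # t | mwu | chi2 | fisher
    statistic: float
    p_value: float


def assess_normality(values: np.ndarray) -> NormalityReport:
    """Skewness, excess kurtosis and Shapiro-Wilk test for one sample."""
    x = np.asarray(values, dtype=np.float64)
    if not 3 <= x.size <= 5000:
        raise ValueError(f"Shapiro-Wilk requires 3 <= n <= 5000, got n={x.size}")
    if np.ptp(x) == 0.0:
        raise ValueError("degenerate (constant) sample")
    w, p = stats.shapiro(x)
    return NormalityReport(
        n=int(x.size),
        skewness=float(stats.skew(x, bias=False)),
        excess_kurtosis=float(stats.kurtosis(x, fisher=True, bias=False)),
        shapiro_w=float(w),
        shapiro_p=float(p),
    )


def select_test(report_a: NormalityReport, report_b: NormalityReport) -> str:
    """``"t"`` when both groups pass Shapiro-Wilk at 0.05, else ``"mwu"``."""
    both_normal = (
        report_a.shapiro_p > ALPHA_NORMALITY and report_b.shapiro_p > ALPHA_NORMALITY
    )
    return "t" if both_normal else "mwu"


def compare_feature(
    values_a: np.ndarray,
    values_b: np.ndarray,
    feature: str = "",
    side: str = "",
    welch: bool = False,
) -> ComparisonRow:
    """Two-group comparison with the distribution-gated test choice.

    The t branch uses Student's pooled-variance t-test by default
    (``welch=True`` switches to Welch); the nonparametric branch is the
    two-sided Mann-Whitney U with normal approximation and tie correction.
    """
    a = np.asarray(values_a, dtype=np.float64)
    b = np.asarray(values_b, dtype=np.float64)
    if a.size < 3 or b.size < 3:
        raise ValueError("each group needs at least 3 observations")
    if np.ptp(a) == 0.0 and np.ptp(b) == 0.0 and a[0] == b[0]:
        # Identical constant groups: no evidence of difference.
        test, stat, p = "t", 0.0, 1.0
    else:
        if np.ptp(a) == 0.0 or np.ptp(b) == 0.0:
            raise ValueError("degenerate (constant) group sample")
        test = select_test(assess_normality(a), assess_normality(b))
        if test == "t":
            stat, p = stats.ttest_ind(a, b, equal_var=not welch)
        else:
            stat, p = stats.mannwhitneyu(a, b, alternative="two-sided",
                                         method="asymptotic")
    return ComparisonRow(
        feature=feature,
        side=side,
        group1_mean=float(a.mean()),
        group1_sd=float(a.std(ddof=1)),
        group2_mean=float(b.mean()),
        group2_sd=float(b.std(ddof=1)),
        test_used=test,
        statistic=float(stat),
        p_value=float(min(p, 1.0)),
    )


def compare_categorical(counts: np.ndarray, feature: str = "") -> ComparisonRow:
    """2x2 categorical comparison: chi-square or Fisher's exact.

    Chi-square (no continuity correction) when every expected count
    exceeds 5, otherwise Fisher's exact two-sided test.  Row order is
    (group1, group2); the reported "mean" fields carry each group's count
    of the first category and its share in percent.
    """
    t = np.asarray(counts, dtype=np.int64)
    if t.shape != (2, 2):
        raise ValueError(f"expected a 2x2 table, got shape {t.shape}")
    if np.any(t < 0):
        raise ValueError("counts must be non-negative")
    total = t.sum()
    if total == 0:
        raise ValueError("all-zero contingency table")
    expected = np.outer(t.sum(axis=1), t.sum(axis=0)) / total
    if np.all(expected > 5.0):
        stat, p, _, _ = stats.chi2_contingency(t, correction=False)
        test = "chi2"
    else:
        stat, p = stats.fisher_exact(t, alternative="two-sided")
        test = "fisher"
    n1, n2 = t.sum(axis=1)
    return ComparisonRow(
        feature=feature,
        side="",
        group1_mean=float(t[0, 0]),
        group1_sd=float(100.0 * t[0, 0] / n1) if n1 else np.nan,
        group2_mean=float(t[1, 0]),
        group2_sd=float(100.0 * t[1, 0] / n2) if n2 else np.nan,
        test_used=test,
        statistic=float(stat),
        p_value=float(p),
    )


def benjamini_hochberg(p_values: np.ndarray) -> np.ndarray:
    """Benjamini-Hochberg adjusted p-values (monotone step-up)."""
    p = np.asarray(p_values, dtype=np.float64)
    n = p.size
    order = np.argsort(p, kind="stable")
    ranked = p[order] * n / np.arange(1, n + 1)
    adj = np.minimum.accumulate(ranked[::-1])[::-1]
    out = np.empty_like(p)
    out[order] = np.minimum(adj, 1.0)
    return out


def build_results_table(
    features: pd.DataFrame,
    alpha: float = 0.05,
    correction: str = "none",
    welch: bool = False,
) -> pd.DataFrame:
    """Full two-group results table over all features plus demographics.

    One row per feature x side (14 x 2 = 28) preceded by a gender row
    (2x2 categorical) and an age row, mirroring the study's reporting
    layout.  ``correction="bh"`` adds a Benjamini-Hochberg adjusted
    p-value column over the 28 feature rows (demographic rows excluded).
    """
    groups = sorted(features["group"].unique())
    if len(groups) != 2:
        raise ValueError(f"exactly two groups required, found {groups}")
    if correction not in ("none", "bh"):
        raise ValueError("correction must be 'none' or 'bh'")
    g1, g2 = ("bipolar", "control") if set(groups) == {"bipolar", "control"} else groups

    per_subject = features.drop_duplicates("subject_id").set_index("subject_id")
    rows: list[ComparisonRow] = []

    # Gender 2x2: rows = groups, cols = (female, male)
    counts = np.array(
        [
            [
                (per_subject["group"].eq(g) & per_subject["sex"].eq("female")).sum(),
                (per_subject["group"].eq(g) & per_subject["sex"].eq("male")).sum(),
            ]
            for g in (g1, g2)
        ]
    )
    rows.append(compare_categorical(counts, feature="gender_female"))

    ages_a = per_subject.loc[per_subject["group"] == g1, "age"].to_numpy()
    ages_b = per_subject.loc[per_subject["group"] == g2, "age"].to_numpy()
    rows.append(compare_feature(ages_a, ages_b, feature="age", welch=welch))

    for side in ("left", "right"):
        sub = features[features["side"] == side]
        a = sub[sub["group"] == g1]
        b = sub[sub["group"] == g2]
        for feat in FEATURE_NAMES:
            rows.append(
                compare_feature(
                    a[feat].to_numpy(), b[feat].to_numpy(),
                    feature=feat, side=side, welch=welch,
                )
            )

    table = pd.DataFrame([r.__dict__ for r in rows])
    table["significant"] = table["p_value"] < alpha
    if correction == "bh":
        is_feature_row = table["side"].isin(["left", "right"])
        adj = np.full(len(table), np.nan)
        adj[is_feature_row.to_numpy()] = benjamini_hochberg(
            table.loc[is_feature_row, "p_value"].to_numpy()
        )
        table["p_adjusted"] = adj
        table["significant"] = np.where(
            is_feature_row, table["p_adjusted"] < alpha, table["p_value"] < alpha
        )
    return table
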