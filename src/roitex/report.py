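"""Derived cohort-level outputs: standardized texture signature and the
percentile-shift series.

The signature expresses each group's mean of every feature x side as a
z-score against the pooled-cohort mean and SD, so the two groups' scores
balance to zero (weighted by group size) by construction.  The shift
series lines up the percentile-family features (10th, 25th, median, 75th,
90th) per hemisphere to show whether one group's whole intensity
distribution sits above the other's.
"""

from __future__ import annotations

import warnings

import numpy as np
import pandas as pd

from .types import FEATURE_NAMES

#: Percentile-family features and the distribution level each represents.
PERCENTILE_LEVELS = [
    (10, "p10"),
    (25, "p25"),
    (50, "median"),
    (75, "p75"),
    (90, "p90"),
]


def zscore_signature(
    features: pd.DataFrame, reference: str = "pooled"
) -> pd.DataFrame:
    """Group-wise standardized score per feature x side.

    ``reference="pooled"`` standardizes against the pooled-cohort mean and
    SD (both groups together); ``reference="control"`` uses the control
    group's mean and SD instead.  Features with zero reference SD are
    skipped with a warning.

    Returns a tidy frame with columns
    ``side, feature, group, group_mean, z``.
    """
    if reference not in ("pooled", "control"):
        raise ValueError("reference must be 'pooled' or 'control'")
    groups = sorted(features["group"].unique())
    if len(groups) != 2:
        raise ValueError(f"exactly two groups required, found {groups}")

    rows = []
    for side in ("left", "right"):
        sub = features[features["side"] == side]
        for feat in FEATURE_NAMES:
            values = sub[feat].to_numpy(dtype=np.float64)
            if reference == "pooled":
                ref_mean, ref_sd = values.mean(), values.std(ddof=1)
            else:
                ctrl = sub.loc[sub["group"] == "control", feat].to_numpy()
                ref_mean, ref_sd = ctrl.mean(), ctrl.std(ddof=1)
            if ref_sd == 0.0 or not np.isfinite(ref_sd):
                warnings.warn(
                    f"skipping {side}/{feat}: zero reference SD", stacklevel=2
                )
                continue
            for g in groups:
                gm = sub.loc[sub["group"] == g, feat].mean()
                rows.append(
                    {
                        "side": side,
                        "feature": feat,
                        "group": g,
                        "group_mean": float(gm),
                        "z": float((gm - ref_mean) / ref_sd),
                    }
                )
    return pd.DataFrame(rows)


def percentile_shift_series(features: pd.DataFrame) -> pd.DataFrame:
    """Across-subject mean of each percentile-family feature, per group/side.

    Returns a tidy frame with columns ``side, level, feature, <group means>,
    difference`` where ``difference`` is bipolar minus control (or the
    lexicographically first group minus the second when other labels are
    used).
    """
    groups = sorted(features["group"].unique())
    if len(groups) != 2:
        raise ValueError(f"exactly two groups required, found {groups}")
    g1, g2 = (
        ("bipolar", "control") if set(groups) == {"bipolar", "control"} else groups
    )

    rows = []
    for side in ("left", "right"):
        sub = features[features["side"] == side]
        for level, feat in PERCENTILE_LEVELS:
            m1 = float(sub.loc[sub["group"] == g1, feat].mean())
            m2 = float(sub.loc[sub["group"] == g2, feat].mean())
            rows.append(
                {
                    "side": side,
                    "level": level,
                    "feature": feat,
                    f"{g1}_mean": m1,
                    f"{g2}_mean": m2,
                    "difference": m1 - m2,
                }
            )
    return pd.DataFrame(rows)


def plot_signature(signature: pd.DataFrame, path) -> None:
    """Optional SVG bar chart of the z-score signature (one panel per side)."""
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    groups = sorted(signature["group"].unique())
    fig, axes = plt.subplots(1, 2, figsize=(12, 4), sharey=True)
    for ax, side in zip(axes, ("left", "right")):
        sub = signature[signature["side"] == side]
        feats = [f for f in FEATURE_NAMES if f in set(sub["feature"])]
        x = np.arange(len(feats))
        for k, g in enumerate(groups):
            z = [
                float(sub[(sub["feature"] == f) & (sub["group"] == g)]["z"].iloc[0])
                for f in feats
            ]
            ax.bar(x + (k - 0.5) * 0.38, z, width=0.36, label=g)
        ax.set_xticks(x)
        ax.set_xticklabels(feats, rotation=75, fontsize=7)
        ax.axhline(0.0, color="k", lw=0.6)
        ax.set_title(f"{side} putamen")
    axes[0].set_ylabel("z-score vs pooled cohort")
    axes[0].legend(frameon=False, fontsize=8)
    fig.tight_layout()
    fig.savefig(path, metadata={"Date": None})
    plt.close(fig)


def plot_shift_series(shift: pd.DataFrame, path) -> None:
    """Optional SVG line plot of the percentile-shift series."""
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    group_cols = [c for c in shift.columns if c.endswith("_mean")]
    fig, axes = plt.subplots(1, 2, figsize=(9, 4), sharey=True)
    for ax, side in zip(axes, ("left", "right")):
        sub = shift[shift["side"] == side]
        for col in group_cols:
            ax.plot(sub["level"], sub[col], marker="o", label=col[:-5])
        ax.set_xlabel("percentile level")
        ax.set_title(f"{side} putamen")
    axes[0].set_ylabel("mean intensity (signal units)")
    axes[0].legend(frameon=False, fontsize=8)
    fig.tight_layout()
    fig.savefig(path, metadata={"Date": None})
    plt.close(fig)
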