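"""Generator configuration and its calibration from printed group summaries.

The simulator is a two-level hierarchical model per (group, side):

* a subject's central intensity is Normal(``mu_subject``, ``sigma_subject``);
* within-ROI pixel intensities are i.i.d. skew-normal with population mean
  equal to the subject's central intensity, population SD ``sigma_within``
  and population skewness ``gamma_within``;
* the ROI pixel count is Normal(``pixcount_mean``, ``pixcount_sd``),
  rounded and floored at a small minimum.

Calibration maps a printed summary row (group mean, between-subject SD,
10th/90th percentile means, mean skewness, pixel-count mean/SD) onto these
parameters.  The within-ROI spread is identified from the 10th-90th
percentile distance alone via the normal quantile relation
``sigma_within = (p90 - p10) / (2 * z_0.9)``, which leaves the 25th/75th
percentiles and the RMS level as out-of-sample predictions of the model.
"""

from __future__ import annotations

from dataclasses import asdict, dataclass, field
from pathlib import Path
from typing import Mapping

import numpy as np
import yaml
from scipy import stats

from .types import GROUPS, SIDES

#: Largest population skewness attainable by the skew-normal family.
MAX_SKEWNORM_SKEWNESS = float(
    0.5 * (4.0 - np.pi) * (2.0 / np.pi) ** 1.5 / (1.0 - 2.0 / np.pi) ** 1.5
)  # ~0.99527

#: Standard-normal 90% quantile used by the percentile-spread calibration.
Z90 = float(stats.norm.ppf(0.9))


@dataclass
class SummaryRow:
    """One printed (group, side) summary row consumed by calibration."""

    mean: float
    between_sd: float
    p10: float
    p90: float
    skewness: float
    pixcount_mean: float
    pixcount_sd: float


@dataclass
class CohortDemographics:
    n_per_group: int
    female_counts: dict[str, int]
    age_mean: dict[str, float]
    age_sd: dict[str, float]


@dataclass
class GroupSideParams:
    """Distributional parameters for one (group, side) cell.

    ``smooth_weight`` in [0, 1) optionally blends each pixel with its 3x3
    neighbourhood mean before masking, injecting spatial autocorrelation
    (lower waveform complexity); 0 disables it.
    """

    mu_subject: float
    sigma_subject: float
    sigma_within: float
    gamma_within: float
    pixcount_mean: float
    pixcount_sd: float
    smooth_weight: float = 0.0

    def validate(self) -> None:
        if self.sigma_subject <= 0:
            raise ValueError("sigma_subject must be > 0")
        if self.sigma_within <= 0:
            raise ValueError("sigma_within must be > 0")
        if self.pixcount_mean <= 0:
            raise ValueError("pixcount_mean must be > 0")
        if self.pixcount_sd < 0:
            raise ValueError("pixcount_sd must be >= 0")
        if abs(self.gamma_within) >= MAX_SKEWNORM_SKEWNESS:
            raise ValueError(
                f"|gamma_within| = {abs(self.gamma_within):.4f} outside the "
                f"attainable skew-normal range (< {MAX_SKEWNORM_SKEWNESS:.4f})"
            )
        if not 0.0 <= self.smooth_weight < 1.0:
            raise ValueError("smooth_weight must be in [0, 1)")


@dataclass
class GroupParams:
    female_count: int
    age_mean: float
    age_sd: float
    sides: dict[str, GroupSideParams]

    def validate(self, n_per_group: int) -> None:
        if not 0 <= self.female_count <= n_per_group:
            raise ValueError("female_count must be in [0, n_per_group]")
        if self.age_sd < 0:
            raise ValueError("age_sd must be >= 0")
        missing = set(SIDES) - set(self.sides)
        if missing:
            raise ValueError(f"missing side parameters: {sorted(missing)}")
        for p in self.sides.values():
            p.validate()


@dataclass
class GeneratorConfig:
    """Full configuration of the synthetic-cohort generator."""

    groups: dict[str, GroupParams]
    n_per_group: int = 33
    intensity_quantization: int = 4096  # 12-bit stored pixel depth
    rng_seed: int = 0
    mask_axes_ratio: float = 2.2  # putamen-like elongation
    mask_roughness: float = 0.1

    def validate(self) -> None:
        if self.n_per_group < 2:
            raise ValueError("n_per_group must be >= 2")
        if self.intensity_quantization < 2:
            raise ValueError("intensity_quantization must be >= 2")
        if self.mask_axes_ratio < 1.0:
            raise ValueError("mask_axes_ratio must be >= 1")
        if not 0.0 <= self.mask_roughness < 0.5:
            raise ValueError("mask_roughness must be in [0, 0.5)")
        missing = set(GROUPS) - set(self.groups)
        if missing:
            raise ValueError(f"missing group parameters: {sorted(missing)}")
        for g in self.groups.values():
            g.validate(self.n_per_group)

    # -- serialization -----------------------------------------------------

    def to_dict(self) -> dict:
        return asdict(self)

    @classmethod
    def from_dict(cls, d: Mapping) -> "GeneratorConfig":
        groups = {
            gname: GroupParams(
                female_count=int(g["female_count"]),
                age_mean=float(g["age_mean"]),
                age_sd=float(g["age_sd"]),
                sides={
                    sname: GroupSideParams(**{k: float(v) for k, v in s.items()})
                    for sname, s in g["sides"].items()
                },
            )
            for gname, g in d["groups"].items()
        }
        cfg = cls(
            groups=groups,
            n_per_group=int(d.get("n_per_group", 33)),
            intensity_quantization=int(d.get("intensity_quantization", 4096)),
            rng_seed=int(d.get("rng_seed", 0)),
            mask_axes_ratio=float(d.get("mask_axes_ratio", 2.2)),
            mask_roughness=float(d.get("mask_roughness", 0.1)),
        )
        return cfg


def load_config(path: str | Path) -> GeneratorConfig:
    """Load and validate a YAML generator configuration."""
    with open(path) as fh:
        d = yaml.safe_load(fh)
    if not isinstance(d, dict):
        raise ValueError(f"config file {path} does not contain a mapping")
    cfg = GeneratorConfig.from_dict(d)
    cfg.validate()
    return cfg


def save_config(cfg: GeneratorConfig, path: str | Path) -> None:
    cfg.validate()
    with open(path, "w") as fh:
        yaml.safe_dump(cfg.to_dict(), fh, sort_keys=True)


def sigma_within_from_percentiles(p10: float, p90: float) -> float:
    """Within-ROI SD implied by the 10th-90th percentile distance.

    Uses the normal-quantile relation p90 - p10 = 2 * z_0.9 * sigma.
    """
    if p90 <= p10:
        raise ValueError(f"p90 ({p90}) must exceed p10 ({p10})")
    return (p90 - p10) / (2.0 * Z90)


def calibrate_group_side(row: SummaryRow) -> GroupSideParams:
    """Map one printed summary row to generator parameters for that cell."""
    params = GroupSideParams(
        mu_subject=row.mean,
        sigma_subject=row.between_sd,
        sigma_within=sigma_within_from_percentiles(row.p10, row.p90),
        gamma_within=row.skewness,
        pixcount_mean=row.pixcount_mean,
        pixcount_sd=row.pixcount_sd,
    )
    params.validate()
    return params


def calibrate_config_from_table(
    rows: Mapping[tuple[str, str], SummaryRow],
    demographics: CohortDemographics,
    rng_seed: int = 0,
) -> GeneratorConfig:
    """Build a full generator configuration from printed group summaries.

    Parameters
    ----------
    rows
        Mapping (group, side) -> SummaryRow for every group in
        ``{"bipolar", "control"}`` and side in ``{"left", "right"}``.
    demographics
        Cohort size, per-group female counts and age distributions.
    rng_seed
        Seed stored in the configuration.
    """
    groups: dict[str, GroupParams] = {}
    for gname in GROUPS:
        sides = {}
        for sname in SIDES:
            if (gname, sname) not in rows:
                raise ValueError(f"missing summary row for ({gname}, {sname})")
            sides[sname] = calibrate_group_side(rows[(gname, sname)])
        groups[gname] = GroupParams(
            female_count=demographics.female_counts[gname],
            age_mean=demographics.age_mean[gname],
            age_sd=demographics.age_sd[gname],
            sides=sides,
        )
    cfg = GeneratorConfig(
        groups=groups, n_per_group=demographics.n_per_group, rng_seed=rng_seed
    )
    cfg.validate()
    return cfg


def default_config(rng_seed: int = 0) -> GeneratorConfig:
    """The reference-calibrated configuration (33 subjects per group)."""
    from .reference import REFERENCE_DEMOGRAPHICS, REFERENCE_SUMMARIES

    return calibrate_config_from_table(
        REFERENCE_SUMMARIES, REFERENCE_DEMOGRAPHICS, rng_seed=rng_seed
    )
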