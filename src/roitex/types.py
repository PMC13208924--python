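"""Core domain containers: one masked ROI, one subject, one feature set.

Intensities are stored as non-negative integers in arbitrary signal units
(T2-weighted FSE units are scanner-relative); the mask is a boolean grid of
the same shape selecting the pixels that belong to the structure.
"""

from __future__ import annotations

from dataclasses import dataclass, field, fields

import numpy as np

SIDES = ("left", "right")
GROUPS = ("bipolar", "control")

#: Names of the 14 per-ROI texture parameters, in reporting order.
FEATURE_NAMES = (
    "pixel_count",
    "mean",
    "median",
    "minimum",
    "maximum",
    "most_frequent_value",
    "skewness",
    "rms_level",
    "rss_level",
    "p10",
    "p25",
    "p75",
    "p90",
    "katz_fd",
)


@dataclass
class ROIImage:
    """A 2D intensity grid plus a same-shape boolean mask for one putamen.

    Parameters
    ----------
    pixels
        2D array of non-negative integer intensities (signal units).
    mask
        2D boolean array, same shape as ``pixels``; True marks ROI pixels.
    side
        ``"left"`` or ``"right"``.
    pixel_spacing
        In-plane pixel size in mm; informational only.
    """

    pixels: np.ndarray
    mask: np.ndarray
    side: str = "left"
    pixel_spacing: float = 1.0

    def __post_init__(self) -> None:
        self.pixels = np.asarray(self.pixels)
        self.mask = np.asarray(self.mask, dtype=bool)
        if self.pixels.ndim != 2:
            raise ValueError(f"pixels must be 2D, got shape {self.pixels.shape}")
        if self.mask.shape != self.pixels.shape:
            raise ValueError(
                f"mask shape {self.mask.shape} != pixel shape {self.pixels.shape}"
            )
        if not self.mask.any():
            raise ValueError("mask must select at least one pixel")
        if np.any(self.pixels < 0):
            raise ValueError("intensities must be non-negative")
        if self.side not in SIDES:
            raise ValueError(f"side must be one of {SIDES}, got {self.side!r}")

    @property
    def pixel_count(self) -> int:
        return int(self.mask.sum())


@dataclass
class SubjectRecord:
    """One simulated participant: group label, demographics, both ROIs."""

    subject_id: str
    group: str
    sex: str
    age: float
    roi_left: ROIImage
    roi_right: ROIImage

    def __post_init__(self) -> None:
        if self.group not in GROUPS:
            raise ValueError(f"group must be one of {GROUPS}, got {self.group!r}")
        if self.sex not in ("female", "male"):
            raise ValueError(f"sex must be female|male, got {self.sex!r}")

    def roi(self, side: str) -> ROIImage:
        return self.roi_left if side == "left" else self.roi_right


@dataclass
class TextureFeatureSet:
    """The 14 first-order / fractal texture parameters of one masked ROI."""

    pixel_count: int
    mean: float
    median: float
    minimum: float
    maximum: float
    most_frequent_value: float
    skewness: float
    rms_level: float
    rss_level: float
    p10: float
    p25: float
    p75: float
    p90: float
    katz_fd: float

    def as_dict(self) -> dict[str, float]:
        return {f.name: getattr(self, f.name) for f in fields(self)}
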