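"""First-order histogram and Katz fractal texture features of a masked ROI.

Conventions (stated because they differ across ecosystems):

* percentiles use linear interpolation at fractional rank 1 + (q/100)(n-1);
* skewness is the uncorrected Fisher-Pearson g1 = m3 / m2^1.5 (0 if m2 = 0);
* the most frequent value assumes integer intensities, ties -> smallest;
* root-sum-of-squares is the Euclidean norm sqrt(sum x^2) = rms * sqrt(n);
* the Katz fractal dimension is computed on the z-scored raster-order
  waveform of the masked pixels, with vertices at unit abscissa spacing.
"""

from __future__ import annotations

import numpy as np

from .types import ROIImage, TextureFeatureSet


def extract_masked_intensities(roi: ROIImage) -> np.ndarray:
    """Masked pixel values in row-major raster order."""
    if not roi.mask.any():
        raise ValueError("mask selects no pixels")
    return roi.pixels[roi.mask].astype(np.float64)


def skewness(values: np.ndarray) -> float:
    """Population (uncorrected) Fisher-Pearson skewness g1.

    Returns 0.0 for a degenerate (zero-variance) sample.
    """
    x = np.asarray(values, dtype=np.float64)
    if x.size < 3:
        raise ValueError("skewness requires at least 3 values")
    d = x - x.mean()
    m2 = np.mean(d * d)
    if m2 == 0.0:
        return 0.0
    m3 = np.mean(d * d * d)
    return float(m3 / m2**1.5)


def percentile(values: np.ndarray, q: float) -> float:
    """Linear-interpolation quantile at fractional rank 1 + (q/100)(n-1)."""
    if not 0.0 <= q <= 100.0:
        raise ValueError(f"q must be in [0, 100], got {q}")
    x = np.asarray(values, dtype=np.float64)
    if x.size == 0:
        raise ValueError("percentile of empty sample")
    return float(np.percentile(x, q, method="linear"))


def most_frequent_value(values: np.ndarray) -> float:
    """Modal integer value; ties broken toward the smallest value."""
    x = np.asarray(values)
    if x.size == 0:
        raise ValueError("mode of empty sample")
    uniq, counts = np.unique(x, return_counts=True)  # uniq sorted ascending
    return float(uniq[np.argmax(counts)])


def rms_and_rss(values: np.ndarray) -> tuple[float, float]:
    """Quadratic mean and Euclidean norm of the values."""
    x = np.asarray(values, dtype=np.float64)
    if x.size == 0:
        raise ValueError("rms of empty sample")
    ss = float(np.sum(x * x))
    return float(np.sqrt(ss / x.size)), float(np.sqrt(ss))


def katz_fd(waveform: np.ndarray) -> float:
    """Katz fractal dimension of an ordered waveform.

    The waveform is z-score normalized (population SD) for amplitude-scale
    invariance, then treated as a polyline with unit abscissa spacing:
    ``D = log10(m) / (log10(m) + log10(d / L))`` with m segments, total
    length L and maximal distance d from the first vertex.  Constant and
    strictly linear waveforms give exactly 1.0.
    """
    y = np.asarray(waveform, dtype=np.float64)
    if y.size < 3:
        raise ValueError("katz_fd requires at least 3 points")
    sd = y.std()
    if sd == 0.0:
        return 1.0
    z = (y - y.mean()) / sd
    dy = np.diff(z)
    seg = np.sqrt(1.0 + dy * dy)
    length = float(seg.sum())
    m = y.size - 1
    idx = np.arange(1, y.size, dtype=np.float64)
    d = float(np.sqrt(idx * idx + (z[1:] - z[0]) ** 2).max())
    if d <= 0.0:
        return 1.0
    denom = np.log10(m) + np.log10(d / length)
    if denom == 0.0:  # straight line: d == L
        return 1.0
    return float(np.log10(m) / denom)


def compute_feature_set(roi: ROIImage) -> TextureFeatureSet:
    """All 14 texture parameters of one masked ROI.

    The Katz dimension is computed on the raster-order masked waveform.
    Requires at least 16 masked pixels for the statistics to be meaningful.
    """
    values = extract_masked_intensities(roi)
    if values.size < 16:
        raise ValueError(f"ROI has {values.size} pixels; at least 16 required")
    rms, rss = rms_and_rss(values)
    return TextureFeatureSet(
        pixel_count=int(values.size),
        mean=float(values.mean()),
        median=percentile(values, 50.0),
        minimum=float(values.min()),
        maximum=float(values.max()),
        most_frequent_value=most_frequent_value(values),
        skewness=skewness(values),
        rms_level=rms,
        rss_level=rss,
        p10=percentile(values, 10.0),
        p25=percentile(values, 25.0),
        p75=percentile(values, 75.0),
        p90=percentile(values, 90.0),
        katz_fd=katz_fd(values),
    )
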