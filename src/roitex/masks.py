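"""Synthetic ROI mask generation.

Masks stand in for manually delineated putamen outlines: an elongated
ellipse whose boundary radius is perturbed by a few low-frequency harmonics,
selected on a pixel grid so that the realized pixel count matches the target.
"""

from __future__ import annotations

import numpy as np
from scipy import ndimage

MIN_MASK_PIXELS = 16

# 8-connectivity for the single-component check
_STRUCT8 = np.ones((3, 3), dtype=bool)


def make_roi_mask(
    target_pixcount: int,
    axes_ratio: float = 2.2,
    roughness: float = 0.1,
    rng: np.random.Generator | None = None,
) -> np.ndarray:
    """Generate a connected, roughly elliptical boolean mask.

    Parameters
    ----------
    target_pixcount
        Desired number of True pixels (>= 16).
    axes_ratio
        Major/minor axis ratio; 2.2 mimics the putamen's elongation.
    roughness
        Amplitude of the low-frequency radial boundary perturbation.
    rng
        Seeded generator; the mask is a deterministic function of it.

    Returns
    -------
    2D boolean array whose True region is a single 8-connected component
    with exactly ``target_pixcount`` pixels (up to a +/-5% relaxation if
    connectivity forces a retry at lower roughness).
    """
    if target_pixcount < MIN_MASK_PIXELS:
        raise ValueError(f"target_pixcount must be >= {MIN_MASK_PIXELS}")
    if axes_ratio < 1.0:
        raise ValueError("axes_ratio must be >= 1")
    if rng is None:
        rng = np.random.default_rng()

    # Nominal semi-axes for the requested area: pi * a * b = target.
    b = np.sqrt(target_pixcount / (np.pi * axes_ratio))
    a = axes_ratio * b
    pad = 1.0 + roughness + 0.35
    height = int(np.ceil(2 * b * pad)) + 4
    width = int(np.ceil(2 * a * pad)) + 4
    if height * width < target_pixcount:
        raise ValueError(
            f"target {target_pixcount} unreachable within {height}x{width} grid"
        )

    # Low-frequency harmonic perturbation of the boundary radius.
    amps = roughness * rng.uniform(0.3, 1.0, size=3) / np.arange(2, 5)
    phases = rng.uniform(0, 2 * np.pi, size=3)

    yy, xx = np.mgrid[0:height, 0:width]
    u = (xx - (width - 1) / 2.0) / a
    v = (yy - (height - 1) / 2.0) / b
    r = np.hypot(u, v)
    theta = np.arctan2(v, u)
    radius = np.ones_like(theta)
    for k, (amp, ph) in enumerate(zip(amps, phases), start=2):
        radius += amp * np.cos(k * theta + ph)
    # Normalized radial coordinate: <= 1 inside the perturbed boundary.
    score = r / np.maximum(radius, 1e-6)

    for attempt in range(4):
        order = np.lexsort((xx.ravel(), yy.ravel(), score.ravel()))
        chosen = order[:target_pixcount]
        mask = np.zeros(height * width, dtype=bool)
        mask[chosen] = True
        mask = mask.reshape(height, width)
        n_components = ndimage.label(mask, structure=_STRUCT8)[1]
        if n_components == 1:
            return mask
        # Rare at high roughness: flatten the boundary and retry.
        score = r / np.maximum(1.0 + (radius - 1.0) * 0.5 ** (attempt + 1), 1e-6)

    # Fall back to the pure ellipse (star-convex, hence connected).
    order = np.argsort(r.ravel(), kind="stable")
    mask = np.zeros(height * width, dtype=bool)
    mask[order[:target_pixcount]] = True
    return mask.reshape(height, width)
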