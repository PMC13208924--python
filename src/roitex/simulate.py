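"""Synthetic cohort simulation.

Each subject contributes one ROI per hemisphere.  The generative model per
(group, side) cell is hierarchical:

1. subject central intensity  mu_i ~ Normal(mu_subject, sigma_subject);
2. ROI pixel count            n_i ~ round(Normal(pixcount_mean, pixcount_sd)),
   floored at the minimum mask size;
3. pixel intensities          x_ij ~ SkewNormal with population mean mu_i,
   SD sigma_within and skewness gamma_within, i.i.d. across pixels;
4. quantization: values rounded to integers and clipped to the stored range.

Skew-normal draws use the exact delta-representation
``z = delta*|u| + sqrt(1-delta^2)*w`` with u, w standard normal, which has
shape ``alpha = delta/sqrt(1-delta^2)``; location and scale are then set so
the population mean/SD hit their targets.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .config import MAX_SKEWNORM_SKEWNESS, GeneratorConfig, GroupSideParams
from .masks import MIN_MASK_PIXELS, make_roi_mask
from .types import GROUPS, SIDES, ROIImage, SubjectRecord

_B = np.sqrt(2.0 / np.pi)  # E|Z| for standard normal


def skewnorm_shape_from_skewness(gamma: float) -> float:
    """Solve the skew-normal shape ``alpha`` giving population skewness gamma.

    Inverts gamma = (4-pi)/2 * (delta*b)^3 / (1 - delta^2*b^2)^{3/2} with
    b = sqrt(2/pi) in closed form.
    """
    if abs(gamma) >= MAX_SKEWNORM_SKEWNESS:
        raise ValueError(
            f"|skewness| {abs(gamma):.4f} outside attainable range "
            f"(< {MAX_SKEWNORM_SKEWNESS:.4f})"
        )
    if gamma == 0.0:
        return 0.0
    s = np.sign(gamma) * (2.0 * abs(gamma) / (4.0 - np.pi)) ** (1.0 / 3.0)
    t = s / np.sqrt(1.0 + s * s)  # = delta * b
    delta = t / _B
    return float(delta / np.sqrt(1.0 - delta * delta))


def sample_skewnorm(
    mean: float, sd: float, gamma: float, size: int, rng: np.random.Generator
) -> np.ndarray:
    """Draw i.i.d. skew-normal values with given population mean/SD/skewness."""
    if sd <= 0:
        raise ValueError("sd must be > 0")
    alpha = skewnorm_shape_from_skewness(gamma)
    delta = alpha / np.sqrt(1.0 + alpha * alpha)
    u = np.abs(rng.standard_normal(size))
    w = rng.standard_normal(size)
    z = delta * u + np.sqrt(1.0 - delta * delta) * w
    omega = sd / np.sqrt(1.0 - (delta * _B) ** 2)
    xi = mean - omega * delta * _B
    return xi + omega * z


def _smooth_field(field: np.ndarray, weight: float) -> np.ndarray:
    """Blend each cell with its 3x3 neighbourhood mean, variance-corrected.

    The blend ``y = (1-w)x + w*m9`` over i.i.d. cells shrinks the variance by
    a known factor; the result is rescaled about its own mean to restore the
    nominal SD so the optional spatial-correlation knob does not move the
    marginal spread.
    """
    from scipy import ndimage

    m9 = ndimage.uniform_filter(field, size=3, mode="nearest")
    y = (1.0 - weight) * field + weight * m9
    var_factor = (1.0 - weight + weight / 9.0) ** 2 + 8.0 * (weight / 9.0) ** 2
    return field.mean() + (y - field.mean()) / np.sqrt(var_factor)


def sample_subject_roi(
    config: GeneratorConfig,
    group: str,
    side: str,
    rng: np.random.Generator,
) -> ROIImage:
    """Simulate one subject's ROI for the given group and hemisphere."""
    config.validate()
    params: GroupSideParams = config.groups[group].sides[side]

    central = rng.normal(params.mu_subject, params.sigma_subject)
    n_pix = int(round(rng.normal(params.pixcount_mean, params.pixcount_sd)))
    n_pix = max(n_pix, MIN_MASK_PIXELS)

    mask = make_roi_mask(
        n_pix,
        axes_ratio=config.mask_axes_ratio,
        roughness=config.mask_roughness,
        rng=rng,
    )
    field = sample_skewnorm(
        central, params.sigma_within, params.gamma_within, mask.size, rng
    ).reshape(mask.shape)
    if params.smooth_weight > 0.0:
        field = _smooth_field(field, params.smooth_weight)

    qmax = config.intensity_quantization - 1
    pixels = np.clip(np.rint(field), 0, qmax).astype(np.uint16)
    return ROIImage(pixels=pixels, mask=mask, side=side)


def generate_cohort(
    config: GeneratorConfig,
) -> tuple[list[SubjectRecord], pd.DataFrame]:
    """Generate the full two-group cohort plus its manifest.

    Returns
    -------
    subjects
        ``2 * n_per_group`` SubjectRecords, bipolar group first.
    manifest
        DataFrame with one row per (subject, side); ``image_path`` and
        ``mask_path`` columns are filled in when the cohort is written to
        disk (see :func:`roitex.io.write_cohort`).

    The whole cohort is a deterministic function of ``config.rng_seed``:
    every subject/side draws from its own spawned random substream.
    """
    config.validate()
    root_ss = np.random.SeedSequence(config.rng_seed)
    demo_rng = np.random.default_rng(root_ss.spawn(1)[0])

    subjects: list[SubjectRecord] = []
    rows = []
    prefix = {"bipolar": "bip", "control": "con"}
    for group in GROUPS:
        gp = config.groups[group]
        n = config.n_per_group
        sexes = ["female"] * gp.female_count + ["male"] * (n - gp.female_count)
        ages = np.clip(demo_rng.normal(gp.age_mean, gp.age_sd, size=n), 18.0, 65.0)
        for i in range(n):
            subject_id = f"{prefix[group]}-{i + 1:03d}"
            rois = {}
            for side in SIDES:
                sub_rng = np.random.default_rng(root_ss.spawn(1)[0])
                rois[side] = sample_subject_roi(config, group, side, sub_rng)
            rec = SubjectRecord(
                subject_id=subject_id,
                group=group,
                sex=sexes[i],
                age=float(round(ages[i], 1)),
                roi_left=rois["left"],
                roi_right=rois["right"],
            )
            subjects.append(rec)
            for side in SIDES:
                rows.append(
                    {
                        "subject_id": subject_id,
                        "group": group,
                        "sex": rec.sex,
                        "age": rec.age,
                        "side": side,
                        "image_path": "",
                        "mask_path": "",
                    }
                )
    return subjects, pd.DataFrame(rows)
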