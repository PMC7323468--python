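"""Two-point in/out-of-phase water–fat decomposition.

In a two-point Dixon acquisition water and fat signals add in the in-phase
image (IP = W + F) and cancel in the out-of-phase image (OP = W − F), so

    S_w = (IP + OP) / 2,    S_f = IP − S_w,
    fat signal fraction = S_f / (S_f + S_w).

Noise can drive individual estimates negative; they are clamped to zero so
the fat fraction stays in [0, 1].  Voxels whose total signal falls below a
small intensity-relative threshold (air/background) cannot support the
ratio and are flagged instead of silently returning 0/0.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .grids import GridMismatchError, ImageVolume

__all__ = ["FatWaterMaps", "decompose", "fraction_above", "EmptyMaskError"]


class EmptyMaskError(ValueError):
    """A fraction was requested over an empty mask."""


@dataclass
class FatWaterMaps:
    """Separated water/fat signal maps and the fat-signal-fraction map.

    `flagged` marks voxels whose total signal was too low for a meaningful
    fraction; those voxels carry fat_fraction 0 and are excluded from ROI
    means downstream.
    """

    water: ImageVolume
    fat: ImageVolume
    fat_fraction: ImageVolume
    flagged: np.ndarray


def decompose(
    in_phase: ImageVolume,
    out_of_phase: ImageVolume,
    eps_rel: float = 1e-6,
) -> FatWaterMaps:
    """Water/fat separation of an in-phase / out-of-phase image pair.

    The denominator guard is ``eps_rel`` times the 99th-percentile in-phase
    intensity; voxels at or below it are flagged.
    """
    if not in_phase.same_grid(out_of_phase):
        raise GridMismatchError("in-phase and out-of-phase images must share a grid")
    ip = np.asarray(in_phase.data, dtype=np.float64)
    op = np.asarray(out_of_phase.data, dtype=np.float64)
    water = np.maximum((ip + op) / 2.0, 0.0)
    fat = np.maximum(ip - (ip + op) / 2.0, 0.0)
    denom = water + fat
    eps = eps_rel * float(np.percentile(ip, 99)) if ip.size else 0.0
    flagged = denom <= max(eps, 0.0)
    with np.errstate(divide="ignore", invalid="ignore"):
        ff = np.where(flagged, 0.0, fat / np.where(flagged, 1.0, denom))
    ff = np.clip(ff, 0.0, 1.0)
    return FatWaterMaps(
        water=in_phase.like(water),
        fat=in_phase.like(fat),
        fat_fraction=in_phase.like(ff),
        flagged=flagged,
    )


def fraction_above(
    fat_fraction: ImageVolume,
    mask: ImageVolume | np.ndarray,
    threshold: float,
) -> float:
    """Fraction of masked voxels whose fat fraction exceeds `threshold`.

    `mask` may be a boolean array or an integer label volume (any nonzero
    label counts); it must already live on the fat-fraction grid.
    """
    if isinstance(mask, ImageVolume):
        if not fat_fraction.same_grid(mask):
            raise GridMismatchError("mask must be resampled to the fat-fraction grid")
        m = mask.data > 0
    else:
        m = np.asarray(mask) > 0
        if m.shape != fat_fraction.shape:
            raise GridMismatchError("mask shape does not match the fat-fraction grid")
    n = int(m.sum())
    if n == 0:
        raise EmptyMaskError("fraction_above over an empty mask is undefined")
    return float((fat_fraction.data[m] > threshold).sum()) / n
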