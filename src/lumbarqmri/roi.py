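"""Vertebral-level ROI definition, mask resampling, and aggregation.

Level-standardized ROIs are axial slabs bounded halfway between the
endplates of adjacent vertebrae (through the centers of the intervertebral
discs).  The six boundaries are strictly increasing axial world
coordinates: the lower edge of the S1 slab followed by the five
inter-vertebral midpoints; each slab is the half-open interval
[lower, upper), and L1 extends upward from the last boundary (its superior
face is effectively unbounded, so the top of the labeled anatomy closes
it).  Every labeled voxel is assigned to exactly one level.

Masks drawn on the high-resolution anatomical grid are carried to the
Dixon and DWI grids by nearest-neighbour assignment at the target voxel
centers — labels are preserved exactly, and resampling is idempotent.
Scalar metrics are averaged on each map's native grid (no second
interpolation); volumes are always computed on the anatomical grid.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from .grids import ImageVolume

__all__ = [
    "slice_levels",
    "resample_mask",
    "aggregate",
    "build_level_table",
    "CoverageError",
    "LEVELS",
    "MUSCLES",
    "LABELS",
]

# kept in sync with the phantom's conventions (defined here to avoid a cycle)
MUSCLES = ("multifidus", "erector_spinae")
LEVELS = ("L1", "L2", "L3", "L4", "L5", "S1")
LABELS = {"multifidus": 1, "erector_spinae": 2}

METRIC_COLUMNS = ("fat_fraction", "fa", "md", "rd", "lambda1", "lambda2", "lambda3")


class CoverageError(ValueError):
    """Source and target grids do not overlap."""


def slice_levels(volume: ImageVolume, boundaries) -> dict[str, np.ndarray]:
    """Boolean slab masks per level, keyed 'L1'..'S1'.

    `boundaries` are six strictly increasing axial world coordinates (mm);
    slabs are half-open [lower, upper), S1 lowest.  Voxels below the first
    boundary belong to no level.
    """
    b = np.asarray(boundaries, dtype=float)
    if b.ndim != 1 or b.size != 6:
        raise ValueError("expected six axial boundaries")
    if not np.all(np.diff(b) > 0):
        raise ValueError("level boundaries must be strictly increasing")
    z = volume.axis_coords(2)
    slab = np.digitize(z, b)  # 0 below S1; 1..6 = S1..L1
    out = {}
    for i, level in enumerate(LEVELS[::-1], start=1):
        zmask = slab == i
        m = np.zeros(volume.shape, dtype=bool)
        m[:, :, zmask] = True
        out[level] = m
    return out


def resample_mask(mask: ImageVolume, target: ImageVolume) -> ImageVolume:
    """Nearest-neighbour resampling of a label volume onto `target`'s grid.

    Each target voxel takes the label of the source voxel whose center is
    nearest to the target voxel center; target voxels outside the source
    field of view become 0.  Output labels are a subset of input labels.
    """
    src = mask.data
    idx = []
    inside = np.ones(1, dtype=bool)
    covered = True
    for ax in range(3):
        t = target.axis_coords(ax)
        i = np.round((t - mask.origin_mm[ax]) / mask.voxel_size_mm[ax]).astype(int)
        valid = (i >= 0) & (i < src.shape[ax])
        if not valid.any():
            raise CoverageError("target grid lies entirely outside the mask volume")
        idx.append((np.clip(i, 0, src.shape[ax] - 1), valid))
    out = src[
        np.ix_(idx[0][0], idx[1][0], idx[2][0])
    ].copy()
    # zero out voxels outside the source extent
    out[~idx[0][1], :, :] = 0
    out[:, ~idx[1][1], :] = 0
    out[:, :, ~idx[2][1]] = 0
    return ImageVolume(out, target.voxel_size_mm, target.origin_mm)


def _roi_mean(data: np.ndarray, sel: np.ndarray) -> float:
    vals = data[sel]
    vals = vals[np.isfinite(vals)]
    return float(vals.mean()) if vals.size else np.nan


def aggregate(
    subject,
    label_volume: ImageVolume,
    boundaries,
    fat_fraction: ImageVolume | None = None,
    fat_flagged: np.ndarray | None = None,
    diffusion_maps=None,
) -> pd.DataFrame:
    """Per-muscle / per-level records for one subject.

    Volumes come from the anatomical-grid label masks (voxel count × voxel
    volume); the fat fraction is averaged on its own grid over unflagged
    masked voxels; diffusion metrics are averaged on the DWI grid over
    valid masked voxels.  Empty ROIs yield NaN metrics and missing=True
    rather than silent zeros.
    """
    levels_anat = slice_levels(label_volume, boundaries)
    voxvol = label_volume.voxel_volume_mm3

    ff_labels = ff_levels = None
    if fat_fraction is not None:
        ff_labels = resample_mask(label_volume, fat_fraction)
        ff_levels = slice_levels(fat_fraction, boundaries)
    d_labels = d_levels = dmaps = None
    if diffusion_maps is not None:
        dmaps = diffusion_maps.as_dict()
        ref = diffusion_maps.fa
        d_labels = resample_mask(label_volume, ref)
        d_levels = slice_levels(ref, boundaries)

    rows = []
    for muscle in MUSCLES:
        lab = LABELS[muscle]
        for level in LEVELS:
            sel_anat = (label_volume.data == lab) & levels_anat[level]
            n_anat = int(sel_anat.sum())
            row = dict(
                subject=subject,
                muscle=muscle,
                level=level,
                volume_ml=n_anat * voxvol / 1000.0,
                missing=n_anat == 0,
            )
            for col in METRIC_COLUMNS:
                row[col] = np.nan
            if fat_fraction is not None:
                sel = (ff_labels.data == lab) & ff_levels[level]
                if fat_flagged is not None:
                    sel = sel & ~fat_flagged
                row["fat_fraction"] = _roi_mean(fat_fraction.data, sel)
                if not sel.any():
                    row["missing"] = True
            if dmaps is not None:
                sel = (d_labels.data == lab) & d_levels[level]
                for name, vol in dmaps.items():
                    row[name] = _roi_mean(vol.data, sel)
                if not sel.any():
                    row["missing"] = True
            rows.append(row)
    return pd.DataFrame(rows)


def build_level_table(per_subject_frames) -> pd.DataFrame:
    """Concatenate per-subject aggregates into one tidy level table."""
    df = pd.concat(list(per_subject_frames), ignore_index=True)
    dup = df.duplicated(subset=["subject", "muscle", "level"])
    if dup.any():
        raise ValueError("duplicate subject×muscle×level records")
    return df
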