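"""Deterministic interpolated-streamline tractography on tensor fields.

Streamlines are integrated bidirectionally from seed points with a fixed
step along the principal eigenvector of the *trilinearly interpolated*
tensor (interpolating the tensor components sidesteps the per-voxel sign
ambiguity of eigenvectors).  At every step the new eigenvector is
sign-aligned with the previous direction; a track terminates when it

* leaves the seeded mask (nearest-voxel lookup),
* turns by more than the angular threshold between successive steps, or
* reaches a point whose FA falls below a floor (noise-only tissue).

Tracks shorter than a minimum length are discarded.  Per-track metrics
include length, mean direction, and the pennation angle relative to a
reference (line-of-action) axis, by default superior–inferior.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .grids import ImageVolume, TensorField

__all__ = ["TractographyConfig", "StreamlineSet", "track", "write_trk", "TrackingError"]


class TrackingError(RuntimeError):
    """Tracking cannot proceed (e.g. non-finite tensor values)."""


@dataclass(frozen=True)
class TractographyConfig:
    angle_threshold_deg: float = 15.0
    step_mm: float = 0.75
    min_length_mm: float = 10.0
    seeds_per_voxel: int = 1
    fa_floor: float = 0.1
    max_steps: int = 5000
    max_seeds: int | None = None
    reference_axis: tuple[float, float, float] = (0.0, 0.0, 1.0)

    def __post_init__(self):
        if not 0.0 < self.angle_threshold_deg < 90.0:
            raise ValueError("angle_threshold_deg must be in (0, 90)")
        if self.step_mm <= 0:
            raise ValueError("step_mm must be positive")
        if self.min_length_mm < 0:
            raise ValueError("min_length_mm must be >= 0")
        if self.seeds_per_voxel < 1:
            raise ValueError("seeds_per_voxel must be >= 1")


@dataclass
class StreamlineSet:
    """Ordered 3D point sequences (mm, world coordinates) with per-track
    length, mean direction, and pennation angle."""

    streamlines: list
    lengths_mm: np.ndarray
    mean_directions: np.ndarray
    pennation_deg: np.ndarray
    config: TractographyConfig

    def __len__(self) -> int:
        return len(self.streamlines)

    def to_dataframe(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "track": np.arange(len(self.streamlines)),
                "length_mm": self.lengths_mm,
                "dir_x": self.mean_directions[:, 0] if len(self) else [],
                "dir_y": self.mean_directions[:, 1] if len(self) else [],
                "dir_z": self.mean_directions[:, 2] if len(self) else [],
                "pennation_deg": self.pennation_deg,
            }
        )


def _empty_set(config) -> StreamlineSet:
    return StreamlineSet(
        [], np.zeros(0), np.zeros((0, 3)), np.zeros(0), config
    )


class _Interpolator:
    """Trilinear interpolation of the 6 unique tensor components."""

    def __init__(self, field: TensorField):
        t = field.tensors
        self.comp = np.stack(
            [
                t[..., 0, 0],
                t[..., 1, 1],
                t[..., 2, 2],
                t[..., 0, 1],
                t[..., 0, 2],
                t[..., 1, 2],
            ],
            axis=-1,
        )
        self.grid = field.grid
        self.shape = np.array(field.valid.shape)

    def __call__(self, pts: np.ndarray) -> np.ndarray:
        """pts (k,3) world mm -> interpolated tensors (k,3,3)."""
        v = self.grid.world_to_voxel(pts)
        i0 = np.floor(v).astype(int)
        i0 = np.clip(i0, 0, self.shape - 2)
        f = np.clip(v - i0, 0.0, 1.0)
        out = np.zeros((len(pts), 6))
        for dx in (0, 1):
            wx = f[:, 0] if dx else 1 - f[:, 0]
            for dy in (0, 1):
                wy = f[:, 1] if dy else 1 - f[:, 1]
                for dz in (0, 1):
                    wz = f[:, 2] if dz else 1 - f[:, 2]
                    w = (wx * wy * wz)[:, None]
                    out += w * self.comp[i0[:, 0] + dx, i0[:, 1] + dy, i0[:, 2] + dz]
        t = np.empty((len(pts), 3, 3))
        t[:, 0, 0], t[:, 1, 1], t[:, 2, 2] = out[:, 0], out[:, 1], out[:, 2]
        t[:, 0, 1] = t[:, 1, 0] = out[:, 3]
        t[:, 0, 2] = t[:, 2, 0] = out[:, 4]
        t[:, 1, 2] = t[:, 2, 1] = out[:, 5]
        return t


def _principal(tensors: np.ndarray):
    """Principal eigenvector and FA of a batch of tensors."""
    evals, evecs = np.linalg.eigh(tensors)
    lam = np.clip(evals[:, ::-1], 0.0, None)
    md = lam.mean(axis=1)
    denom = (lam**2).sum(axis=1)
    num = 1.5 * ((lam - md[:, None]) ** 2).sum(axis=1)
    with np.errstate(invalid="ignore", divide="ignore"):
        fa = np.where(denom > 0, np.sqrt(num / np.where(denom > 0, denom, 1.0)), 0.0)
    v1 = evecs[:, :, -1]  # eigenvector of the largest eigenvalue
    return v1, fa


def _inside_mask(pts: np.ndarray, mask: np.ndarray, grid: ImageVolume) -> np.ndarray:
    v = np.round(grid.world_to_voxel(pts)).astype(int)
    ok = np.all((v >= 0) & (v < np.array(mask.shape)), axis=1)
    out = np.zeros(len(pts), dtype=bool)
    if ok.any():
        w = v[ok]
        out[ok] = mask[w[:, 0], w[:, 1], w[:, 2]]
    return out


def _march(seeds, dirs, interp, mask, grid, config):
    """March all seeds simultaneously in one direction.

    Returns (points array (k, max_steps+1, 3) NaN-padded, n_points (k,))."""
    k = len(seeds)
    pts = np.full((k, config.max_steps + 1, 3), np.nan)
    pts[:, 0] = seeds
    npts = np.ones(k, dtype=int)
    pos = seeds.copy()
    prev = dirs.copy()
    alive = np.ones(k, dtype=bool)
    cos_thresh = math.cos(math.radians(config.angle_threshold_deg))
    for step in range(config.max_steps):
        if not alive.any():
            break
        ai = np.nonzero(alive)[0]
        newpos = pos[ai] + config.step_mm * prev[ai]
        inside = _inside_mask(newpos, mask, grid)
        live = ai[inside]
        alive[ai[~inside]] = False
        if live.size == 0:
            continue
        t = interp(newpos[inside])
        if not np.isfinite(t).all():
            raise TrackingError("non-finite tensor values encountered while tracking")
        v1, fa = _principal(t)
        ok_fa = fa >= config.fa_floor
        alive[live[~ok_fa]] = False
        live = live[ok_fa]
        if live.size == 0:
            continue
        newpos = newpos[inside][ok_fa]
        v1 = v1[ok_fa]
        # sign-align with the incoming direction
        dots = (v1 * prev[live]).sum(axis=1)
        v1 = np.where(dots[:, None] < 0, -v1, v1)
        dots = np.abs(dots)
        # the step is taken (point added); a sharp turn terminates afterwards
        pts[live, npts[live]] = newpos
        npts[live] += 1
        pos[live] = newpos
        turn_ok = dots >= cos_thresh
        alive[live[~turn_ok]] = False
        prev[live[turn_ok]] = v1[turn_ok]
    return pts, npts


def track(
    field: TensorField,
    mask: ImageVolume | np.ndarray,
    config: TractographyConfig = TractographyConfig(),
    seed: int = 0,
) -> StreamlineSet:
    """Streamline tractography over `mask` on a tensor field.

    Seeds are placed at the centers of masked voxels with a valid tensor
    (jittered within the voxel when seeds_per_voxel > 1, under the given
    seed); each seed is integrated in both directions along the principal
    eigenvector and the halves are joined.
    """
    grid = field.grid
    if isinstance(mask, ImageVolume):
        m = mask.data > 0
        if m.shape != field.valid.shape:
            raise ValueError("mask must live on the tensor-field grid")
    else:
        m = np.asarray(mask) > 0
        if m.shape != field.valid.shape:
            raise ValueError("mask must live on the tensor-field grid")
    m = m & field.valid
    if not m.any():
        warnings.warn("tractography mask is empty; returning an empty set")
        return _empty_set(config)
    if not np.isfinite(field.tensors[m]).all():
        raise TrackingError("non-finite tensor values inside the mask")

    rng = np.random.default_rng(seed)
    ijk = np.argwhere(m)
    if config.max_seeds is not None and len(ijk) > config.max_seeds:
        keep = rng.choice(len(ijk), size=config.max_seeds, replace=False)
        keep.sort()
        ijk = ijk[keep]
    seeds = grid.voxel_to_world(ijk)
    if config.seeds_per_voxel > 1:
        reps = np.repeat(seeds, config.seeds_per_voxel, axis=0)
        jitter = rng.uniform(-0.5, 0.5, size=reps.shape) * np.array(
            field.voxel_size_mm
        )
        seeds = reps + jitter
        inside = _inside_mask(seeds, m, grid)
        seeds = seeds[inside]

    interp = _Interpolator(field)
    v0, fa0 = _principal(interp(seeds))
    good = fa0 >= config.fa_floor
    seeds, v0 = seeds[good], v0[good]
    if len(seeds) == 0:
        return _empty_set(config)

    fwd_pts, fwd_n = _march(seeds, v0, interp, m, grid, config)
    bwd_pts, bwd_n = _march(seeds, -v0, interp, m, grid, config)

    streamlines = []
    for i in range(len(seeds)):
        back = bwd_pts[i, 1 : bwd_n[i]][::-1]
        fore = fwd_pts[i, : fwd_n[i]]
        line = np.vstack([back, fore])
        if len(line) < 2:
            continue
        seg = np.diff(line, axis=0)
        length = float(np.linalg.norm(seg, axis=1).sum())
        if length < config.min_length_mm:
            continue
        streamlines.append(line)

    if not streamlines:
        return _empty_set(config)

    ref = np.asarray(config.reference_axis, dtype=float)
    ref = ref / np.linalg.norm(ref)
    lengths = np.empty(len(streamlines))
    mean_dirs = np.empty((len(streamlines), 3))
    penn = np.empty(len(streamlines))
    for i, line in enumerate(streamlines):
        seg = np.diff(line, axis=0)
        norms = np.linalg.norm(seg, axis=1)
        lengths[i] = norms.sum()
        u = (seg / norms[:, None]).mean(axis=0)
        u = u / np.linalg.norm(u)
        if u @ ref < 0:
            u = -u
        mean_dirs[i] = u
        penn[i] = math.degrees(math.acos(min(1.0, abs(float(u @ ref)))))
    return StreamlineSet(streamlines, lengths, mean_dirs, penn, config)


def write_trk(
    sset: StreamlineSet, reference: ImageVolume, path: str
) -> str:
    """Write a TrackVis .trk (version 2) file with a proper voxel-to-world
    header taken from `reference`.  Points are stored in world mm (RAS)."""
    import nibabel as nib
    from nibabel.streamlines import Tractogram
    from nibabel.streamlines.trk import TrkFile

    if len(sset) == 0:
        raise ValueError("refusing to write an empty streamline set")
    tractogram = Tractogram(
        [s.astype(np.float32) for s in sset.streamlines],
        affine_to_rasmm=np.eye(4),
    )
    header = {
        "voxel_sizes": np.asarray(reference.voxel_size_mm, dtype=np.float32),
        "dimensions": np.asarray(reference.shape, dtype=np.int16),
        "voxel_to_rasmm": reference.affine.astype(np.float32),
        "voxel_order": "RAS",
    }
    TrkFile(tractogram, header).save(str(path))
    return str(path)
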