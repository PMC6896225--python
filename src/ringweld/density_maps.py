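"""Density grids: synthesis from trajectories, symmetry averaging, RSCC.

This module works in Å (the lattice convention of EM maps); trajectory
coordinates in nm are converted at entry.  Grids are scalar fields on a
regular orthogonal lattice with an explicit origin and per-axis spacing,
stored x-fastest (``values[ix, iy, iz]``).
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Callable, Sequence

import numpy as np
from scipy.ndimage import map_coordinates

from .errors import (
    DegenerateInputError,
    FormatError,
    GeometryError,
    MaskError,
    SelectionError,
    SpecError,
)
from .model_core import NM_TO_ANGSTROM, Trajectory


def rotation_increment(order: int) -> float:
    """Rotation step, in degrees, for ``order``-fold symmetry averaging.

    For the 14-fold ring this is 360/14 ≈ 25.7°.
    """
    if order < 1:
        raise SpecError(f"symmetry order must be >= 1, got {order}")
    return 360.0 / order


@dataclass
class DensityGrid:
    """Scalar field on a regular lattice (origin/spacing in Å)."""

    origin: np.ndarray
    spacing: np.ndarray
    values: np.ndarray

    def __post_init__(self) -> None:
        self.origin = np.asarray(self.origin, dtype=np.float64)
        self.spacing = np.asarray(self.spacing, dtype=np.float64)
        self.values = np.asarray(self.values, dtype=np.float64)
        if np.any(self.spacing <= 0):
            raise SpecError(f"grid spacing must be positive, got {self.spacing}")
        if self.values.ndim != 3:
            raise SpecError("grid values must be a 3-D array")
        if not np.all(np.isfinite(self.values)):
            raise SpecError("grid values must be finite")

    @property
    def dims(self) -> tuple[int, int, int]:
        return self.values.shape

    @property
    def voxel_volume(self) -> float:
        return float(np.prod(self.spacing))

    def axes(self) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
        return tuple(
            self.origin[i] + self.spacing[i] * np.arange(self.dims[i])
            for i in range(3)
        )

    def points(self) -> np.ndarray:
        """All lattice points as an (nx, ny, nz, 3) array."""
        ax, ay, az = self.axes()
        gx, gy, gz = np.meshgrid(ax, ay, az, indexing="ij")
        return np.stack([gx, gy, gz], axis=-1)

    def center(self) -> np.ndarray:
        return self.origin + self.spacing * (np.asarray(self.dims) - 1) / 2.0

    def same_lattice(self, other: "DensityGrid | Mask") -> bool:
        return (
            self.dims == other.dims
            and np.allclose(self.origin, other.origin)
            and np.allclose(self.spacing, other.spacing)
        )

    def like(self, values: np.ndarray) -> "DensityGrid":
        return DensityGrid(self.origin.copy(), self.spacing.copy(), values)


@dataclass
class Mask:
    """Boolean companion lattice of a parent grid."""

    origin: np.ndarray
    spacing: np.ndarray
    values: np.ndarray

    def __post_init__(self) -> None:
        self.origin = np.asarray(self.origin, dtype=np.float64)
        self.spacing = np.asarray(self.spacing, dtype=np.float64)
        self.values = np.asarray(self.values, dtype=bool)

    @property
    def dims(self) -> tuple[int, int, int]:
        return self.values.shape

    @property
    def n_true(self) -> int:
        return int(self.values.sum())


# ---------------------------------------------------------------------------
# synthesis
# ---------------------------------------------------------------------------


def _mass_within(x: float) -> float:
    """Fraction of a 3-D isotropic Gaussian's mass within radius x·σ."""
    from math import erf, exp, pi, sqrt

    return erf(x / sqrt(2.0)) - sqrt(2.0 / pi) * x * exp(-0.5 * x * x)


def trajectory_to_density(
    traj: Trajectory,
    selection: np.ndarray | Callable,
    spacing: float = 1.0,
    sigma: float = 1.0,
    frame_range: tuple[int, int] | None = None,
) -> DensityGrid:
    """Time-averaged Gaussian density of selected beads (volmap-style).

    Each selected bead deposits an isotropic Gaussian truncated at 4σ and
    normalized to unit integral over the truncated support; per-frame grids
    are averaged over the frame range.  The lattice covers the trajectory box at ``spacing`` Å with the
    membrane midplane (z = 0 nm) at grid z = 0 Å.
    """
    if sigma <= 0:
        raise SpecError(f"sigma must be positive, got {sigma}")
    sel = selection(traj.structure) if callable(selection) else np.asarray(selection)
    sel = np.asarray(sel, dtype=bool)
    if sel.shape != (traj.structure.n_beads,):
        raise SelectionError("selection mask length != bead count")
    if not sel.any():
        raise SelectionError("empty bead selection")
    lo, hi = (0, traj.n_frames) if frame_range is None else frame_range
    if hi <= lo:
        raise SpecError(f"empty frame range {frame_range}")

    box = traj.boxes[lo] * NM_TO_ANGSTROM
    origin = np.array([0.0, 0.0, -box[2] / 2.0])
    dims = np.maximum(np.ceil(box / spacing).astype(int) + 1, 2)
    values = np.zeros(tuple(dims))
    sp = np.full(3, float(spacing))
    reach = int(np.ceil(4.0 * sigma / spacing))
    norm = 1.0 / ((2.0 * np.pi) ** 1.5 * sigma**3 * _mass_within(4.0))

    cut2 = (4.0 * sigma) ** 2
    for f in range(lo, hi):
        pts = traj.coords[f][sel] * NM_TO_ANGSTROM
        for p in pts:
            idx = np.round((p - origin) / sp).astype(int)
            slices, offs = [], []
            skip = False
            for d in range(3):
                i0 = max(idx[d] - reach, 0)
                i1 = min(idx[d] + reach + 1, dims[d])
                if i1 <= i0:
                    skip = True
                    break
                slices.append(slice(i0, i1))
                offs.append(origin[d] + sp[d] * np.arange(i0, i1) - p[d])
            if skip:
                continue
            d2 = (offs[0][:, None, None] ** 2 + offs[1][None, :, None] ** 2
                  + offs[2][None, None, :] ** 2)
            patch = np.where(d2 <= cut2, np.exp(-0.5 * d2 / sigma**2), 0.0)
            values[tuple(slices)] += patch * norm
    values /= hi - lo
    return DensityGrid(origin=origin, spacing=sp, values=values)


# ---------------------------------------------------------------------------
# lattice operations
# ---------------------------------------------------------------------------


def _sample_at(grid: DensityGrid, points: np.ndarray) -> np.ndarray:
    """Trilinear interpolation of ``grid`` at Cartesian ``points`` (Å);
    points outside the grid extent evaluate to 0."""
    frac = (points.reshape(-1, 3) - grid.origin) / grid.spacing
    out = map_coordinates(
        grid.values, frac.T, order=1, mode="constant", cval=0.0, prefilter=False
    )
    return out.reshape(points.shape[:-1])


def resample(grid: DensityGrid, target: "DensityGrid | Mask") -> DensityGrid:
    """Resample ``grid`` onto the lattice of ``target`` (trilinear, zero fill)."""
    if grid.same_lattice(target):
        return grid.like(grid.values.copy())
    t = DensityGrid(target.origin, target.spacing, np.zeros(target.dims))
    lo_t, hi_t = t.origin, t.origin + t.spacing * (np.asarray(t.dims) - 1)
    lo_s, hi_s = grid.origin, grid.origin + grid.spacing * (
        np.asarray(grid.dims) - 1
    )
    if np.any(hi_t < lo_s) or np.any(lo_t > hi_s):
        raise GeometryError("source and target lattices do not overlap")
    return t.like(_sample_at(grid, t.points()))


def symmetry_average(
    grid: DensityGrid,
    order: int,
    axis_point: np.ndarray | None = None,
    axis_dir: np.ndarray = (0.0, 0.0, 1.0),
) -> DensityGrid:
    """n-fold rotational average of a map about the given axis.

    The output is the mean of the map and its copies rotated by multiples of
    360°/order (trilinear resampling per rotation; zero outside the grid).
    """
    if order < 1:
        raise SpecError(f"symmetry order must be >= 1, got {order}")
    if order == 1:
        return grid.like(grid.values.copy())
    axis_dir = np.asarray(axis_dir, dtype=np.float64)
    nrm = np.linalg.norm(axis_dir)
    if nrm < 1e-12:
        raise GeometryError("axis direction must be nonzero")
    axis_dir = axis_dir / nrm
    if axis_point is None:
        axis_point = grid.center()
    axis_point = np.asarray(axis_point, dtype=np.float64)

    from scipy.spatial.transform import Rotation

    pts = grid.points()
    acc = grid.values.copy()
    step = rotation_increment(order)
    for k in range(1, order):
        # inverse mapping: sample the source at back-rotated target points
        rot = Rotation.from_rotvec(np.deg2rad(-k * step) * axis_dir)
        back = (pts - axis_point) @ rot.as_matrix().T + axis_point
        acc += _sample_at(grid, back)
    return grid.like(acc / order)


def estimate_symmetry_axis(
    grid: DensityGrid,
    order: int,
    tilt_search: float = 2.0,
    step: float = 0.5,
    axis_point: np.ndarray | None = None,
) -> tuple[np.ndarray, np.ndarray, float]:
    """Grid search for the n-fold symmetry axis near +z.

    Candidate axes pass through the density center of mass (or
    ``axis_point``) and are tilted by up to ``tilt_search`` degrees about x
    and y in increments of ``step``.  The score of an axis is the mean
    Pearson correlation between the map and its ``order - 1`` rotated
    copies; the argmax is returned as (axis_point, axis_dir, score).
    """
    if order < 2:
        raise SpecError(f"axis estimation needs order >= 2, got {order}")
    vals = grid.values
    if float(vals.std()) == 0.0:
        raise DegenerateInputError("flat (zero-variance) grid")
    if axis_point is None:
        w = vals - vals.min()
        total = w.sum()
        axis_point = (
            (grid.points() * w[..., None]).reshape(-1, 3).sum(axis=0) / total
            if total > 0
            else grid.center()
        )
    from scipy.spatial.transform import Rotation

    tilts = np.arange(-tilt_search, tilt_search + step / 2, step)
    best = (None, -np.inf)
    for tx in tilts:
        for ty in tilts:
            rot = Rotation.from_euler("xy", [tx, ty], degrees=True)
            axis_dir = rot.apply([0.0, 0.0, 1.0])
            score = _axis_score(grid, order, axis_point, axis_dir)
            if score > best[1]:
                best = (axis_dir, score)
    return np.asarray(axis_point), best[0], float(best[1])


def _axis_score(grid, order, axis_point, axis_dir) -> float:
    from scipy.spatial.transform import Rotation

    pts = grid.points()
    a = grid.values.ravel()
    scores = []
    for k in range(1, order):
        rot = Rotation.from_rotvec(
            np.deg2rad(-k * rotation_increment(order)) * np.asarray(axis_dir)
        )
        back = (pts - axis_point) @ rot.as_matrix().T + axis_point
        b = _sample_at(grid, back).ravel()
        if b.std() == 0 or a.std() == 0:
            scores.append(0.0)
        else:
            scores.append(float(np.corrcoef(a, b)[0, 1]))
    return float(np.mean(scores))


# ---------------------------------------------------------------------------
# mask and correlation
# ---------------------------------------------------------------------------


def build_mask(grid: DensityGrid, level: float) -> Mask:
    """Threshold mask: true exactly where density is strictly above ``level``."""
    if not np.isfinite(level):
        raise SpecError("mask level must be finite")
    return Mask(grid.origin.copy(), grid.spacing.copy(), grid.values > level)


def rscc(
    grid_a: DensityGrid, grid_b: DensityGrid, mask: Mask | None = None
) -> float:
    """Masked real-space correlation coefficient of two maps.

    ``grid_b`` is resampled onto the lattice of ``grid_a`` first; the RSCC
    is the Pearson correlation over masked voxels, hence invariant under
    positive affine rescaling of either map.
    """
    b = resample(grid_b, grid_a)
    if mask is None:
        sel = np.ones(grid_a.dims, dtype=bool)
    else:
        if grid_a.dims != mask.dims or not np.allclose(
            grid_a.origin, mask.origin
        ) or not np.allclose(grid_a.spacing, mask.spacing):
            raise MaskError("mask lattice incompatible with grid_a")
        sel = mask.values
    if sel.sum() < 2:
        raise MaskError(f"mask selects {int(sel.sum())} voxels, need >= 2")
    va = grid_a.values[sel]
    vb = b.values[sel]
    da = va - va.mean()
    db = vb - vb.mean()
    denom = np.sqrt((da * da).sum() * (db * db).sum())
    if denom == 0.0:
        raise DegenerateInputError("zero variance over the mask")
    return float((da * db).sum() / denom)


# ---------------------------------------------------------------------------
# MRC/CCP4 I/O (MRC2014 mode 2)
# ---------------------------------------------------------------------------


def write_map(grid: DensityGrid, path: str | Path) -> None:
    import gemmi

    nx, ny, nz = grid.dims
    g = gemmi.FloatGrid(nx, ny, nz)
    np.asarray(g.array)[...] = grid.values.astype(np.float32)
    g.set_unit_cell(
        gemmi.UnitCell(
            nx * grid.spacing[0], ny * grid.spacing[1], nz * grid.spacing[2],
            90, 90, 90,
        )
    )
    m = gemmi.Ccp4Map()
    m.grid = g
    m.update_ccp4_header()
    for word, v in zip((50, 51, 52), grid.origin):
        m.set_header_float(word, float(v))
    m.write_ccp4_map(str(path))


def read_map(path: str | Path) -> DensityGrid:
    import gemmi

    try:
        m = gemmi.read_ccp4_map(str(path))
    except (RuntimeError, ValueError) as exc:
        raise FormatError(f"cannot read map {path}: {exc}") from None
    mode = m.header_i32(4)
    if mode != 2:
        raise FormatError(f"unsupported MRC mode {mode}; only mode 2 (float32)")
    m.setup(0.0)  # normalizes axis order to X, Y, Z
    values = np.array(m.grid.array, dtype=np.float64)
    cell = m.grid.unit_cell
    dims = values.shape
    spacing = np.array([cell.a / dims[0], cell.b / dims[1], cell.c / dims[2]])
    origin = np.array([m.header_float(w) for w in (50, 51, 52)])
    return DensityGrid(origin=origin, spacing=spacing, values=values)
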