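"""Trajectory analytics around the ring interior.

The "inner volume" of a (half-)ring follows the verbal definition used for
residence-time analysis: the simple polygon through the outer-column
centroids of all protomers — including the gap between separated
half-rings — bounded in z by ``z_extent`` on either side of the protomer
midplane.  Lipids are located by their head bead; leaflets are assigned
per frame by the head z-sign relative to the midplane (loop side = +z).
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Callable, Sequence

import numpy as np
import pandas as pd

from .errors import (
    DegenerateInputError,
    GeometryError,
    SelectionError,
    TopologyError,
)
from .model_core import BeadKind, Leaflet, Structure, Trajectory

#: default half-width of the inner volume in z (nm) — the bilayer span
DEFAULT_Z_EXTENT = 2.0


@dataclass
class RingRegion:
    """In-plane polygon plus z-slab bounding the ring interior."""

    polygon: np.ndarray  # (V, 2) vertices, nm
    z_midplane: float
    z_extent: float

    def __post_init__(self) -> None:
        self.polygon = np.asarray(self.polygon, dtype=np.float64)
        if self.polygon.ndim != 2 or len(self.polygon) < 3:
            raise GeometryError("region polygon needs >= 3 vertices")


@dataclass
class ResidenceRecord:
    """One maximal interval a molecule spends inside the region."""

    molecule_index: int
    entry_time: float  # ps
    exit_time: float  # ps
    duration: float  # ps
    censored: bool  # touches a trajectory end


@dataclass
class ExtrusionEvent:
    molecule_index: int
    time: float  # ps, first frame outside
    direction: Leaflet  # leaflet at the last inside frame


@dataclass
class ContactSeries:
    """Per-frame counts of distinct solvent molecules within the cutoff of
    each site group."""

    times: np.ndarray  # (T,)
    counts: np.ndarray  # (T, G) int
    site_labels: list[str]
    cutoff: float  # Å


# ---------------------------------------------------------------------------
# geometry
# ---------------------------------------------------------------------------


def points_in_polygon(
    points: np.ndarray, polygon: np.ndarray, eps: float = 1e-9
) -> np.ndarray:
    """Vectorized even-odd point-in-polygon test; boundary counts as inside."""
    pts = np.atleast_2d(np.asarray(points, dtype=np.float64))
    poly = np.asarray(polygon, dtype=np.float64)
    x, y = pts[:, 0], pts[:, 1]
    n = len(poly)
    inside = np.zeros(len(pts), dtype=bool)
    on_edge = np.zeros(len(pts), dtype=bool)
    for k in range(n):
        x1, y1 = poly[k]
        x2, y2 = poly[(k + 1) % n]
        # boundary check: point within eps of the segment
        dx, dy = x2 - x1, y2 - y1
        L2 = dx * dx + dy * dy
        if L2 > 0:
            t = np.clip(((x - x1) * dx + (y - y1) * dy) / L2, 0.0, 1.0)
            d2 = (x - (x1 + t * dx)) ** 2 + (y - (y1 + t * dy)) ** 2
            on_edge |= d2 <= eps * eps
        # even-odd crossing of the upward ray
        cond = (y1 > y) != (y2 > y)
        with np.errstate(divide="ignore", invalid="ignore"):
            xint = x1 + (y - y1) * dx / np.where(dy == 0, np.inf, dy)
        inside ^= cond & (x < xint)
    return inside | on_edge


def ring_region(
    structure: Structure,
    coords: np.ndarray | None = None,
    z_extent: float = DEFAULT_Z_EXTENT,
) -> RingRegion:
    """Region spanned by the outer protomer columns of one frame.

    Vertices are the per-protomer outer-column centroids ("OC*"-named beads;
    all protomer beads if no such names exist), ordered by azimuth about
    their common centroid.
    """
    coords = structure.coords if coords is None else np.asarray(coords)
    prot = structure.protomer_mask
    if structure.n_protomers < 3:
        raise GeometryError("region needs >= 3 protomers")
    names = np.array([str(n) for n in structure.names])
    outer = prot & np.char.startswith(names, "OC")
    if not outer.any():
        outer = prot
    pids = structure.protomer_index[outer]
    xy = coords[outer][:, :2]
    verts = np.array([
        xy[pids == p].mean(axis=0) for p in np.unique(pids)
    ])
    centroid = verts.mean(axis=0)
    order = np.argsort(np.arctan2(*(verts - centroid).T[::-1]))
    z_mid = float(coords[prot, 2].mean())
    return RingRegion(polygon=verts[order], z_midplane=z_mid, z_extent=z_extent)


# ---------------------------------------------------------------------------
# classification and counting
# ---------------------------------------------------------------------------


def _lipid_heads(structure: Structure) -> tuple[np.ndarray, np.ndarray]:
    heads = np.flatnonzero(structure.lipid_head_mask)
    lipid_beads = np.isin(
        structure.kinds, [BeadKind.lipid_head, BeadKind.lipid_tail]
    )
    if lipid_beads.any() and not len(heads):
        raise TopologyError("lipids present but no head beads")
    mols = structure.molecule_index[heads]
    order = np.argsort(mols)
    return heads[order], mols[order]


def classify_lipids(
    structure: Structure,
    region: RingRegion,
    coords: np.ndarray | None = None,
) -> tuple[np.ndarray, np.ndarray]:
    """Per-lipid (inside, leaflet) for one frame, in molecule-index order.

    A lipid is inside iff its head (x, y) lies in the region polygon
    (boundary inclusive) and its head z is within ``z_extent`` of the
    midplane; the leaflet is the head z-sign (>= midplane -> loop side).
    """
    coords = structure.coords if coords is None else np.asarray(coords)
    heads, _ = _lipid_heads(structure)
    hxy = coords[heads][:, :2]
    hz = coords[heads][:, 2]
    inside = points_in_polygon(hxy, region.polygon) & (
        np.abs(hz - region.z_midplane) <= region.z_extent
    )
    leaflet = np.where(
        hz >= region.z_midplane, int(Leaflet.loop_side), int(Leaflet.nc_side)
    ).astype(np.int8)
    return inside, leaflet


def count_encapsulated(
    traj: Trajectory, z_extent: float = DEFAULT_Z_EXTENT
) -> pd.DataFrame:
    """Per-frame counts of encapsulated lipids by leaflet.

    Returns a frame-indexed table with columns time_ps, n_loop, n_nc,
    n_total (n_total = n_loop + n_nc by construction).
    """
    rows = []
    for i, f in enumerate(traj):
        region = ring_region(traj.structure, coords=f.coords, z_extent=z_extent)
        inside, leaflet = classify_lipids(traj.structure, region, coords=f.coords)
        n_loop = int(np.sum(inside & (leaflet == Leaflet.loop_side)))
        n_nc = int(np.sum(inside & (leaflet == Leaflet.nc_side)))
        rows.append((f.time_ps, n_loop, n_nc, n_loop + n_nc))
    return pd.DataFrame(rows, columns=["time_ps", "n_loop", "n_nc", "n_total"])


def _inside_matrix(traj: Trajectory, z_extent: float):
    """(T, n_lipids) inside flags and (T, n_lipids) leaflet codes."""
    _, mols = _lipid_heads(traj.structure)
    inside = np.zeros((traj.n_frames, len(mols)), dtype=bool)
    leaflet = np.zeros((traj.n_frames, len(mols)), dtype=np.int8)
    for i, f in enumerate(traj):
        region = ring_region(traj.structure, coords=f.coords, z_extent=z_extent)
        inside[i], leaflet[i] = classify_lipids(
            traj.structure, region, coords=f.coords
        )
    return inside, leaflet, mols


def residence_times(
    traj: Trajectory,
    z_extent: float = DEFAULT_Z_EXTENT,
    include_censored: bool = False,
) -> tuple[list[ResidenceRecord], dict]:
    """Maximal inside-intervals per lipid and a survival-style summary.

    A record's duration is (last inside frame time + Δt) - (first inside
    frame time) with Δt the local frame spacing; intervals touching either
    trajectory end are censored and excluded from the summary statistics
    unless ``include_censored`` is set.
    """
    if traj.n_frames < 2:
        raise DegenerateInputError("residence analysis needs >= 2 frames")
    inside, _, mols = _inside_matrix(traj, z_extent)
    times = traj.times
    records: list[ResidenceRecord] = []
    for col, mol in enumerate(mols):
        flags = inside[:, col]
        f = 0
        while f < len(flags):
            if not flags[f]:
                f += 1
                continue
            start = f
            while f + 1 < len(flags) and flags[f + 1]:
                f += 1
            last = f
            censored = start == 0 or last == len(flags) - 1
            entry = float(times[start])
            if last + 1 < len(times):
                exit_t = float(times[last + 1])
            else:
                # open at the end: extrapolate the final frame spacing
                exit_t = float(times[last] + (times[-1] - times[-2]))
            records.append(
                ResidenceRecord(int(mol), entry, exit_t, exit_t - entry, censored)
            )
            f += 1
    used = [r.duration for r in records if include_censored or not r.censored]
    summary = {
        "n_records": len(records),
        "n_censored": sum(r.censored for r in records),
        "mean_ps": float(np.mean(used)) if used else float("nan"),
        "median_ps": float(np.median(used)) if used else float("nan"),
        "max_ps": float(np.max(used)) if used else float("nan"),
    }
    return records, summary


def detect_extrusions(
    traj: Trajectory,
    z_extent: float = DEFAULT_Z_EXTENT,
    debounce: int = 10,
) -> list[ExtrusionEvent]:
    """Inside->outside transitions not reversed within ``debounce`` frames.

    The event time is the first outside frame; the direction is the leaflet
    the lipid occupied at its last inside frame.
    """
    inside, leaflet, mols = _inside_matrix(traj, z_extent)
    events: list[ExtrusionEvent] = []
    T = traj.n_frames
    for col, mol in enumerate(mols):
        flags = inside[:, col]
        for f in range(T - 1):
            if flags[f] and not flags[f + 1]:
                nxt = np.flatnonzero(flags[f + 1:])
                if len(nxt) == 0 or nxt[0] > debounce:
                    events.append(
                        ExtrusionEvent(
                            int(mol),
                            float(traj.times[f + 1]),
                            Leaflet(int(leaflet[f, col])),
                        )
                    )
    return events


# ---------------------------------------------------------------------------
# solvent contacts and profiles
# ---------------------------------------------------------------------------


def _resolve_selection(structure: Structure, selection) -> np.ndarray:
    if callable(selection):
        sel = np.asarray(selection(structure), dtype=bool)
    else:
        sel = np.asarray(selection, dtype=bool)
    if sel.shape != (structure.n_beads,):
        raise SelectionError("selection mask length != bead count")
    if not sel.any():
        raise SelectionError("empty bead selection")
    return sel


def contact_series(
    traj: Trajectory,
    sites,
    solvent,
    cutoff: float = 4.0,
) -> ContactSeries:
    """Distinct solvent molecules within ``cutoff`` Å of each site group.

    Site beads are grouped by molecule (a group models e.g. the two
    carboxyl oxygens of one glutamate); a solvent molecule is counted once
    per group per frame regardless of how many of its beads are in range.
    Distances use the minimum image in x,y.
    """
    s = traj.structure
    site_mask = _resolve_selection(s, sites)
    solv_mask = _resolve_selection(s, solvent)
    cutoff_nm = cutoff / 10.0

    site_idx = np.flatnonzero(site_mask)
    groups = s.molecule_index[site_idx]
    uniq_groups = np.unique(groups)
    labels = [
        str(s.names[site_idx[groups == g][0]]) for g in uniq_groups
    ]
    solv_idx = np.flatnonzero(solv_mask)
    solv_mol = s.molecule_index[solv_idx]

    counts = np.zeros((traj.n_frames, len(uniq_groups)), dtype=int)
    for i, f in enumerate(traj):
        box = f.box
        for gi, g in enumerate(uniq_groups):
            gidx = site_idx[groups == g]
            delta = f.coords[solv_idx][:, None, :] - f.coords[gidx][None, :, :]
            for d in (0, 1):
                delta[..., d] -= box[d] * np.round(delta[..., d] / box[d])
            dist = np.linalg.norm(delta, axis=-1)
            near = (dist <= cutoff_nm).any(axis=1)
            counts[i, gi] = len(np.unique(solv_mol[near]))
    return ContactSeries(
        times=traj.times.copy(), counts=counts, site_labels=labels,
        cutoff=cutoff,
    )


def z_profile(
    traj: Trajectory, selection, bin_width: float = 0.1
) -> tuple[np.ndarray, np.ndarray]:
    """Time-averaged normalized density of selected-bead z positions.

    Returns (bin_edges, density); bins are half-open [low, high) aligned to
    multiples of ``bin_width``, and density integrates to 1 over z.
    """
    sel = _resolve_selection(traj.structure, selection)
    z = traj.coords[:, sel, 2].ravel()
    lo = np.floor(z.min() / bin_width) * bin_width
    hi = np.ceil(z.max() / bin_width + 1e-9) * bin_width
    edges = np.arange(lo, hi + bin_width / 2, bin_width)
    if len(edges) < 2:
        edges = np.array([lo, lo + bin_width])
    counts, edges = np.histogram(z, bins=edges)
    density = counts / (len(z) * bin_width)
    return edges, density


def plug_displacement(
    traj: Trajectory, z_extent: float = DEFAULT_Z_EXTENT
) -> dict:
    """Per-leaflet vertical offset of encapsulated vs bulk lipid heads.

    For each leaflet, the time-average of (mean inside head z - mean
    outside head z), in nm; positive values point toward the loop side.
    """
    inside, leaflet, mols = _inside_matrix(traj, z_extent)
    heads, _ = _lipid_heads(traj.structure)
    result = {}
    for leaf in (Leaflet.loop_side, Leaflet.nc_side):
        diffs = []
        for i in range(traj.n_frames):
            on_leaf = leaflet[i] == leaf
            zin = traj.coords[i, heads[on_leaf & inside[i]], 2]
            zout = traj.coords[i, heads[on_leaf & ~inside[i]], 2]
            if len(zin) and len(zout):
                diffs.append(zin.mean() - zout.mean())
        if not diffs:
            raise DegenerateInputError(
                f"no frame with both inside and outside lipids on {leaf.name}"
            )
        result[leaf] = float(np.mean(diffs))
    return result
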