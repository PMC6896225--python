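"""Synthetic systems with known ground truth.

The toy ring protein stands in for an n-fold membrane rotor ring: each
subunit ("protomer") is a rigid pair of vertical bead columns, the outer
and inner column playing the role of the two transmembrane helices.  Toy
lipids are 3-bead rods (head + two tail beads) whose leaflet is set by the
head z-sign relative to the bilayer midplane z = 0; the +z leaflet is the
``loop_side`` by convention.

Every generator is deterministic: the same spec and seed give bit-identical
output.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np

from .density_maps import DensityGrid, rotation_increment
from .errors import ScriptError, SpecError
from .model_core import BeadKind, Leaflet, Structure, Trajectory

#: default box (nm); roughly two ring diameters of bilayer in x,y
DEFAULT_BOX = (24.0, 18.0, 12.0)

#: |z| of lipid head beads (nm); tails sit at 0.65 and 0.3 toward z = 0
LIPID_HEAD_Z = 1.0
LIPID_TAIL_DZ = (0.35, 0.70)
#: minimal center-center distance of placed lipids (> bead diameter 0.5 nm)
PLUG_SPACING = 0.70


@dataclass
class RingSpec:
    """Geometry of the toy reference ring.

    Two concentric bead columns per protomer stand for the two TM helices;
    radii are testing placeholders, not measurements of any real ring.
    """

    n_protomers: int = 14
    outer_radius: float = 2.6
    inner_radius: float = 1.7
    beads_per_column: int = 3
    column_z_span: float = 3.0
    box: tuple[float, float, float] = DEFAULT_BOX

    def __post_init__(self) -> None:
        if self.n_protomers < 3:
            raise SpecError(f"need >= 3 protomers, got {self.n_protomers}")
        if self.inner_radius >= self.outer_radius:
            raise SpecError(
                f"inner_radius {self.inner_radius} must be < outer_radius "
                f"{self.outer_radius}"
            )
        if self.beads_per_column < 1 or self.column_z_span <= 0:
            raise SpecError("invalid column geometry")

    @property
    def beads_per_protomer(self) -> int:
        return 2 * self.beads_per_column


@dataclass
class PlugSpec:
    """Lipids placed inside the ring, per leaflet."""

    n_loop: int = 7
    n_nc: int = 10
    bulk_lipid_density: float = 1.5  # per nm^2, per leaflet, outside the ring

    def __post_init__(self) -> None:
        if self.n_loop < 0 or self.n_nc < 0 or self.bulk_lipid_density < 0:
            raise SpecError("plug counts and bulk density must be >= 0")


# ---------------------------------------------------------------------------
# reference ring
# ---------------------------------------------------------------------------


def make_reference_ring(spec: RingSpec) -> Structure:
    """Exactly C_n-symmetric ring of rigid two-column protomers.

    Protomer k sits at azimuth 360 k / n about +z through the box center;
    rotating the structure by one increment and advancing the protomer
    index reproduces it to floating-point rounding.
    """
    n = spec.n_protomers
    cx, cy = spec.box[0] / 2.0, spec.box[1] / 2.0
    zs = (
        np.linspace(-spec.column_z_span / 2.0, spec.column_z_span / 2.0,
                    spec.beads_per_column)
        if spec.beads_per_column > 1
        else np.array([0.0])
    )
    ids, kinds, prot, mol, leaf, names, coords = [], [], [], [], [], [], []
    for k in range(n):
        theta = 2.0 * np.pi * k / n
        c, s = np.cos(theta), np.sin(theta)
        for radius, tag in ((spec.outer_radius, "OC"), (spec.inner_radius, "IC")):
            x, y = cx + radius * c, cy + radius * s
            for j, z in enumerate(zs):
                ids.append(len(ids))
                kinds.append(int(BeadKind.protomer_bead))
                prot.append(k)
                mol.append(k)
                leaf.append(int(Leaflet.none))
                names.append(f"{tag}{j + 1}")
                coords.append([x, y, z])
    return Structure(
        bead_ids=np.array(ids),
        kinds=np.array(kinds),
        protomer_index=np.array(prot),
        molecule_index=np.array(mol),
        leaflet=np.array(leaf),
        names=np.array(names, dtype=object),
        coords=np.array(coords),
        box=np.array(spec.box),
    )


# ---------------------------------------------------------------------------
# assembly system
# ---------------------------------------------------------------------------


def _hex_grid(extent_x, extent_y, spacing, rng=None, jitter=0.0):
    """Deterministic hexagonal lattice covering [0, ex) x [0, ey)."""
    dy = spacing * np.sqrt(3.0) / 2.0
    pts = []
    row = 0
    y = spacing / 2.0
    while y < extent_y:
        x0 = spacing / 2.0 + (spacing / 2.0 if row % 2 else 0.0)
        x = x0
        while x < extent_x:
            pts.append((x, y))
            x += spacing
        y += dy
        row += 1
    pts = np.array(pts) if pts else np.zeros((0, 2))
    if jitter > 0 and rng is not None and len(pts):
        pts = pts + rng.uniform(-jitter, jitter, size=pts.shape)
    return pts


def _plug_slots(center, max_radius, n, spacing=PLUG_SPACING):
    """First ``n`` hexagonal-lattice points inside a circle, nearest-first."""
    extent = 2.0 * max_radius + 2.0 * spacing
    pts = _hex_grid(extent, extent, spacing) - extent / 2.0 + np.asarray(center)
    r = np.linalg.norm(pts - center, axis=1)
    pts = pts[np.argsort(r, kind="stable")]
    inside = pts[np.linalg.norm(pts - center, axis=1) <= max_radius]
    if len(inside) < n:
        raise SpecError(
            f"cannot place {n} plug lipids inside radius {max_radius} nm"
        )
    return inside[:n]


def _lipid_rows(xy, leaflet, mol_start, id_start):
    """Bead rows for vertical 3-bead lipids at the given (x, y) positions."""
    sign = 1.0 if leaflet == Leaflet.loop_side else -1.0
    rows = []
    for m, (x, y) in enumerate(xy):
        mol = mol_start + m
        beads = [
            ("HD", BeadKind.lipid_head, sign * LIPID_HEAD_Z),
            ("T1", BeadKind.lipid_tail, sign * (LIPID_HEAD_Z - LIPID_TAIL_DZ[0])),
            ("T2", BeadKind.lipid_tail, sign * (LIPID_HEAD_Z - LIPID_TAIL_DZ[1])),
        ]
        for name, kind, z in beads:
            rows.append(
                (id_start + len(rows), int(kind), -1, mol, int(leaflet), name,
                 (x, y, z))
            )
    return rows


def _stack_rows(structure_rows, box):
    ids, kinds, prot, mol, leaf, names, coords = zip(*[
        (r[0], r[1], r[2], r[3], r[4], r[5], r[6]) for r in structure_rows
    ])
    return Structure(
        bead_ids=np.array(ids),
        kinds=np.array(kinds),
        protomer_index=np.array(prot),
        molecule_index=np.array(mol),
        leaflet=np.array(leaf),
        names=np.array(names, dtype=object),
        coords=np.array(coords),
        box=np.array(box),
    )


def make_assembly_system(
    spec: RingSpec,
    plug: PlugSpec,
    separation: float = 5.0,
    seed: int = 0,
) -> tuple[Structure, Structure]:
    """Split-ring starting system plus its intact reference.

    The ring is split into two half-rings displaced by ±separation/2 along
    x; plug lipids fill the gap interior and a bulk bath (jittered
    hexagonal lattice at ``plug.bulk_lipid_density`` per leaflet) fills both
    leaflets outside a stadium-shaped footprint that covers both half-rings
    and the gap between them.  Protomer bead ids match the returned
    reference ring exactly.
    """
    if separation < 0:
        raise SpecError("separation must be >= 0")
    reference = make_reference_ring(spec)
    lx, ly, _ = spec.box
    cx, cy = lx / 2.0, ly / 2.0
    half = separation / 2.0
    if cx - half - spec.outer_radius < 0 or cx + half + spec.outer_radius > lx:
        raise SpecError(
            f"box x-length {lx} too small for separation {separation}"
        )

    system = reference.copy()
    theta = 2.0 * np.pi * system.protomer_index[system.protomer_mask] / spec.n_protomers
    # +x half: protomers whose reference azimuth has cos >= 0
    shift = np.where(np.cos(theta) >= 0.0, half, -half)
    coords = system.coords.copy()
    coords[system.protomer_mask, 0] += shift
    system.coords = coords

    rows = []
    next_id = system.n_beads
    next_mol = int(system.molecule_index.max()) + 1

    plug_radius = spec.inner_radius - 0.45
    for count, leaflet in ((plug.n_loop, Leaflet.loop_side),
                           (plug.n_nc, Leaflet.nc_side)):
        if count:
            xy = _plug_slots(np.array([cx, cy]), plug_radius, count)
            new = _lipid_rows(xy, leaflet, next_mol, next_id)
            rows.extend(new)
            next_id += len(new)
            next_mol += count

    if plug.bulk_lipid_density > 0:
        a = np.sqrt(2.0 / (np.sqrt(3.0) * plug.bulk_lipid_density))
        rng = np.random.default_rng(seed)
        margin = 0.6
        for leaflet in (Leaflet.loop_side, Leaflet.nc_side):
            pts = _hex_grid(lx, ly, a, rng=rng, jitter=0.15 * a)
            # exclude the stadium around the segment joining the half-ring
            # centers (covers both halves and the gap)
            dx = np.clip(pts[:, 0] - cx, -half, half)
            closest = np.stack([cx + dx, np.full(len(pts), cy)], axis=1)
            dist = np.linalg.norm(pts - closest, axis=1)
            keep = pts[dist > spec.outer_radius + margin]
            new = _lipid_rows(keep, leaflet, next_mol, next_id)
            rows.extend(new)
            next_id += len(new)
            next_mol += len(keep)

    if rows:
        lipids = _stack_rows(rows, spec.box)
        system = _concat(system, lipids)
    return system, reference


def _concat(a: Structure, b: Structure) -> Structure:
    return Structure(
        bead_ids=np.concatenate([a.bead_ids, b.bead_ids]),
        kinds=np.concatenate([a.kinds, b.kinds]),
        protomer_index=np.concatenate([a.protomer_index, b.protomer_index]),
        molecule_index=np.concatenate([a.molecule_index, b.molecule_index]),
        leaflet=np.concatenate([a.leaflet, b.leaflet]),
        names=np.concatenate([a.names, b.names]),
        coords=np.concatenate([a.coords, b.coords]),
        box=a.box.copy(),
        periodic_xy=a.periodic_xy,
    )


def ring_footprint_free_area(spec: RingSpec, separation: float) -> float:
    """Analytic bath area: box area minus the excluded stadium footprint."""
    lx, ly, _ = spec.box
    r = spec.outer_radius + 0.6
    return lx * ly - (np.pi * r * r + 2.0 * r * separation)


# ---------------------------------------------------------------------------
# symmetric density maps
# ---------------------------------------------------------------------------


def make_symmetric_map(
    order: int,
    blobs: Sequence[tuple[Sequence[float], float, float]],
    lattice: tuple[Sequence[float], Sequence[float], Sequence[int]],
    axis_point: np.ndarray | None = None,
) -> DensityGrid:
    """Exactly C_n-symmetric analytic Gaussian map.

    Each blob ``(center_Å, sigma_Å, amplitude)`` is replicated at all
    ``order`` rotations about the z axis through ``axis_point`` (default:
    lattice center) and evaluated analytically per voxel — no interpolation,
    so the result is symmetric to rounding.
    """
    rotation_increment(order)  # validates order
    origin, spacing, dims = (np.asarray(x, dtype=float) for x in lattice)
    grid = DensityGrid(origin, spacing, np.zeros(tuple(dims.astype(int))))
    if axis_point is None:
        axis_point = grid.center()
    axis_point = np.asarray(axis_point, dtype=float)
    pts = grid.points()
    values = np.zeros(grid.dims)
    for center, sigma, amplitude in blobs:
        if sigma <= 0:
            raise SpecError(f"blob sigma must be positive, got {sigma}")
        center = np.asarray(center, dtype=float)
        rel = center - axis_point
        rho = np.hypot(rel[0], rel[1])
        phi0 = np.arctan2(rel[1], rel[0])
        for k in range(order):
            phi = phi0 + 2.0 * np.pi * k / order
            ck = axis_point + np.array(
                [rho * np.cos(phi), rho * np.sin(phi), rel[2]]
            )
            d2 = np.sum((pts - ck) ** 2, axis=-1)
            values += amplitude * np.exp(-0.5 * d2 / sigma**2)
    return grid.like(values)


# ---------------------------------------------------------------------------
# scripted trajectories
# ---------------------------------------------------------------------------


@dataclass
class LipidScript:
    """One scripted lipid: inside the ring region during the listed frame
    intervals (inclusive), outside otherwise."""

    leaflet: Leaflet
    inside_intervals: list[tuple[int, int]] = field(default_factory=list)


@dataclass
class WaterScript:
    """One scripted solvent molecule: at an exact distance from a named site
    during each listed contact, parked far away otherwise."""

    contacts: list[tuple[str, int, int, float]] = field(default_factory=list)
    # (site_name, first_frame, last_frame, distance_nm)


@dataclass
class SiteScript:
    name: str
    position: tuple[float, float, float]


@dataclass
class TrajectoryScript:
    n_frames: int = 20
    dt_ps: float = 1000.0  # 1 ns between frames
    ring: RingSpec = field(default_factory=RingSpec)
    lipids: list[LipidScript] = field(default_factory=list)
    waters: list[WaterScript] = field(default_factory=list)
    sites: list[SiteScript] = field(default_factory=list)
    noise_sigma: float = 0.0  # optional xy/z jitter on lipid heads, nm
    seed: int = 0


def _check_intervals(intervals, n_frames, what):
    last_end = -1
    for f0, f1 in sorted(intervals):
        if f0 < 0 or f1 >= n_frames or f1 < f0:
            raise ScriptError(f"{what}: bad interval ({f0}, {f1})")
        if f0 <= last_end:
            raise ScriptError(f"{what}: overlapping intervals at frame {f0}")
        last_end = f1


def make_scripted_trajectory(script: TrajectoryScript) -> Trajectory:
    """Trajectory realizing the script exactly.

    Lipid heads sit on plug slots at the ring center while "inside" and on a
    parking lattice near the box corner while "outside"; scripted
    solvent-site distances are reproduced to rounding.  Ground truth for the
    downstream residence, extrusion and contact analyses is therefore known
    by construction.
    """
    spec = script.ring
    ring = make_reference_ring(spec)
    lx, ly, _ = spec.box
    cx, cy = lx / 2.0, ly / 2.0

    rows = []
    next_id = ring.n_beads
    next_mol = spec.n_protomers

    # inside slots are allocated per leaflet: the leaflets sit at different z
    # and may share in-plane positions, mirroring a stacked lipid plug
    n_by_leaf = {
        leaf: sum(1 for ls in script.lipids if ls.leaflet == leaf)
        for leaf in (Leaflet.loop_side, Leaflet.nc_side)
    }
    slots_by_leaf = {
        leaf: (_plug_slots(np.array([cx, cy]), spec.inner_radius - 0.45, n)
               if n else np.zeros((0, 2)))
        for leaf, n in n_by_leaf.items()
    }
    slot_cursor = {Leaflet.loop_side: 0, Leaflet.nc_side: 0}
    inside_xy = np.zeros((len(script.lipids), 2))
    for m, ls in enumerate(script.lipids):
        inside_xy[m] = slots_by_leaf[ls.leaflet][slot_cursor[ls.leaflet]]
        slot_cursor[ls.leaflet] += 1
    # parking lattice along the box edge, well outside the ring footprint
    park = []
    k = 0
    for ls in script.lipids:
        px = 1.0 + 0.8 * (k % max(int((lx - 2) / 0.8), 1))
        py = 1.0 + 0.8 * (k // max(int((lx - 2) / 0.8), 1))
        park.append((px, py))
        k += 1
        _check_intervals(ls.inside_intervals, script.n_frames, f"lipid {k}")
    park = np.array(park) if park else np.zeros((0, 2))

    lipid_rows_start = []
    for m, ls in enumerate(script.lipids):
        lipid_rows_start.append(len(rows))
        new = _lipid_rows(park[m:m + 1], ls.leaflet, next_mol, next_id)
        rows.extend(new)
        next_id += len(new)
        next_mol += 1

    site_pos = {}
    site_rows = {}
    for ss in script.sites:
        site_rows[ss.name] = len(rows)
        site_pos[ss.name] = np.asarray(ss.position, dtype=float)
        rows.append(
            (next_id, int(BeadKind.site), -1, next_mol, int(Leaflet.none),
             ss.name, tuple(ss.position))
        )
        next_id += 1
        next_mol += 1

    water_rows = []
    for w, ws in enumerate(script.waters):
        seen = {}
        for name, f0, f1, dist in ws.contacts:
            if name not in site_pos:
                raise ScriptError(f"water {w}: unknown site {name!r}")
            for f in range(f0, f1 + 1):
                if f in seen:
                    raise ScriptError(
                        f"water {w}: contradictory contacts at frame {f}"
                    )
                seen[f] = (name, dist)
            if f1 >= script.n_frames or f0 < 0 or f1 < f0:
                raise ScriptError(f"water {w}: bad contact frames ({f0}, {f1})")
        water_rows.append(len(rows))
        rows.append(
            (next_id, int(BeadKind.water), -1, next_mol, int(Leaflet.none),
             "W", (lx - 1.0, ly - 1.0 - 0.6 * w, 0.0))
        )
        next_id += 1
        next_mol += 1

    structure = ring if not rows else _concat(ring, _stack_rows(rows, spec.box))
    base = structure.coords.copy()
    rng = np.random.default_rng(script.seed)

    times = script.dt_ps * np.arange(script.n_frames)
    frames = np.repeat(base[None, :, :], script.n_frames, axis=0)
    for m, ls in enumerate(script.lipids):
        i0 = ring.n_beads + lipid_rows_start[m]
        inside_frames = np.zeros(script.n_frames, dtype=bool)
        for f0, f1 in ls.inside_intervals:
            inside_frames[f0:f1 + 1] = True
        sign = 1.0 if ls.leaflet == Leaflet.loop_side else -1.0
        for f in range(script.n_frames):
            xy = inside_xy[m] if inside_frames[f] else park[m]
            if script.noise_sigma > 0:
                xy = xy + rng.normal(0, script.noise_sigma, 2)
            zs = sign * np.array([
                LIPID_HEAD_Z,
                LIPID_HEAD_Z - LIPID_TAIL_DZ[0],
                LIPID_HEAD_Z - LIPID_TAIL_DZ[1],
            ])
            if script.noise_sigma > 0:
                zs = zs + rng.normal(0, script.noise_sigma)
            frames[f, i0:i0 + 3, 0] = xy[0]
            frames[f, i0:i0 + 3, 1] = xy[1]
            frames[f, i0:i0 + 3, 2] = zs

    for w, ws in enumerate(script.waters):
        i = ring.n_beads + water_rows[w]
        direction = np.array([
            np.cos(2 * np.pi * w / max(len(script.waters), 1)),
            np.sin(2 * np.pi * w / max(len(script.waters), 1)),
            0.0,
        ])
        for name, f0, f1, dist in ws.contacts:
            target = site_pos[name] + dist * direction
            frames[f0:f1 + 1, i, :] = target

    boxes = np.repeat(np.asarray(spec.box, dtype=float)[None, :],
                      script.n_frames, axis=0)
    return Trajectory(structure=structure, times=times, coords=frames,
                      boxes=boxes)
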