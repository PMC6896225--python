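"""Inside/outside classification, residence, extrusion, contacts, profiles."""

import numpy as np
import pytest

from ringweld import ring_analysis as ra
from ringweld.errors import (
    DegenerateInputError,
    GeometryError,
    SelectionError,
)
from ringweld.fixtures import (
    LipidScript,
    PlugSpec,
    RingSpec,
    SiteScript,
    TrajectoryScript,
    WaterScript,
    make_assembly_system,
    make_reference_ring,
    make_scripted_trajectory,
)
from ringweld.model_core import BeadKind, Leaflet, Structure, Trajectory

from _oracles import ray_casting_inside


def _static_traj(structure, n_frames=2, dt=1000.0):
    return Trajectory(
        structure,
        dt * np.arange(n_frames),
        np.repeat(structure.coords[None], n_frames, axis=0),
        np.repeat(structure.box[None], n_frames, axis=0),
    )


# ---------------------------------------------------------------------------
# region geometry and point-in-polygon
# ---------------------------------------------------------------------------


class TestRingRegion:
    def test_reference_ring_gives_regular_14_gon(self, reference_ring,
                                                 ring_spec):
        region = ra.ring_region(reference_ring)
        assert len(region.polygon) == 14
        center = region.polygon.mean(axis=0)
        assert np.allclose(center, [12.0, 9.0], atol=1e-9)
        radii = np.linalg.norm(region.polygon - center, axis=1)
        assert np.allclose(radii, ring_spec.outer_radius, atol=1e-9)
        assert region.z_midplane == pytest.approx(0.0, abs=1e-12)

    def test_split_halves_single_polygon_spans_gap(self, split_system):
        system, _ = split_system
        region = ra.ring_region(system)
        assert len(region.polygon) == 14
        xs = region.polygon[:, 0]
        assert xs.max() - xs.min() > 5.0  # spans both halves plus the gap

    def test_too_few_protomers_raise(self):
        ring = make_reference_ring(RingSpec(n_protomers=3))
        two = ring.copy()
        keep = ring.protomer_index < 2
        two = Structure(
            ring.bead_ids[keep], ring.kinds[keep], ring.protomer_index[keep],
            ring.molecule_index[keep], ring.leaflet[keep], ring.names[keep],
            ring.coords[keep], ring.box)
        with pytest.raises(GeometryError):
            ra.ring_region(two)


class TestPointInPolygon:
    @pytest.mark.parametrize("shape", ["ring", "square", "concave"])
    def test_agrees_with_ray_casting_oracle(self, shape, reference_ring):
        if shape == "ring":
            polygon = ra.ring_region(reference_ring).polygon
            lo, hi = 8.0, 16.0
        elif shape == "square":
            polygon = np.array([[0.0, 0], [4, 0], [4, 4], [0, 4]])
            lo, hi = -1.0, 5.0
        else:
            polygon = np.array([[0.0, 0], [6, 0], [6, 6], [3, 2], [0, 6]])
            lo, hi = -1.0, 7.0
        rng = np.random.default_rng(13)
        pts = rng.uniform(lo, hi, size=(10_000, 2))
        mine = ra.points_in_polygon(pts, polygon)
        oracle = np.array([ray_casting_inside(p, polygon) for p in pts])
        assert (mine == oracle).all()

    def test_agrees_with_shapely(self, reference_ring):
        from shapely.geometry import Point, Polygon

        polygon = ra.ring_region(reference_ring).polygon
        poly = Polygon(polygon)
        rng = np.random.default_rng(14)
        pts = rng.uniform(8.0, 16.0, size=(2000, 2))
        mine = ra.points_in_polygon(pts, polygon)
        ref = np.array([poly.intersects(Point(*p)) for p in pts])
        assert (mine == ref).all()

    def test_boundary_counts_as_inside(self):
        square = np.array([[0.0, 0], [2, 0], [2, 2], [0, 2]])
        assert ra.points_in_polygon(np.array([[1.0, 0.0]]), square)[0]
        assert ra.points_in_polygon(np.array([[0.0, 0.0]]), square)[0]


# ---------------------------------------------------------------------------
# classification and counting
# ---------------------------------------------------------------------------


class TestClassifyAndCount:
    def test_head_at_centroid_is_inside_loop_side(self, split_system):
        system, _ = split_system
        region = ra.ring_region(system)
        inside, leaflet = ra.classify_lipids(system, region)
        heads = np.flatnonzero(system.lipid_head_mask)
        mols = np.sort(system.molecule_index[heads])
        hz = system.coords[heads][np.argsort(system.molecule_index[heads]), 2]
        # plug lipids sit at the ring center: all inside
        plug = np.isin(mols, np.arange(14, 14 + 17))
        assert inside[plug].all()
        assert (leaflet[hz > 0] == Leaflet.loop_side).all()
        assert (leaflet[hz < 0] == Leaflet.nc_side).all()

    def test_partition_is_exhaustive(self, split_system):
        system, _ = split_system
        region = ra.ring_region(system)
        inside, _ = ra.classify_lipids(system, region)
        n_lipids = int(system.lipid_head_mask.sum())
        assert len(inside) == n_lipids
        assert (inside.sum() + (~inside).sum()) == n_lipids

    @pytest.mark.parametrize("n_loop,n_nc", [(7, 10), (6, 9), (0, 0)])
    def test_scripted_plug_counts(self, n_loop, n_nc):
        script = TrajectoryScript(
            n_frames=3,
            lipids=[LipidScript(Leaflet.loop_side, [(0, 2)])] * n_loop
                   + [LipidScript(Leaflet.nc_side, [(0, 2)])] * n_nc,
        )
        df = ra.count_encapsulated(make_scripted_trajectory(script))
        assert (df.n_loop == n_loop).all()
        assert (df.n_nc == n_nc).all()
        assert (df.n_total == n_loop + n_nc).all()
        assert (df.n_total == df.n_loop + df.n_nc).all()

    def test_z_extent_excludes_far_lipids(self, reference_ring):
        region = ra.ring_region(reference_ring, z_extent=2.0)
        # a lipid head 3 nm above the midplane at the ring center
        s = reference_ring
        extra = Structure(
            bead_ids=np.concatenate([s.bead_ids, [1000, 1001, 1002]]),
            kinds=np.concatenate([s.kinds, [1, 2, 2]]),
            protomer_index=np.concatenate([s.protomer_index, [-1] * 3]),
            molecule_index=np.concatenate([s.molecule_index, [99] * 3]),
            leaflet=np.concatenate([s.leaflet, [1] * 3]),
            names=np.concatenate([s.names,
                                  np.array(["HD", "T1", "T2"], object)]),
            coords=np.concatenate([s.coords,
                                   [[12.0, 9.0, 3.0], [12, 9, 2.6],
                                    [12, 9, 2.2]]]),
            box=s.box,
        )
        inside, _ = ra.classify_lipids(extra, region)
        assert not inside[0]


# ---------------------------------------------------------------------------
# residence times
# ---------------------------------------------------------------------------


class TestResidence:
    def test_scripted_interval(self):
        traj = make_scripted_trajectory(TrajectoryScript(
            n_frames=30, dt_ps=1000.0,
            lipids=[LipidScript(Leaflet.loop_side, [(10, 19)])],
        ))
        records, summary = ra.residence_times(traj)
        assert len(records) == 1
        r = records[0]
        assert (r.entry_time, r.duration, r.censored) == (10_000.0, 10_000.0,
                                                          False)
        assert summary["mean_ps"] == pytest.approx(10_000.0)

    def test_final_frame_only_is_censored(self):
        traj = make_scripted_trajectory(TrajectoryScript(
            n_frames=10, dt_ps=1000.0,
            lipids=[LipidScript(Leaflet.nc_side, [(9, 9)])],
        ))
        records, summary = ra.residence_times(traj)
        assert len(records) == 1
        assert records[0].censored
        assert np.isnan(summary["mean_ps"])  # censored excluded by default

    def test_censored_included_on_request(self):
        traj = make_scripted_trajectory(TrajectoryScript(
            n_frames=10, dt_ps=1000.0,
            lipids=[LipidScript(Leaflet.nc_side, [(0, 3)])],
        ))
        _, summary = ra.residence_times(traj, include_censored=True)
        assert summary["mean_ps"] == pytest.approx(4000.0)

    def test_durations_bounded_by_trajectory_length(self):
        traj = make_scripted_trajectory(TrajectoryScript(
            n_frames=40, dt_ps=500.0,
            lipids=[LipidScript(Leaflet.loop_side, [(0, 5), (10, 20), (30, 39)]),
                    LipidScript(Leaflet.nc_side, [(3, 36)])],
        ))
        records, _ = ra.residence_times(traj)
        total = traj.times[-1] - traj.times[0] + 500.0
        by_mol = {}
        for r in records:
            by_mol.setdefault(r.molecule_index, 0.0)
            by_mol[r.molecule_index] += r.duration
        assert all(v <= total + 1e-9 for v in by_mol.values())

    def test_exponential_dwell_recovery(self):
        # scripted ensemble: 200+ exponential dwells, mean 50 frames (1 ns each)
        rng = np.random.default_rng(101)
        mean_frames = 50.0
        n_frames = 900
        lipids = []
        n_kept = 0
        for _ in range(16):
            intervals = []
            cursor = 1
            while True:
                dwell = max(1, int(round(rng.exponential(mean_frames))))
                if cursor + dwell > n_frames - 2:
                    break
                intervals.append((cursor, cursor + dwell - 1))
                cursor += dwell + 3
            n_kept += len(intervals)
            lipids.append(LipidScript(
                Leaflet.loop_side if len(lipids) % 2 else Leaflet.nc_side,
                intervals))
        assert n_kept >= 200
        traj = make_scripted_trajectory(TrajectoryScript(
            n_frames=n_frames, dt_ps=1000.0, lipids=lipids))
        _, summary = ra.residence_times(traj)
        assert summary["mean_ps"] == pytest.approx(50_000.0, rel=0.15)


# ---------------------------------------------------------------------------
# extrusion
# ---------------------------------------------------------------------------


class TestExtrusion:
    def test_leaver_and_debounced_flicker(self):
        traj = make_scripted_trajectory(TrajectoryScript(
            n_frames=40,
            lipids=[LipidScript(Leaflet.nc_side, [(0, 4)]),  # leaves, stays out
                    LipidScript(Leaflet.loop_side, [(0, 10), (13, 39)])],
        ))
        events = ra.detect_extrusions(traj)
        assert len(events) == 1
        assert events[0].molecule_index == 14
        assert events[0].time == pytest.approx(5000.0)
        assert events[0].direction == Leaflet.nc_side

    def test_three_leavers_with_directions(self):
        traj = make_scripted_trajectory(TrajectoryScript(
            n_frames=40,
            lipids=[LipidScript(Leaflet.nc_side, [(0, 5)]),
                    LipidScript(Leaflet.nc_side, [(0, 9)]),
                    LipidScript(Leaflet.loop_side, [(0, 14)])],
        ))
        events = ra.detect_extrusions(traj)
        assert len(events) == 3
        directions = sorted(e.direction.name for e in events)
        assert directions == ["loop_side", "nc_side", "nc_side"]

    def test_no_events_on_static_plug(self):
        traj = make_scripted_trajectory(TrajectoryScript(
            n_frames=20,
            lipids=[LipidScript(Leaflet.loop_side, [(0, 19)])] * 3,
        ))
        assert ra.detect_extrusions(traj) == []


# ---------------------------------------------------------------------------
# contacts
# ---------------------------------------------------------------------------


class TestContacts:
    def _traj(self, distance, n_frames=6, last=4):
        return make_scripted_trajectory(TrajectoryScript(
            n_frames=n_frames,
            sites=[SiteScript("E61A", (14.0, 9.0, 0.5))],
            waters=[WaterScript([("E61A", 0, last, distance)])],
        ))

    def test_inside_cutoff_counts_one(self):
        series = ra.contact_series(
            self._traj(0.39),
            sites=lambda s: s.mask(BeadKind.site),
            solvent=lambda s: s.mask(BeadKind.water))
        assert series.counts[:5, 0].tolist() == [1] * 5
        assert series.counts[5, 0] == 0

    def test_outside_cutoff_counts_zero(self):
        series = ra.contact_series(
            self._traj(0.41),
            sites=lambda s: s.mask(BeadKind.site),
            solvent=lambda s: s.mask(BeadKind.water))
        assert not series.counts.any()

    def test_molecule_level_dedup(self):
        # two site beads of one group, both near one solvent molecule
        traj = make_scripted_trajectory(TrajectoryScript(
            n_frames=3,
            sites=[SiteScript("E61A", (14.0, 9.0, 0.5)),
                   SiteScript("E61B", (14.1, 9.0, 0.5))],
            waters=[WaterScript([("E61A", 0, 2, 0.2)])],
        ))
        s = traj.structure
        # merge the two sites into one molecule-group
        mols = s.molecule_index.copy()
        site_rows = np.flatnonzero(s.kinds == BeadKind.site)
        mols[site_rows[1]] = mols[site_rows[0]]
        merged = Structure(s.bead_ids, s.kinds, s.protomer_index, mols,
                           s.leaflet, s.names, s.coords, s.box)
        traj2 = Trajectory(merged, traj.times, traj.coords, traj.boxes)
        series = ra.contact_series(
            traj2, sites=lambda x: x.mask(BeadKind.site),
            solvent=lambda x: x.mask(BeadKind.water))
        assert series.counts.shape[1] == 1
        assert (series.counts[:, 0] == 1).all()  # one molecule, counted once

    def test_empty_selection_raises(self):
        traj = self._traj(0.39)
        with pytest.raises(SelectionError):
            ra.contact_series(traj, sites=lambda s: s.mask(BeadKind.site),
                              solvent=np.zeros(traj.structure.n_beads, bool))


# ---------------------------------------------------------------------------
# z profile and plug displacement
# ---------------------------------------------------------------------------


class TestProfilesAndDisplacement:
    def test_profile_normalization_and_single_bin(self, reference_ring):
        s = reference_ring.copy()
        c = s.coords.copy()
        c[:, 2] = 2.05
        s.coords = c
        traj = _static_traj(s, n_frames=3)
        edges, density = ra.z_profile(traj, lambda x: x.protomer_mask,
                                      bin_width=0.1)
        assert density.sum() * 0.1 == pytest.approx(1.0, abs=1e-10)
        occupied = np.flatnonzero(density)
        assert len(occupied) == 1
        assert edges[occupied[0]] == pytest.approx(2.0)

    def test_uniform_beads_give_flat_profile(self):
        rng = np.random.default_rng(3)
        n = 20_000
        s = Structure(
            bead_ids=np.arange(n),
            kinds=np.full(n, int(BeadKind.water)),
            protomer_index=np.full(n, -1),
            molecule_index=np.arange(n),
            leaflet=np.zeros(n, int),
            names=np.array(["W"] * n, object),
            coords=np.column_stack([
                rng.uniform(0, 10, n), rng.uniform(0, 10, n),
                rng.uniform(0.0, 5.0, n)]),
            box=np.array([10.0, 10.0, 10.0]),
        )
        traj = _static_traj(s, n_frames=1)
        edges, density = ra.z_profile(traj, lambda x: np.ones(n, bool),
                                      bin_width=0.5)
        interior = density[1:-1]
        expected = 1.0 / 5.0
        # binomial noise bound: ~4 sigma on each interior bin
        sigma = np.sqrt(expected * 0.5 * (1 - expected * 0.5) / (n * 0.5)) / 0.5
        assert np.max(np.abs(interior - expected)) < 4 * sigma + 1e-12

    def test_exact_plug_shift_recovered(self, ring_spec):
        system, _ = make_assembly_system(ring_spec, PlugSpec(), separation=0.0)
        region = ra.ring_region(system)
        inside, _ = ra.classify_lipids(system, region)
        heads = np.flatnonzero(system.lipid_head_mask)
        mols_sorted = np.sort(system.molecule_index[heads])
        inside_mols = mols_sorted[inside]
        shift = system.copy()
        c = shift.coords.copy()
        sel = np.isin(shift.molecule_index, inside_mols) & np.isin(
            shift.kinds, [1, 2])
        c[sel, 2] += 0.3
        shift.coords = c
        result = ra.plug_displacement(_static_traj(shift))
        assert result[Leaflet.loop_side] == pytest.approx(0.3, abs=1e-9)
        assert result[Leaflet.nc_side] == pytest.approx(0.3, abs=1e-9)

    def test_no_shift_gives_zero(self, ring_spec):
        system, _ = make_assembly_system(ring_spec, PlugSpec(), separation=0.0)
        result = ra.plug_displacement(_static_traj(system))
        assert result[Leaflet.loop_side] == pytest.approx(0.0, abs=1e-9)

    def test_empty_population_rejected(self, reference_ring):
        with pytest.raises(DegenerateInputError):
            ra.plug_displacement(_static_traj(reference_ring))
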