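"""Biased-assembly simulator (overdamped Langevin dynamics).

The assembly driver of the protocol — a harmonic positional restraint
pulling each ring-subunit bead toward its position in the reference
structure — is integrator-agnostic, so the toy realization uses first-order
(Brownian) dynamics:

    x <- x + (F/γ) Δt + sqrt(2 k_B T Δt / γ) ξ,   ξ ~ N(0, 1)

with three force terms: purely repulsive WCA pair interactions, a harmonic
leaflet confinement on lipid head beads, and the position restraint on
protomer beads with spring constant ``k_bias`` in kJ/(mol nm²), applied per
bead.  Protomers move as rigid bodies restricted to in-plane translation
plus rotation about their own vertical axis (a membrane-embedded
approximation; z and tilt frozen); lipids are rigid 3-bead rods translating
in all three directions; water beads are free; site beads are inert.

Absolute timescales and trapped-lipid counts of the original μs-scale
protocol are not reproduction targets of this toy; the protocol logic
(staged restraints, convergence detection, outcome classification) is.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
from scipy.spatial import cKDTree

from .errors import DivergenceError, SpecError, TopologyError
from .model_core import (
    BeadKind,
    Frame,
    Leaflet,
    Structure,
    Trajectory,
    rmsd,
)

#: Boltzmann constant, kJ/(mol K)
KB = 0.00831446261815324

DEFAULT_BEAD_RADII = {
    BeadKind.protomer_bead: 0.25,
    BeadKind.lipid_head: 0.25,
    BeadKind.lipid_tail: 0.25,
    BeadKind.water: 0.15,
    BeadKind.site: 0.0,
}


@dataclass
class SimParams:
    """Integrator and force-field parameters of the toy model.

    temperature mirrors the coarse-grained reference runs (303 K);
    friction, timestep and the repulsion are toy-scale choices (see the
    methods note).  ``max_drift`` caps the deterministic displacement per
    step, a standard guard against repulsive-core force spikes.
    """

    temperature: float = 303.0  # K
    friction: float = 200.0  # kJ ps / (mol nm^2), per bead
    timestep: float = 0.05  # ps
    bead_radii: dict = field(default_factory=lambda: dict(DEFAULT_BEAD_RADII))
    repulsion_strength: float = 2.5  # kJ/mol (WCA epsilon)
    leaflet_k: float = 50.0  # kJ/(mol nm^2) on lipid head z
    leaflet_z: dict = field(
        default_factory=lambda: {Leaflet.loop_side: 1.0, Leaflet.nc_side: -1.0}
    )
    cutoff: float = 0.6  # nm, pair-list cutoff (>= max WCA reach 2^(1/6)*0.5)
    skin: float = 0.5  # nm, neighbor-list skin
    max_drift: float = 0.05  # nm, per-step cap on F Δt / γ

    def __post_init__(self) -> None:
        for name in ("friction", "timestep", "cutoff",
                     "repulsion_strength", "leaflet_k"):
            if getattr(self, name) <= 0:
                raise SpecError(f"{name} must be positive")
        if self.temperature < 0:
            raise SpecError("temperature must be >= 0")

    @property
    def kT(self) -> float:
        return KB * self.temperature


@dataclass
class BiasProtocol:
    """Staged restraint schedule.

    The weak stage runs until the lab-frame protomer RMSD drops below
    ``convergence_threshold`` or ``weak_max_duration`` elapses; converged
    runs are then tightened by the strong stages (defaults 10, 100,
    1000 kJ/(mol nm²) for 200 ps each).
    """

    weak_k: float = 30.0  # kJ/(mol nm^2)
    weak_max_duration: float = 2000.0  # ps
    rmsd_check_interval: float = 5.0  # ps
    convergence_threshold: float = 5.0  # Å
    strong_stages: tuple = ((10.0, 200.0), (100.0, 200.0), (1000.0, 200.0))
    assembled_threshold: float = 5.0  # Å
    save_interval: float = 20.0  # ps

    def __post_init__(self) -> None:
        ks = [k for k, _ in self.strong_stages]
        if any(k2 <= k1 for k1, k2 in zip(ks, ks[1:])):
            raise SpecError("strong-stage spring constants must strictly increase")
        if any(d <= 0 for _, d in self.strong_stages):
            raise SpecError("strong-stage durations must be positive")
        if self.weak_max_duration <= 0 or self.rmsd_check_interval <= 0:
            raise SpecError("weak-stage durations must be positive")


@dataclass
class AssemblyResult:
    outcome: str  # "assembled" | "not_assembled"
    convergence_time: float | None  # ps, first sampled RMSD below threshold
    final_rmsd: float  # Å, lab frame, protomer beads
    rmsd_trace: list  # [(time_ps, rmsd_A, stage_label), ...]
    n_loop_trapped: int
    n_nc_trapped: int
    n_total_trapped: int
    trajectory: Trajectory | None = None

    def __post_init__(self) -> None:
        assert self.n_total_trapped == self.n_loop_trapped + self.n_nc_trapped


# ---------------------------------------------------------------------------
# forces
# ---------------------------------------------------------------------------


def _bead_radii(structure: Structure, params: SimParams) -> np.ndarray:
    return np.array([params.bead_radii.get(BeadKind(k), 0.0)
                     for k in structure.kinds])


def _pair_list(structure: Structure, coords: np.ndarray, params: SimParams,
               radius: float, radii: np.ndarray | None = None
               ) -> tuple[np.ndarray, np.ndarray]:
    """Neighbor pairs within ``radius`` (min-image x,y), excluding
    intramolecular pairs and zero-radius (site) beads."""
    if radii is None:
        radii = _bead_radii(structure, params)
    active = radii > 0
    idx = np.flatnonzero(active)
    if len(idx) < 2:
        return np.zeros((0, 2), dtype=int), radii
    pos = coords[idx].copy()
    lx, ly, _ = structure.box
    zmin = pos[:, 2].min()
    zspan = pos[:, 2].max() - zmin
    pos[:, 0] %= lx
    pos[:, 1] %= ly
    pos[:, 2] += radius + 1.0 - zmin
    tree = cKDTree(pos, boxsize=[lx, ly, zspan + 2 * (radius + 1.0)])
    pairs = tree.query_pairs(radius, output_type="ndarray")
    if len(pairs):
        pairs = idx[pairs]
        mols = structure.molecule_index
        pairs = pairs[mols[pairs[:, 0]] != mols[pairs[:, 1]]]
    else:
        pairs = np.zeros((0, 2), dtype=int)
    return pairs, radii


def _min_image_delta(delta: np.ndarray, box: np.ndarray) -> np.ndarray:
    delta = delta.copy()
    for d in (0, 1):
        delta[:, d] -= box[d] * np.round(delta[:, d] / box[d])
    return delta


def _wca(r: np.ndarray, sig: np.ndarray, eps: float):
    """WCA energy and force magnitude (dU/dr with sign flipped) at distance r."""
    rc = 2.0 ** (1.0 / 6.0) * sig
    inside = r < rc
    u = np.zeros_like(r)
    f = np.zeros_like(r)
    if np.any(inside):
        rr = np.maximum(r[inside], 1e-6)
        s6 = (sig[inside] / rr) ** 6
        u[inside] = 4.0 * eps * (s6 * s6 - s6) + eps
        f[inside] = 24.0 * eps * (2.0 * s6 * s6 - s6) / rr
    return u, f


def _bias_map(state: Structure, reference: Structure) -> tuple[np.ndarray, np.ndarray]:
    """Rows of (state, reference) protomer beads matched by bead id."""
    smask = state.protomer_mask
    sidx = np.flatnonzero(smask)
    ref_ids = {int(b): i for i, b in enumerate(reference.bead_ids)}
    try:
        ridx = np.array([ref_ids[int(b)] for b in state.bead_ids[sidx]])
    except KeyError as exc:
        raise TopologyError(f"protomer bead id {exc} missing in reference") from None
    return sidx, ridx


def compute_forces(
    state: Structure,
    reference: Structure,
    k_bias: float,
    params: SimParams,
    pairs: np.ndarray | None = None,
) -> np.ndarray:
    """Per-bead forces, kJ/(mol nm): WCA repulsion + leaflet confinement +
    position restraint on protomer beads."""
    coords = state.coords
    n = state.n_beads
    forces = np.zeros((n, 3))
    if pairs is None:
        pairs, radii = _pair_list(state, coords, params, params.cutoff)
    else:
        radii = np.array([params.bead_radii.get(BeadKind(k), 0.0)
                          for k in state.kinds])
    if len(pairs):
        i, j = pairs[:, 0], pairs[:, 1]
        delta = _min_image_delta(coords[i] - coords[j], state.box)
        r = np.linalg.norm(delta, axis=1)
        sig = radii[i] + radii[j]
        _, fmag = _wca(r, sig, params.repulsion_strength)
        fvec = delta * (fmag / np.maximum(r, 1e-6))[:, None]
        for d in range(3):
            forces[:, d] += np.bincount(i, weights=fvec[:, d], minlength=n)
            forces[:, d] -= np.bincount(j, weights=fvec[:, d], minlength=n)
    heads = state.lipid_head_mask
    if heads.any():
        targets = np.array([
            params.leaflet_z.get(Leaflet(l), 0.0) for l in state.leaflet[heads]
        ])
        forces[heads, 2] += -params.leaflet_k * (coords[heads, 2] - targets)
    if k_bias != 0.0 and state.protomer_mask.any():
        sidx, ridx = _bias_map(state, reference)
        forces[sidx] += -k_bias * (coords[sidx] - reference.coords[ridx])
    return forces


def potential_energy(
    state: Structure,
    reference: Structure,
    k_bias: float,
    params: SimParams,
) -> float:
    """Total potential, the integral of :func:`compute_forces` (oracle hook)."""
    coords = state.coords
    pairs, radii = _pair_list(state, coords, params, params.cutoff)
    u = 0.0
    if len(pairs):
        i, j = pairs[:, 0], pairs[:, 1]
        delta = _min_image_delta(coords[i] - coords[j], state.box)
        r = np.linalg.norm(delta, axis=1)
        uu, _ = _wca(r, radii[i] + radii[j], params.repulsion_strength)
        u += float(uu.sum())
    heads = state.lipid_head_mask
    if heads.any():
        targets = np.array([
            params.leaflet_z.get(Leaflet(l), 0.0) for l in state.leaflet[heads]
        ])
        u += 0.5 * params.leaflet_k * float(
            np.sum((coords[heads, 2] - targets) ** 2)
        )
    if k_bias != 0.0 and state.protomer_mask.any():
        sidx, ridx = _bias_map(state, reference)
        u += 0.5 * k_bias * float(
            np.sum((coords[sidx] - reference.coords[ridx]) ** 2)
        )
    return u


# ---------------------------------------------------------------------------
# integrator
# ---------------------------------------------------------------------------


class BrownianSimulator:
    """Stateful integrator over a fixed bead table.

    Drawing order of the noise (free beads, lipid bodies, protomer
    translations, protomer rotations) is fixed, so identical seeds give
    bit-identical trajectories.
    """

    def __init__(
        self,
        system: Structure,
        reference: Structure,
        params: SimParams,
        rng: np.random.Generator | int = 0,
    ):
        self.structure = system.copy()
        self.reference = reference
        self.params = params
        self.rng = (
            rng if isinstance(rng, np.random.Generator)
            else np.random.default_rng(rng)
        )
        self.time = 0.0
        self.step_count = 0

        s = self.structure
        self.free_idx = np.flatnonzero(s.kinds == BeadKind.water)
        lipid = np.isin(s.kinds, [BeadKind.lipid_head, BeadKind.lipid_tail])
        self._init_bodies(lipid)
        self._pairs = None
        self._pairs_ref = None
        self._precompute_bias()
        # static per-bead caches used by the fast force path
        self._radii = np.array([
            params.bead_radii.get(BeadKind(k), 0.0) for k in s.kinds
        ])
        self._head_idx = np.flatnonzero(s.lipid_head_mask)
        self._head_target = np.array([
            params.leaflet_z.get(Leaflet(l), 0.0)
            for l in s.leaflet[self._head_idx]
        ])
        sidx, ridx = self._bias_rows
        self._ref_coords = reference.coords[ridx] if len(ridx) else np.zeros((0, 3))

    def _init_bodies(self, lipid_mask: np.ndarray) -> None:
        s = self.structure
        # lipid rods: dense body id per lipid bead
        lip_idx = np.flatnonzero(lipid_mask)
        mols = s.molecule_index[lip_idx]
        uniq, dense = np.unique(mols, return_inverse=True)
        self.lip_idx = lip_idx
        self.lip_body = dense
        self.n_lip = len(uniq)
        self.lip_count = np.bincount(dense, minlength=self.n_lip).astype(float)
        # protomer bodies
        prot_idx = np.flatnonzero(s.protomer_mask)
        pids = s.protomer_index[prot_idx]
        puniq, pdense = np.unique(pids, return_inverse=True)
        self.prot_idx = prot_idx
        self.prot_body = pdense
        self.n_prot = len(puniq)
        self.prot_count = np.bincount(pdense, minlength=self.n_prot).astype(float)

    def _precompute_bias(self) -> None:
        if self.n_prot:
            self._bias_rows = _bias_map(self.structure, self.reference)
        else:
            self._bias_rows = (np.zeros(0, int), np.zeros(0, int))

    # -- neighbor bookkeeping --------------------------------------------

    def _ensure_pairs(self) -> None:
        p = self.params
        coords = self.structure.coords
        stale = self._pairs is None
        if not stale:
            disp = _min_image_delta(coords - self._pairs_ref,
                                    self.structure.box)
            stale = np.max(np.abs(disp)) > p.skin / 2.0
        if stale:
            if not np.all(np.isfinite(coords)):
                raise DivergenceError(
                    f"non-finite coordinates at step {self.step_count}"
                )
            self._pairs, _ = _pair_list(
                self.structure, coords, p, p.cutoff + p.skin, radii=self._radii
            )
            self._pair_sig = (
                self._radii[self._pairs[:, 0]] + self._radii[self._pairs[:, 1]]
                if len(self._pairs) else np.zeros(0)
            )
            self._pairs_ref = coords.copy()

    # -- stepping ---------------------------------------------------------

    def _forces(self, k_bias: float) -> np.ndarray:
        """Cached-topology equivalent of :func:`compute_forces`."""
        p = self.params
        s = self.structure
        coords = s.coords
        n = s.n_beads
        forces = np.zeros((n, 3))
        pairs = self._pairs
        if len(pairs):
            delta = _min_image_delta(coords[pairs[:, 0]] - coords[pairs[:, 1]],
                                     s.box)
            r2 = np.einsum("ij,ij->i", delta, delta)
            rc = 2.0 ** (1.0 / 6.0) * self._pair_sig
            hit = r2 < rc * rc
            if hit.any():
                i, j = pairs[hit, 0], pairs[hit, 1]
                r = np.sqrt(r2[hit])
                _, fmag = _wca(r, self._pair_sig[hit], p.repulsion_strength)
                fvec = delta[hit] * (fmag / np.maximum(r, 1e-6))[:, None]
                for d in range(3):
                    forces[:, d] += np.bincount(i, weights=fvec[:, d], minlength=n)
                    forces[:, d] -= np.bincount(j, weights=fvec[:, d], minlength=n)
        if len(self._head_idx):
            forces[self._head_idx, 2] += -p.leaflet_k * (
                coords[self._head_idx, 2] - self._head_target
            )
        if k_bias != 0.0:
            sidx, _ = self._bias_rows
            if len(sidx):
                forces[sidx] += -k_bias * (coords[sidx] - self._ref_coords)
        return forces

    def step(self, k_bias: float) -> None:
        p = self.params
        s = self.structure
        self._ensure_pairs()
        forces = self._forces(k_bias)
        dt = p.timestep
        coords = s.coords
        mob = dt / p.friction
        cap = p.max_drift

        if len(self.free_idx):
            drift = np.clip(forces[self.free_idx] * mob, -cap, cap)
            noise = self.rng.standard_normal((len(self.free_idx), 3))
            coords[self.free_idx] += drift + np.sqrt(2 * p.kT * mob) * noise

        if self.n_lip:
            fbody = np.empty((self.n_lip, 3))
            for d in range(3):
                fbody[:, d] = np.bincount(
                    self.lip_body, weights=forces[self.lip_idx, d],
                    minlength=self.n_lip,
                )
            drift = np.clip(fbody * (mob / self.lip_count[:, None]), -cap, cap)
            noise = self.rng.standard_normal((self.n_lip, 3))
            disp = drift + np.sqrt(
                2 * p.kT * mob / self.lip_count
            )[:, None] * noise
            coords[self.lip_idx] += disp[self.lip_body]

        if self.n_prot:
            fp = forces[self.prot_idx]
            pos = coords[self.prot_idx]
            cxy = np.empty((self.n_prot, 2))
            fxy = np.empty((self.n_prot, 2))
            for d in (0, 1):
                cxy[:, d] = np.bincount(
                    self.prot_body, weights=pos[:, d], minlength=self.n_prot
                ) / self.prot_count
                fxy[:, d] = np.bincount(
                    self.prot_body, weights=fp[:, d], minlength=self.n_prot
                )
            off = pos[:, :2] - cxy[self.prot_body]
            torque = np.bincount(
                self.prot_body,
                weights=off[:, 0] * fp[:, 1] - off[:, 1] * fp[:, 0],
                minlength=self.n_prot,
            )
            inertia = np.bincount(
                self.prot_body, weights=np.sum(off * off, axis=1),
                minlength=self.n_prot,
            )
            drift = np.clip(fxy * (mob / self.prot_count[:, None]), -cap, cap)
            tnoise = self.rng.standard_normal((self.n_prot, 2))
            dxy = drift + np.sqrt(2 * p.kT * mob / self.prot_count)[:, None] * tnoise
            rnoise = self.rng.standard_normal(self.n_prot)
            rotatable = inertia > 1e-12
            gamma_rot = p.friction * np.where(rotatable, inertia, 1.0)
            dtheta = np.where(
                rotatable,
                torque * dt / gamma_rot
                + np.sqrt(2 * p.kT * dt / gamma_rot) * rnoise,
                0.0,
            )
            c = np.cos(dtheta)[self.prot_body]
            sn = np.sin(dtheta)[self.prot_body]
            newx = c * off[:, 0] - sn * off[:, 1]
            newy = sn * off[:, 0] + c * off[:, 1]
            coords[self.prot_idx, 0] = cxy[self.prot_body, 0] + newx + dxy[self.prot_body, 0]
            coords[self.prot_idx, 1] = cxy[self.prot_body, 1] + newy + dxy[self.prot_body, 1]

        self._wrap()
        self.time += dt
        self.step_count += 1

    def _wrap(self) -> None:
        """Periodic wrap in x,y, whole molecules at a time."""
        s = self.structure
        if not s.periodic_xy:
            return
        coords = s.coords
        lx, ly = s.box[0], s.box[1]
        if len(self.free_idx):
            coords[self.free_idx, 0] %= lx
            coords[self.free_idx, 1] %= ly
        if self.n_lip:
            for d, L in ((0, lx), (1, ly)):
                cen = np.bincount(
                    self.lip_body, weights=coords[self.lip_idx, d],
                    minlength=self.n_lip,
                ) / self.lip_count
                shift = -np.floor(cen / L) * L
                coords[self.lip_idx, d] += shift[self.lip_body]

    def protomer_rmsd(self) -> float:
        """Lab-frame RMSD of protomer beads vs the reference, Å."""
        sidx, ridx = self._bias_rows
        return rmsd(self.structure.coords[sidx], self.reference.coords[ridx])

    def integrate(
        self,
        n_steps: int,
        k_bias: float = 0.0,
        record_beads: np.ndarray | None = None,
        record_every: int = 1,
    ) -> np.ndarray | None:
        """Run ``n_steps``; optionally record selected bead positions."""
        rec = None
        if record_beads is not None:
            record_beads = np.atleast_1d(record_beads)
            rec = np.empty((n_steps // record_every, len(record_beads), 3))
        for i in range(n_steps):
            self.step(k_bias)
            if rec is not None and (i + 1) % record_every == 0:
                rec[(i + 1) // record_every - 1] = self.structure.coords[record_beads]
        if not np.all(np.isfinite(self.structure.coords)):
            raise DivergenceError(f"non-finite coordinates at step {self.step_count}")
        return rec


# ---------------------------------------------------------------------------
# protocol stages
# ---------------------------------------------------------------------------


def run_stage(
    sim: BrownianSimulator,
    k_bias: float,
    duration: float,
    save_interval: float = 20.0,
    check_interval: float = 5.0,
    stop_below: float | None = None,
    stage_label: str = "",
) -> tuple[list[Frame], list[tuple], float | None]:
    """Integrate one restraint stage.

    RMSD is sampled every ``check_interval`` ps; frames are saved every
    ``save_interval`` ps.  With ``stop_below`` set, the stage ends at the
    first sampled RMSD strictly below that threshold (the crossing time is
    returned; no interpolation between samples).
    """
    if duration <= 0:
        raise SpecError("stage duration must be positive")
    p = sim.params
    steps_per_check = max(int(round(check_interval / p.timestep)), 1)
    steps_per_save = max(int(round(save_interval / p.timestep)), 1)
    n_steps = int(round(duration / p.timestep))
    frames: list[Frame] = []
    trace: list[tuple] = []
    crossing: float | None = None
    for i in range(n_steps):
        sim.step(k_bias)
        done = i + 1 == n_steps
        if (i + 1) % steps_per_save == 0 or done:
            if not np.all(np.isfinite(sim.structure.coords)):
                raise DivergenceError(
                    f"non-finite coordinates at step {sim.step_count}"
                )
            frames.append(
                Frame(sim.time, sim.structure.coords.copy(),
                      sim.structure.box.copy())
            )
        if (i + 1) % steps_per_check == 0 or done:
            value = sim.protomer_rmsd()
            trace.append((sim.time, value, stage_label))
            if stop_below is not None and value < stop_below:
                crossing = sim.time
                break
    return frames, trace, crossing


def run_assembly_protocol(
    system: Structure,
    reference: Structure,
    protocol: BiasProtocol | None = None,
    params: SimParams | None = None,
    seed: int = 0,
    keep_trajectory: bool = True,
) -> AssemblyResult:
    """Full staged protocol: weak pulling stage, then (if converged) the
    strong-restraint stages; classifies the outcome and counts trapped
    lipids on the final frame."""
    from . import ring_analysis

    protocol = protocol or BiasProtocol()
    params = params or SimParams()
    sim = BrownianSimulator(system, reference, params, rng=seed)

    frames: list[Frame] = [Frame(0.0, sim.structure.coords.copy(),
                                 sim.structure.box.copy())]
    trace: list[tuple] = []
    r0 = sim.protomer_rmsd()
    trace.append((0.0, r0, "weak"))
    convergence_time: float | None = None
    if r0 < protocol.convergence_threshold:
        convergence_time = 0.0
    else:
        f, t, crossing = run_stage(
            sim,
            protocol.weak_k,
            protocol.weak_max_duration,
            save_interval=protocol.save_interval,
            check_interval=protocol.rmsd_check_interval,
            stop_below=protocol.convergence_threshold,
            stage_label="weak",
        )
        frames += f
        trace += t
        convergence_time = crossing

    if convergence_time is not None:
        for k, duration in protocol.strong_stages:
            f, t, _ = run_stage(
                sim, k, duration,
                save_interval=protocol.save_interval,
                check_interval=protocol.rmsd_check_interval,
                stage_label=f"strong_k{k:g}",
            )
            frames += f
            trace += t

    final_rmsd = sim.protomer_rmsd()
    outcome = (
        "assembled" if final_rmsd < protocol.assembled_threshold
        else "not_assembled"
    )

    final = sim.structure
    n_loop = n_nc = 0
    if final.lipid_head_mask.any() and final.n_protomers >= 3:
        region = ring_analysis.ring_region(final)
        inside, leaflet = ring_analysis.classify_lipids(final, region)
        n_loop = int(np.sum(inside & (leaflet == Leaflet.loop_side)))
        n_nc = int(np.sum(inside & (leaflet == Leaflet.nc_side)))

    traj = None
    if keep_trajectory:
        # de-duplicate frame times at stage boundaries
        uniq: list[Frame] = []
        for fr in frames:
            if not uniq or fr.time_ps > uniq[-1].time_ps:
                uniq.append(fr)
        traj = Trajectory.from_frames(sim.structure, uniq)

    return AssemblyResult(
        outcome=outcome,
        convergence_time=convergence_time,
        final_rmsd=final_rmsd,
        rmsd_trace=trace,
        n_loop_trapped=n_loop,
        n_nc_trapped=n_nc,
        n_total_trapped=n_loop + n_nc,
        trajectory=traj,
    )
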