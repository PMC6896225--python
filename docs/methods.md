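# Methods

## Model

`ringweld` models an n-fold membrane rotor ring and its surrounding bilayer
with rigid bead bodies:

- **Protomer**: two vertical 3-bead columns (outer and inner, standing for
  the two transmembrane helices of a subunit), radius 0.25 nm per bead. Each
  protomer is a rigid body whose motion is restricted to in-plane
  translation plus rotation about its own vertical axis; z position and tilt
  are frozen. This is the minimal kinematics of a membrane-embedded,
  bilayer-spanning unit, and it makes "assembly" a purely in-plane docking
  problem, as in the steered protocol the package implements.
- **Lipid**: a rigid 3-bead rod (head + two tails, 0.35 nm spacing)
  translating in all three directions, with the leaflet defined by the head
  z-sign relative to the bilayer midplane z = 0 (loop side ≡ +z). There are
  no chain conformations and no lipid-species chemistry: the protocol is
  lipid-model-agnostic and the analyses only need head positions and
  excluded volume.
- **Water / site beads** exist for the contact-map analytics; site beads are
  inert markers (for glutamate-carboxyl-like contact targets), waters are
  free beads.

Default geometry: 14 protomers, outer/inner column radii 2.6/1.7 nm (testing
placeholders, not measurements of any real ring), box 24 × 18 × 12 nm,
periodic in x,y only, bulk bath 1.5 lipids/nm² per leaflet (≈ 1100–1200
lipids — a bilayer patch of the size used in the coarse-grained study
systems this toy emulates).

## Dynamics

Overdamped (first-order) Langevin dynamics,

x ← x + (F/γ)Δt + √(2 k_B T Δt/γ) ξ,

with rigid-body reduction for protomers (net in-plane force and z-torque per
body, rotational friction γ Σ r⊥²) and lipid rods (net force, shared
displacement). The staged-restraint protocol is integrator-agnostic;
Brownian dynamics is its simplest testable realization, and the integrator
is validated by an equipartition check (positional variance k_BT/k in a
harmonic well, 10⁶ steps, within 5%).

Forces (all terms analytic, validated against a central-difference gradient
of the total potential to 1e−6 relative error):

1. **WCA repulsion** between beads of different molecules, ε = 2.5 kJ/mol,
   pair diameter = sum of bead radii, cut at 2^{1/6}σ (purely repulsive,
   continuous at the cutoff). Minimum image in x,y.
2. **Leaflet confinement** on lipid head beads, F_z = −k_l (z − z_target),
   k_l = 50 kJ/(mol·nm²), targets ±1.0 nm. This stands in for the bilayer's
   own cohesion, which the toy does not otherwise have.
3. **Positional restraint (the assembly bias)** on protomer beads,
   F = −k (x − x_ref), applied per bead in the lab frame. The spring
   constant is quoted in kJ/(mol·nm²) per bead.

Parameters: T = 303 K (k_BT ≈ 2.52 kJ/mol), γ = 200 kJ·ps·mol⁻¹·nm⁻²,
Δt = 0.05 ps, with a 0.05 nm cap on the deterministic displacement per step
(a standard guard against repulsive-core force spikes during the initial
plowing phase; the cap is never active in the validation tests). Stability:
k·Δt/γ = 0.25 at the strongest restraint (k = 1000), comfortably inside the
Euler stability region. T = 0 is allowed and gives the deterministic limit
used by the drift and monotonic-relaxation tests.

Neighbor lists use a periodic k-d tree with a 0.5 nm skin, rebuilt when any
bead's minimum-image displacement exceeds half the skin. Noise is drawn in a
fixed order (free beads, lipid bodies, protomer translations, protomer
rotations), so a given seed yields bit-identical trajectories.

## Assembly protocol

The split system places the two half-rings at ±separation/2 along x
(default 5 nm; the initial lab-frame protomer RMSD is then exactly 25 Å),
with plug lipids on a hexagonal lattice in the gap interior and the bath on
a jittered hexagonal lattice outside a stadium-shaped footprint covering
both halves and the gap.

The weak stage runs until the lab-frame protomer RMSD drops below 5 Å
(sampled every 5 ps, first sample strictly below the threshold, no
interpolation) or a maximum duration elapses; converged runs continue
through the strong stages (10, 100, 1000 kJ/(mol·nm²) × 200 ps). A run is
classified `assembled` iff the final RMSD is below the 5 Å threshold.
Unconverged weak stages skip the strong stages: slamming a far-from-target
configuration shut with k = 1000 would make every run "assembled" and
destroy both the zero-bias control and the bias-strength trend the protocol
is supposed to expose. Trapped lipids are counted on the final frame.

**Weak-stage spring constants.** The scanned values are 6, 15, 30 and
60 kJ/(mol·nm²) — a single ×3000 scaling of the 0.002–0.02 kJ/(mol·nm²)
range meaningful for a protein with thousands of restrained beads. The toy
protomer has 6 beads, so its equilibrium positional fluctuation under a
restraint of strength k is √(k_BT/6k) per axis; at the unscaled constants
this noise floor sits far above the convergence threshold and no bias
strength would ever converge. The scaled values reproduce the qualitative
regime structure: the weakest constant converges slowly or not at all
within the desk budget, stronger constants converge progressively faster,
and zero bias never assembles. Absolute convergence times (tens of ps here
vs microseconds in CG MD) are explicitly not comparable.

RMSD for convergence is lab-frame over protomer beads only, because the
bias itself is defined in the lab frame; the Kabsch-fitted variant exists
for reporting. The fitted RMSD is computed with
`scipy.spatial.transform.Rotation.align_vectors` and cross-checked in the
tests against a hierarchically refined brute-force rotation-grid search.

## Density maps and RSCC

Maps live on regular lattices in Å (factor 10 at the module boundary; the
rest of the package works in nm). `trajectory_to_density` deposits, per
selected bead and frame, an isotropic Gaussian truncated at 4σ and
normalized to unit integral over its truncated support, then averages over
frames — the volmap convention. σ defaults to 1 Å and is exposed; the
kernel width of the reference implementation this mirrors is not published,
and RSCC comparisons are insensitive to it as long as both maps use the
same kernel.

Symmetry averaging replaces a map by the mean of its `order` rotations
about the axis (increment 360°/order ≈ 25.7° for order 14), using inverse
mapping with trilinear resampling and zero fill outside the grid; it is
idempotent and mass-conserving to well under 1% for maps whose support
stays ≥ 4σ inside the boundary — the test fixtures respect that margin,
which is why their lattices look generously padded. The symmetry axis can
be estimated by a grid search over small tilts, scoring each candidate by
the mean Pearson correlation between the map and its rotated copies.

Masks are strict thresholds (value > level, matching the "above 0.8"
convention for simulated-map units); RSCC is the Pearson correlation over
masked voxels after resampling the second map onto the first map's lattice.
Pearson is the right statistic here because simulated and experimental maps
have unrelated absolute scales — the correlation is invariant under
positive affine rescaling, which the tests assert. For the synthetic
model-selection check the mask level is 0.8 × the reference map's maximum,
since the toy maps' absolute units differ from the conventions of any
particular map-rendering package. Map I/O is MRC2014 mode 2 via gemmi; any
other mode is rejected by name.

## Ring-interior analytics

The "inner volume" is the simple polygon through the per-protomer
outer-column centroids (ordered by azimuth; for split halves the polygon
spans both halves and the gap), bounded in z by ±2 nm around the protomer
midplane — the bilayer span. Boundary points count as inside (an
artifact choice affecting only measure-zero configurations). Point-in-
polygon is an even-odd test validated against both a scalar ray-casting
oracle and shapely on 10⁴ random points per polygon shape.

Residence records are maximal runs of inside-frames; the duration is
(last inside frame time + Δt) − (first inside frame time) with per-gap Δt,
and intervals touching either trajectory end are censored (excluded from
summary statistics by default — the survival-analysis-correct choice —
includable by flag; an interval open at the trajectory end uses the final
frame spacing as its observed Δt so its lower-bound duration is positive).
Extrusions are inside→outside transitions not reversed within a debounce
window (default 10 frames). Contact series count distinct solvent molecules
within a cutoff (default 4 Å) of each site group, deduplicated at molecule
level. Leaflet assignment uses the head z-sign per frame, so lipid flips
are tracked rather than frozen at construction.

## Synthetic data: what it does and does not emulate

The generators produce exactly symmetric rings (analytic construction, no
interpolation), overlap-free lipid placements, analytic Gaussian maps, and
scripted trajectories whose residence intervals, contact distances and
displacements are realized exactly. They emulate the *geometry and
bookkeeping* of a steered-assembly study: split rings, leaflet-resolved
plugs, bath densities, map lattices at 1 Å (simulated) and 1.053 Å
(experimental) sampling. They do not emulate force-field chemistry, lipid
conformational entropy, water structure, or experimental map noise — so
passing tests validate the protocol logic, the estimators and the numerics,
not the thermodynamics of any real bilayer.

## Numerical choices and degenerate inputs

- Kabsch requires ≥ 3 non-collinear points; reflections are excluded.
- The convergence-crossing time is the first sampled time strictly below
  threshold; no interpolation between samples.
- Flat maps, empty selections, masks with < 2 voxels, and zero-variance
  masked regions raise typed domain errors rather than returning NaN.
- All generators and simulations are deterministic given a seed; the CLI
  requires explicit seeds for stochastic commands.

## Problem sizes

The default test and acceptance runs use the full default system
(~3450 beads) with 600 ps of strong-stage dynamics per seed, an 800 ps
weak-stage budget for the bias scan and a 500 ps zero-bias control; the
equipartition check integrates a single bead for 10⁶ steps. These sizes
were chosen so the complete stochastic battery (5 seeds × 4 + 1 bias
values) gives stable orderings of means while an entire study remains a
desk-scale computation.

## Known limitations

- Protomer z and tilt are frozen; the protocol cannot express
  out-of-plane assembly failure modes.
- The bilayer has no cohesive energy beyond the leaflet springs; lateral
  pressure and area-per-lipid are not meaningful observables.
- Map-to-map comparison assumes a shared coordinate frame (both maps
  derive from the same aligned structure); rigid map alignment is out of
  scope.
- Absolute convergence times, trapped-lipid counts and RSCC values are
  properties of the toy, not predictions for any molecular system.
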