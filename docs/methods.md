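# Methods

## Model

`spheroidcpm` simulates the self-organization of articular-cartilage
chondrocytes into spheroids and cell clusters, resolved by the longitudinal
depth zone the cells come from (surface SZ, middle MZ, deep DZ).  It is a 3D
Cellular Potts Model (Glazier–Graner–Hogeweg type): every simulated object —
a cell, a structural-ECM blob (ECMst, collagen-I-like and cell-binding), a
volumetric-ECM blob (ECMv, aggrecan/hyaluronan-like and water-retaining), or
the culture medium — is a *compartment*, a set of voxels sharing an integer
id on a rectangular lattice.  Configurations are scored by

```
H = H_contact + H_volume
H_contact = Σ_{neighbor pairs i,j} J(τ(σ_i), τ(σ_j)) · (1 − δ(σ_i, σ_j))
H_volume  = Σ_σ λ_vol (V_σ − V_target,σ)²
```

where `J` is a symmetric contact-energy table over compartment classes
(medium, zone-specific cell, ECMst, ECMv; lower J between cells means
stronger effective adhesion) and the quadratic volume constraint pulls every
non-medium compartment toward its target volume.  The medium (id 0) carries
no volume constraint and `J(medium, medium) = 0`.

Dynamics are Metropolis index-copy attempts: sample a target voxel uniformly,
sample a source site uniformly among its neighbors, and, when the two carry
different ids, overwrite the target's id with the source's with probability
`min(1, exp(−ΔH/Tm))` at domain temperature `Tm = 37`.  One Monte Carlo Step
(MCS) is one attempt per lattice voxel by default.  Time is calibrated as
1 MCS = 6 min and 240 MCS = 1 day, with MCS 0 representing culture day 1
(3120 MCS = day 14).

## Lifecycle

After each sweep a per-MCS lifecycle pass updates compartments:

* **ECM first**: every ECM target volume decays by `v_d` voxel³/MCS (ECM has
  no fixed target; its decaying target *is* its volume law), and any ECM
  whose realized volume fell below `V_Delete = 3` is deleted, its voxels
  reverting to medium.  Running ECM before cells means a freshly secreted
  blob always gets one sweep to grow before it is judged against the
  deletion threshold.
* **Cells**: every cell's target volume grows by `v_g`; cells whose realized
  volume exceeds `V_Death = 60` (or that were annihilated by the dynamics)
  are removed.  Cells above the action threshold `V_A = 20` draw, per MCS,
  mitosis with probability `P_M` and secretion of ECMst/ECMv with `P_ECMst` /
  `P_ECMv`; a successful mitosis draw pre-empts that cell's secretion draws
  for the step (a config flag makes all three draws independent instead).
  Eligibility is judged on the *realized* volume — growth and decay act on
  targets, and only the Hamiltonian moves realized volumes.

Mitosis splits the cell's voxels by a random plane through its centroid
(median split when the plane is degenerate); both halves get target volume
`V_Cell/2 = 15`.  Secretion claims up to a 2×2×2 block of medium adjacent to
the cell boundary (most-medium block wins, RNG tie-break) with target
`V_ECMInit = 30`; a fully enclosed cell logs a blocked secretion.  Event
draws are vectorized in id order, but the resulting discrete events are
*applied* in an RNG-shuffled order each MCS so low ids gain no systematic
advantage when competing for space.

## Parameters

All defaults are the published zone columns.  Probabilities are stored in
percent per MCS; volumes in voxel³; speeds in voxel³/MCS.

| symbol | meaning | SZ | MZ | DZ |
|---|---|---|---|---|
| v_g | cell target growth | 0.080 | 0.060 | 0.060 |
| P_M | mitosis probability | 1.0 | 1.0 | 1.0 |
| P_ECMst | ECMst secretion | 3.2 | 0.67 | 3.0 |
| P_ECMv | ECMv secretion | 3.2 | 9.3 | 8.3 |
| v_d | ECM decay | 0.003 | 0.027 | 0.097 |
| J(cell–cell) | contact energy | 5.0 | 2.5 | 2.5 |
| J(medium–ECM) | contact energy | 20 | 2.5 | 2.5 |

Shared rows: V_Cell 30, V_CellInit 27, V_A 20, V_Death 60, V_ECMInit 30,
V_Delete 3, λ_vol 10, Tm 37, J(medium–cell) 5, J(cell–ECM) 10, J(ECM–ECM) 10.
The zone-dependent J(medium–ECM) row applies to both ECM classes (the table
publishes a single medium–ECM row).  Zone-specific parameters can
alternatively be derived from day-7 RT-qPCR relative quantities through
anchored linear scaling (`translate` module): Col1a1→P_ECMst, Col2a1→P_ECMv,
Mmp13→v_d, Pcna→v_g and ItgaV→J(cell–ECM) proportionally, Cdh2→J(cell–cell)
inversely (more cadherin ⇒ stronger adhesion ⇒ lower J).  The bundled RQ
table is synthetic — back-solved so the translation reproduces the default
columns — and exists to exercise and round-trip-test the translation path.

## Initialization

1,000 cells plus ECM at zone ratios (8:1:1 SZ, 4:4:3 MZ/DZ) are seeded as
3×3×3 cubes (27 voxel³, cells targeting 30) at random non-overlapping slots
in a cylinder resting on the substrate plane z = 0.  The published cylinder
sizes (36/84/84 diameter × 5/3/3 height) cannot hold 1,000 disjoint 27-voxel
cubes when read in voxels, so the default `unit_mode='cell-slot'` reads them
in 3-voxel slot units (SZ cylinder 108×15 voxels); `unit_mode='voxel'`
honors the literal reading and raises a capacity error naming the shortfall.
Default lattice dimensions leave a 6-voxel margin around the cylinder and 60
voxels of headroom at full scale (120×120×60 for SZ).  The substrate is the
flat fixed-medium boundary plane; out-of-lattice sites everywhere behave as
immutable medium (a low-adhesion culture well), with periodic wrap available
for testing.

Reduced problem sizes scale the cylinder diameter as `sqrt(n_cells/1000)` at
fixed height, preserving the thin-disk areal density.  The package's standard
desk-scale surrogate — used by the test suite and the acceptance script — is
100 cells, the scaled cylinder, and 720 MCS (three simulated days).

## Numerical choices

* Contact energy is counted once per unordered neighbor pair; the default
  contact/sampling neighborhood is order 2 (18 neighbors) to reduce lattice
  anisotropy, with order 1 used in hand-checkable tests.
* The sweep is a numba-compiled loop with an inline xorshift128+ RNG; its
  two-word state plus a numpy Generator for the lifecycle are both derived
  from the run seed and checkpointed in snapshots, so a (config, seed) pair
  fixes the trajectory bit-for-bit, including across checkpoint/resume.
* Local ΔH is validated against a full-Hamiltonian recompute to 1e−9 in the
  tests, for both the reference Python path and the compiled kernel.
* Compartment bounding boxes only grow during sweeps; they are re-tightened
  every 25 MCS so per-event voxel scans stay local.
* No connectivity constraint is enforced: compartments may fragment, which
  at Tm = 37 produces a haze of few-voxel cell fragments around aggregates.
  Cells-only cluster counts therefore include transient fragments; ordering
  comparisons between zones remain meaningful because all zones share this
  property.

## Emergent behavior and limitations

With the default parameters an eligible cell divides roughly every 170 MCS
(~60 MCS to regrow past V_A after division, then a geometric wait of mean
100 MCS at P_M = 1 %/MCS).  Proliferation and secretion therefore expand the
aggregate until crowding pins realized cell volumes near V_A, at which point
the population self-limits; at full scale the aggregate reaches the lattice
boundary around MCS 800–1000.  Quantitative size readouts at day 14 (e.g.
the largest-cluster diameter ratio) are consequently bounded by the lattice
geometry, and the package treats them as qualitative observables at that
horizon; the zone *contrasts* — a single SZ spheroid with an ECM-rich core
and cell-rich rim versus multiple MZ cell clusters, and ECM content falling
as v_d rises — are robust at the desk scale and are what the acceptance
battery asserts.

The synthetic seeding emulates the settled day-1 cell disk but not medium
convection (cells never re-suspend), phenotype is fixed for a run (no
expression dynamics), and ECM "diffusion" is emergent compartment motion
only.  Passing tests therefore demonstrate the model's internal consistency
and its zone-contrast morphologies, not quantitative agreement with any
particular culture.
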