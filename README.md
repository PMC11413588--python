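# spheroidcpm

A 3D Cellular Potts Model of how primary chondrocytes from the three
longitudinal depth zones of articular cartilage — surface (SZ), middle (MZ)
and deep (DZ) — self-organize into spheroids and cell clusters in low-adhesion
round-bottom culture.  It is written for tissue-engineering and cartilage-
biology groups who want to explore how cell–cell adhesion, two classes of
extracellular matrix (structural, collagen-I-like **ECMst**; volumetric,
aggrecan/hyaluronan-like **ECMv**), ECM secretion and ECM decay shape
multicellular morphology, without running a two-week culture per condition.

## Model

Cells, ECM blobs and the culture medium are voxel *compartments* on a lattice.
Configurations are scored by the Hamiltonian

```
H = Σ_{⟨i,j⟩} J(τ(σ_i), τ(σ_j)) (1 − δ(σ_i,σ_j))  +  Σ_σ λ_vol (V_σ − V_target,σ)²
```

and evolve by Metropolis index-copy dynamics at domain temperature Tm = 37:
a voxel's id is copied onto a neighbor with probability min(1, exp(−ΔH/Tm)).
One Monte Carlo Step (MCS) is one attempt per voxel; 1 MCS = 6 min, 240 MCS =
1 culture day, MCS 0 = day 1.  Each MCS the lifecycle runs: cell targets grow
at v_g; cells above the action threshold V_A may divide (P_M) or secrete an
ECMst/ECMv compartment (P_ECMst, P_ECMv); ECM targets decay at v_d and ECM
below V_Delete is deleted.  The three zones differ only in a handful of
parameter values (v_g, the secretion probabilities, v_d, J(cell–cell),
J(medium–ECM)), which can also be derived from day-7 RT-qPCR relative
quantities via the `translate` module.  See `docs/methods.md` for the full
parameter table, units and numerical choices.

## Worked example

Run the desk-scale SZ surrogate (100 cells, three simulated days) and analyze
the first and last snapshots:

```
$ spheroidcpm init --zone SZ --n-cells 100 --mcs 720 --out sz.yaml
$ spheroidcpm run --config sz.yaml --seed 7 --snapshot-every 240 --out sz_run
final snapshot hash 38679e5147a176db59c5f9a497ed7e3a1182a768a0f0d44ae7288b5fa35ea67b
$ spheroidcpm analyze sz_run/snapshot_000000.npz sz_run/snapshot_000720.npz
 mcs  day  n_clusters_all_matter  n_clusters_cells_only  largest_projected_diameter  ...
   0  1.0                     55                     57                   12.2
 720  4.0                      1                    191                   54.2
```

At day 1 the seeded disk is a loose scatter of 124 compartments (55 connected
groups, largest footprint 12.2 voxels).  By 720 MCS everything has merged
into a single spheroid of projected diameter 54.2 voxels whose core is packed
with ECM and whose rim is cell-rich — the SZ phenotype.  Running `--zone MZ`
instead yields many separate cell clusters embedded in short-lived ECMv, and
DZ sits in between (higher ECM decay, intermediate clustering).  The run
directory also contains `metrics.csv` (one row per snapshot), `events.csv`
(every mitosis/secretion/deletion) and checksummed snapshot archives that
`spheroidcpm run --resume` continues bit-identically; `spheroidcpm audit`
prints H_contact, H_volume and per-class bond counts for any snapshot.

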