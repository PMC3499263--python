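# ncdsbm — dual-basin structure-based model of the Ncd motor dimer

Ncd (kinesin-14) is a minus-end-directed microtubule motor despite sharing
its catalytic motor-head fold with the plus-end-directed kinesin-1. The
leading structural explanation is a *dual-basin* picture: the dimer can
occupy a symmetric conformation (coiled-coil stalk pointing to the
plus-end) and an asymmetric one (one head rotated about the head–stalk
junction, stalk swung toward the minus-end), and nucleotide chemistry tips
the balance between them — the stalk swing *is* the power stroke.

`ncdsbm` is a tested Python implementation of that modelling pipeline for
people who study motor mechanochemistry with coarse-grained simulation:

* **Topology construction** — Cα native-contact maps from two conformers
  of the same molecule, merged into one topology whose contacts carry a
  basin label: `S` (symmetric-native), `A` (asymmetric-only), `IF`
  (motor–track interface). Junction-contact deletion mimics ATP binding.
* **Energetics** — the structure-based Hamiltonian

  V = Σ K_b(r−r0)² + Σ K_a(θ−θ0)² + Σ K₁[1−cos(φ−φ0)] + K₃[1−cos3(φ−φ0)]
    + Σ_contacts ε[5(r0/r)¹² − 6(r0/r)¹⁰] + Σ_non-native ε_rep(σ/r)¹²

  with analytic forces (NumPy reference plus compiled kernels,
  cross-checked against each other and against finite differences).
* **Dynamics** — low-friction Langevin (BBK / velocity-Verlet) at
  T = 300 K, ζ = 0.05, h = 0.0025 τ_L, with frozen track beads and
  bit-reproducible seeding.
* **Observables** — inter-residue distances, the stalk angle θ, per-basin
  contact counts, nucleotide-pocket RMSD, free-energy surfaces
  F = −k_BT log P, the stall-force bound from a PMF over the stalk tip,
  and PCA of superposed coordinates.
* **Synthetic system** — a deterministic 40-bead two-conformer chain whose
  tail re-docks through a single 180° torsion flip, giving two mutually
  exclusive contact sets and an analytically predictable, calibratable
  basin free-energy gap — so the entire pipeline runs and is validated
  without downloading any structures.

## Worked example

```python
import numpy as np
from ncdsbm import (ToyDualBasinSpec, build_toy_topology, run_simulation,
                    SimulationParams, residue_distance_series,
                    free_energy_surface, basin_indicator_series, occupancy_gap)

spec = ToyDualBasinSpec()                      # 40 residues, 8-residue tail
top, conf_a, conf_b = build_toy_topology(spec, epsilon_asymmetric=0.67)
print(f"contacts: {int((top.contact_basin=='S').sum())} S, "
      f"{int((top.contact_basin=='A').sum())} A")

params = SimulationParams(n_steps=2_000_000, save_interval=500, seed=7)
traj = run_simulation(top, conf_a, params)
print(f"frames: {traj.n_frames}, span: {traj.times[-1]:.0f} tau_L")

ind = basin_indicator_series(traj, spec)[traj.n_frames // 5:]
gap, occ, se = occupancy_gap(ind)
print(f"minor-basin occupancy: {occ:.3f}  (dF = {gap:.2f} +/- {se:.2f} kT)")

dock = residue_distance_series(traj, ("A", 36), ("A", 15))
fes = free_energy_surface(dock)
finite = np.isfinite(fes.free_energy)
print(f"dock distance: spans [{dock.min():.1f}, {dock.max():.1f}] A, "
      f"barrier {fes.free_energy[finite].max():.1f} kT")
```

prints (about one minute on one core):

```
contacts: 70 S, 7 A
frames: 4001, span: 5000 tau_L
minor-basin occupancy: 0.151  (dF = 1.73 +/- 0.20 kT)
dock distance: spans [6.4, 19.3] A, barrier 5.8 kT
```

The chain hops between its two docked states; the minor (asymmetric)
basin occupancy matches the Boltzmann weight of the measured gap
(e^(−1.73)/(1+e^(−1.73)) ≈ 0.15), and the arm–body docking distance
explores both basins across a ~6 k_BT barrier. `calibrate_gap` tunes the
A-contact depth until the gap hits a requested value (2.0 k_BT →
occupancy ≈ 0.119), pooling independent replicas for honest errors.

A command-line interface wraps the same stages:

```
ncdsbm make-fixtures --out fx --with-track
ncdsbm build-topology --symmetric fx/conformer_a.pdb \
       --asymmetric fx/conformer_b.pdb --out fx/top.json
ncdsbm run --topology fx/top.json --initial fx/conformer_a.pdb \
       --steps 200000 --seed 1 --out fx/traj.npz
ncdsbm validate --out fx/report --quick
```

plus `analyze` and `run-experiment --config experiment.yaml` for the
config-driven experiments (solution state, track-bound nucleotide-free
state, ATP state with junction deletion, power-stroke PMF).

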