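# Methods

## The model

`ncdsbm` implements a Cα-level, dual-basin structure-based (Gō-type) model
of a motor-protein dimer that interconverts between two folded
conformations — a *symmetric* state and an *asymmetric* state in which one
motor head is rotated about the head–stalk junction. Each residue is one
bead at the Cα position. The Hamiltonian is

```
V = Σ_bonds    K_b (r − r0)²
  + Σ_angles   K_a (θ − θ0)²
  + Σ_dihedrals K₁[1 − cos(φ − φ0)] + K₃[1 − cos 3(φ − φ0)]
  + Σ_contacts ε [5 (r0/r)¹² − 6 (r0/r)¹⁰]
  + Σ_non-native ε_rep (σ/r)¹²
```

with defaults `K_b = 20 kcal/(mol·Å²)`, `K_a = 20 kcal/(mol·rad²)`,
`K₁ = 1.0`, `K₃ = 0.5 kcal/mol`, `σ = 4 Å`, contact cutoff 8 Å, and
sequence separation |i−j| > 3 within a chain (all inter-chain pairs under
the cutoff are eligible). The 10–12 contact well has its minimum −ε exactly
at r0; that is the defining contract of the functional form.

Bonded native values (r0, θ0, φ0) are taken from the symmetric conformer
only. The contact list carries one basin label per pair:

* **S** — native in the symmetric conformer. A pair native in *both*
  conformers is labeled S and keeps the symmetric distance: this keeps
  every pair single-welled and the symmetric basin dominant, consistent
  with biasing the backbone toward the symmetric state.
* **A** — native only in the asymmetric conformer, at the asymmetric
  distance (the perturbative bias that opens the second basin).
* **IF** — motor–track interface contacts of the bound complex.

Well depths: ε = 1.8 kcal/mol for contacts whose both partners carry an
author residue number below the neck threshold (331 for Ncd — the upper
coiled-coil) and for all IF contacts; ε = 1.0 kcal/mol otherwise. The
depth of A contacts is a configuration knob `epsilon_asymmetric`
(default 1.0): the asymmetric basin is a perturbation and no separate
published depth exists for it, so it is exposed rather than hard-coded.
Pairs native in neither basin are repulsive-only with ε_rep = 1.0 kcal/mol
(only σ is prescribed; the prefactor is a knob).

ATP binding is mimicked by deleting the S contacts that span the head–stalk
junction (author residues 341–345 of the stalk against 346–351 of the motor
head on the track-bound monomer), which removes the bias holding the stalk
in its symmetric, plus-end-pointing pose.

## Units and dynamics

Energies are kcal/mol, lengths Å, temperature K, with
k_B = 0.0019872 kcal/(mol·K) (k_BT ≈ 0.596 kcal/mol at 300 K). Time is the
reduced unit τ_L with uniform bead mass m = 1; friction ζ = 0.05 m/τ_L and
timestep h = 0.0025 τ_L are the low-friction defaults chosen for efficient
conformational sampling. All reported times are in τ_L, never ps: the
coarse-grained time scale has no calibrated physical bridge here.

The equation of motion m·dv = (F − ζv)dt + Γdt, with
⟨Γᵢ(t)Γⱼ(t′)⟩ = 2ζk_BT δᵢⱼδ(t−t′)/h in discretized form, is integrated
with the BBK (velocity-Verlet with impulsive friction/noise)
discretization. At ζ = 0 it reduces exactly to velocity Verlet, which is
what the symplectic-limit check exploits. The production integrator draws
one Gaussian random-force row per step and shares it between the adjoining
half-kicks of consecutive steps; the single-step reference API applies one
row to both half-kicks of its own step. Both inject identical noise power;
drawing *independent* noise per half-kick would undercool the system by a
factor of two, which the equipartition test would catch. Track beads are
frozen: they receive no noise, no force, and never move; track-internal
contacts are dropped as constant terms.

Before production, the initial structure is relaxed by L-BFGS with the
analytic gradient to max |F| ≤ 1e-3 kcal/(mol·Å) (limited-memory
quasi-Newton converges far faster than damped dynamics on this stiff,
well-conditioned problem; non-convergence is an error, not a warning).
Initial velocities are Maxwell–Boltzmann at the run temperature from the
run's seeded generator, so a (seed, topology, initial, parameters) tuple
reproduces a trajectory bit-for-bit.

Two force implementations exist deliberately: a plain NumPy reference
(`energetics`) and compiled kernels (`_kernels`, numba) used by the
integrator. The test suite asserts they agree to 1e-9 on random
configurations, and the reference is checked against central finite
differences (relative error < 1e-4 at step 1e-5 Å). Non-native repulsion
pairs are enumerated exactly (no cell list): the systems this package runs
offline are a few hundred beads, where exact O(n²) enumeration is both
faster to set up and free of truncation error; a neighbor list is the
obvious extension for full-size dimer-on-microtubule runs.

## The synthetic two-conformer system

The generator builds what the analysis assumes about its inputs, at desk
scale: two conformers of one chain with partially conflicting contact sets
and a tunable basin gap.

Geometry: an S-shaped three-strand ladder of equal-length strands (strand
separation 5.4 Å, consecutive-bead spacing ≈ 3.8 Å) whose chain ends on
the middle strand. The body is *exactly planar in z*: the zig-zag that
keeps backbone torsions non-degenerate lies in the plane (y pucker, with
the top strand's pucker phase the mirror image of the bottom strand's at
the same x). The chain continues through a two-bead *hinge* prolonging the
middle strand exactly along x, a riser climbing close to the mid-plane
ridge, and an *arm* whose second and third residues dip to 7.2 Å above the
bottom strand — the docking patch — while the rest cruises out of contact
range. Conformer B is conformer A with everything past the hinge bond
rotated rigidly by 180° about that bond axis. A rotation about a bond
preserves every bond length and bend angle and changes exactly one
backbone torsion — by π, costing exactly 2K₁ + 2K₃ = 3 kcal/mol — and,
because the body is planar and the hinge axis lies in that plane, maps the
docked tail onto an exactly mirror-symmetric pose docked *below the top
strand*. Three design rules earned their place the hard way and are worth
stating as properties:

* the conflicting contact sets are mirror images of each other, so the two
  basins differ only through the hinge-torsion penalty and the contact
  depths (the test suite asserts the contact-map difference is exactly the
  docking patches);
* the docking residues sit two to three torsions from the hinge, so the
  dock position is stiffly slaved to the hinge angle and interconversion
  is an essentially one-dimensional rotation — a distal docking tip, slaved
  through many soft torsions, mixes orders of magnitude more slowly;
* the docking *targets* lie on strand segments backed by the full-length
  middle strand; docking onto an unsupported strand overhang couples the
  basin populations to slow body-deformation modes. A handful of
  pose-independent tail-body contacts (riser/arm-base against the big
  turn) survive the flip unchanged and act as a pivot tether that keeps
  the undocked arm near the body.

The default spec (40 residues, 8-residue tail) yields 70 S contacts, 5 of
them conflicting docking contacts, 7 A-only contacts (5 of them
conflicting mirrors of the S dock; 2 are cutoff-edge pairs that stay
formed in both poses), and interconverts hundreds of times per 10⁶ steps
at 300 K. Geometry is fully deterministic; randomness enters only as
thermal noise.

**Basin indicator.** A frame is assigned to the asymmetric basin when it
forms more *conflicting* A contacts than *conflicting* S docking contacts
(a contact is "formed" when r < 1.2·r0; a pair is conflicting when it is
beyond 1.2·r0 in the other conformer). Restricting to conflicting pairs
mirrors the head–stalk contact-count semantics while excluding pairs that
carry no basin information.

**Gap calibration and occupancy measurement.** Occupancies are measured by
pooling independent replicas started from the relaxed symmetric pose
(burn-in: first fifth of each), and the quoted standard error is the
*between-replica* error — within-run block averaging would understate the
uncertainty contributed by slowly mixing degrees of freedom.
`calibrate_gap` tunes `epsilon_asymmetric` until the measured
ΔF = ln(P_S/P_A) is within ±0.3 k_BT of the target, stepping along the
secant through the last two measurements (falling back on the linear
response dΔF/dε ≈ −n_conflict/k_BT), and re-measures at doubled length
when the estimate is under-resolved. The calibration tolerance — not the
production run — dominates the uncertainty of downstream population
predictions, so the validation suite propagates both error sources when
comparing the minor-basin occupancy against e^(−ΔF)/(1+e^(−ΔF)).

**What the toy does not emulate.** Real fold topology and residue
numbering; chemistry-dependent contact energies; a helical 13-protofilament
lattice (the track is a flat rigid grid); solvent beyond Langevin friction;
and any absolute time scale. Passing tests therefore demonstrate that the
machinery (topology arithmetic, Hamiltonian, integrator, estimators) is
correct and self-consistent — not that the model reproduces any particular
protein's measured kinetics.

## Observables

* Distance and θ-angle series address residues by (chain, author number);
  θ is the angle at the apex residue between the two arm residues, in
  [0°, 180°]. The apex is configurable because the three defining residues
  do not by themselves fix which is the vertex; the default takes the
  junction-proximal residue of the bound head (D424 in Ncd numbering).
* Pocket RMSD superposes the whole motor head of a frame onto the
  reference and evaluates RMSD over the pocket residues only, so rigid
  head motion scores zero.
* Free-energy surfaces are F = −log P in k_BT units, minimum shifted to
  zero, empty bins +inf; 1-D binning defaults to Freedman–Diaconis, 2-D to
  50×50. Re-exponentiation recovers the input histogram exactly.
* The stall-force bound from a 1-D PMF over the stalk-tip position
  projected on the track axis is the maximum |ΔF/Δz| between adjacent
  finite bins (a lower-bound estimator; the endpoint slope is also
  available), converted with 1 kcal/(mol·Å) = 69.48 pN. The track axis is
  the principal axis of the frozen beads.
* PCA superposes every frame on the reference, diagonalizes the 3N×3N
  coordinate covariance, and returns the largest-variance modes
  ("low-frequency" collective motions). Modes beyond the covariance rank
  carry zero eigenvalues.

## Numerical choices and degenerate inputs

* Contact definition is strict `r < cutoff`; ties at exactly 8 Å are out.
* Alternate locations resolve to highest occupancy, then first listed;
  insertion codes are rejected (absent from the intended inputs); residues
  without a Cα are skipped with a warning.
* Collinear angle triples and torsion quads raise errors during topology
  construction; the generator's pucker exists precisely to avoid them.
* Superposition requires ≥ 3 non-collinear pairs and always returns a
  proper rotation (det +1).
* The pairwise-alignment helper scores match +1 / mismatch 0 with affine
  gaps −2/−0.5 (integer-scaled ×2 internally); it exists because motor-head
  pairings must be explicit, reproducible inputs, not hidden heuristics.
* Junction deletion is idempotent; deleting zero contacts warns rather
  than fails (whether any exist is topology-dependent).

## Problem sizes

The shipped validation suite runs a 40-bead (30-bead for the gradient
check) toy: calibration iterations pool four 500k-step replicas, the
population check pools six 1M-step replicas, equipartition runs 1M steps
of a 16-well 1-D system. These sizes converge the measured quantities to
the precision their comparisons need while keeping the whole suite in the
minutes range on one core.

## Known limitations

* No electrostatics, no sequence-dependent contact energies, no implicit
  solvent beyond friction, no replica exchange or umbrella sampling.
* Exact repulsion enumeration scales O(n²) in memory and time; full-size
  motor-on-microtubule systems need a neighbor list before this package is
  used at that scale.
* The dual-distance case (a pair native in both conformers with different
  distances) is resolved to the symmetric distance, not a double well.
* Trajectory storage is a NumPy container with the topology embedded;
  there is no interoperable DCD/XTC writer, only multi-model PDB export.
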