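"""Low-friction Langevin dynamics with a velocity-Verlet (BBK) integrator.

Units are reduced: uniform bead mass m = 1, time in tau_L, energies in
kcal/mol, lengths in Å, temperature in K bridged through
k_B = 0.0019872 kcal/(mol·K). The random force satisfies the
fluctuation–dissipation relation ⟨Γ_i(t)Γ_j(t')⟩ = 2 ζ k_B T δ_ij δ(t-t')/h
in discretized form. At ζ = 0 and T = 0 the scheme reduces exactly to
velocity Verlet, which is the symplectic-limit contract the tests rely on.

Track (frozen) sites never move and never accumulate force or noise.
"""
from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
from scipy.optimize import minimize

from . import constants as C
from .model_builder import DualBasinTopology
from .structure_io import CaStructure
from .energetics import total_energy
from . import _kernels

logger = logging.getLogger(__name__)

__all__ = ["SimulationParams", "TrajectoryEnsemble", "langevin_step",
           "relax", "run_simulation"]

# largest noise block kept in memory per integrator chunk
_CHUNK_STEPS = 20_000


def _call_forces(x: np.ndarray, flat: "_kernels.FlatTopology",
                 forces: np.ndarray) -> np.ndarray:
    """Invoke the compiled force kernel with an unpacked flat topology."""
    return _kernels.forces_kernel(
        x, flat.bonds, flat.bond_r0, flat.k_bond, flat.angles, flat.theta0,
        flat.k_angle, flat.dihedrals, flat.phi0, flat.k_dih1, flat.k_dih3,
        flat.cpairs, flat.cr0, flat.ceps, flat.cbasin, flat.rpairs,
        flat.sigma, flat.eps_rep, flat.frozen_mask, forces)


@dataclass(frozen=True)
class SimulationParams:
    """Langevin run parameters (reduced units; temperature in K)."""
    temperature: float = C.TEMPERATURE
    friction: float = C.FRICTION
    timestep: float = C.TIMESTEP
    n_steps: int = 100_000
    save_interval: int = 100
    seed: int = 0
    mass: float = C.MASS

    def __post_init__(self) -> None:
        if self.timestep <= 0:
            raise ValueError("timestep must be positive")
        if self.friction < 0 or self.temperature < 0:
            raise ValueError("friction and temperature must be non-negative")

    @property
    def noise_scale(self) -> float:
        """Std-dev of each random-force component per step."""
        return np.sqrt(2.0 * self.friction * C.KB * self.temperature
                       / self.timestep)


@dataclass
class TrajectoryEnsemble:
    """Time-ordered mobile-site frames at a fixed sampling interval.

    ``frames`` holds mobile sites only; the frozen track block is stored
    once in ``frozen_coords``. ``energies`` carries the 7-component
    decomposition [bond, angle, dihedral, S, A, IF, repulsive] per frame.
    """
    frames: np.ndarray            # (n_frames, n_mobile, 3)
    times: np.ndarray             # tau_L
    params: SimulationParams
    topology: DualBasinTopology
    mobile_sites: np.ndarray
    frozen_coords: np.ndarray     # (n_frozen, 3)
    energies: np.ndarray | None = None

    @property
    def n_frames(self) -> int:
        return len(self.frames)

    def full_coords(self, frame: int) -> np.ndarray:
        """All-site coordinates of one frame (frozen block merged back)."""
        out = np.empty((self.topology.n_sites, 3))
        out[self.mobile_sites] = self.frames[frame]
        out[self.topology.frozen_sites] = self.frozen_coords
        return out

    def full_frames(self) -> np.ndarray:
        """(n_frames, n_sites, 3) array with the frozen block broadcast."""
        out = np.empty((self.n_frames, self.topology.n_sites, 3))
        out[:, self.mobile_sites] = self.frames
        out[:, self.topology.frozen_sites] = self.frozen_coords
        return out

    def site_series(self, site: int) -> np.ndarray:
        """(n_frames, 3) positions of one site across the trajectory."""
        where = np.nonzero(self.mobile_sites == site)[0]
        if where.size:
            return self.frames[:, where[0]]
        return np.broadcast_to(
            self.frozen_coords[np.nonzero(self.topology.frozen_sites == site)[0][0]],
            (self.n_frames, 3))

    def to_multi_model_pdb(self, stride: int = 1) -> str:
        """Export as multi-model PDB text for visualization."""
        from .structure_io import write_ca_structure
        top = self.topology
        blocks = []
        for m, f in enumerate(range(0, self.n_frames, stride), start=1):
            body = write_ca_structure(CaStructure(
                top.residue_ids, top.chain_ids, top.residue_names,
                self.full_coords(f)))
            lines = [ln for ln in body.splitlines() if ln.startswith(("ATOM", "TER"))]
            blocks.append(f"MODEL     {m:4d}\n" + "\n".join(lines) + "\nENDMDL")
        return "\n".join(blocks) + "\nEND\n"

    def save(self, path: str) -> None:
        np.savez_compressed(
            path, frames=self.frames, times=self.times,
            energies=self.energies if self.energies is not None else np.zeros(0),
            mobile_sites=self.mobile_sites, frozen_coords=self.frozen_coords,
            topology_json=np.array(self.topology.to_json()),
            params=np.array([self.params.temperature, self.params.friction,
                             self.params.timestep, self.params.n_steps,
                             self.params.save_interval, self.params.seed,
                             self.params.mass]))

    @classmethod
    def load(cls, path: str) -> "TrajectoryEnsemble":
        z = np.load(path, allow_pickle=False)
        p = z["params"]
        params = SimulationParams(p[0], p[1], p[2], int(p[3]), int(p[4]),
                                  int(p[5]), p[6])
        energies = z["energies"] if z["energies"].size else None
        return cls(z["frames"], z["times"], params,
                   DualBasinTopology.from_json(str(z["topology_json"])),
                   z["mobile_sites"], z["frozen_coords"], energies)


def langevin_step(coords: np.ndarray, velocities: np.ndarray,
                  forces: np.ndarray, params: SimulationParams,
                  rng: np.random.Generator, force_fn=None,
                  frozen_mask: np.ndarray | None = None):
    """One BBK step for an arbitrary force field (reference implementation).

    ``force_fn(coords) -> forces``; None means free (zero-force) motion.
    Returns updated ``(coords, velocities, forces)`` (new arrays). One
    random-force row is drawn per call and applied in both half-kicks
    (classic BBK); the chunked production integrator instead shares each
    row between the adjoining half-kicks of consecutive steps — the two
    discretizations inject identical noise power and sample the same
    distribution.
    """
    if not np.all(np.isfinite(forces)):
        raise FloatingPointError("NaN in forces")
    x = np.array(coords, dtype=np.float64)
    v = np.array(velocities, dtype=np.float64)
    h, m, zeta = params.timestep, params.mass, params.friction
    c = zeta * h / (2.0 * m)
    hm = h / (2.0 * m)
    scale = params.noise_scale
    noise = scale * rng.standard_normal(x.shape) if scale > 0 else 0.0
    v_half = v * (1.0 - c) + hm * (forces + noise)
    if frozen_mask is not None:
        v_half[frozen_mask] = 0.0
    x = x + h * v_half
    new_forces = force_fn(x) if force_fn is not None else np.zeros_like(x)
    v = (v_half + hm * (new_forces + noise)) / (1.0 + c)
    if frozen_mask is not None:
        v[frozen_mask] = 0.0
    return x, v, new_forces


def relax(topology: DualBasinTopology, coords: np.ndarray,
          gtol: float = 1e-3, max_iter: int = 100_000) -> np.ndarray:
    """Minimize the Hamiltonian over mobile sites (L-BFGS, analytic gradient).

    Converges when the largest mobile-site force component falls below
    ``gtol`` kcal/(mol·Å); raises RuntimeError otherwise.
    """
    x0 = np.array(coords, dtype=np.float64)
    mobile = topology.mobile_sites
    flat = _kernels.flatten_topology(topology)
    work = x0.copy()
    fbuf = np.zeros_like(work)

    def fun(xm: np.ndarray):
        work[mobile] = xm.reshape(-1, 3)
        e = _call_forces(work, flat, fbuf)
        return float(e.sum()), -fbuf[mobile].ravel()

    res = minimize(fun, x0[mobile].ravel(), jac=True, method="L-BFGS-B",
                   options={"maxiter": max_iter, "gtol": gtol, "ftol": 0.0})
    out = x0.copy()
    out[mobile] = res.x.reshape(-1, 3)
    _, forces = total_energy(out, topology)
    gnorm = float(np.abs(forces).max())
    if gnorm > gtol:
        raise RuntimeError(
            f"relaxation did not converge: max |force| = {gnorm:.3e} "
            f"kcal/(mol·Å) > {gtol:g}")
    return out


def run_simulation(topology: DualBasinTopology, initial: CaStructure,
                   params: SimulationParams, relax_first: bool = True,
                   relax_gtol: float = 1e-3) -> TrajectoryEnsemble:
    """Relax the initial structure, then run production Langevin dynamics.

    Deterministic for a fixed (seed, params, topology, initial): initial
    velocities and all noise are drawn sequentially from one Generator.
    With ``n_steps = 0`` the trajectory is the single relaxed frame.
    """
    if initial.n_sites != topology.n_sites:
        raise ValueError("initial structure does not cover topology sites")
    x = np.array(initial.coords, dtype=np.float64)
    if relax_first:
        x = relax(topology, x, gtol=relax_gtol)

    rng = np.random.default_rng(params.seed)
    flat = _kernels.flatten_topology(topology)
    mobile = topology.mobile_sites
    n = topology.n_sites

    v = np.zeros((n, 3))
    sigma_v = np.sqrt(C.KB * params.temperature / params.mass)
    v[mobile] = sigma_v * rng.standard_normal((len(mobile), 3))

    n_frames = params.n_steps // params.save_interval + 1
    frames = np.empty((n_frames, n, 3))
    energies = np.empty((n_frames, 7))
    frames[0] = x
    forces = np.zeros_like(x)
    energies[0] = _call_forces(x, flat, forces)

    scale = params.noise_scale
    saved = 1
    step_offset = 0
    carry = scale * rng.standard_normal((1, n, 3)) if scale > 0 \
        else np.zeros((1, n, 3))
    while step_offset < params.n_steps:
        nsteps = min(_CHUNK_STEPS, params.n_steps - step_offset)
        noise = np.empty((nsteps + 1, n, 3))
        noise[0] = carry[0]
        if scale > 0:
            noise[1:] = scale * rng.standard_normal((nsteps, n, 3))
        else:
            noise[1:] = 0.0
        noise[:, flat.frozen_mask] = 0.0
        nsaved = _kernels.run_chunk(
            x, v, forces, noise, params.timestep, params.friction, params.mass,
            flat.bonds, flat.bond_r0, flat.k_bond, flat.angles, flat.theta0,
            flat.k_angle, flat.dihedrals, flat.phi0, flat.k_dih1, flat.k_dih3,
            flat.cpairs, flat.cr0, flat.ceps, flat.cbasin, flat.rpairs,
            flat.sigma, flat.eps_rep, flat.frozen_mask,
            params.save_interval, step_offset,
            frames[saved:], energies[saved:])
        if not np.all(np.isfinite(x)):
            bad = frames[max(saved - 1, 0)]
            raise FloatingPointError(
                f"NaN in forces/coordinates near step {step_offset}; last "
                f"finite frame centroid {bad[mobile].mean(axis=0)}")
        saved += nsaved
        step_offset += nsteps
        carry = noise[-1:].copy()

    times = params.timestep * params.save_interval * np.arange(n_frames)
    return TrajectoryEnsemble(frames[:saved, mobile], times[:saved], params,
                              topology, mobile,
                              x[topology.frozen_sites].copy(),
                              energies[:saved])
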