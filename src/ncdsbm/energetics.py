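"""Total Hamiltonian and analytic gradient for a dual-basin topology.

The energy separates into bonded backbone terms and nonbonded terms:

* bonds       V = Σ K_b (r − r0)²
* angles      V = Σ K_a (θ − θ0)²
* dihedrals   V = Σ K₁(1 − cos(φ − φ0)) + K₃(1 − cos 3(φ − φ0))
* contacts    V = Σ ε [5 (r0/r)¹² − 6 (r0/r)¹⁰]   (10–12 Lennard-Jones,
  minimum −ε at r = r0), per basin S / A / IF
* repulsion   V = Σ ε_rep (σ/r)¹² over eligible non-native pairs

A pair that is a contact in any basin carries only its contact term, never
the excluded-volume repulsion. Frozen (track) sites contribute energy but
their force entries are zeroed after evaluation. This module is the plain
NumPy reference implementation; the compiled fast path used by the
integrator lives in ``_kernels`` and is cross-checked against it.
"""
from __future__ import annotations

from dataclasses import dataclass, fields

import numpy as np

from .model_builder import DualBasinTopology, BASIN_S, BASIN_A, BASIN_IF

__all__ = ["EnergyReport", "bonded_energy", "nonbonded_energy",
           "total_energy", "repulsive_pairs"]


@dataclass
class EnergyReport:
    """Energy decomposition, kcal/mol. ``total`` is the exact sum."""
    bond: float
    angle: float
    dihedral: float
    contact_S: float
    contact_A: float
    contact_IF: float
    repulsive: float

    @property
    def total(self) -> float:
        return (self.bond + self.angle + self.dihedral + self.contact_S
                + self.contact_A + self.contact_IF + self.repulsive)

    def as_dict(self) -> dict[str, float]:
        d = {f.name: getattr(self, f.name) for f in fields(self)}
        d["total"] = self.total
        return d


def repulsive_pairs(topology: DualBasinTopology) -> np.ndarray:
    """Eligible non-native pairs: separation rule holds, pair is not a
    contact in any basin, and not frozen–frozen (rigid track internal)."""
    n = topology.n_sites
    same_chain = topology.chain_ids[:, None] == topology.chain_ids[None, :]
    sep = np.abs(topology.residue_ids[:, None] - topology.residue_ids[None, :])
    eligible = np.triu(np.ones((n, n), dtype=bool), k=1)
    eligible &= ~(same_chain & (sep <= topology.min_separation))
    ci, cj = topology.contact_pairs[:, 0], topology.contact_pairs[:, 1]
    eligible[ci, cj] = False
    eligible[cj, ci] = False
    frozen = np.zeros(n, dtype=bool)
    frozen[topology.frozen_sites] = True
    eligible &= ~(frozen[:, None] & frozen[None, :])
    ii, jj = np.nonzero(eligible)
    return np.column_stack([ii, jj])


def _accumulate(forces: np.ndarray, idx: np.ndarray, contrib: np.ndarray) -> None:
    np.add.at(forces, idx, contrib)


def bonded_energy(coords: np.ndarray, topology: DualBasinTopology
                  ) -> tuple[dict[str, float], np.ndarray]:
    """Bond + angle + dihedral energy and forces (−gradient)."""
    x = np.asarray(coords, dtype=np.float64)
    forces = np.zeros_like(x)
    out = {"bond": 0.0, "angle": 0.0, "dihedral": 0.0}

    b = topology.bonds
    if len(b):
        dvec = x[b[:, 1]] - x[b[:, 0]]
        r = np.linalg.norm(dvec, axis=1)
        if np.any(r < 1e-10):
            raise ValueError("zero-length bond")
        dr = r - topology.bond_r0
        out["bond"] = float(topology.k_bond * np.sum(dr ** 2))
        f = (2.0 * topology.k_bond * dr / r)[:, None] * dvec
        _accumulate(forces, b[:, 0], f)
        _accumulate(forces, b[:, 1], -f)

    a = topology.angles
    if len(a):
        u = x[a[:, 0]] - x[a[:, 1]]
        v = x[a[:, 2]] - x[a[:, 1]]
        nu = np.linalg.norm(u, axis=1)
        nv = np.linalg.norm(v, axis=1)
        cosang = np.clip(np.sum(u * v, axis=1) / (nu * nv), -1.0, 1.0)
        theta = np.arccos(cosang)
        dtheta = theta - topology.angle_theta0
        out["angle"] = float(topology.k_angle * np.sum(dtheta ** 2))
        sin = np.sqrt(np.maximum(1.0 - cosang ** 2, 1e-12))
        dVdt = 2.0 * topology.k_angle * dtheta
        uh = u / nu[:, None]
        vh = v / nv[:, None]
        dthe_di = (cosang[:, None] * uh - vh) / (nu * sin)[:, None]
        dthe_dk = (cosang[:, None] * vh - uh) / (nv * sin)[:, None]
        fi = -dVdt[:, None] * dthe_di
        fk = -dVdt[:, None] * dthe_dk
        _accumulate(forces, a[:, 0], fi)
        _accumulate(forces, a[:, 2], fk)
        _accumulate(forces, a[:, 1], -(fi + fk))

    d = topology.dihedrals
    if len(d):
        b1 = x[d[:, 1]] - x[d[:, 0]]
        b2 = x[d[:, 2]] - x[d[:, 1]]
        b3 = x[d[:, 3]] - x[d[:, 2]]
        n1 = np.cross(b1, b2)
        n2 = np.cross(b2, b3)
        n1sq = np.sum(n1 ** 2, axis=1)
        n2sq = np.sum(n2 ** 2, axis=1)
        if np.any(n1sq < 1e-16) or np.any(n2sq < 1e-16):
            raise ValueError("collinear sites: torsion undefined")
        nb2 = np.linalg.norm(b2, axis=1)
        phi = np.arctan2(np.sum(np.cross(n1, n2) * (b2 / nb2[:, None]), axis=1),
                         np.sum(n1 * n2, axis=1))
        dphi = phi - topology.dihedral_phi0
        out["dihedral"] = float(
            topology.k_dihedral_1 * np.sum(1.0 - np.cos(dphi))
            + topology.k_dihedral_3 * np.sum(1.0 - np.cos(3.0 * dphi)))
        dVdphi = (topology.k_dihedral_1 * np.sin(dphi)
                  + 3.0 * topology.k_dihedral_3 * np.sin(3.0 * dphi))
        # standard torsion gradient (see e.g. van Schaik et al.)
        dphi_di = -(nb2 / n1sq)[:, None] * n1
        dphi_dl = (nb2 / n2sq)[:, None] * n2
        s12 = (np.sum(b1 * b2, axis=1) / nb2 ** 2)[:, None]
        s32 = (np.sum(b3 * b2, axis=1) / nb2 ** 2)[:, None]
        dphi_dj = -(1.0 + s12) * dphi_di + s32 * dphi_dl
        dphi_dk = s12 * dphi_di - (1.0 + s32) * dphi_dl
        _accumulate(forces, d[:, 0], -dVdphi[:, None] * dphi_di)
        _accumulate(forces, d[:, 1], -dVdphi[:, None] * dphi_dj)
        _accumulate(forces, d[:, 2], -dVdphi[:, None] * dphi_dk)
        _accumulate(forces, d[:, 3], -dVdphi[:, None] * dphi_dl)

    return out, forces


def _pair_forces(x, pairs, dVdr_over_r) -> np.ndarray:
    forces = np.zeros_like(x)
    dvec = x[pairs[:, 1]] - x[pairs[:, 0]]
    f = dVdr_over_r[:, None] * dvec
    _accumulate(forces, pairs[:, 0], f)
    _accumulate(forces, pairs[:, 1], -f)
    return forces


def nonbonded_energy(coords: np.ndarray, topology: DualBasinTopology,
                     rep_pairs: np.ndarray | None = None
                     ) -> tuple[dict[str, float], np.ndarray]:
    """Contact (per basin) + repulsive energy and forces.

    ``rep_pairs`` may carry a precomputed :func:`repulsive_pairs` array to
    avoid re-enumeration in hot loops.
    """
    x = np.asarray(coords, dtype=np.float64)
    forces = np.zeros_like(x)
    out = {"contact_S": 0.0, "contact_A": 0.0, "contact_IF": 0.0,
           "repulsive": 0.0}

    cp = topology.contact_pairs
    if len(cp):
        dvec = x[cp[:, 1]] - x[cp[:, 0]]
        r = np.linalg.norm(dvec, axis=1)
        if np.any(r < 1e-10):
            raise ValueError("coincident contact pair")
        q = topology.contact_r0 / r
        e = topology.contact_eps * (5.0 * q ** 12 - 6.0 * q ** 10)
        for basin, key in ((BASIN_S, "contact_S"), (BASIN_A, "contact_A"),
                           (BASIN_IF, "contact_IF")):
            out[key] = float(np.sum(e[topology.contact_basin == basin]))
        dVdr = (60.0 * topology.contact_eps / r) * (q ** 10 - q ** 12)
        f = (dVdr / r)[:, None] * dvec
        _accumulate(forces, cp[:, 0], f)
        _accumulate(forces, cp[:, 1], -f)

    if rep_pairs is None:
        rep_pairs = repulsive_pairs(topology)
    if len(rep_pairs):
        dvec = x[rep_pairs[:, 1]] - x[rep_pairs[:, 0]]
        r = np.linalg.norm(dvec, axis=1)
        if np.any(r < 1e-10):
            raise ValueError("coincident repulsive pair")
        s = topology.repulsion_sigma / r
        out["repulsive"] = float(topology.repulsion_epsilon * np.sum(s ** 12))
        dVdr = -12.0 * topology.repulsion_epsilon * s ** 12 / r
        f = (dVdr / r)[:, None] * dvec
        _accumulate(forces, rep_pairs[:, 0], f)
        _accumulate(forces, rep_pairs[:, 1], -f)

    return out, forces


def total_energy(coords: np.ndarray, topology: DualBasinTopology,
                 rep_pairs: np.ndarray | None = None
                 ) -> tuple[EnergyReport, np.ndarray]:
    """Full energy decomposition and forces; frozen-site forces are zeroed."""
    e_b, f_b = bonded_energy(coords, topology)
    e_nb, f_nb = nonbonded_energy(coords, topology, rep_pairs)
    forces = f_b + f_nb
    forces[topology.frozen_sites] = 0.0
    report = EnergyReport(e_b["bond"], e_b["angle"], e_b["dihedral"],
                          e_nb["contact_S"], e_nb["contact_A"],
                          e_nb["contact_IF"], e_nb["repulsive"])
    if not np.isfinite(report.total):
        raise FloatingPointError("non-finite energy")
    return report, forces
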