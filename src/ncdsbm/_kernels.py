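"""Compiled inner loops: force evaluation and the BBK Langevin chunk runner.

These kernels are numerically identical (bar float summation order) to the
NumPy reference in :mod:`ncdsbm.energetics`; the test suite asserts the
agreement. ``fastmath`` stays off so runs are bit-reproducible for a fixed
seed across invocations.
"""
from __future__ import annotations

from typing import NamedTuple

import numpy as np
from numba import njit

from .model_builder import DualBasinTopology
from .energetics import repulsive_pairs

__all__ = ["FlatTopology", "flatten_topology", "forces_kernel", "run_chunk"]

_BASIN_CODE = {"S": 0, "A": 1, "IF": 2}


class FlatTopology(NamedTuple):
    """Topology unpacked into plain arrays for the compiled kernels."""
    bonds: np.ndarray
    bond_r0: np.ndarray
    k_bond: float
    angles: np.ndarray
    theta0: np.ndarray
    k_angle: float
    dihedrals: np.ndarray
    phi0: np.ndarray
    k_dih1: float
    k_dih3: float
    cpairs: np.ndarray
    cr0: np.ndarray
    ceps: np.ndarray
    cbasin: np.ndarray          # int8 codes: 0=S, 1=A, 2=IF
    rpairs: np.ndarray
    sigma: float
    eps_rep: float
    frozen_mask: np.ndarray     # bool per site


def flatten_topology(topology: DualBasinTopology) -> FlatTopology:
    frozen = np.zeros(topology.n_sites, dtype=np.bool_)
    frozen[topology.frozen_sites] = True
    cbasin = np.array([_BASIN_CODE[b] for b in topology.contact_basin],
                      dtype=np.int8)
    return FlatTopology(
        np.ascontiguousarray(topology.bonds),
        np.ascontiguousarray(topology.bond_r0), float(topology.k_bond),
        np.ascontiguousarray(topology.angles),
        np.ascontiguousarray(topology.angle_theta0), float(topology.k_angle),
        np.ascontiguousarray(topology.dihedrals),
        np.ascontiguousarray(topology.dihedral_phi0),
        float(topology.k_dihedral_1), float(topology.k_dihedral_3),
        np.ascontiguousarray(topology.contact_pairs),
        np.ascontiguousarray(topology.contact_r0),
        np.ascontiguousarray(topology.contact_eps), cbasin,
        np.ascontiguousarray(repulsive_pairs(topology)),
        float(topology.repulsion_sigma), float(topology.repulsion_epsilon),
        frozen)


@njit(cache=False)
def forces_kernel(x, bonds, bond_r0, k_bond, angles, theta0, k_angle,
                  dihedrals, phi0, k_dih1, k_dih3,
                  cpairs, cr0, ceps, cbasin, rpairs, sigma, eps_rep,
                  frozen_mask, forces):
    """Fill ``forces`` (-gradient) and return the 7-component energy vector
    [bond, angle, dihedral, contact_S, contact_A, contact_IF, repulsive]."""
    n = x.shape[0]
    for i in range(n):
        forces[i, 0] = 0.0
        forces[i, 1] = 0.0
        forces[i, 2] = 0.0
    e = np.zeros(7)

    for b in range(bonds.shape[0]):
        i, j = bonds[b, 0], bonds[b, 1]
        dx = x[j, 0] - x[i, 0]
        dy = x[j, 1] - x[i, 1]
        dz = x[j, 2] - x[i, 2]
        r = np.sqrt(dx * dx + dy * dy + dz * dz)
        dr = r - bond_r0[b]
        e[0] += k_bond * dr * dr
        g = 2.0 * k_bond * dr / r
        forces[i, 0] += g * dx
        forces[i, 1] += g * dy
        forces[i, 2] += g * dz
        forces[j, 0] -= g * dx
        forces[j, 1] -= g * dy
        forces[j, 2] -= g * dz

    for a in range(angles.shape[0]):
        i, j, k = angles[a, 0], angles[a, 1], angles[a, 2]
        ux = x[i, 0] - x[j, 0]
        uy = x[i, 1] - x[j, 1]
        uz = x[i, 2] - x[j, 2]
        vx = x[k, 0] - x[j, 0]
        vy = x[k, 1] - x[j, 1]
        vz = x[k, 2] - x[j, 2]
        nu = np.sqrt(ux * ux + uy * uy + uz * uz)
        nv = np.sqrt(vx * vx + vy * vy + vz * vz)
        c = (ux * vx + uy * vy + uz * vz) / (nu * nv)
        if c > 1.0:
            c = 1.0
        elif c < -1.0:
            c = -1.0
        theta = np.arccos(c)
        dth = theta - theta0[a]
        e[1] += k_angle * dth * dth
        s = np.sqrt(max(1.0 - c * c, 1e-12))
        dvdt = 2.0 * k_angle * dth
        fi_x = -dvdt * (c * ux / nu - vx / nv) / (nu * s)
        fi_y = -dvdt * (c * uy / nu - vy / nv) / (nu * s)
        fi_z = -dvdt * (c * uz / nu - vz / nv) / (nu * s)
        fk_x = -dvdt * (c * vx / nv - ux / nu) / (nv * s)
        fk_y = -dvdt * (c * vy / nv - uy / nu) / (nv * s)
        fk_z = -dvdt * (c * vz / nv - uz / nu) / (nv * s)
        forces[i, 0] += fi_x
        forces[i, 1] += fi_y
        forces[i, 2] += fi_z
        forces[k, 0] += fk_x
        forces[k, 1] += fk_y
        forces[k, 2] += fk_z
        forces[j, 0] -= fi_x + fk_x
        forces[j, 1] -= fi_y + fk_y
        forces[j, 2] -= fi_z + fk_z

    for d in range(dihedrals.shape[0]):
        i, j, k, l = dihedrals[d, 0], dihedrals[d, 1], dihedrals[d, 2], dihedrals[d, 3]
        b1x = x[j, 0] - x[i, 0]
        b1y = x[j, 1] - x[i, 1]
        b1z = x[j, 2] - x[i, 2]
        b2x = x[k, 0] - x[j, 0]
        b2y = x[k, 1] - x[j, 1]
        b2z = x[k, 2] - x[j, 2]
        b3x = x[l, 0] - x[k, 0]
        b3y = x[l, 1] - x[k, 1]
        b3z = x[l, 2] - x[k, 2]
        n1x = b1y * b2z - b1z * b2y
        n1y = b1z * b2x - b1x * b2z
        n1z = b1x * b2y - b1y * b2x
        n2x = b2y * b3z - b2z * b3y
        n2y = b2z * b3x - b2x * b3z
        n2z = b2x * b3y - b2y * b3x
        n1sq = n1x * n1x + n1y * n1y + n1z * n1z
        n2sq = n2x * n2x + n2y * n2y + n2z * n2z
        nb2 = np.sqrt(b2x * b2x + b2y * b2y + b2z * b2z)
        cxx = n1y * n2z - n1z * n2y
        cxy = n1z * n2x - n1x * n2z
        cxz = n1x * n2y - n1y * n2x
        y = (cxx * b2x + cxy * b2y + cxz * b2z) / nb2
        xx = n1x * n2x + n1y * n2y + n1z * n2z
        phi = np.arctan2(y, xx)
        dphi = phi - phi0[d]
        e[2] += k_dih1 * (1.0 - np.cos(dphi)) + k_dih3 * (1.0 - np.cos(3.0 * dphi))
        dvdphi = k_dih1 * np.sin(dphi) + 3.0 * k_dih3 * np.sin(3.0 * dphi)
        gi = -nb2 / n1sq
        gl = nb2 / n2sq
        di_x = gi * n1x
        di_y = gi * n1y
        di_z = gi * n1z
        dl_x = gl * n2x
        dl_y = gl * n2y
        dl_z = gl * n2z
        s12 = (b1x * b2x + b1y * b2y + b1z * b2z) / (nb2 * nb2)
        s32 = (b3x * b2x + b3y * b2y + b3z * b2z) / (nb2 * nb2)
        dj_x = -(1.0 + s12) * di_x + s32 * dl_x
        dj_y = -(1.0 + s12) * di_y + s32 * dl_y
        dj_z = -(1.0 + s12) * di_z + s32 * dl_z
        dk_x = s12 * di_x - (1.0 + s32) * dl_x
        dk_y = s12 * di_y - (1.0 + s32) * dl_y
        dk_z = s12 * di_z - (1.0 + s32) * dl_z
        forces[i, 0] -= dvdphi * di_x
        forces[i, 1] -= dvdphi * di_y
        forces[i, 2] -= dvdphi * di_z
        forces[j, 0] -= dvdphi * dj_x
        forces[j, 1] -= dvdphi * dj_y
        forces[j, 2] -= dvdphi * dj_z
        forces[k, 0] -= dvdphi * dk_x
        forces[k, 1] -= dvdphi * dk_y
        forces[k, 2] -= dvdphi * dk_z
        forces[l, 0] -= dvdphi * dl_x
        forces[l, 1] -= dvdphi * dl_y
        forces[l, 2] -= dvdphi * dl_z

    for c_ in range(cpairs.shape[0]):
        i, j = cpairs[c_, 0], cpairs[c_, 1]
        dx = x[j, 0] - x[i, 0]
        dy = x[j, 1] - x[i, 1]
        dz = x[j, 2] - x[i, 2]
        r = np.sqrt(dx * dx + dy * dy + dz * dz)
        q = cr0[c_] / r
        q2 = q * q
        q10 = q2 * q2 * q2 * q2 * q2
        q12 = q10 * q2
        e[3 + cbasin[c_]] += ceps[c_] * (5.0 * q12 - 6.0 * q10)
        dvdr = (60.0 * ceps[c_] / r) * (q10 - q12)
        g = dvdr / r
        forces[i, 0] += g * dx
        forces[i, 1] += g * dy
        forces[i, 2] += g * dz
        forces[j, 0] -= g * dx
        forces[j, 1] -= g * dy
        forces[j, 2] -= g * dz

    for p in range(rpairs.shape[0]):
        i, j = rpairs[p, 0], rpairs[p, 1]
        dx = x[j, 0] - x[i, 0]
        dy = x[j, 1] - x[i, 1]
        dz = x[j, 2] - x[i, 2]
        r = np.sqrt(dx * dx + dy * dy + dz * dz)
        s = sigma / r
        s2 = s * s
        s12 = s2 * s2 * s2 * s2 * s2 * s2
        e[6] += eps_rep * s12
        dvdr = -12.0 * eps_rep * s12 / r
        g = dvdr / r
        forces[i, 0] += g * dx
        forces[i, 1] += g * dy
        forces[i, 2] += g * dz
        forces[j, 0] -= g * dx
        forces[j, 1] -= g * dy
        forces[j, 2] -= g * dz

    for i in range(n):
        if frozen_mask[i]:
            forces[i, 0] = 0.0
            forces[i, 1] = 0.0
            forces[i, 2] = 0.0
    return e


@njit(cache=False)
def run_chunk(x, v, forces, noise, h, zeta, mass,
              bonds, bond_r0, k_bond, angles, theta0, k_angle,
              dihedrals, phi0, k_dih1, k_dih3,
              cpairs, cr0, ceps, cbasin, rpairs, sigma, eps_rep,
              frozen_mask, save_every, step_offset, frames, energies):
    """Advance BBK Langevin dynamics by ``noise.shape[0] - 1`` steps in place.

    ``noise`` holds one pre-drawn random-force row per step plus one carry
    row; row ``s`` enters both the second half-kick of step ``s-1`` and the
    first half-kick of step ``s``, so chunks chain exactly when the caller
    reuses the last row as the next chunk's first. Frames/energies are
    recorded whenever the global step index is a multiple of ``save_every``.
    Returns the number of frames written.
    """
    n = x.shape[0]
    nsteps = noise.shape[0] - 1
    c = zeta * h / (2.0 * mass)
    hm = h / (2.0 * mass)
    nsaved = 0
    for step in range(nsteps):
        for i in range(n):
            if frozen_mask[i]:
                continue
            v[i, 0] = v[i, 0] * (1.0 - c) + hm * (forces[i, 0] + noise[step, i, 0])
            v[i, 1] = v[i, 1] * (1.0 - c) + hm * (forces[i, 1] + noise[step, i, 1])
            v[i, 2] = v[i, 2] * (1.0 - c) + hm * (forces[i, 2] + noise[step, i, 2])
            x[i, 0] += h * v[i, 0]
            x[i, 1] += h * v[i, 1]
            x[i, 2] += h * v[i, 2]
        e = forces_kernel(x, bonds, bond_r0, k_bond, angles, theta0, k_angle,
                          dihedrals, phi0, k_dih1, k_dih3,
                          cpairs, cr0, ceps, cbasin, rpairs, sigma, eps_rep,
                          frozen_mask, forces)
        for i in range(n):
            if frozen_mask[i]:
                continue
            v[i, 0] = (v[i, 0] + hm * (forces[i, 0] + noise[step + 1, i, 0])) / (1.0 + c)
            v[i, 1] = (v[i, 1] + hm * (forces[i, 1] + noise[step + 1, i, 1])) / (1.0 + c)
            v[i, 2] = (v[i, 2] + hm * (forces[i, 2] + noise[step + 1, i, 2])) / (1.0 + c)
        gstep = step_offset + step + 1
        if gstep % save_every == 0:
            for i in range(n):
                frames[nsaved, i, 0] = x[i, 0]
                frames[nsaved, i, 1] = x[i, 1]
                frames[nsaved, i, 2] = x[i, 2]
            for q in range(7):
                energies[nsaved, q] = e[q]
            nsaved += 1
    return nsaved
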