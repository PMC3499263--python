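"""Vectorized internal-coordinate geometry (bond lengths, bend and torsion angles)."""
from __future__ import annotations

import numpy as np

__all__ = ["bond_lengths", "bend_angles", "torsion_angles"]


def bond_lengths(coords: np.ndarray, pairs: np.ndarray) -> np.ndarray:
    """Distances |r_j - r_i| for (n, 2) index pairs, Å."""
    if len(pairs) == 0:
        return np.zeros(0)
    d = coords[pairs[:, 1]] - coords[pairs[:, 0]]
    return np.linalg.norm(d, axis=1)


def bend_angles(coords: np.ndarray, triples: np.ndarray) -> np.ndarray:
    """Angle at the middle site of each (i, j, k) triple, radians in [0, π]."""
    if len(triples) == 0:
        return np.zeros(0)
    u = coords[triples[:, 0]] - coords[triples[:, 1]]
    v = coords[triples[:, 2]] - coords[triples[:, 1]]
    nu = np.linalg.norm(u, axis=1)
    nv = np.linalg.norm(v, axis=1)
    if np.any(nu == 0) or np.any(nv == 0):
        raise ValueError("coincident sites in angle triple")
    cosang = np.sum(u * v, axis=1) / (nu * nv)
    return np.arccos(np.clip(cosang, -1.0, 1.0))


def torsion_angles(coords: np.ndarray, quads: np.ndarray) -> np.ndarray:
    """Dihedral angle of each (i, j, k, l) quad, radians in (-π, π].

    Raises ValueError for collinear inner triples (undefined torsion).
    """
    if len(quads) == 0:
        return np.zeros(0)
    b1 = coords[quads[:, 1]] - coords[quads[:, 0]]
    b2 = coords[quads[:, 2]] - coords[quads[:, 1]]
    b3 = coords[quads[:, 3]] - coords[quads[:, 2]]
    n1 = np.cross(b1, b2)
    n2 = np.cross(b2, b3)
    if np.any(np.linalg.norm(n1, axis=1) < 1e-10) \
            or np.any(np.linalg.norm(n2, axis=1) < 1e-10):
        raise ValueError("collinear sites: torsion undefined")
    b2n = b2 / np.linalg.norm(b2, axis=1)[:, None]
    x = np.sum(n1 * n2, axis=1)
    y = np.sum(np.cross(n1, n2) * b2n, axis=1)
    return np.arctan2(y, x)
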