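"""Analysis observables for dual-basin motor trajectories.

Covers the quantities used to characterize the symmetric/asymmetric
equilibrium and the power stroke: inter-residue distance series, the stalk
orientation angle θ, per-basin formed-contact counts, nucleotide-pocket
RMSD, free-energy surfaces F = −k_BT log P, the stall-force bound from a
1-D potential of mean force over the stalk-tip position, and principal
component analysis of superposed coordinates (essential dynamics).
"""
from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from . import constants as C
from .model_builder import DualBasinTopology, BASIN_S, BASIN_A
from .structure_io import CaStructure, superpose
from .dynamics import TrajectoryEnsemble

__all__ = [
    "FreeEnergySurface", "PCAResult",
    "residue_distance_series", "theta_angle_series",
    "contact_formed_mask", "head_stalk_contact_count",
    "pocket_rmsd_series", "free_energy_surface", "stall_force_estimate",
    "track_axis", "pca_modes",
]


# --------------------------------------------------------------------------
# containers

@dataclass
class FreeEnergySurface:
    """Binned −log P over 1 or 2 order parameters, in k_BT units.

    The minimum is shifted to zero; empty bins carry F = +inf.
    """
    bin_edges: list[np.ndarray]
    free_energy: np.ndarray
    counts: np.ndarray
    n_frames: int

    @property
    def ndim(self) -> int:
        return len(self.bin_edges)

    def bin_centers(self, dim: int = 0) -> np.ndarray:
        e = self.bin_edges[dim]
        return 0.5 * (e[:-1] + e[1:])

    def probabilities(self) -> np.ndarray:
        """Re-exponentiate F back to normalized bin probabilities."""
        p = np.where(np.isfinite(self.free_energy),
                     np.exp(-np.where(np.isfinite(self.free_energy),
                                      self.free_energy, 0.0)), 0.0)
        return p / p.sum()


@dataclass
class PCAResult:
    """Essential-dynamics decomposition of superposed coordinates."""
    eigenvalues: np.ndarray       # Å², descending
    modes: np.ndarray             # (n_modes, n_sites, 3), unit norm
    mean_structure: np.ndarray    # (n_sites, 3)

    def project(self, frames: np.ndarray, mode: int = 0) -> np.ndarray:
        """Scalar projections of (already superposed) frames onto one mode."""
        disp = frames - self.mean_structure
        return np.tensordot(disp, self.modes[mode], axes=([1, 2], [0, 1]))

    def to_multi_model_pdb(self, topology: DualBasinTopology, mode: int = 0,
                           amplitude: float | None = None,
                           n_models: int = 7,
                           sites: np.ndarray | None = None) -> str:
        """Porcupine-style visualization: mean structure swept ± one mode.

        ``amplitude`` defaults to two standard deviations of the mode
        (2·sqrt(eigenvalue)). Models interpolate mean − a·v … mean + a·v.
        """
        from .structure_io import write_ca_structure
        if amplitude is None:
            amplitude = 2.0 * float(np.sqrt(self.eigenvalues[mode]))
        if sites is None:
            sites = np.arange(len(self.mean_structure))
        sites = np.asarray(sites, dtype=np.int64)
        blocks = []
        for m, a in enumerate(np.linspace(-amplitude, amplitude, n_models),
                              start=1):
            coords = self.mean_structure + a * self.modes[mode]
            body = write_ca_structure(CaStructure(
                topology.residue_ids[sites], topology.chain_ids[sites],
                topology.residue_names[sites], coords))
            lines = [ln for ln in body.splitlines()
                     if ln.startswith(("ATOM", "TER"))]
            blocks.append(f"MODEL     {m:4d}\n" + "\n".join(lines) + "\nENDMDL")
        return "\n".join(blocks) + "\nEND\n"


# --------------------------------------------------------------------------
# series

def _site(traj: TrajectoryEnsemble, residue: tuple[str, int] | int) -> int:
    top = traj.topology
    if isinstance(residue, tuple):
        chain, rid = residue
        hits = np.nonzero((top.chain_ids == chain) & (top.residue_ids == rid))[0]
    else:
        hits = np.nonzero(top.residue_ids == residue)[0]
        if hits.size > 1:
            raise KeyError(f"residue {residue} is ambiguous; pass (chain, id)")
    if hits.size == 0:
        raise KeyError(f"residue {residue} not found in topology")
    return int(hits[0])


def residue_distance_series(traj: TrajectoryEnsemble,
                            resid_a: tuple[str, int] | int,
                            resid_b: tuple[str, int] | int) -> np.ndarray:
    """Per-frame Euclidean distance between two residues, Å.

    Residues are addressed as (chain, author residue number); a bare number
    is accepted when unambiguous.
    """
    pa = traj.site_series(_site(traj, resid_a))
    pb = traj.site_series(_site(traj, resid_b))
    return np.linalg.norm(pa - pb, axis=1)


def theta_angle_series(traj: TrajectoryEnsemble,
                       apex: tuple[str, int] | int,
                       arm1: tuple[str, int] | int,
                       arm2: tuple[str, int] | int) -> np.ndarray:
    """Per-frame angle (degrees, [0, 180]) at ``apex`` between the two arms.

    For the stalk-orientation angle of the track-bound dimer the apex is
    D424 of the bound monomer and the arms are LEU296 (unbound monomer) and
    E567 (bound monomer).
    """
    a = traj.site_series(_site(traj, apex))
    u = traj.site_series(_site(traj, arm1)) - a
    v = traj.site_series(_site(traj, arm2)) - a
    nu = np.linalg.norm(u, axis=1)
    nv = np.linalg.norm(v, axis=1)
    if np.any(nu < 1e-10) or np.any(nv < 1e-10):
        raise ValueError("coincident points in angle definition")
    cosang = np.clip(np.sum(u * v, axis=1) / (nu * nv), -1.0, 1.0)
    return np.degrees(np.arccos(cosang))


# --------------------------------------------------------------------------
# contacts

def contact_formed_mask(coords: np.ndarray, topology: DualBasinTopology,
                        tolerance: float = 1.2) -> np.ndarray:
    """Boolean per contact: formed when r < tolerance × r0."""
    if tolerance < 1.0:
        raise ValueError("tolerance must be >= 1")
    cp = topology.contact_pairs
    r = np.linalg.norm(coords[cp[:, 1]] - coords[cp[:, 0]], axis=1)
    return r < tolerance * topology.contact_r0


def head_stalk_contact_count(coords: np.ndarray, topology: DualBasinTopology,
                             boundary: int = C.HEAD_STALK_BOUNDARY,
                             tolerance: float = 1.2
                             ) -> dict[str, dict[str, int]]:
    """Formed head–stalk contact counts per monomer chain and basin.

    A head–stalk contact is an intra-chain contact with one author residue
    number below ``boundary`` (neck/stalk) and the other at or above it
    (motor head). Returns ``{chain: {"S": n, "A": n}}``.
    """
    formed = contact_formed_mask(coords, topology, tolerance)
    cp = topology.contact_pairs
    rid_i = topology.residue_ids[cp[:, 0]]
    rid_j = topology.residue_ids[cp[:, 1]]
    ch_i = topology.chain_ids[cp[:, 0]]
    spanning = (ch_i == topology.chain_ids[cp[:, 1]]) & (
        ((rid_i < boundary) & (rid_j >= boundary))
        | ((rid_j < boundary) & (rid_i >= boundary)))
    out: dict[str, dict[str, int]] = {}
    for chain in np.unique(ch_i[spanning]):
        sel = spanning & (ch_i == chain)
        out[str(chain)] = {
            BASIN_S: int(np.sum(formed & sel & (topology.contact_basin == BASIN_S))),
            BASIN_A: int(np.sum(formed & sel & (topology.contact_basin == BASIN_A))),
        }
    return out


def pocket_rmsd_series(traj: TrajectoryEnsemble, reference: CaStructure,
                       pocket: list[tuple[str, int]],
                       head: list[tuple[str, int]] | None = None
                       ) -> np.ndarray:
    """Per-frame RMSD of pocket residues after head superposition.

    Each frame's motor head (``head`` residues; defaults to the whole chain
    of the first pocket residue) is superposed onto ``reference``, then the
    RMSD is evaluated over ``pocket`` residues only — so a pocket that
    moves rigidly with its head scores 0. ``reference`` must share site
    ordering with the trajectory topology (the native conformer does).
    """
    top = traj.topology

    def site_list(residues):
        return np.array([_site(traj, r) for r in residues], dtype=np.int64)

    pocket_idx = site_list(pocket)
    if head is None:
        chain = top.chain_ids[pocket_idx[0]]
        head_idx = np.nonzero(top.chain_ids == chain)[0]
    else:
        head_idx = site_list(head)
    pairs = np.column_stack([head_idx, head_idx])
    ref_pocket = reference.coords[pocket_idx]
    out = np.empty(traj.n_frames)
    frame_struct = CaStructure(top.residue_ids, top.chain_ids,
                               top.residue_names, np.zeros((top.n_sites, 3)))
    for f in range(traj.n_frames):
        frame_struct.coords = traj.full_coords(f)
        rot, trans, _ = superpose(frame_struct, reference, pairs)
        fitted = frame_struct.coords[pocket_idx] @ rot.T + trans
        out[f] = np.sqrt(np.mean(np.sum((fitted - ref_pocket) ** 2, axis=1)))
    return out


# --------------------------------------------------------------------------
# free energy

def free_energy_surface(series, bins=None,
                        range_=None) -> FreeEnergySurface:
    """Histogram one or two order-parameter series into F = −log P (k_BT).

    ``series`` is a 1-D array or a pair of equal-length arrays. Default
    binning is Freedman–Diaconis in 1-D and 50×50 in 2-D.
    """
    if isinstance(series, (tuple, list)) and len(series) == 2 \
            and np.ndim(series[0]) == 1:
        a = np.asarray(series[0], dtype=float)
        b = np.asarray(series[1], dtype=float)
        if a.size == 0:
            raise ValueError("empty series")
        if bins is None:
            bins = 50
        counts, ex, ey = np.histogram2d(a, b, bins=bins, range=range_)
        edges = [ex, ey]
        n = a.size
    else:
        a = np.asarray(series, dtype=float).ravel()
        if a.size == 0:
            raise ValueError("empty series")
        if bins is None:
            bins = np.histogram_bin_edges(a, bins="fd")
            if len(bins) < 2:
                bins = 1
        counts, e = np.histogram(a, bins=bins, range=range_)
        edges = [e]
        n = a.size
    with np.errstate(divide="ignore"):
        f = -np.log(counts / counts.sum())
    f = np.where(counts > 0, f, np.inf)
    f -= f[np.isfinite(f)].min()
    return FreeEnergySurface(edges, f, counts.astype(np.int64), int(n))


def stall_force_estimate(fz: FreeEnergySurface,
                         temperature: float = C.TEMPERATURE,
                         method: str = "max_slope") -> float:
    """Lower-bound stall force (pN) from a 1-D PMF over the stalk tip z (Å).

    ``max_slope`` takes the largest |ΔF/Δz| between adjacent finite bins;
    ``endpoint`` uses the overall ΔF between the first and last finite bin
    divided by their separation. Conversion: 1 kcal/(mol·Å) = 69.48 pN.
    """
    if fz.ndim != 1:
        raise ValueError("stall force needs a one-dimensional PMF")
    z = fz.bin_centers()
    finite = np.isfinite(fz.free_energy)
    if finite.sum() < 2:
        raise ValueError("need at least 2 finite bins")
    zf = z[finite]
    ff = fz.free_energy[finite]
    if method == "max_slope":
        slope_kt = np.max(np.abs(np.diff(ff) / np.diff(zf)))
    elif method == "endpoint":
        slope_kt = abs((ff[-1] - ff[0]) / (zf[-1] - zf[0]))
    else:
        raise ValueError(f"unknown method {method!r}")
    kcal_per_ang = slope_kt * C.KB * temperature
    return float(kcal_per_ang * C.KCAL_PER_MOL_ANG_IN_PN)


def track_axis(track_coords: np.ndarray) -> np.ndarray:
    """Unit principal axis of the frozen track beads (the filament axis).

    The sign convention (plus-end direction) comes from the lattice
    builder's metadata; this helper returns the axis oriented along
    increasing coordinate of the dominant component.
    """
    x = np.asarray(track_coords, dtype=float)
    c = x - x.mean(axis=0)
    _, _, vt = np.linalg.svd(c, full_matrices=False)
    axis = vt[0]
    if axis[np.argmax(np.abs(axis))] < 0:
        axis = -axis
    return axis


# --------------------------------------------------------------------------
# PCA

def pca_modes(traj: TrajectoryEnsemble, reference: CaStructure,
              n_modes: int = 2,
              sites: np.ndarray | None = None) -> PCAResult:
    """Principal components of the superposed-coordinate covariance.

    Every frame is rigidly superposed onto ``reference`` over ``sites``
    (default: all trajectory sites), the 3N×3N covariance of those sites is
    diagonalized, and the largest-variance ("low frequency") modes are
    returned. Modes beyond the covariance rank have eigenvalue ≈ 0.
    """
    if traj.n_frames < 2:
        raise ValueError("PCA needs more than one frame")
    top = traj.topology
    if sites is None:
        sites = np.arange(top.n_sites)
    sites = np.asarray(sites, dtype=np.int64)
    pairs = np.column_stack([sites, sites])
    frame_struct = CaStructure(top.residue_ids, top.chain_ids,
                               top.residue_names, np.zeros((top.n_sites, 3)))
    fitted = np.empty((traj.n_frames, len(sites), 3))
    for f in range(traj.n_frames):
        frame_struct.coords = traj.full_coords(f)
        rot, trans, _ = superpose(frame_struct, reference, pairs)
        fitted[f] = frame_struct.coords[sites] @ rot.T + trans
    mean = fitted.mean(axis=0)
    disp = (fitted - mean).reshape(traj.n_frames, -1)
    cov = disp.T @ disp / traj.n_frames
    evals, evecs = np.linalg.eigh(cov)
    order = np.argsort(evals)[::-1]
    evals = np.clip(evals[order], 0.0, None)
    evecs = evecs[:, order]
    n_modes = min(n_modes, len(evals))
    modes = evecs[:, :n_modes].T.reshape(n_modes, len(sites), 3)
    return PCAResult(evals, modes, mean)
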