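"""Dual-basin topology construction.

The model combines native-contact information from two conformers of the
same molecule. Bonded terms (bonds, angles, dihedrals) take their native
values from the primary ("symmetric") conformer only. The contact list
carries a basin label per pair:

* ``S`` — native in the symmetric conformer (pairs native in both
  conformers are labeled S and use the symmetric distance),
* ``A`` — native only in the asymmetric conformer (the perturbative bias),
* ``IF`` — motor-track interface contacts of the bound complex.

Pairs native in neither basin interact through a purely repulsive
excluded-volume term.
"""
from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field

import numpy as np
from scipy.spatial.distance import cdist

from . import constants as C
from .structure_io import CaStructure, superpose, apply_transform

logger = logging.getLogger(__name__)

__all__ = [
    "DualBasinTopology",
    "compute_contact_map",
    "build_dual_basin_topology",
    "assign_epsilons",
    "build_mt_bound_complex",
    "delete_junction_contacts",
]

BASIN_S, BASIN_A, BASIN_IF = "S", "A", "IF"


@dataclass
class DualBasinTopology:
    """Bonds/angles/dihedrals with native values plus a labeled contact list.

    Site metadata (residue ids, chain ids, residue names) mirrors the
    reference structure the topology was built from, so contacts can be
    addressed by author residue numbers. ``frozen_sites`` lists track beads
    whose coordinates never move.
    """

    residue_ids: np.ndarray
    chain_ids: np.ndarray
    residue_names: np.ndarray
    native_coords: np.ndarray          # symmetric-conformer reference, Å

    bonds: np.ndarray                  # (nb, 2) int
    bond_r0: np.ndarray                # Å
    angles: np.ndarray                 # (na, 3) int
    angle_theta0: np.ndarray           # rad
    dihedrals: np.ndarray              # (nd, 4) int
    dihedral_phi0: np.ndarray          # rad

    contact_pairs: np.ndarray          # (nc, 2) int, i < j
    contact_basin: np.ndarray          # (nc,) str in {S, A, IF}
    contact_r0: np.ndarray             # Å
    contact_eps: np.ndarray            # kcal/mol

    k_bond: float = C.K_BOND
    k_angle: float = C.K_ANGLE
    k_dihedral_1: float = C.K_DIHEDRAL_1
    k_dihedral_3: float = C.K_DIHEDRAL_3
    repulsion_sigma: float = C.REPULSION_SIGMA
    repulsion_epsilon: float = C.REPULSION_EPSILON
    min_separation: int = C.MIN_SEQ_SEPARATION
    frozen_sites: np.ndarray = field(default_factory=lambda: np.array([], dtype=np.int64))

    def __post_init__(self) -> None:
        self.residue_ids = np.asarray(self.residue_ids, dtype=np.int64)
        self.chain_ids = np.asarray(self.chain_ids, dtype="U4")
        self.residue_names = np.asarray(self.residue_names, dtype="U3")
        self.native_coords = np.asarray(self.native_coords, dtype=np.float64)
        self.bonds = np.asarray(self.bonds, dtype=np.int64).reshape(-1, 2)
        self.bond_r0 = np.asarray(self.bond_r0, dtype=np.float64)
        self.angles = np.asarray(self.angles, dtype=np.int64).reshape(-1, 3)
        self.angle_theta0 = np.asarray(self.angle_theta0, dtype=np.float64)
        self.dihedrals = np.asarray(self.dihedrals, dtype=np.int64).reshape(-1, 4)
        self.dihedral_phi0 = np.asarray(self.dihedral_phi0, dtype=np.float64)
        self.contact_pairs = np.asarray(self.contact_pairs, dtype=np.int64).reshape(-1, 2)
        self.contact_basin = np.asarray(self.contact_basin, dtype="U2")
        self.contact_r0 = np.asarray(self.contact_r0, dtype=np.float64)
        self.contact_eps = np.asarray(self.contact_eps, dtype=np.float64)
        self.frozen_sites = np.asarray(self.frozen_sites, dtype=np.int64)

    @property
    def n_sites(self) -> int:
        return len(self.residue_ids)

    @property
    def mobile_sites(self) -> np.ndarray:
        mask = np.ones(self.n_sites, dtype=bool)
        mask[self.frozen_sites] = False
        return np.nonzero(mask)[0]

    def validate(self) -> None:
        pairs = {tuple(p) for p in self.contact_pairs}
        if len(pairs) != len(self.contact_pairs):
            raise ValueError("duplicate contact pair")
        if np.any(self.contact_r0 <= 0) or np.any(self.contact_eps <= 0):
            raise ValueError("contact r0 and epsilon must be positive")
        same_chain = (self.chain_ids[self.contact_pairs[:, 0]]
                      == self.chain_ids[self.contact_pairs[:, 1]])
        sep = np.abs(self.residue_ids[self.contact_pairs[:, 0]]
                     - self.residue_ids[self.contact_pairs[:, 1]])
        if np.any(same_chain & (sep <= self.min_separation)):
            raise ValueError("intra-chain contact violates sequence separation")

    def basin_mask(self, basin: str) -> np.ndarray:
        return self.contact_basin == basin

    def copy(self) -> "DualBasinTopology":
        return DualBasinTopology(
            self.residue_ids.copy(), self.chain_ids.copy(),
            self.residue_names.copy(), self.native_coords.copy(),
            self.bonds.copy(), self.bond_r0.copy(),
            self.angles.copy(), self.angle_theta0.copy(),
            self.dihedrals.copy(), self.dihedral_phi0.copy(),
            self.contact_pairs.copy(), self.contact_basin.copy(),
            self.contact_r0.copy(), self.contact_eps.copy(),
            self.k_bond, self.k_angle, self.k_dihedral_1, self.k_dihedral_3,
            self.repulsion_sigma, self.repulsion_epsilon, self.min_separation,
            self.frozen_sites.copy())

    # ---- serialization ---------------------------------------------------
    def to_json(self) -> str:
        def arr(a):
            return a.tolist()
        doc = {
            "sites": {
                "residue_ids": arr(self.residue_ids),
                "chain_ids": arr(self.chain_ids),
                "residue_names": arr(self.residue_names),
                "native_coords": arr(self.native_coords),
            },
            "bonds": {"pairs": arr(self.bonds), "r0": arr(self.bond_r0)},
            "angles": {"triples": arr(self.angles), "theta0": arr(self.angle_theta0)},
            "dihedrals": {"quads": arr(self.dihedrals), "phi0": arr(self.dihedral_phi0)},
            "contacts": {
                "pairs": arr(self.contact_pairs),
                "basin": arr(self.contact_basin),
                "r0": arr(self.contact_r0),
                "eps": arr(self.contact_eps),
            },
            "params": {
                "k_bond": self.k_bond, "k_angle": self.k_angle,
                "k_dihedral_1": self.k_dihedral_1,
                "k_dihedral_3": self.k_dihedral_3,
                "repulsion_sigma": self.repulsion_sigma,
                "repulsion_epsilon": self.repulsion_epsilon,
                "min_separation": self.min_separation,
            },
            "frozen_sites": arr(self.frozen_sites),
        }
        return json.dumps(doc)

    @classmethod
    def from_json(cls, text: str) -> "DualBasinTopology":
        doc = json.loads(text)
        p = doc["params"]
        return cls(
            doc["sites"]["residue_ids"], doc["sites"]["chain_ids"],
            doc["sites"]["residue_names"], doc["sites"]["native_coords"],
            doc["bonds"]["pairs"], doc["bonds"]["r0"],
            doc["angles"]["triples"], doc["angles"]["theta0"],
            doc["dihedrals"]["quads"], doc["dihedrals"]["phi0"],
            doc["contacts"]["pairs"], doc["contacts"]["basin"],
            doc["contacts"]["r0"], doc["contacts"]["eps"],
            p["k_bond"], p["k_angle"], p["k_dihedral_1"], p["k_dihedral_3"],
            p["repulsion_sigma"], p["repulsion_epsilon"], p["min_separation"],
            doc["frozen_sites"])


def compute_contact_map(structure: CaStructure, cutoff: float = C.CONTACT_CUTOFF,
                        min_separation: int = C.MIN_SEQ_SEPARATION
                        ) -> list[tuple[int, int, float]]:
    """Native contacts: ordered site pairs ``i < j`` with distance < cutoff.

    Within a chain, pairs must be separated by more than ``min_separation``
    residues (author numbering); all inter-chain pairs under the cutoff are
    eligible.
    """
    if structure.n_sites == 0:
        raise ValueError("empty structure")
    if cutoff <= 0:
        raise ValueError("cutoff must be positive")
    d = cdist(structure.coords, structure.coords)
    same_chain = structure.chain_ids[:, None] == structure.chain_ids[None, :]
    sep = np.abs(structure.residue_ids[:, None] - structure.residue_ids[None, :])
    eligible = np.triu(d < cutoff, k=1)
    eligible &= ~(same_chain & (sep <= min_separation))
    ii, jj = np.nonzero(eligible)
    return [(int(i), int(j), float(d[i, j])) for i, j in zip(ii, jj)]


def _bonded_terms(structure: CaStructure,
                  bonded_chains: list[str] | None = None) -> tuple:
    """Enumerate consecutive bonds/angles/dihedrals per chain with native values."""
    from .geometry import bond_lengths, bend_angles, torsion_angles

    bonds, angles, dihedrals = [], [], []
    for chain in structure.chains():
        if bonded_chains is not None and chain not in bonded_chains:
            continue
        idx = structure.chain_slice(chain)
        for a, b in zip(idx[:-1], idx[1:]):
            bonds.append((a, b))
        for a, b, c in zip(idx[:-2], idx[1:-1], idx[2:]):
            angles.append((a, b, c))
        for a, b, c, d in zip(idx[:-3], idx[1:-2], idx[2:-1], idx[3:]):
            dihedrals.append((a, b, c, d))
    bonds = np.array(bonds, dtype=np.int64).reshape(-1, 2)
    angles = np.array(angles, dtype=np.int64).reshape(-1, 3)
    dihedrals = np.array(dihedrals, dtype=np.int64).reshape(-1, 4)
    x = structure.coords
    r0 = bond_lengths(x, bonds)
    theta0 = bend_angles(x, angles)
    phi0 = torsion_angles(x, dihedrals)
    return bonds, r0, angles, theta0, dihedrals, phi0


def build_dual_basin_topology(symmetric: CaStructure,
                              asymmetric: CaStructure,
                              site_map: np.ndarray | list | None = None,
                              cutoff: float = C.CONTACT_CUTOFF,
                              min_separation: int = C.MIN_SEQ_SEPARATION,
                              neck_threshold: int | None = None,
                              epsilon_high: float = C.EPSILON_HIGH,
                              epsilon_low: float = C.EPSILON_LOW,
                              epsilon_asymmetric: float = C.EPSILON_ASYMMETRIC,
                              bonded_chains: list[str] | None = None,
                              ) -> DualBasinTopology:
    """Combine two conformers of the same chain into a dual-basin topology.

    Bonded native values come from ``symmetric``. The contact list is the
    union of the symmetric map (basin S, symmetric distances) and the pairs
    present only in the asymmetric map (basin A, asymmetric distances).

    Parameters
    ----------
    site_map : (m, 2) int array of (asymmetric_site, symmetric_site)
        correspondences, a list of such arrays (e.g. to apply the contacts
        of one distorted monomer to both monomers of a homodimer), or None
        for the identity map of equally sized conformers. Every site present
        in both conformers must be covered.
    neck_threshold : author residue number below which both partners of a
        contact get ``epsilon_high``; None disables the rule.
    bonded_chains : chains that receive bond/angle/dihedral terms (None =
        all); rigid track chains are excluded by the complex builders.
    """
    if site_map is None:
        if symmetric.n_sites != asymmetric.n_sites:
            raise ValueError("site_map required when conformer sizes differ")
        maps = [np.column_stack([np.arange(asymmetric.n_sites),
                                 np.arange(symmetric.n_sites)])]
    elif isinstance(site_map, list):
        maps = [np.asarray(m, dtype=np.int64) for m in site_map]
    else:
        maps = [np.asarray(site_map, dtype=np.int64)]

    covered = np.zeros(asymmetric.n_sites, dtype=bool)
    for m in maps:
        covered[m[:, 0]] = True
    if not covered.all():
        missing = np.nonzero(~covered)[0]
        raise ValueError(
            "site_map does not cover asymmetric sites (residues "
            + ", ".join(f"{asymmetric.chain_ids[i]}:{asymmetric.residue_ids[i]}"
                        for i in missing[:10])
            + ("..." if missing.size > 10 else "") + ")")

    bonds, r0, angles, theta0, dihedrals, phi0 = _bonded_terms(
        symmetric, bonded_chains)

    s_contacts = compute_contact_map(symmetric, cutoff, min_separation)
    s_set = {(i, j): d for i, j, d in s_contacts}

    a_contacts = compute_contact_map(asymmetric, cutoff, min_separation)
    a_set: dict[tuple[int, int], float] = {}
    for m in maps:
        lut = dict(zip(m[:, 0].tolist(), m[:, 1].tolist()))
        for i, j, d in a_contacts:
            if i in lut and j in lut:
                p, q = sorted((lut[i], lut[j]))
                key = (p, q)
                if key not in s_set and key not in a_set:
                    a_set[key] = d

    pairs = [list(k) for k in s_set] + [list(k) for k in a_set]
    basin = [BASIN_S] * len(s_set) + [BASIN_A] * len(a_set)
    dist = list(s_set.values()) + list(a_set.values())

    top = DualBasinTopology(
        symmetric.residue_ids, symmetric.chain_ids, symmetric.residue_names,
        symmetric.coords,
        bonds, r0, angles, theta0, dihedrals, phi0,
        np.array(pairs, dtype=np.int64).reshape(-1, 2),
        np.array(basin, dtype="U2"), np.array(dist), np.ones(len(dist)),
        min_separation=min_separation)
    return assign_epsilons(top, neck_threshold=neck_threshold,
                           epsilon_high=epsilon_high, epsilon_low=epsilon_low,
                           epsilon_asymmetric=epsilon_asymmetric)


def assign_epsilons(topology: DualBasinTopology,
                    neck_threshold: int | None = C.NECK_THRESHOLD,
                    epsilon_high: float = C.EPSILON_HIGH,
                    epsilon_low: float = C.EPSILON_LOW,
                    epsilon_asymmetric: float = C.EPSILON_ASYMMETRIC
                    ) -> DualBasinTopology:
    """Assign contact well depths.

    Interface (IF) contacts and contacts whose both partners carry an author
    residue number below ``neck_threshold`` (the upper neck / coiled-coil
    region) get ``epsilon_high`` to secure coiled-coil association and track
    binding; remaining A-basin contacts get ``epsilon_asymmetric``; all other
    contacts get ``epsilon_low``.
    """
    top = topology.copy()
    eps = np.full(len(top.contact_pairs), epsilon_low)
    eps[top.basin_mask(BASIN_A)] = epsilon_asymmetric
    if neck_threshold is not None:
        rid_i = top.residue_ids[top.contact_pairs[:, 0]]
        rid_j = top.residue_ids[top.contact_pairs[:, 1]]
        eps[(rid_i < neck_threshold) & (rid_j < neck_threshold)] = epsilon_high
    eps[top.basin_mask(BASIN_IF)] = epsilon_high
    top.contact_eps = eps
    return top


def build_mt_bound_complex(binder: CaStructure,
                           track: CaStructure,
                           adaptor: CaStructure | None = None,
                           binder_to_adaptor_pairs: np.ndarray | None = None,
                           adaptor_to_track_pairs: np.ndarray | None = None,
                           bound_chains: set[str] | None = None,
                           cutoff: float = C.CONTACT_CUTOFF,
                           truncate_track: float | None = 40.0,
                           ) -> tuple[CaStructure, list[tuple[int, int, float]]]:
    """Pose a binder on a rigid track and extract interface contacts.

    Placement follows two chained rigid superpositions: the adaptor complex
    (a homologous binder crystallized on a track fragment) is superposed
    onto the terminal track unit, then the binder is superposed onto the
    placed adaptor. With ``adaptor=None`` the binder is used as already
    posed (identity placement).

    Returns the merged structure (binder chains first, then track chains)
    and the interface contact list ``(binder_site, track_site, distance)``
    in merged indexing, restricted to ``bound_chains`` of the binder when
    given. Track sites beyond ``truncate_track`` Å of any binder site are
    dropped (they are frozen and outside interaction range).
    """
    placed = binder
    if adaptor is not None:
        if adaptor_to_track_pairs is None or binder_to_adaptor_pairs is None:
            raise ValueError("adaptor placement requires both pairings")
        rot, trans, _ = superpose(adaptor, track, adaptor_to_track_pairs)
        adaptor_on_track = apply_transform(adaptor, rot, trans)
        rot2, trans2, _ = superpose(binder, adaptor_on_track,
                                    binder_to_adaptor_pairs)
        placed = apply_transform(binder, rot2, trans2)

    track_kept = np.arange(track.n_sites)
    if truncate_track is not None:
        d = cdist(track.coords, placed.coords).min(axis=1)
        track_kept = np.nonzero(d <= truncate_track)[0]

    n_b = placed.n_sites
    merged = CaStructure(
        np.concatenate([placed.residue_ids, track.residue_ids[track_kept]]),
        np.concatenate([placed.chain_ids, track.chain_ids[track_kept]]),
        np.concatenate([placed.residue_names, track.residue_names[track_kept]]),
        np.vstack([placed.coords, track.coords[track_kept]]))

    if bound_chains is None:
        binder_idx = np.arange(n_b)
    else:
        binder_idx = np.nonzero(np.isin(placed.chain_ids, sorted(bound_chains)))[0]
    track_idx = np.arange(n_b, merged.n_sites)

    d = cdist(merged.coords[binder_idx], merged.coords[track_idx])
    ii, jj = np.nonzero(d < cutoff)
    interface = [(int(binder_idx[i]), int(track_idx[j]), float(d[i, j]))
                 for i, j in zip(ii, jj)]
    return merged, interface


def add_interface_contacts(topology: DualBasinTopology,
                           interface: list[tuple[int, int, float]],
                           epsilon: float = C.EPSILON_HIGH
                           ) -> DualBasinTopology:
    """Append IF contacts (from :func:`build_mt_bound_complex`) to a topology."""
    top = topology.copy()
    if not interface:
        return top
    arr = np.array([(i, j) for i, j, _ in interface], dtype=np.int64)
    r0 = np.array([d for _, _, d in interface])
    top.contact_pairs = np.vstack([top.contact_pairs, arr])
    top.contact_basin = np.concatenate(
        [top.contact_basin, np.full(len(arr), BASIN_IF, dtype="U2")])
    top.contact_r0 = np.concatenate([top.contact_r0, r0])
    top.contact_eps = np.concatenate([top.contact_eps, np.full(len(arr), epsilon)])
    return top


def freeze_sites(topology: DualBasinTopology, sites: np.ndarray
                 ) -> DualBasinTopology:
    """Mark track sites immobile and drop contacts internal to the rigid
    track (constant-energy terms)."""
    top = topology.copy()
    top.frozen_sites = np.asarray(sites, dtype=np.int64)
    frozen = np.zeros(top.n_sites, dtype=bool)
    frozen[top.frozen_sites] = True
    keep = ~(frozen[top.contact_pairs[:, 0]] & frozen[top.contact_pairs[:, 1]])
    top.contact_pairs = top.contact_pairs[keep]
    top.contact_basin = top.contact_basin[keep]
    top.contact_r0 = top.contact_r0[keep]
    top.contact_eps = top.contact_eps[keep]
    return top


def delete_junction_contacts(topology: DualBasinTopology,
                             stalk_range: tuple[int, int] = C.JUNCTION_STALK_RANGE,
                             head_range: tuple[int, int] = C.JUNCTION_HEAD_RANGE,
                             chain: str | None = None
                             ) -> tuple[DualBasinTopology, int]:
    """Remove S-basin contacts spanning the stalk/head junction.

    Mimics ATP binding: every S contact with one author residue number in
    ``stalk_range`` and the other in ``head_range`` (restricted to
    ``chain``, the track-bound monomer, when given) is deleted; the pair
    becomes repulsive-only. Returns the new topology and the deletion count.
    Ranges are inclusive.
    """
    top = topology.copy()
    rid_i = top.residue_ids[top.contact_pairs[:, 0]]
    rid_j = top.residue_ids[top.contact_pairs[:, 1]]

    def in_range(r, lo_hi):
        return (r >= lo_hi[0]) & (r <= lo_hi[1])

    spans = ((in_range(rid_i, stalk_range) & in_range(rid_j, head_range))
             | (in_range(rid_j, stalk_range) & in_range(rid_i, head_range)))
    if chain is not None:
        spans &= ((top.chain_ids[top.contact_pairs[:, 0]] == chain)
                  & (top.chain_ids[top.contact_pairs[:, 1]] == chain))
    doomed = spans & top.basin_mask(BASIN_S)
    count = int(doomed.sum())
    if count == 0:
        logger.warning("no junction contacts matched the given ranges")
    keep = ~doomed
    top.contact_pairs = top.contact_pairs[keep]
    top.contact_basin = top.contact_basin[keep]
    top.contact_r0 = top.contact_r0[keep]
    top.contact_eps = top.contact_eps[keep]
    return top, count
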