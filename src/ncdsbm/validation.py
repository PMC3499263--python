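"""Closed-form validation suite for the toy dual-basin system.

Each check exercises one pillar of the simulation machinery against an
analytically known answer: gradient consistency, the symplectic limit of
the integrator, equipartition under the thermostat, Boltzmann recovery of
calibrated basin populations, contact-map set arithmetic, PCA mode
recovery, and the free-energy/stall-force plumbing. The pipeline's
``synthetic_validation`` experiment and the acceptance script both run
these functions; the test suite asserts their pass flags.
"""
from __future__ import annotations

import numpy as np

from . import constants as C
from .structure_io import CaStructure
from .model_builder import (build_dual_basin_topology,
                            delete_junction_contacts, BASIN_S, BASIN_A)
from .energetics import total_energy
from .dynamics import SimulationParams, TrajectoryEnsemble, langevin_step, \
    run_simulation
from .observables import free_energy_surface, stall_force_estimate, pca_modes, \
    FreeEnergySurface
from . import synthetic_data as syn
from . import _kernels
from .dynamics import _call_forces

__all__ = ["check_force_consistency", "check_symplectic_limit",
           "check_equipartition", "check_boltzmann_recovery",
           "check_contact_oracle", "check_pca_rank1", "check_pmf_plumbing",
           "run_validation_suite"]


def check_force_consistency(seed: int = 0, n_configs: int = 100,
                            n_residues: int = 30, fd_step: float = 1e-5
                            ) -> dict:
    """Analytic forces vs central finite differences of the total energy."""
    spec = syn.ToyDualBasinSpec(n_residues=n_residues, tail_length=6)
    top, a, _ = syn.build_toy_topology(spec)
    flat = _kernels.flatten_topology(top)
    rng = np.random.default_rng(seed)
    fbuf = np.zeros_like(a.coords)
    worst = 0.0
    for _ in range(n_configs):
        x = a.coords + 0.3 * rng.standard_normal(a.coords.shape)
        _, forces = total_energy(x, top)
        num = np.zeros_like(forces)
        for i in range(top.n_sites):
            for d in range(3):
                xp = x.copy()
                xp[i, d] += fd_step
                ep = _call_forces(xp, flat, fbuf).sum()
                xp[i, d] -= 2 * fd_step
                em = _call_forces(xp, flat, fbuf).sum()
                num[i, d] = -(ep - em) / (2 * fd_step)
        rel = float(np.abs(num - forces).max() / np.abs(forces).max())
        worst = max(worst, rel)
    return {"max_relative_error": worst, "n_configs": n_configs,
            "passed": worst < 1e-4}


def check_symplectic_limit(n_steps: int = 10_000, stretch: float = 0.1
                           ) -> dict:
    """Energy conservation of the ζ=0, T=0 integrator on a harmonic dimer."""
    r0 = C.CA_SPACING
    x = np.array([[0.0, 0.0, 0.0], [r0 + stretch, 0.0, 0.0]])
    v = np.zeros_like(x)

    def force(coords):
        d = coords[1] - coords[0]
        r = np.linalg.norm(d)
        f = 2.0 * C.K_BOND * (r - r0) / r * d
        return np.array([f, -f])

    def energy(coords, vels):
        r = np.linalg.norm(coords[1] - coords[0])
        return C.K_BOND * (r - r0) ** 2 + 0.5 * np.sum(vels ** 2)

    params = SimulationParams(temperature=0.0, friction=0.0,
                              n_steps=n_steps)
    rng = np.random.default_rng(0)
    f = force(x)
    e0 = energy(x, v)
    drift = 0.0
    for _ in range(n_steps):
        x, v, f = langevin_step(x, v, f, params, rng, force)
        drift = max(drift, float(abs(energy(x, v) - e0)))
    return {"energy_drift": drift, "n_steps": n_steps,
            "passed": drift < 1e-4}


def check_equipartition(seed: int = 0, n_steps: int = 1_000_000,
                        k_spring: float = 1.0, n_wells: int = 16) -> dict:
    """⟨x²⟩ = k_BT/k for independent 1-D harmonic wells at 300 K."""
    params = SimulationParams(n_steps=n_steps)
    kt = C.KB * params.temperature
    rng = np.random.default_rng(seed)
    x = np.zeros((n_wells, 1))
    v = np.sqrt(kt) * rng.standard_normal((n_wells, 1))

    def force(coords):
        return -k_spring * coords

    f = force(x)
    burn = n_steps // 10
    samples = np.empty((n_steps - burn, n_wells))
    for step in range(n_steps):
        x, v, f = langevin_step(x, v, f, params, rng, force)
        if step >= burn:
            samples[step - burn] = x[:, 0]
    x2 = samples ** 2
    est = float(x2.mean())
    # block over time (autocorrelation), wells are independent
    blocks = np.array([b.mean() for b in np.array_split(x2, 20, axis=0)])
    se = float(blocks.std(ddof=1) / np.sqrt(len(blocks)))
    expected = kt / k_spring
    return {"x2": est, "expected": expected, "se": se,
            "deviation_in_se": abs(est - expected) / se,
            "passed": bool(abs(est - expected) <= 3 * se)}


def check_boltzmann_recovery(seed: int = 0,
                             calibration_steps: int = 2_000_000,
                             budget_steps: int = 14_000_000,
                             production_steps: int = 6_000_000) -> dict:
    """Calibrate the toy to ΔF = 2 k_BT; verify e^{-2}/(1+e^{-2}) occupancy.

    Both the calibration and the production measurement pool independent
    replicas; the quoted uncertainty combines the production between-replica
    standard error with the calibration's achieved-gap standard error
    (propagated to the occupancy scale), since the calibration tolerance
    dominates.
    """
    spec = syn.ToyDualBasinSpec(target_gap=2.0)
    cal = syn.calibrate_gap(spec, seed=seed, steps_per_iter=calibration_steps,
                            budget_steps=budget_steps)
    m = syn.measure_basin_occupancy(
        spec, cal.epsilon_asymmetric, seed=seed + 10_000,
        n_replicas=6, steps_per_replica=production_steps // 6)
    occ = m["occupancy"]
    expected = float(np.exp(-spec.target_gap) / (1 + np.exp(-spec.target_gap)))
    dp = occ * (1 - occ)
    se_occ = float(np.hypot(m["occupancy_se"], dp * cal.gap_se))
    return {"minor_occupancy": occ, "expected": expected,
            "achieved_gap_kT": m["gap"], "epsilon_asymmetric":
                cal.epsilon_asymmetric, "se": se_occ,
            "replica_occupancies": m["replica_occupancies"],
            "calibration_steps_used": cal.n_steps_used,
            "passed": bool(abs(occ - expected) <= 3 * se_occ)}


def _brute_force_map(s: CaStructure, cutoff: float, min_sep: int) -> set:
    out = set()
    for i in range(s.n_sites):
        for j in range(i + 1, s.n_sites):
            same = s.chain_ids[i] == s.chain_ids[j]
            if same and abs(int(s.residue_ids[i]) - int(s.residue_ids[j])) <= min_sep:
                continue
            if np.linalg.norm(s.coords[i] - s.coords[j]) < cutoff:
                out.add((i, j))
    return out


def check_contact_oracle(seed: int = 0) -> dict:
    """Dual-basin classification equals brute-force set arithmetic;
    junction deletion equals a brute-force range filter."""
    spec = syn.ToyDualBasinSpec()
    a, b, site_map = syn.generate_two_conformer_chain(spec)
    top = build_dual_basin_topology(a, b, site_map, neck_threshold=None)
    s_bf = _brute_force_map(a, C.CONTACT_CUTOFF, C.MIN_SEQ_SEPARATION)
    a_bf = _brute_force_map(b, C.CONTACT_CUTOFF, C.MIN_SEQ_SEPARATION) - s_bf
    s_top = {tuple(p) for p, bas in zip(top.contact_pairs.tolist(),
                                        top.contact_basin) if bas == BASIN_S}
    a_top = {tuple(p) for p, bas in zip(top.contact_pairs.tolist(),
                                        top.contact_basin) if bas == BASIN_A}
    sets_ok = (s_top == s_bf) and (a_top == a_bf) and not (s_top & a_top)

    stalk = (5, 9)
    head = (20, 30)
    rid = top.residue_ids
    expect_deleted = {
        tuple(p) for p, bas in zip(top.contact_pairs.tolist(),
                                   top.contact_basin)
        if bas == BASIN_S and (
            (stalk[0] <= rid[p[0]] <= stalk[1] and head[0] <= rid[p[1]] <= head[1])
            or (stalk[0] <= rid[p[1]] <= stalk[1] and head[0] <= rid[p[0]] <= head[1]))}
    cut, n_del = delete_junction_contacts(top, stalk, head)
    kept = {tuple(p) for p in cut.contact_pairs.tolist()}
    deletion_ok = (n_del == len(expect_deleted)
                   and not (kept & expect_deleted))
    cut2, n_del2 = delete_junction_contacts(cut, stalk, head)
    idempotent = n_del2 == 0 and len(cut2.contact_pairs) == len(cut.contact_pairs)
    passed = bool(sets_ok and deletion_ok and idempotent)
    return {"n_S": len(s_top), "n_A": len(a_top),
            "n_junction_deleted": n_del, "passed": passed}


def check_pca_rank1(seed: int = 0) -> dict:
    """PCA recovers a constructed single-direction displacement."""
    spec = syn.ToyDualBasinSpec()
    top, a, _ = syn.build_toy_topology(spec)
    rng = np.random.default_rng(seed)
    vec = rng.standard_normal((top.n_sites, 3))
    # remove rigid-body components (superposition would absorb them)
    n = top.n_sites
    centered = a.coords - a.coords.mean(axis=0)
    rigid = []
    for d in range(3):
        t = np.zeros((n, 3))
        t[:, d] = 1.0
        rigid.append(t.ravel())
    for d in range(3):
        axis = np.zeros(3)
        axis[d] = 1.0
        rigid.append(np.cross(np.broadcast_to(axis, (n, 3)), centered).ravel())
    basis = np.linalg.qr(np.column_stack(rigid))[0]
    flat = vec.ravel() - basis @ (basis.T @ vec.ravel())
    vec = (flat / np.linalg.norm(flat)).reshape(n, 3)
    amps = np.linspace(-0.5, 0.5, 41)
    frames = a.coords[None] + amps[:, None, None] * vec[None]
    traj = TrajectoryEnsemble(frames, np.arange(len(amps), dtype=float),
                              SimulationParams(n_steps=0),
                              top, np.arange(top.n_sites),
                              np.zeros((0, 3)))
    res = pca_modes(traj, a, n_modes=3)
    cos = abs(float(res.modes[0].ravel() @ vec.ravel()))
    rank1 = float(res.eigenvalues[1] / res.eigenvalues[0])
    return {"cos_with_direction": cos, "eigenvalue_ratio_2_1": rank1,
            "passed": cos > 0.999 and rank1 < 1e-3}


def check_pmf_plumbing() -> dict:
    """Two-state ΔF and the stall-force unit conversion, end to end."""
    # two-state indicator with exact 0.88/0.12 occupancies
    series = np.concatenate([np.zeros(8800), np.ones(1200)])
    fes = free_energy_surface(series, bins=2)
    dF = float(fes.free_energy.max() - fes.free_energy.min())
    expected_dF = float(np.log(0.88 / 0.12))
    # exact linear PMF: F rises 1 k_BT per 10 Å at 300 K -> 4.14 pN
    edges = np.linspace(0.0, 50.0, 26)
    centers = 0.5 * (edges[:-1] + edges[1:])
    f_lin = centers / 10.0
    p = np.exp(-f_lin)
    counts = np.round(1e6 * p / p.sum()).astype(np.int64)
    lin = FreeEnergySurface([edges], f_lin - f_lin.min(), counts,
                            int(counts.sum()))
    stall = stall_force_estimate(lin, temperature=300.0)
    expected_stall = 0.1 * C.KB * 300.0 * C.KCAL_PER_MOL_ANG_IN_PN
    # re-exponentiation consistency on a sampled surface
    rng = np.random.default_rng(7)
    samp = rng.standard_normal(4000)
    fes_g = free_energy_surface(samp, bins=20)
    recon = fes_g.probabilities() * fes_g.n_frames
    hist_ok = np.allclose(recon[fes_g.counts > 0],
                          fes_g.counts[fes_g.counts > 0], rtol=1e-9)
    passed = (abs(dF - expected_dF) < 1e-9
              and abs(stall - expected_stall) < 1e-9 and bool(hist_ok))
    return {"two_state_dF_kT": dF, "expected_dF_kT": expected_dF,
            "stall_force_pN": stall, "expected_stall_pN": expected_stall,
            "passed": passed}


def run_validation_suite(seed: int = 0, quick: bool = False) -> dict:
    """Run every check; ``quick`` shrinks the stochastic runs for smoke use."""
    report = {
        "force_consistency": check_force_consistency(
            seed, n_configs=10 if quick else 100),
        "symplectic_limit": check_symplectic_limit(),
        "equipartition": check_equipartition(
            seed, n_steps=200_000 if quick else 1_000_000),
        "contact_oracle": check_contact_oracle(seed),
        "pca_rank1": check_pca_rank1(seed),
        "pmf_plumbing": check_pmf_plumbing(),
        "boltzmann_recovery": check_boltzmann_recovery(
            seed,
            calibration_steps=1_000_000 if quick else 2_000_000,
            budget_steps=8_000_000 if quick else 14_000_000,
            production_steps=3_000_000 if quick else 6_000_000),
    }
    report["all_passed"] = all(v["passed"] for v in report.values()
                               if isinstance(v, dict))
    return report
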