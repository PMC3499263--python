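"""Config-driven orchestration of the model's computational experiments.

An experiment bundles topology construction (with the state-appropriate
modifications), a Langevin production run, and the requested observables,
and records a manifest (inputs, seeds, content hashes, stage wall times)
sufficient to re-run it exactly.

Experiments
-----------
``adp_adp_solution``
    Dual-basin dimer free in solution (no track terms).
``phi_adp_on_mt``
    Track-bound state: interface contacts added, track beads frozen.
``atp_adp_on_mt``
    Track-bound with the junction contacts deleted (ATP-state flexibility).
``power_stroke_pmf``
    PMF over the stalk-tip position along the track axis and the
    stall-force bound, computed from a track-bound ensemble.
``synthetic_validation``
    The toy-system closed-form validation suite.
"""
from __future__ import annotations

import hashlib
import json
import logging
import time
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import constants as C
from .structure_io import read_ca_structure, CaStructure
from .model_builder import (build_dual_basin_topology, build_mt_bound_complex,
                            add_interface_contacts, delete_junction_contacts,
                            freeze_sites, DualBasinTopology)
from .dynamics import SimulationParams, run_simulation, TrajectoryEnsemble
from . import observables as obs
from . import synthetic_data as syn

logger = logging.getLogger(__name__)

__all__ = ["ExperimentConfig", "run_experiment"]

EXPERIMENTS = ("adp_adp_solution", "phi_adp_on_mt", "atp_adp_on_mt",
               "power_stroke_pmf", "synthetic_validation")


@dataclass
class ExperimentConfig:
    """Inputs for one experiment; see the module docstring for kinds."""
    experiment: str
    output_dir: str
    seed: int = 0
    # structure inputs: PDB paths, or a toy spec when absent
    symmetric_pdb: str | None = None
    asymmetric_pdb: str | None = None
    track_pdb: str | None = None
    toy: dict = field(default_factory=dict)
    # model parameters
    cutoff: float = C.CONTACT_CUTOFF
    neck_threshold: int | None = None
    epsilon_asymmetric: float = C.EPSILON_ASYMMETRIC
    junction_stalk_range: tuple[int, int] = C.JUNCTION_STALK_RANGE
    junction_head_range: tuple[int, int] = C.JUNCTION_HEAD_RANGE
    junction_chain: str | None = None
    # simulation parameters
    temperature: float = C.TEMPERATURE
    friction: float = C.FRICTION
    timestep: float = C.TIMESTEP
    n_steps: int = 500_000
    save_interval: int = 500
    # observable requests: list of dicts, e.g.
    #   {kind: distance, a: [A, 39], b: [A, 20]}
    #   {kind: theta, apex: [...], arm1: [...], arm2: [...]}
    #   {kind: fes, source: <name of a series request>}
    #   {kind: pca, n_modes: 2}
    #   {kind: basin_occupancy}
    observables: list = field(default_factory=list)
    # synthetic_validation only: shrink the stochastic runs
    quick: bool = False

    @classmethod
    def from_yaml(cls, path: str) -> "ExperimentConfig":
        with open(path) as fh:
            doc = yaml.safe_load(fh)
        return cls(**doc)

    def simulation_params(self) -> SimulationParams:
        return SimulationParams(self.temperature, self.friction, self.timestep,
                                self.n_steps, self.save_interval, self.seed)

    def toy_spec(self) -> syn.ToyDualBasinSpec:
        kw = dict(self.toy)
        track = kw.pop("track", None)
        if self.experiment in ("phi_adp_on_mt", "atp_adp_on_mt",
                               "power_stroke_pmf") and track is None:
            track = {}
        return syn.ToyDualBasinSpec(
            **kw, track=syn.TrackSpec(**track) if track is not None else None)


def _sha256(path: Path) -> str:
    h = hashlib.sha256()
    h.update(path.read_bytes())
    return h.hexdigest()


class _Stages:
    """Stage runner that records wall time and the first failure."""

    def __init__(self) -> None:
        self.log: list[dict] = []

    def run(self, name: str, fn, *args, **kwargs):
        t0 = time.perf_counter()
        try:
            out = fn(*args, **kwargs)
        except Exception as exc:
            self.log.append({"stage": name, "status": "failed",
                             "error": repr(exc),
                             "wall_s": time.perf_counter() - t0})
            raise
        self.log.append({"stage": name, "status": "ok",
                         "wall_s": time.perf_counter() - t0})
        return out


def _build_topology(cfg: ExperimentConfig
                    ) -> tuple[DualBasinTopology, CaStructure]:
    """Topology + initial structure with experiment-appropriate terms."""
    on_track = cfg.experiment in ("phi_adp_on_mt", "atp_adp_on_mt",
                                  "power_stroke_pmf")
    if cfg.symmetric_pdb is None:
        spec = cfg.toy_spec()
        top, init, _ = syn.build_toy_topology(
            spec, epsilon_asymmetric=cfg.epsilon_asymmetric)
    else:
        sym = read_ca_structure(Path(cfg.symmetric_pdb).read_text())
        asym = read_ca_structure(Path(cfg.asymmetric_pdb).read_text())
        init = sym
        if on_track:
            track = read_ca_structure(Path(cfg.track_pdb).read_text())
            merged, interface = build_mt_bound_complex(sym, track)
            n = sym.n_sites
            m = merged.n_sites
            asym_m = CaStructure(
                merged.residue_ids, merged.chain_ids, merged.residue_names,
                np.vstack([asym.coords, merged.coords[n:]]))
            top = build_dual_basin_topology(
                merged, asym_m, cutoff=cfg.cutoff,
                neck_threshold=cfg.neck_threshold,
                epsilon_asymmetric=cfg.epsilon_asymmetric,
                bonded_chains=sym.chains())
            # binder-track pairs found by the contact map are the interface
            ci = top.contact_pairs
            is_if = (ci[:, 0] < n) ^ (ci[:, 1] < n)
            top.contact_basin[is_if] = "IF"
            top.contact_eps[is_if] = C.EPSILON_HIGH
            top = freeze_sites(top, np.arange(n, m))
            init = merged
        else:
            top = build_dual_basin_topology(
                sym, asym, cutoff=cfg.cutoff,
                neck_threshold=cfg.neck_threshold,
                epsilon_asymmetric=cfg.epsilon_asymmetric)
    if cfg.experiment == "atp_adp_on_mt":
        top, n_del = delete_junction_contacts(
            top, cfg.junction_stalk_range, cfg.junction_head_range,
            cfg.junction_chain)
        logger.info("deleted %d junction contacts", n_del)
    return top, init


def _resolve_residue(r) -> tuple[str, int]:
    return (str(r[0]), int(r[1]))


def _compute_observables(cfg: ExperimentConfig, traj: TrajectoryEnsemble,
                         reference: CaStructure, outdir: Path) -> dict:
    results: dict = {}
    series_store: dict[str, np.ndarray] = {}
    for req in cfg.observables:
        kind = req["kind"]
        name = req.get("name", kind)
        if kind == "distance":
            s = obs.residue_distance_series(
                traj, _resolve_residue(req["a"]), _resolve_residue(req["b"]))
            series_store[name] = s
            pd.DataFrame({"time": traj.times, name: s}).to_csv(
                outdir / f"{name}.csv", index=False)
            results[name] = {"mean": float(s.mean()), "std": float(s.std())}
        elif kind == "theta":
            s = obs.theta_angle_series(
                traj, _resolve_residue(req["apex"]),
                _resolve_residue(req["arm1"]), _resolve_residue(req["arm2"]))
            series_store[name] = s
            pd.DataFrame({"time": traj.times, name: s}).to_csv(
                outdir / f"{name}.csv", index=False)
            results[name] = {"mean": float(s.mean()),
                             "peak": float(np.median(s))}
        elif kind == "fes":
            src = req["source"]
            fes = obs.free_energy_surface(series_store[src],
                                          bins=req.get("bins"))
            df = pd.DataFrame({"center": fes.bin_centers(),
                               "free_energy_kT": fes.free_energy,
                               "counts": fes.counts})
            df.to_csv(outdir / f"{name}.csv", index=False)
            finite = np.isfinite(fes.free_energy)
            results[name] = {"n_bins": int(finite.sum()),
                             "max_kT": float(fes.free_energy[finite].max())}
        elif kind == "pmf_z":
            tip = _resolve_residue(req["tip"])
            axis = obs.track_axis(traj.frozen_coords)
            site = traj.site_series(obs._site(traj, tip))
            z = site @ axis
            fes = obs.free_energy_surface(z, bins=req.get("bins"))
            stall = obs.stall_force_estimate(fes, cfg.temperature)
            stall_ep = obs.stall_force_estimate(fes, cfg.temperature,
                                                method="endpoint")
            pd.DataFrame({"z": fes.bin_centers(),
                          "free_energy_kT": fes.free_energy,
                          "counts": fes.counts}).to_csv(
                outdir / f"{name}.csv", index=False)
            results[name] = {"stall_force_pN": stall,
                             "stall_force_endpoint_pN": stall_ep}
        elif kind == "pca":
            pca = obs.pca_modes(traj, reference,
                                n_modes=req.get("n_modes", 2))
            results[name] = {
                "eigenvalues": pca.eigenvalues[:10].tolist(),
                "variance_fraction_top2": float(
                    pca.eigenvalues[:2].sum() / pca.eigenvalues.sum()),
            }
            np.savetxt(outdir / f"{name}_eigenvalues.csv", pca.eigenvalues,
                       delimiter=",")
        elif kind == "basin_occupancy":
            spec = cfg.toy_spec()
            ind = syn.basin_indicator_series(traj, spec)
            burn = len(ind) // 5
            gap, p, se = syn.occupancy_gap(ind[burn:])
            results[name] = {"minor_occupancy": p, "gap_kT": gap,
                             "gap_se_kT": se}
        else:
            raise ValueError(f"unknown observable kind {kind!r}")
    return results


def _synthetic_validation(cfg: ExperimentConfig, outdir: Path) -> dict:
    """Toy-system checks against closed forms; returns a pass/fail report."""
    from .validation import run_validation_suite
    report = run_validation_suite(seed=cfg.seed, quick=cfg.quick)
    (outdir / "validation.json").write_text(json.dumps(report, indent=2))
    return report


def run_experiment(config: ExperimentConfig) -> dict:
    """Execute one experiment; returns (and writes) the manifest."""
    if config.experiment not in EXPERIMENTS:
        raise ValueError(f"unknown experiment {config.experiment!r}")
    outdir = Path(config.output_dir)
    outdir.mkdir(parents=True, exist_ok=True)
    stages = _Stages()
    manifest: dict = {"experiment": config.experiment,
                      "config": asdict(config),
                      "stages": stages.log}
    try:
        if config.experiment == "synthetic_validation":
            manifest["results"] = stages.run(
                "validate", _synthetic_validation, config, outdir)
        else:
            top, init = stages.run("build_topology", _build_topology, config)
            (outdir / "topology.json").write_text(top.to_json())
            traj = stages.run("simulate", run_simulation, top, init,
                              config.simulation_params())
            traj.save(str(outdir / "trajectory.npz"))
            pd.DataFrame(
                traj.energies,
                columns=["bond", "angle", "dihedral", "contact_S",
                         "contact_A", "contact_IF", "repulsive"],
            ).assign(total=traj.energies.sum(axis=1),
                     time=traj.times).to_csv(
                outdir / "energies.csv", index=False)
            manifest["results"] = stages.run(
                "observables", _compute_observables, config, traj, init,
                outdir)
    finally:
        manifest["outputs"] = {
            p.name: _sha256(p) for p in sorted(outdir.iterdir())
            if p.is_file() and p.name != "manifest.json"}
        (outdir / "manifest.json").write_text(
            json.dumps(manifest, indent=2, default=str))
    return manifest
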