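"""End-to-end study orchestration: scan → MD protocol → observables.

A :class:`StudyConfig` is the unit of reproducibility: it fixes the
system (toy fixture specs or structure files), the solvent and
temperature, the scan grid and orientation set, the MD protocol (by
default twelve trajectories, three from each of the four canonical
initial dispositions) and every seed.  :func:`run_study` executes the
stages and writes a self-describing output bundle.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
import time
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import yaml

from . import fixtures, mm_scan, observables
from .constants import DEFAULT_TEMPERATURE
from .forcefield import SolventModel
from .md_engine import (DISPOSITION_CLASSES, InitialDisposition, ThermostatSpec,
                        Trajectory, run_trajectory)
from .structures import place_guest, read_structure

logger = logging.getLogger(__name__)

__all__ = ["StudyConfig", "run_study", "StudyResult"]


@dataclass
class StudyConfig:
    """Declarative description of one complete study run."""

    # system: "toy" fixtures or explicit structure paths
    system: str = "toy"
    host_path: str | None = None
    guest_path: str | None = None
    params_path: str | None = None

    epsilon: float = 80.0
    temperature: float = DEFAULT_TEMPERATURE

    # scan stage (the full reproduction grid is 0.1 Å and ~23 000
    # orientations; the default here is a desk-scale scan)
    grid_bounds: float = 5.0
    grid_spacing: float = 0.5
    orientation_scheme: str = "euler-lattice"
    orientation_count: int = 256
    pes: bool = True

    # MD stage
    n_per_disposition: int = 3
    dt: float = 1.0
    sample_every: int = 100
    max_steps: int = 200_000
    exit_patience: int = 50

    seed: int = 1
    outdir: str = "study_out"

    @classmethod
    def from_yaml(cls, path: str) -> "StudyConfig":
        with open(path) as fh:
            data = yaml.safe_load(fh) or {}
        unknown = set(data) - {f.name for f in dataclasses.fields(cls)}
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        return cls(**data)

    def to_dict(self) -> dict:
        return dataclasses.asdict(self)

    def config_hash(self) -> str:
        text = json.dumps(self.to_dict(), sort_keys=True)
        return hashlib.sha256(text.encode()).hexdigest()[:16]

    def trajectory_seed(self, index: int) -> int:
        """Deterministic per-trajectory seed derived from the study seed."""
        return (self.seed * 100_003 + 7919 * index + 1) % (2**31 - 1)


@dataclass
class StudyResult:
    """In-memory handles to the artifacts of one study run."""

    config: StudyConfig
    scan: mm_scan.ScanResult | None
    penetration: mm_scan.PenetrationPotential | None
    pes: mm_scan.PESMap | None
    emin: float | None
    trajectories: list[Trajectory]
    summary: observables.SimulationSummary | None
    density: observables.DensityGrid | None
    outdir: Path


def _load_system(config: StudyConfig):
    if config.system == "toy":
        return fixtures.default_study_system()
    if config.system == "packaged":
        return fixtures.packaged_bcd_eugenol(seed=config.seed)
    if config.system == "files":
        from .forcefield import ParameterTable
        if not (config.host_path and config.guest_path and config.params_path):
            raise ValueError("system=files needs host_path, guest_path, params_path")
        host = read_structure(config.host_path, role="host")
        guest = read_structure(config.guest_path, role="guest")
        return host, guest, ParameterTable.from_yaml(config.params_path)
    raise ValueError(f"unknown system {config.system!r}")


def run_study(config: StudyConfig) -> StudyResult:
    """Execute scan → MD → analysis and write the output bundle.

    Stages are independent where possible; a failure in a later stage
    leaves earlier outputs on disk.
    """
    out = Path(config.outdir)
    out.mkdir(parents=True, exist_ok=True)
    chash = config.config_hash()
    with open(out / "config.yaml", "w") as fh:
        yaml.safe_dump({**config.to_dict(), "config_hash": chash}, fh, sort_keys=True)

    host, guest, params = _load_system(config)
    solvent = SolventModel(epsilon=config.epsilon)
    manifest: dict = {"config_hash": chash, "stages": {}}

    # --- molecular-mechanics scan -----------------------------------------
    t0 = time.perf_counter()
    b = config.grid_bounds
    grid = mm_scan.ScanGrid(bounds=((-b, b), (-b, b), (-b, b)), spacing=config.grid_spacing)
    orientations = mm_scan.generate_orientations(
        config.orientation_scheme, config.orientation_count, seed=config.seed)
    scan_result = mm_scan.scan(host, guest, grid, orientations, params, solvent)
    scan_result.save(str(out / "scan.npz"))
    pen = mm_scan.penetration_potential(scan_result)
    pen.to_frame().to_csv(out / "penetration_potential.csv", index=False)
    emin, emin_pose, emin_breakdown = mm_scan.global_minimum(scan_result)
    incl, frac = mm_scan.classify_inclusion(place_guest(guest, emin_pose), host)
    with open(out / "emin.json", "w") as fh:
        json.dump({"Emin": emin, "pose": {"com": emin_pose.com.tolist(),
                                          "quaternion": emin_pose.quaternion.tolist()},
                   "breakdown": emin_breakdown.as_dict(),
                   "inclusion": incl, "fraction_inside": frac}, fh, indent=1)
    pes_map = None
    if config.pes:
        pes_map = mm_scan.boltzmann_pes(host, guest, grid, orientations, params,
                                        solvent, temperature=config.temperature)
        pes_map.save(str(out / "pes.npz"))
    manifest["stages"]["scan"] = {"seconds": round(time.perf_counter() - t0, 2),
                                  "Emin": emin, "inclusion": incl}
    logger.info("scan stage done in %.1fs, Emin=%.3f", time.perf_counter() - t0, emin)

    # --- molecular dynamics -----------------------------------------------
    t0 = time.perf_counter()
    thermostat = ThermostatSpec(temperature=config.temperature)
    trajectories: list[Trajectory] = []
    idx = 0
    for region, heading in DISPOSITION_CLASSES:
        for _rep in range(config.n_per_disposition):
            disp = InitialDisposition(region=region, heading=heading,
                                      seed=config.trajectory_seed(idx))
            traj = run_trajectory(host, guest, params, solvent, disp,
                                  thermostat=thermostat, dt=config.dt,
                                  sample_every=config.sample_every,
                                  max_steps=config.max_steps,
                                  exit_patience=config.exit_patience)
            traj.save(str(out / f"trajectory_{idx:02d}_{region}_{heading}"))
            trajectories.append(traj)
            idx += 1
    manifest["stages"]["md"] = {"seconds": round(time.perf_counter() - t0, 2),
                                "n_trajectories": len(trajectories)}
    logger.info("md stage done in %.1fs (%d trajectories)",
                time.perf_counter() - t0, len(trajectories))

    # --- observables -------------------------------------------------------
    summary = density = None
    if trajectories:
        t0 = time.perf_counter()
        summary = observables.summarize(trajectories, temperature=config.temperature)
        summary.save(str(out / "summary.json"))
        density = observables.position_density(trajectories)
        observables.write_cube(density, str(out / "density.cube"))
        for plane in ("XY", "XZ"):
            np.savetxt(out / f"density_{plane.lower()}.csv",
                       observables.project_density(density, plane), delimiter=",")
        manifest["stages"]["analysis"] = {"seconds": round(time.perf_counter() - t0, 2),
                                          "Emean": summary.e_mean,
                                          "Fmean": summary.f_mean,
                                          "tmean": summary.t_mean}

    with open(out / "manifest.json", "w") as fh:
        json.dump(manifest, fh, indent=1, sort_keys=True)
    return StudyResult(config=config, scan=scan_result, penetration=pen,
                       pes=pes_map, emin=emin, trajectories=trajectories,
                       summary=summary, density=density, outdir=out)
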