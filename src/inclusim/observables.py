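"""Trajectory analysis: occupancy densities, free energy, summary statistics.

The centre-of-mass *position probability density* is the normalized
occupancy of guest COM positions over a voxel grid — the number of
sampled positions in each volume element divided by the total number of
sampled positions.  The ensemble *binding free energy* is estimated from
the registered complex energies Wi as

    F = −kB·T · ln Σᵢ exp(−Wi / kB·T),

evaluated with a log-sum-exp for numerical safety.  Summaries aggregate
frame-weighted mean energies, per-trajectory F (and their mean Fmean)
and residence times (tmean).
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from typing import Callable, Sequence

import numpy as np
from scipy.special import logsumexp

from .constants import DEFAULT_TEMPERATURE, KB
from .md_engine import InitialDisposition, Trajectory, residence_time

__all__ = [
    "DensityGrid",
    "SimulationSummary",
    "position_density",
    "project_density",
    "subset_density",
    "binding_free_energy",
    "summarize",
    "write_cube",
    "SUBSET_PRESETS",
]


@dataclass
class DensityGrid:
    """COM occupancy over a regular voxel grid.

    ``counts`` has the grid shape; ``overflow`` counts samples outside
    the grid.  ``probability`` normalizes by *all* samples, so the grid
    probabilities plus the overflow fraction sum to one.
    """

    origin: np.ndarray            # Å, lower corner of voxel (0,0,0)
    spacing: float                # Å, cubic voxels
    counts: np.ndarray            # (nx, ny, nz) int
    overflow: int = 0

    @property
    def total(self) -> int:
        return int(self.counts.sum()) + self.overflow

    @property
    def probability(self) -> np.ndarray:
        return self.counts / self.total

    @property
    def overflow_fraction(self) -> float:
        return self.overflow / self.total


def _grid_edges(origin: np.ndarray, spacing: float, shape: tuple[int, int, int]):
    return [origin[d] + spacing * np.arange(shape[d] + 1) for d in range(3)]


def position_density(trajectories: Sequence[Trajectory],
                     origin: Sequence[float] = (-8.0, -8.0, -8.0),
                     spacing: float = 0.5,
                     shape: tuple[int, int, int] = (32, 32, 32)) -> DensityGrid:
    """Histogram all sampled COM positions into a voxel grid.

    Binning is half-open ([edge, edge+spacing)); each sample lands in
    exactly one voxel or in the overflow count.
    """
    if not trajectories or not any(len(t.times) for t in trajectories):
        raise ValueError("need at least one trajectory with at least one frame")
    origin = np.asarray(origin, dtype=float)
    coms = np.concatenate([t.coms for t in trajectories if len(t.times)])
    idx = np.floor((coms - origin) / spacing).astype(int)
    in_grid = np.all((idx >= 0) & (idx < np.array(shape)), axis=1)
    counts = np.zeros(shape, dtype=np.int64)
    np.add.at(counts, tuple(idx[in_grid].T), 1)
    return DensityGrid(origin=origin, spacing=spacing, counts=counts,
                       overflow=int((~in_grid).sum()))


def project_density(density: DensityGrid, plane: str) -> np.ndarray:
    """Marginal 2-D probability map: ``"XY"`` sums out Z, ``"XZ"`` sums out Y."""
    p = density.probability
    if plane.upper() == "XY":
        return p.sum(axis=2)
    if plane.upper() == "XZ":
        return p.sum(axis=1)
    raise ValueError(f"plane must be XY or XZ, got {plane!r}")


#: named trajectory-subset predicates matching the four analysis groupings
SUBSET_PRESETS: dict[str, Callable[[InitialDisposition], bool]] = {
    "radical-first": lambda d: d.heading == "radical-first",
    "phenyl-first": lambda d: d.heading == "phenyl-first",
    "narrow-rim": lambda d: d.region == "narrow-rim",
    "wide-rim": lambda d: d.region == "wide-rim",
}


def subset_density(trajectories: Sequence[Trajectory],
                   predicate: Callable[[InitialDisposition], bool] | str,
                   **grid_kwargs) -> DensityGrid:
    """Density over the trajectories whose initial disposition matches.

    ``predicate`` may be a callable on :class:`InitialDisposition` or one
    of the preset names in :data:`SUBSET_PRESETS`.
    """
    if isinstance(predicate, str):
        try:
            predicate = SUBSET_PRESETS[predicate]
        except KeyError:
            raise ValueError(f"unknown subset preset {predicate!r}; "
                             f"options: {sorted(SUBSET_PRESETS)}") from None
    subset = [t for t in trajectories if predicate(t.disposition)]
    if not subset:
        raise ValueError("no trajectory matches the subset predicate")
    return position_density(subset, **grid_kwargs)


def binding_free_energy(energies: Sequence[float],
                        temperature: float = DEFAULT_TEMPERATURE) -> float:
    """F = −kBT ln Σ exp(−Wi/kBT) over the registered complex energies (kcal/mol)."""
    w = np.asarray(energies, dtype=float)
    if w.size == 0:
        raise ValueError("energy list must be non-empty")
    if temperature <= 0:
        raise ValueError("temperature must be positive")
    kt = KB * temperature
    return float(-kt * logsumexp(-w / kt))


@dataclass
class SimulationSummary:
    """Aggregate statistics of a set of trajectories (kcal/mol, ps)."""

    e_mean: float
    einter_mean: float
    eintra_mean: float
    component_means: dict[str, float]
    f_per_trajectory: list[float]
    f_mean: float
    t_per_trajectory: list[float]
    t_mean: float
    n_trajectories: int
    n_frames: int

    def as_dict(self) -> dict:
        return {"Emean": self.e_mean, "Einter_mean": self.einter_mean,
                "Eintra_mean": self.eintra_mean,
                "component_means": self.component_means,
                "F": self.f_per_trajectory, "Fmean": self.f_mean,
                "t": self.t_per_trajectory, "tmean": self.t_mean,
                "n_trajectories": self.n_trajectories, "n_frames": self.n_frames}

    def save(self, path: str) -> None:
        with open(path, "w") as fh:
            json.dump(self.as_dict(), fh, indent=1, sort_keys=True)


def summarize(trajectories: Sequence[Trajectory],
              temperature: float = DEFAULT_TEMPERATURE,
              threshold: float | None = None) -> SimulationSummary:
    """Frame-weighted mean energies, per-trajectory F / Fmean, residence times.

    F is evaluated per trajectory over its registered frames and averaged
    (unweighted) into Fmean; residence times use the −kBT attractiveness
    threshold unless overridden.
    """
    if not trajectories:
        raise ValueError("need at least one trajectory")
    keys = ("lj", "ele", "hbond", "bond", "angle", "torsion")
    sums = dict.fromkeys(keys, 0.0)
    n_frames = 0
    f_list, t_list = [], []
    for traj in trajectories:
        for br in traj.energies:
            d = br.as_dict()
            for k in keys:
                sums[k] += d[k]
        n_frames += len(traj.energies)
        f_list.append(binding_free_energy(traj.etotal, temperature))
        t_list.append(residence_time(traj, threshold)[0])
    means = {k: sums[k] / n_frames for k in keys}
    einter_mean = means["lj"] + means["ele"] + means["hbond"]
    eintra_mean = means["bond"] + means["angle"] + means["torsion"]
    return SimulationSummary(
        e_mean=einter_mean + eintra_mean, einter_mean=einter_mean,
        eintra_mean=eintra_mean, component_means=means,
        f_per_trajectory=f_list, f_mean=float(np.mean(f_list)),
        t_per_trajectory=t_list, t_mean=float(np.mean(t_list)),
        n_trajectories=len(trajectories), n_frames=n_frames)


def write_cube(density: DensityGrid, path: str, comment: str = "COM probability density") -> None:
    """Write the probability density as a Gaussian cube file (Bohr units).

    A single dummy atom marks the origin; volumetric values are the
    per-voxel probabilities.
    """
    bohr = 1.0 / 0.529177210903
    nx, ny, nz = density.counts.shape
    o = density.origin * bohr
    s = density.spacing * bohr
    p = density.probability
    with open(path, "w") as fh:
        fh.write(f"{comment}\ninclusim density grid\n")
        fh.write(f"{1:5d}{o[0]:12.6f}{o[1]:12.6f}{o[2]:12.6f}\n")
        fh.write(f"{nx:5d}{s:12.6f}{0.0:12.6f}{0.0:12.6f}\n")
        fh.write(f"{ny:5d}{0.0:12.6f}{s:12.6f}{0.0:12.6f}\n")
        fh.write(f"{nz:5d}{0.0:12.6f}{0.0:12.6f}{s:12.6f}\n")
        fh.write(f"{1:5d}{0.0:12.6f}{0.0:12.6f}{0.0:12.6f}{0.0:12.6f}\n")
        for i in range(nx):
            for j in range(ny):
                row = p[i, j, :]
                for start in range(0, nz, 6):
                    fh.write("".join(f"{v:13.5E}" for v in row[start:start + 6]) + "\n")
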