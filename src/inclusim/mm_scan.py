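"""Exhaustive position × orientation molecular-mechanics scan.

The guest's centre of mass is stepped over a cubic lattice in the host
frame (default −5..5 Å at 0.1 Å) and, at each lattice point, the complex
energy is evaluated for a fixed set of rigid-body orientations (default a
regular 36×18×36 Euler-angle lattice, 23 328 orientations).  Products:

* the per-point minimum energy and its minimizing orientation;
* the penetration potential W(Z) — the minimum *intermolecular* energy
  over each plane Z = const, traced along the cavity axis;
* Boltzmann-averaged potential-energy surfaces: at each point the
  expectation of E under Boltzmann weights over orientations, reduced to
  four ~2.5 Å Z-slabs spanning the host;
* the global lattice minimum (Emin) and its pose, and an inclusion /
  non-inclusion classification of any guest configuration.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field

import numpy as np
from scipy.spatial.transform import Rotation

from .constants import DEFAULT_TEMPERATURE, KB
from .forcefield import (EnergyBreakdown, InteractionModel, ParameterTable,
                         SolventModel, intramolecular_energy)
from .structures import (HostFrame, ParameterizedMolecule, Pose, host_frame,
                         place_guest)

__all__ = [
    "ScanGrid",
    "OrientationSet",
    "ScanResult",
    "PenetrationPotential",
    "PESMap",
    "generate_orientations",
    "scan",
    "penetration_potential",
    "boltzmann_pes",
    "global_minimum",
    "classify_inclusion",
]

#: pair distances are clamped to this floor (Å) during scans to avoid overflow
R_FLOOR = 0.1
#: stored energies above this (kcal/mol) mark a steric clash
CLASH_ENERGY = 1e6


@dataclass(frozen=True)
class ScanGrid:
    """Cubic lattice of guest COM positions (Å) in the host frame."""

    bounds: tuple[tuple[float, float], tuple[float, float], tuple[float, float]] = \
        ((-5.0, 5.0), (-5.0, 5.0), (-5.0, 5.0))
    spacing: float = 0.1

    def __post_init__(self):
        if self.spacing <= 0:
            raise ValueError("grid spacing must be positive")
        for lo, hi in self.bounds:
            if hi < lo:
                raise ValueError("grid bounds must be ordered")

    def axis(self, dim: int) -> np.ndarray:
        lo, hi = self.bounds[dim]
        n = int(round((hi - lo) / self.spacing)) + 1
        return lo + self.spacing * np.arange(n)

    @property
    def shape(self) -> tuple[int, int, int]:
        return tuple(len(self.axis(d)) for d in range(3))

    def points(self) -> np.ndarray:
        """All lattice points, shape (nx*ny*nz, 3), x fastest in axis order."""
        gx, gy, gz = (self.axis(d) for d in range(3))
        pts = np.stack(np.meshgrid(gx, gy, gz, indexing="ij"), axis=-1)
        return pts.reshape(-1, 3)


@dataclass
class OrientationSet:
    """A reproducible set of unit quaternions (scalar-first, shape (n, 4))."""

    quaternions: np.ndarray
    descriptor: dict = field(default_factory=dict)

    def __post_init__(self):
        self.quaternions = np.atleast_2d(np.asarray(self.quaternions, dtype=float))
        norms = np.linalg.norm(self.quaternions, axis=1)
        if not np.allclose(norms, 1.0, atol=1e-9):
            raise ValueError("orientations must be unit quaternions")

    def __len__(self) -> int:
        return len(self.quaternions)

    def matrices(self) -> np.ndarray:
        """(n, 3, 3) rotation matrices."""
        q = self.quaternions
        return Rotation.from_quat(q[:, [1, 2, 3, 0]]).as_matrix()


def generate_orientations(scheme: str = "euler-lattice", count: int = 23000,
                          seed: int | None = None) -> OrientationSet:
    """Build an orientation set.

    ``euler-lattice``: a regular intrinsic Z-Y-Z lattice with per-angle
    counts (2n, n, 2n) whose product is closest to ``count`` — the
    default target 23 000 yields 36×18×36 = 23 328 orientations.  Beta
    spans [0, π] inclusive, so every lattice (however coarse) contains
    the axis-aligned orientations a slender guest needs to fit a narrow
    cavity; the polar duplicates this creates are accepted.
    ``random``: seeded uniform random rotations.
    """
    if count < 1:
        raise ValueError("count must be >= 1")
    if count == 1:
        return OrientationSet(np.array([[1.0, 0, 0, 0]]),
                              {"scheme": scheme, "count": 1})
    if scheme == "euler-lattice":
        nb = max(2, round((count / 4.0) ** (1.0 / 3.0)))
        na = nc = 2 * nb
        alphas = 2 * np.pi * np.arange(na) / na
        betas = np.linspace(0.0, np.pi, nb)
        gammas = 2 * np.pi * np.arange(nc) / nc
        grid = np.stack(np.meshgrid(alphas, betas, gammas, indexing="ij"),
                        axis=-1).reshape(-1, 3)
        q = Rotation.from_euler("ZYZ", grid).as_quat()  # (x, y, z, w)
        quats = q[:, [3, 0, 1, 2]]
        return OrientationSet(quats, {"scheme": "euler-lattice", "target": count,
                                      "counts": [na, nb, nc]})
    if scheme == "random":
        rot = Rotation.random(count, random_state=np.random.default_rng(seed))
        q = rot.as_quat()
        return OrientationSet(q[:, [3, 0, 1, 2]],
                              {"scheme": "random", "count": count, "seed": seed})
    raise ValueError(f"unknown orientation scheme {scheme!r}")


@dataclass
class ScanResult:
    """Per-grid-point minima over the orientation set.

    ``min_e``/``min_einter`` have the grid shape; ``argmin_orient`` holds
    the index of the minimizing orientation (ties → lowest index).
    Points where every orientation clashes are +inf.  ``eintra`` is the
    (conformation-constant) internal energy of the rigid guest.
    """

    grid: ScanGrid
    orientations: OrientationSet
    min_e: np.ndarray
    min_einter: np.ndarray
    argmin_orient: np.ndarray
    eintra: float
    host: ParameterizedMolecule
    guest: ParameterizedMolecule
    params: ParameterTable
    solvent: SolventModel

    def save(self, path: str) -> None:
        """Persist arrays (.npz) with a JSON metadata sidecar."""
        np.savez_compressed(path, min_e=self.min_e, min_einter=self.min_einter,
                            argmin_orient=self.argmin_orient)
        meta = {"grid": {"bounds": self.grid.bounds, "spacing": self.grid.spacing},
                "orientations": self.orientations.descriptor,
                "epsilon": self.solvent.epsilon, "eintra": self.eintra}
        with open(str(path) + ".json", "w") as fh:
            json.dump(meta, fh, indent=1)


def _oriented_guest(guest: ParameterizedMolecule, orientations: OrientationSet) -> np.ndarray:
    """Guest coordinates about its COM for every orientation: (n_or, ng, 3)."""
    rel = guest.coords - guest.reference_com
    return np.einsum("oij,nj->oni", orientations.matrices(), rel)


def _guest_eintra(guest: ParameterizedMolecule, params: ParameterTable) -> float:
    if guest.bonds or guest.angles or guest.torsions:
        return float(sum(intramolecular_energy(guest, guest.coords, params)))
    return 0.0


def scan(host: ParameterizedMolecule, guest: ParameterizedMolecule,
         grid: ScanGrid, orientations: OrientationSet,
         params: ParameterTable, solvent: SolventModel,
         orientation_chunk: int = 4096) -> ScanResult:
    """Exhaustive scan: per-point minimum E and Einter over orientations.

    Deterministic and order-independent: every (point, orientation) pair
    is evaluated; results do not depend on chunking.
    """
    model = InteractionModel(host, guest, params, solvent)
    oriented = _oriented_guest(guest, orientations)
    eintra = _guest_eintra(guest, params)
    pts = grid.points()
    n_or = len(orientations)

    min_einter = np.full(len(pts), np.inf)
    argmin = np.zeros(len(pts), dtype=np.int64)
    for start in range(0, n_or, orientation_chunk):
        block = oriented[start:start + orientation_chunk]  # (b, ng, 3)
        for p_idx, point in enumerate(pts):
            lj, ele, hb = model.energy_components(block + point, r_floor=R_FLOOR)
            einter = lj + ele + hb
            i = int(np.argmin(einter))
            if einter[i] < min_einter[p_idx]:
                min_einter[p_idx] = einter[i]
                argmin[p_idx] = start + i
    clashed = min_einter > CLASH_ENERGY
    min_einter[clashed] = np.inf
    shape = grid.shape
    return ScanResult(grid=grid, orientations=orientations,
                      min_e=(min_einter + eintra).reshape(shape),
                      min_einter=min_einter.reshape(shape),
                      argmin_orient=argmin.reshape(shape), eintra=eintra,
                      host=host, guest=guest, params=params, solvent=solvent)


@dataclass
class PenetrationPotential:
    """W(Z): minimum intermolecular energy over every plane Z = const,
    with the (lj, ele, hbond) decomposition of each plane's argmin."""

    z: np.ndarray
    w: np.ndarray
    lj: np.ndarray
    ele: np.ndarray
    hbond: np.ndarray

    def to_frame(self):
        import pandas as pd
        return pd.DataFrame({"Z": self.z, "W": self.w, "lj": self.lj,
                             "ele": self.ele, "hbond": self.hbond})


def penetration_potential(result: ScanResult) -> PenetrationPotential:
    """Reduce a scan to the penetration potential along the cavity axis."""
    model = InteractionModel(result.host, result.guest, result.params, result.solvent)
    zs = result.grid.axis(2)
    nx, ny, nz = result.min_einter.shape
    w = np.empty(nz)
    comp = np.zeros((nz, 3))
    gx, gy = result.grid.axis(0), result.grid.axis(1)
    for k in range(nz):
        plane = result.min_einter[:, :, k]
        w[k] = plane.min()
        if not np.isfinite(w[k]):
            comp[k] = np.nan
            continue
        # lexicographic (X, Y) argmin of the plane
        i, j = np.unravel_index(int(np.argmin(plane)), plane.shape)
        pose = Pose(com=np.array([gx[i], gy[j], zs[k]]),
                    quaternion=result.orientations.quaternions[result.argmin_orient[i, j, k]])
        coords = place_guest(result.guest, pose)
        comp[k] = model.energy_components(coords, r_floor=R_FLOOR)
    return PenetrationPotential(z=zs, w=w, lj=comp[:, 0], ele=comp[:, 1], hbond=comp[:, 2])


@dataclass
class PESMap:
    """Boltzmann-orientation-averaged energy ⟨E⟩ per grid point, plus the
    four Z-domain surfaces (per-(X,Y) minimum of ⟨E⟩ within each slab)."""

    grid: ScanGrid
    temperature: float
    avg_e: np.ndarray                      # grid-shaped ⟨E⟩
    min_e: np.ndarray                      # grid-shaped per-point minimum (bound check)
    domain_bounds: list[tuple[float, float]]
    domain_surfaces: list[np.ndarray]      # four (nx, ny) maps

    def save(self, path: str) -> None:
        np.savez_compressed(path, avg_e=self.avg_e, min_e=self.min_e,
                            **{f"domain_{i}": s for i, s in enumerate(self.domain_surfaces)})
        meta = {"grid": {"bounds": self.grid.bounds, "spacing": self.grid.spacing},
                "temperature": self.temperature,
                "domain_bounds": self.domain_bounds}
        with open(str(path) + ".json", "w") as fh:
            json.dump(meta, fh, indent=1)


def boltzmann_average(energies: np.ndarray, temperature: float) -> float:
    """⟨E⟩ = Σ E exp(−E/kBT) / Σ exp(−E/kBT), overflow-safe."""
    e = np.asarray(energies, dtype=float)
    kt = KB * temperature
    shifted = -(e - e.min()) / kt
    w = np.exp(shifted)
    return float((e * w).sum() / w.sum())


def boltzmann_pes(host: ParameterizedMolecule, guest: ParameterizedMolecule,
                  grid: ScanGrid, orientations: OrientationSet,
                  params: ParameterTable, solvent: SolventModel,
                  temperature: float = DEFAULT_TEMPERATURE,
                  n_domains: int = 4) -> PESMap:
    """Boltzmann-averaged PES over orientations, reduced to Z-domain surfaces.

    The host's Z extent is split into ``n_domains`` contiguous equal-width
    slabs (≈2.5 Å each for an 8-10 Å host); each surface is the per-(X,Y)
    minimum of ⟨E⟩ over the slab's grid planes.
    """
    if temperature <= 0:
        raise ValueError("temperature must be positive")
    model = InteractionModel(host, guest, params, solvent)
    oriented = _oriented_guest(guest, orientations)
    eintra = _guest_eintra(guest, params)
    pts = grid.points()
    kt = KB * temperature

    avg = np.empty(len(pts))
    mins = np.empty(len(pts))
    for p_idx, point in enumerate(pts):
        lj, ele, hb = model.energy_components(oriented + point, r_floor=R_FLOOR)
        e = lj + ele + hb + eintra
        emin = e.min()
        w = np.exp(-(e - emin) / kt)
        avg[p_idx] = (e * w).sum() / w.sum()
        mins[p_idx] = emin
    shape = grid.shape
    avg = avg.reshape(shape)
    mins = mins.reshape(shape)

    host_z = host.coords[:, 2]
    z_lo, z_hi = float(host_z.min()), float(host_z.max())
    edges = np.linspace(z_lo, z_hi, n_domains + 1)
    gz = grid.axis(2)
    bounds_list = []
    surfaces = []
    for d in range(n_domains):
        lo, hi = edges[d], edges[d + 1]
        sel = (gz >= lo - 1e-9) & (gz <= hi + 1e-9)
        bounds_list.append((float(lo), float(hi)))
        surfaces.append(avg[:, :, sel].min(axis=2) if sel.any()
                        else np.full(shape[:2], np.nan))
    return PESMap(grid=grid, temperature=temperature, avg_e=avg, min_e=mins,
                  domain_bounds=bounds_list, domain_surfaces=surfaces)


def global_minimum(result: ScanResult) -> tuple[float, Pose, EnergyBreakdown]:
    """The lattice-and-orientation-set minimizer of E.

    Ties are broken lexicographically by (Z, X, Y, orientation index).
    """
    e = result.min_e
    if not np.isfinite(e).any():
        raise ValueError("scan has no finite point")
    # transpose so C-order argmin realizes (Z, X, Y) lexicographic tie-break
    ezxy = np.transpose(e, (2, 0, 1))
    k, i, j = np.unravel_index(int(np.argmin(ezxy)), ezxy.shape)
    gx, gy, gz = (result.grid.axis(d) for d in range(3))
    pose = Pose(com=np.array([gx[i], gy[j], gz[k]]),
                quaternion=result.orientations.quaternions[result.argmin_orient[i, j, k]])
    from .forcefield import total_energy
    breakdown = total_energy(result.host, result.guest, pose, result.params, result.solvent)
    return float(e[i, j, k]), pose, breakdown


def cavity_radius_fit(host: ParameterizedMolecule) -> tuple[float, float]:
    """Linear fit radius(z) = a + b·z of host-site radial distance vs Z."""
    coords = host.coords - host.reference_com
    z = coords[:, 2]
    r = np.linalg.norm(coords[:, :2], axis=1)
    b, a = np.polyfit(z, r, 1)
    return float(a), float(b)


def classify_inclusion(guest_coords: np.ndarray, host: ParameterizedMolecule,
                       frame: HostFrame | None = None) -> tuple[bool, float]:
    """Inclusion test: fraction of guest atoms inside the host cavity.

    An atom is *inside* if its Z lies within the host's Z extent and its
    radial distance is below the cavity radius at that Z (linear
    interpolation of the rim radii).  The complex is an inclusion complex
    iff the fraction is positive.
    """
    if frame is None:
        frame = host_frame(host)
    local = frame.to_frame(np.asarray(guest_coords, dtype=float))
    host_local = frame.to_frame(host.coords)
    z_lo, z_hi = host_local[:, 2].min(), host_local[:, 2].max()
    a, b = cavity_radius_fit(host.with_coords(host_local))
    z = local[:, 2]
    r = np.linalg.norm(local[:, :2], axis=1)
    inside = (z >= z_lo) & (z <= z_hi) & (r <= a + b * z)
    frac = float(inside.mean()) if len(inside) else 0.0
    return frac > 0.0, frac
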