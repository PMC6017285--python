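"""AMBER-style force field for host-guest complexation in continuum solvent.

The complexation energy is E = Einter + Eintra with

* Einter = sum over host-guest atom pairs of a 12-6 Lennard-Jones term
  A/R^12 - B/R^6, a continuum-dielectric Coulomb term q_i q_j/(eps R),
  and — for flagged donor-H/acceptor pairs — a 12-10 hydrogen-bond term
  C/R^12 - D/R^10 that *replaces* the 12-6 term for that pair (classic
  AMBER-84 behaviour).  No distance cutoff is applied: the system is a
  single host-guest pair, not a periodic box.
* Eintra = harmonic bond stretch kr (r-req)^2 + harmonic angle bend
  ktheta (theta-thetaeq)^2 + torsion Vn/2 [1 + cos(n phi - gamma)],
  evaluated for the guest conformation.  The host is held at its input
  geometry, so its internal energy is an additive constant and is not
  evaluated.

Per-type Lennard-Jones coefficients combine geometrically,
Aij = sqrt(Ai Aj), Bij = sqrt(Bi Bj); explicit pair overrides may be
given in the parameter table.  Energies are kcal/mol, distances Å,
charges e.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import yaml

from .constants import COULOMB
from .structures import ParameterizedMolecule, Pose, place_guest

__all__ = [
    "LJParam",
    "HBondParam",
    "BondParam",
    "AngleParam",
    "TorsionTerm",
    "ParameterTable",
    "SolventModel",
    "EnergyBreakdown",
    "InteractionModel",
    "intermolecular_energy",
    "intramolecular_energy",
    "total_energy",
    "force_and_torque",
]


class ForceFieldError(ValueError):
    """Unresolvable parameters or singular geometry."""


@dataclass(frozen=True)
class LJParam:
    """12-6 coefficients: U = A/R^12 - B/R^6, A in kcal·Å¹²/mol, B in kcal·Å⁶/mol."""
    A: float
    B: float

    def __post_init__(self):
        if self.A < 0 or self.B < 0:
            raise ForceFieldError("LJ A and B must be non-negative")

    @classmethod
    def from_eps_rmin(cls, epsilon: float, rmin: float) -> "LJParam":
        """From well depth (kcal/mol) and minimum-energy distance (Å)."""
        return cls(A=epsilon * rmin**12, B=2.0 * epsilon * rmin**6)

    @classmethod
    def from_eps_sigma(cls, epsilon: float, sigma: float) -> "LJParam":
        """From well depth (kcal/mol) and zero-crossing distance (Å)."""
        return cls(A=4.0 * epsilon * sigma**12, B=4.0 * epsilon * sigma**6)


@dataclass(frozen=True)
class HBondParam:
    """12-10 hydrogen-bond coefficients: U = C/R^12 - D/R^10."""
    C: float
    D: float

    def __post_init__(self):
        if self.C < 0 or self.D < 0:
            raise ForceFieldError("H-bond C and D must be non-negative")


@dataclass(frozen=True)
class BondParam:
    kr: float    # kcal/mol/Å²
    req: float   # Å

    def __post_init__(self):
        if self.kr < 0:
            raise ForceFieldError("bond kr must be non-negative")


@dataclass(frozen=True)
class AngleParam:
    ktheta: float    # kcal/mol/rad²
    thetaeq: float   # rad

    def __post_init__(self):
        if self.ktheta < 0:
            raise ForceFieldError("angle ktheta must be non-negative")


@dataclass(frozen=True)
class TorsionTerm:
    vn: float     # barrier height Vn, kcal/mol
    n: int        # multiplicity, >= 1
    gamma: float  # phase, rad

    def __post_init__(self):
        if self.n < 1:
            raise ForceFieldError("torsion multiplicity must be >= 1")


@dataclass(frozen=True)
class SolventModel:
    """Uniform continuum solvent entering only through its dielectric constant."""
    epsilon: float = 80.0

    def __post_init__(self):
        if self.epsilon < 1:
            raise ForceFieldError("relative dielectric constant must be >= 1")


def _canon(key: tuple[str, ...]) -> tuple[str, ...]:
    return min(key, key[::-1])


@dataclass
class ParameterTable:
    """Force-field parameters keyed by atom type (and type tuples).

    ``hbond`` is keyed by (donor-H type, acceptor type); the wildcard key
    ``("*", "*")`` matches any flagged pair.  ``lj_pairs`` holds explicit
    pair overrides of the geometric combining rule.
    """

    lj: dict[str, LJParam] = field(default_factory=dict)
    lj_pairs: dict[tuple[str, str], LJParam] = field(default_factory=dict)
    hbond: dict[tuple[str, str], HBondParam] = field(default_factory=dict)
    bonds: dict[tuple[str, str], BondParam] = field(default_factory=dict)
    angles: dict[tuple[str, str, str], AngleParam] = field(default_factory=dict)
    torsions: dict[tuple[str, str, str, str], list[TorsionTerm]] = field(default_factory=dict)

    def lj_for(self, ff_type: str) -> LJParam:
        try:
            return self.lj[ff_type]
        except KeyError:
            raise ForceFieldError(f"no LJ parameters for atom type {ff_type!r}") from None

    def lj_pair(self, ti: str, tj: str) -> LJParam:
        override = self.lj_pairs.get(_canon((ti, tj)))
        if override is not None:
            return override
        a, b = self.lj_for(ti), self.lj_for(tj)
        return LJParam(A=math.sqrt(a.A * b.A), B=math.sqrt(a.B * b.B))

    def hbond_pair(self, donor_h_type: str, acceptor_type: str) -> HBondParam:
        for key in ((donor_h_type, acceptor_type), ("*", "*")):
            if key in self.hbond:
                return self.hbond[key]
        raise ForceFieldError(
            f"no 12-10 parameters for donor-H {donor_h_type!r} / acceptor {acceptor_type!r}")

    def bond_for(self, ti: str, tj: str) -> BondParam:
        try:
            return self.bonds[_canon((ti, tj))]
        except KeyError:
            raise ForceFieldError(f"no bond parameters for {ti}-{tj}") from None

    def angle_for(self, ti: str, tj: str, tk: str) -> AngleParam:
        try:
            return self.angles[_canon((ti, tj, tk))]
        except KeyError:
            raise ForceFieldError(f"no angle parameters for {ti}-{tj}-{tk}") from None

    def torsion_for(self, ti: str, tj: str, tk: str, tl: str) -> list[TorsionTerm]:
        for key in (_canon((ti, tj, tk, tl)), _canon(("*", tj, tk, "*"))):
            if key in self.torsions:
                return self.torsions[key]
        raise ForceFieldError(f"no torsion parameters for {ti}-{tj}-{tk}-{tl}")

    # -- serialization ------------------------------------------------------

    @classmethod
    def from_yaml(cls, path_or_text: str) -> "ParameterTable":
        """Load a table from a YAML file path or YAML text.

        Schema (angles/phases in degrees in the file, radians in memory)::

            lj:        {TYPE: {A: .., B: ..} | {epsilon: .., rmin: ..} | {epsilon: .., sigma: ..}}
            lj_pairs:  {"T1-T2": {A: .., B: ..}}
            hbond:     {"HD-OA": {C: .., D: ..}}
            bonds:     {"T1-T2": {kr: .., req: ..}}
            angles:    {"T1-T2-T3": {ktheta: .., thetaeq_deg: ..}}
            torsions:  {"T1-T2-T3-T4": [{vn: .., n: .., gamma_deg: ..}, ..]}
        """
        if "\n" in path_or_text or ":" in path_or_text.splitlines()[0]:
            data = yaml.safe_load(path_or_text)
        else:
            with open(path_or_text) as fh:
                data = yaml.safe_load(fh)
        if not isinstance(data, dict):
            raise ForceFieldError("parameter table must be a YAML mapping")
        known = {"lj", "lj_pairs", "hbond", "bonds", "angles", "torsions"}
        extra = set(data) - known
        if extra:
            raise ForceFieldError(f"unknown parameter sections: {sorted(extra)}")

        def lj_entry(spec: dict) -> LJParam:
            if {"A", "B"} <= set(spec):
                return LJParam(A=float(spec["A"]), B=float(spec["B"]))
            if {"epsilon", "rmin"} <= set(spec):
                return LJParam.from_eps_rmin(float(spec["epsilon"]), float(spec["rmin"]))
            if {"epsilon", "sigma"} <= set(spec):
                return LJParam.from_eps_sigma(float(spec["epsilon"]), float(spec["sigma"]))
            raise ForceFieldError(f"LJ entry needs A/B, epsilon/rmin or epsilon/sigma: {spec}")

        table = cls()
        for t, spec in (data.get("lj") or {}).items():
            table.lj[str(t)] = lj_entry(spec)
        for key, spec in (data.get("lj_pairs") or {}).items():
            table.lj_pairs[_canon(tuple(key.split("-")))] = lj_entry(spec)
        for key, spec in (data.get("hbond") or {}).items():
            table.hbond[tuple(key.split("-"))] = HBondParam(C=float(spec["C"]), D=float(spec["D"]))
        for key, spec in (data.get("bonds") or {}).items():
            table.bonds[_canon(tuple(key.split("-")))] = BondParam(
                kr=float(spec["kr"]), req=float(spec["req"]))
        for key, spec in (data.get("angles") or {}).items():
            table.angles[_canon(tuple(key.split("-")))] = AngleParam(
                ktheta=float(spec["ktheta"]), thetaeq=math.radians(float(spec["thetaeq_deg"])))
        for key, terms in (data.get("torsions") or {}).items():
            table.torsions[_canon(tuple(key.split("-")))] = [
                TorsionTerm(vn=float(t["vn"]), n=int(t["n"]), gamma=math.radians(float(t["gamma_deg"])))
                for t in terms]
        return table

    def to_yaml(self) -> str:
        data: dict = {}
        if self.lj:
            data["lj"] = {t: {"A": p.A, "B": p.B} for t, p in self.lj.items()}
        if self.lj_pairs:
            data["lj_pairs"] = {"-".join(k): {"A": p.A, "B": p.B} for k, p in self.lj_pairs.items()}
        if self.hbond:
            data["hbond"] = {"-".join(k): {"C": p.C, "D": p.D} for k, p in self.hbond.items()}
        if self.bonds:
            data["bonds"] = {"-".join(k): {"kr": p.kr, "req": p.req} for k, p in self.bonds.items()}
        if self.angles:
            data["angles"] = {"-".join(k): {"ktheta": p.ktheta, "thetaeq_deg": math.degrees(p.thetaeq)}
                              for k, p in self.angles.items()}
        if self.torsions:
            data["torsions"] = {
                "-".join(k): [{"vn": t.vn, "n": t.n, "gamma_deg": math.degrees(t.gamma)} for t in terms]
                for k, terms in self.torsions.items()}
        return yaml.safe_dump(data, sort_keys=True)


@dataclass
class EnergyBreakdown:
    """Energy decomposition in kcal/mol: total = (lj + ele + hbond) + (bond + angle + torsion)."""

    lj: float = 0.0
    ele: float = 0.0
    hbond: float = 0.0
    bond: float = 0.0
    angle: float = 0.0
    torsion: float = 0.0

    @property
    def einter(self) -> float:
        return self.lj + self.ele + self.hbond

    @property
    def eintra(self) -> float:
        return self.bond + self.angle + self.torsion

    @property
    def total(self) -> float:
        return self.einter + self.eintra

    def as_dict(self) -> dict[str, float]:
        return {"E": self.total, "Einter": self.einter, "Eintra": self.eintra,
                "lj": self.lj, "ele": self.ele, "hbond": self.hbond,
                "bond": self.bond, "angle": self.angle, "torsion": self.torsion}


# ---------------------------------------------------------------------------
# Intermolecular terms

#: pairs closer than this (Å) raise a singularity error
MIN_SEPARATION = 1e-8


class InteractionModel:
    """Precomputed host-guest pair coefficient matrices.

    All pair matrices have shape (n_host, n_guest).  The hydrogen-bond
    mask selects host-guest pairs in which one atom is a donor hydrogen
    and the other an acceptor; for those pairs the 12-10 term replaces
    the 12-6 term.
    """

    def __init__(self, host: ParameterizedMolecule, guest: ParameterizedMolecule,
                 params: ParameterTable, solvent: SolventModel | None = None):
        self.host = host
        self.guest = guest
        self.params = params
        self.solvent = solvent or SolventModel()
        nh, ng = len(host), len(guest)

        self.A = np.zeros((nh, ng))
        self.B = np.zeros((nh, ng))
        self.C = np.zeros((nh, ng))
        self.D = np.zeros((nh, ng))
        self.hb_mask = np.zeros((nh, ng), dtype=bool)
        for i, ha in enumerate(host.atoms):
            for j, ga in enumerate(guest.atoms):
                roles = (ha.hbond_role, ga.hbond_role)
                if roles == ("donor-H", "acceptor"):
                    hb = params.hbond_pair(ha.ff_type, ga.ff_type)
                elif roles == ("acceptor", "donor-H"):
                    hb = params.hbond_pair(ga.ff_type, ha.ff_type)
                else:
                    hb = None
                if hb is not None:
                    self.hb_mask[i, j] = True
                    self.C[i, j], self.D[i, j] = hb.C, hb.D
                else:
                    p = params.lj_pair(ha.ff_type, ga.ff_type)
                    self.A[i, j], self.B[i, j] = p.A, p.B
        self.qq = COULOMB * np.outer(host.charges, guest.charges)
        self.host_coords = host.coords

    def _distances(self, guest_coords: np.ndarray) -> np.ndarray:
        """Pair distances, shape (..., n_host, n_guest)."""
        diff = self.host_coords[:, None, :] - guest_coords[..., None, :, :]
        return np.sqrt((diff * diff).sum(axis=-1))

    def energy_components(self, guest_coords: np.ndarray,
                          r_floor: float | None = None) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
        """(lj, ele, hbond) summed over pairs; broadcasts over leading axes.

        ``guest_coords`` may be (n_guest, 3) or (..., n_guest, 3); the
        returned arrays have the leading shape (scalars for a single
        conformation).  With ``r_floor`` set, pair distances are clamped
        below it instead of raising — used by grid scans to keep clashed
        points finite.
        """
        guest_coords = np.asarray(guest_coords, dtype=float)
        r = self._distances(guest_coords)
        if r_floor is not None:
            r = np.maximum(r, r_floor)
        elif np.any(r < MIN_SEPARATION):
            idx = np.unravel_index(int(np.argmin(r)), r.shape)
            raise ForceFieldError(
                f"coincident atoms: host {idx[-2]} / guest {idx[-1]} at R={r[idx]:.2e} Å")
        inv2 = 1.0 / (r * r)
        inv6 = inv2 * inv2 * inv2
        inv10 = inv6 * inv2 * inv2
        inv12 = inv6 * inv6
        lj = (self.A * inv12 - self.B * inv6).sum(axis=(-2, -1))
        hb = (self.C * inv12 - self.D * inv10).sum(axis=(-2, -1))
        ele = (self.qq / (self.solvent.epsilon * r)).sum(axis=(-2, -1))
        return lj, ele, hb

    def guest_forces(self, guest_coords: np.ndarray) -> np.ndarray:
        """Analytic intermolecular force on each guest atom, kcal/mol/Å."""
        guest_coords = np.asarray(guest_coords, dtype=float)
        diff = guest_coords[None, :, :] - self.host_coords[:, None, :]  # (nh, ng, 3): host→guest
        r2 = (diff * diff).sum(axis=-1)
        r = np.sqrt(r2)
        if np.any(r < MIN_SEPARATION):
            raise ForceFieldError("coincident atoms in force evaluation")
        inv2 = 1.0 / r2
        inv6 = inv2 * inv2 * inv2
        inv8 = inv6 * inv2
        inv12 = inv6 * inv6
        inv14 = inv12 * inv2
        # -dU/dR / R for each term; force on guest atom j = sum_i coeff * diff_ij
        coeff = (12.0 * self.A * inv14 - 6.0 * self.B * inv8
                 + 12.0 * self.C * inv14 - 10.0 * self.D * inv12
                 + self.qq / self.solvent.epsilon * inv2 / r)
        return (coeff[:, :, None] * diff).sum(axis=0)


def intermolecular_energy(host: ParameterizedMolecule, guest_coords: np.ndarray,
                          guest: ParameterizedMolecule, params: ParameterTable,
                          solvent: SolventModel) -> tuple[float, float, float]:
    """(lj, ele, hbond) in kcal/mol summed over all host-guest pairs."""
    model = InteractionModel(host, guest, params, solvent)
    lj, ele, hb = model.energy_components(guest_coords)
    return float(lj), float(ele), float(hb)


# ---------------------------------------------------------------------------
# Intramolecular terms

def dihedral_angle(p0: np.ndarray, p1: np.ndarray, p2: np.ndarray, p3: np.ndarray) -> float:
    """Signed torsion angle (rad) of the chain p0-p1-p2-p3."""
    b0, b1, b2 = p1 - p0, p2 - p1, p3 - p2
    n1 = np.cross(b0, b1)
    n2 = np.cross(b1, b2)
    norm_b1 = np.linalg.norm(b1)
    if norm_b1 < 1e-12 or np.linalg.norm(n1) < 1e-12 or np.linalg.norm(n2) < 1e-12:
        raise ForceFieldError("undefined dihedral: collinear atoms")
    return math.atan2(float(np.dot(np.cross(n1, n2), b1) / norm_b1), float(np.dot(n1, n2)))


def intramolecular_energy(molecule: ParameterizedMolecule, coords: np.ndarray,
                          params: ParameterTable) -> tuple[float, float, float]:
    """(bond, angle, torsion) in kcal/mol for the given conformation."""
    coords = np.asarray(coords, dtype=float)
    types = [a.ff_type for a in molecule.atoms]

    e_bond = 0.0
    for i, j in molecule.bonds:
        p = params.bond_for(types[i], types[j])
        r = float(np.linalg.norm(coords[i] - coords[j]))
        e_bond += p.kr * (r - p.req) ** 2

    e_angle = 0.0
    for i, j, k in molecule.angles:
        p = params.angle_for(types[i], types[j], types[k])
        v1 = coords[i] - coords[j]
        v2 = coords[k] - coords[j]
        cosang = float(np.dot(v1, v2) / (np.linalg.norm(v1) * np.linalg.norm(v2)))
        theta = math.acos(max(-1.0, min(1.0, cosang)))
        e_angle += p.ktheta * (theta - p.thetaeq) ** 2

    e_torsion = 0.0
    for i, j, k, l in molecule.torsions:
        phi = dihedral_angle(coords[i], coords[j], coords[k], coords[l])
        for term in params.torsion_for(types[i], types[j], types[k], types[l]):
            e_torsion += 0.5 * term.vn * (1.0 + math.cos(term.n * phi - term.gamma))

    return e_bond, e_angle, e_torsion


# ---------------------------------------------------------------------------
# Totals, forces, torques

def total_energy(host: ParameterizedMolecule, guest: ParameterizedMolecule, pose: Pose,
                 params: ParameterTable, solvent: SolventModel,
                 model: InteractionModel | None = None) -> EnergyBreakdown:
    """Full energy decomposition of the complex at a guest pose.

    The guest's internal energy depends only on its stored conformation
    (placement is rigid) but is evaluated from the placed coordinates,
    which is equivalent.
    """
    guest_coords = place_guest(guest, pose)
    if model is None:
        model = InteractionModel(host, guest, params, solvent)
    lj, ele, hb = model.energy_components(guest_coords)
    eb, ea, et = intramolecular_energy(guest, guest_coords, params) if guest.bonds or guest.angles \
        or guest.torsions else (0.0, 0.0, 0.0)
    return EnergyBreakdown(lj=float(lj), ele=float(ele), hbond=float(hb),
                           bond=eb, angle=ea, torsion=et)


def force_and_torque(host: ParameterizedMolecule, guest: ParameterizedMolecule, pose: Pose,
                     params: ParameterTable, solvent: SolventModel,
                     model: InteractionModel | None = None) -> tuple[np.ndarray, np.ndarray]:
    """Net intermolecular force (kcal/mol/Å) on the guest COM and torque
    (kcal/mol) about the COM, both in the lab frame."""
    if model is None:
        model = InteractionModel(host, guest, params, solvent)
    guest_coords = place_guest(guest, pose)
    f_atoms = model.guest_forces(guest_coords)
    force = f_atoms.sum(axis=0)
    rel = guest_coords - pose.com
    torque = np.cross(rel, f_atoms).sum(axis=0)
    return force, torque
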