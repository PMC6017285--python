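"""Synthetic host-guest systems and independent energy oracles.

Real cyclodextrin coordinate/charge sets are external inputs; this module
generates idealized stand-ins so the whole pipeline can run and be tested
self-contained:

* a truncated-cone *toy host* of Lennard-Jones sites (βCD-like: cavity
  inner diameter ≈ 6-6.5 Å, height ≈ 8 Å) with optional rim charges and
  hydrogen-bond acceptor sites;
* a rod-like *toy guest* (~10 sites, one polar donor-H end, an optional
  rotatable-torsion zig-zag backbone);
* a single-particle *harmonic probe* with closed-form energy, force and
  oscillation period, for integrator and scan oracles;
* ``brute_force_energy`` — a deliberately naive pure-Python double-loop
  energy evaluation sharing no code with :mod:`inclusim.forcefield`;
* ``packaged_bcd_eugenol`` — a best-effort β-cyclodextrin/eugenol pair
  built at run time from connectivity (RDKit 3D embedding + Gasteiger
  charges).  These are synthetic reconstructions, *not* literature
  coordinate/charge sets, and carry no stereochemistry for the host.

All generators are deterministic given their spec.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np

from .constants import COULOMB, KCAL_PER_MOL_TO_AMU_A2_FS2
from .forcefield import EnergyBreakdown, ParameterTable, SolventModel
from .structures import Atom, ParameterizedMolecule, Pose, derive_topology

__all__ = [
    "ToyHostSpec",
    "ToyGuestSpec",
    "make_toy_host",
    "make_toy_guest",
    "toy_parameter_table",
    "default_study_system",
    "HarmonicProbe",
    "make_harmonic_probe",
    "brute_force_energy",
    "packaged_bcd_eugenol",
]


@dataclass(frozen=True)
class ToyHostSpec:
    """Truncated-cone host: rings of identical LJ sites between two rims.

    The narrow rim sits at -height/2, the wide rim at +height/2, matching
    the package convention that +Z points toward the wider rim.  Rim
    charges are ±``rim_charge`` on the narrow/wide rim rings (net zero).
    ``n_rim_acceptors`` sites on the wide rim are flagged as hydrogen-bond
    acceptors (ff type ``OA``).
    """

    n_rings: int = 4
    sites_per_ring: int = 10
    narrow_radius: float = 3.0   # Å
    wide_radius: float = 3.9     # Å
    height: float = 8.0          # Å
    epsilon_site: float = 0.135  # kcal/mol LJ well depth per site
    rmin_site: float = 3.6       # Å LJ minimum distance per site
    rim_charge: float = 0.05     # e
    n_rim_acceptors: int = 2

    def __post_init__(self):
        if self.narrow_radius <= 0 or self.wide_radius < self.narrow_radius:
            raise ValueError("need 0 < narrow_radius <= wide_radius")
        if self.height <= 0 or self.n_rings < 2 or self.sites_per_ring < 3:
            raise ValueError("degenerate toy host spec")
        if self.n_rim_acceptors > self.sites_per_ring:
            raise ValueError("more rim acceptors than rim sites")


@dataclass(frozen=True)
class ToyGuestSpec:
    """Rod guest: n_sites along the body Z axis with a polar donor-H end.

    The long axis is body Z so that the identity orientation aligns the
    rod with the host's cavity axis.

    With ``torsion`` set, the backbone is a shallow planar zig-zag (so
    every dihedral is well defined) and bonds/angles/torsions are
    parameterized; without it the rod is straight and carries no bonded
    terms.
    """

    n_sites: int = 10
    spacing: float = 1.1        # Å between consecutive sites (x-projection)
    epsilon_site: float = 0.12  # kcal/mol
    rmin_site: float = 3.4      # Å
    polar_charge: float = 0.25  # e on the terminal donor-H site (and -q on its neighbour)
    zig: float = 0.3            # Å transverse zig-zag amplitude (used when torsion is set)
    # (Vn kcal/mol, n, gamma rad): phase pi puts the planar-trans backbone at a
    # torsional maximum, giving the rigid guest a positive constant Eintra
    torsion: tuple[float, int, float] | None = (0.81, 3, math.pi)

    def __post_init__(self):
        if self.n_sites < 1 or self.spacing <= 0:
            raise ValueError("degenerate toy guest spec")


def make_toy_host(spec: ToyHostSpec = ToyHostSpec()) -> ParameterizedMolecule:
    """Build the truncated-cone host, centred on the origin, axis = Z."""
    atoms = []
    zs = np.linspace(-spec.height / 2, spec.height / 2, spec.n_rings)
    radii = np.linspace(spec.narrow_radius, spec.wide_radius, spec.n_rings)
    for ring, (z, radius) in enumerate(zip(zs, radii)):
        # stagger alternate rings by half a site for a less artificial
        # lattice; the pattern is mirror-symmetric about the midplane so an
        # equal-rim host is exactly Z → −Z symmetric
        phase = (math.pi / spec.sites_per_ring) * (min(ring, spec.n_rings - 1 - ring) % 2)
        for s in range(spec.sites_per_ring):
            ang = 2 * math.pi * s / spec.sites_per_ring + phase
            pos = np.array([radius * math.cos(ang), radius * math.sin(ang), z])
            charge = 0.0
            ff_type, role = "TH", "none"
            if ring == 0:
                charge = spec.rim_charge
            elif ring == spec.n_rings - 1:
                charge = -spec.rim_charge
                if s < spec.n_rim_acceptors:
                    ff_type, role = "OA", "acceptor"
            atoms.append(Atom(element="X", name=f"T{ring}{s}", position=pos,
                              charge=charge, ff_type=ff_type, hbond_role=role))
    return ParameterizedMolecule(atoms=atoms, role="host")


def make_toy_guest(spec: ToyGuestSpec = ToyGuestSpec()) -> ParameterizedMolecule:
    """Build the rod guest along body Z, centred on its own COM."""
    atoms = []
    n = spec.n_sites
    for i in range(n):
        x = spec.zig * (-1) ** i if (spec.torsion is not None and n >= 4) else 0.0
        pos = np.array([x, 0.0, i * spec.spacing])
        charge, ff_type, role = 0.0, "TG", "none"
        if n >= 2 and spec.polar_charge:
            if i == n - 1:
                charge, ff_type, role = spec.polar_charge, "HD", "donor-H"
            elif i == n - 2:
                charge = -spec.polar_charge
        atoms.append(Atom(element="X", name=f"G{i}", position=pos,
                          charge=charge, ff_type=ff_type, hbond_role=role))
    mol = ParameterizedMolecule(atoms=atoms, bonds=[(i, i + 1) for i in range(n - 1)],
                                role="guest")
    # recentre on the COM so identity pose reproduces the stored coordinates
    mol = mol.with_coords(mol.coords - mol.reference_com)
    if spec.torsion is not None and n >= 4:
        mol = derive_topology(mol)
    return mol


def toy_parameter_table(host_spec: ToyHostSpec = ToyHostSpec(),
                        guest_spec: ToyGuestSpec = ToyGuestSpec()) -> ParameterTable:
    """Parameter table consistent with the generated toy geometries.

    Bond and angle equilibria are taken from the constructed zig-zag, so
    the reference conformation has zero stretch/bend energy; the torsion
    term is nonzero for the planar chain, giving the positive internal
    energy typical of a bound guest.
    """
    from .forcefield import (AngleParam, BondParam, HBondParam, LJParam, TorsionTerm)

    table = ParameterTable()

    table.lj["TH"] = LJParam.from_eps_rmin(host_spec.epsilon_site, host_spec.rmin_site)
    table.lj["OA"] = LJParam.from_eps_rmin(0.20, 3.2)
    table.lj["TG"] = LJParam.from_eps_rmin(guest_spec.epsilon_site, guest_spec.rmin_site)
    table.lj["HD"] = LJParam.from_eps_rmin(0.02, 2.0)
    table.hbond[("HD", "OA")] = HBondParam(C=7557.0, D=2385.0)

    if guest_spec.torsion is not None and guest_spec.n_sites >= 4:
        s, d = guest_spec.spacing, guest_spec.zig
        req = math.sqrt(s * s + 4 * d * d)
        # interior angle of the planar zig-zag
        thetaeq = math.pi - 2 * math.atan2(2 * d, s)
        vn, n, gamma = guest_spec.torsion
        for key in (("TG", "TG"), ("TG", "HD")):
            table.bonds[min(key, key[::-1])] = BondParam(kr=300.0, req=req)
        for key in (("TG", "TG", "TG"), ("TG", "TG", "HD")):
            table.angles[min(key, key[::-1])] = AngleParam(ktheta=60.0, thetaeq=thetaeq)
        table.torsions[("*", "TG", "TG", "*")] = [TorsionTerm(vn=vn, n=n, gamma=gamma)]
    else:
        from .forcefield import BondParam as _BP
        table.bonds[("TG", "TG")] = _BP(kr=300.0, req=guest_spec.spacing)
        table.bonds[("HD", "TG")] = _BP(kr=300.0, req=guest_spec.spacing)
    return table


def default_study_system() -> tuple[ParameterizedMolecule, ParameterizedMolecule, ParameterTable]:
    """The default toy complexation system: (host, guest, parameters).

    Site well depths are fixed so the cavity minimum of the rod guest is
    roughly −10 kcal/mol — the energy scale typical of small-molecule
    cyclodextrin complexation — with a continuum-water electrostatic
    contribution a few 10⁻² kcal/mol.
    """
    host_spec, guest_spec = ToyHostSpec(), ToyGuestSpec()
    return (make_toy_host(host_spec), make_toy_guest(guest_spec),
            toy_parameter_table(host_spec, guest_spec))


# ---------------------------------------------------------------------------
# Harmonic probe

@dataclass(frozen=True)
class HarmonicProbe:
    """Single particle in an isotropic harmonic well ½ k |r|²."""

    k: float  # kcal/mol/Å²
    m: float  # amu

    def energy(self, r: np.ndarray) -> float:
        r = np.asarray(r, dtype=float)
        return 0.5 * self.k * float(r @ r)

    def force(self, r: np.ndarray) -> np.ndarray:
        return -self.k * np.asarray(r, dtype=float)

    @property
    def omega(self) -> float:
        """Angular frequency in rad/fs."""
        return math.sqrt(self.k * KCAL_PER_MOL_TO_AMU_A2_FS2 / self.m)

    @property
    def period(self) -> float:
        """Oscillation period in fs."""
        return 2 * math.pi / self.omega


def make_harmonic_probe(k: float = 1.0, m: float = 12.0) -> HarmonicProbe:
    if k <= 0 or m <= 0:
        raise ValueError("k and m must be positive")
    return HarmonicProbe(k=k, m=m)


# ---------------------------------------------------------------------------
# Brute-force oracle

def brute_force_energy(host: ParameterizedMolecule, guest: ParameterizedMolecule,
                       pose: Pose, params: ParameterTable,
                       solvent: SolventModel) -> EnergyBreakdown:
    """Plain-Python double-loop energy evaluation (independent oracle).

    Intentionally naive: explicit quaternion rotation, per-pair parameter
    lookups and scalar arithmetic, sharing no evaluation code with
    :mod:`inclusim.forcefield`.
    """
    # rigid placement via the explicit quaternion rotation formula
    w, x, y, z = (float(v) for v in pose.quaternion)
    norm = math.sqrt(w * w + x * x + y * y + z * z)
    w, x, y, z = w / norm, x / norm, y / norm, z / norm
    rot = [
        [1 - 2 * (y * y + z * z), 2 * (x * y - w * z), 2 * (x * z + w * y)],
        [2 * (x * y + w * z), 1 - 2 * (x * x + z * z), 2 * (y * z - w * x)],
        [2 * (x * z - w * y), 2 * (y * z + w * x), 1 - 2 * (x * x + y * y)],
    ]
    masses = [a.mass for a in guest.atoms]
    mtot = sum(masses)
    com_ref = [sum(m * a.position[d] for m, a in zip(masses, guest.atoms)) / mtot
               for d in range(3)]
    placed = []
    for a in guest.atoms:
        rel = [a.position[d] - com_ref[d] for d in range(3)]
        placed.append(tuple(sum(rot[r][c] * rel[c] for c in range(3)) + pose.com[r]
                            for r in range(3)))

    lj = ele = hb = 0.0
    for ha in host.atoms:
        for ga, gpos in zip(guest.atoms, placed):
            dx = ha.position[0] - gpos[0]
            dy = ha.position[1] - gpos[1]
            dz = ha.position[2] - gpos[2]
            r = math.sqrt(dx * dx + dy * dy + dz * dz)
            pair_is_hb = ({ha.hbond_role, ga.hbond_role} == {"donor-H", "acceptor"})
            if pair_is_hb:
                donor = ha.ff_type if ha.hbond_role == "donor-H" else ga.ff_type
                accep = ga.ff_type if ha.hbond_role == "donor-H" else ha.ff_type
                p = params.hbond.get((donor, accep)) or params.hbond.get(("*", "*"))
                if p is None:
                    raise KeyError(f"no hbond params for {donor}-{accep}")
                hb += p.C / r**12 - p.D / r**10
            else:
                key = (ha.ff_type, ga.ff_type)
                pp = params.lj_pairs.get(min(key, key[::-1]))
                if pp is not None:
                    a_ij, b_ij = pp.A, pp.B
                else:
                    pa, pb = params.lj[ha.ff_type], params.lj[ga.ff_type]
                    a_ij = math.sqrt(pa.A * pb.A)
                    b_ij = math.sqrt(pa.B * pb.B)
                lj += a_ij / r**12 - b_ij / r**6
            ele += COULOMB * ha.charge * ga.charge / (solvent.epsilon * r)

    types = [a.ff_type for a in guest.atoms]
    e_bond = 0.0
    for i, j in guest.bonds:
        d = [placed[i][c] - placed[j][c] for c in range(3)]
        r = math.sqrt(sum(v * v for v in d))
        key = min((types[i], types[j]), (types[j], types[i]))
        bp = params.bonds[key]
        e_bond += bp.kr * (r - bp.req) ** 2
    e_angle = 0.0
    for i, j, k_ in guest.angles:
        v1 = [placed[i][c] - placed[j][c] for c in range(3)]
        v2 = [placed[k_][c] - placed[j][c] for c in range(3)]
        dot = sum(a * b for a, b in zip(v1, v2))
        n1 = math.sqrt(sum(v * v for v in v1))
        n2 = math.sqrt(sum(v * v for v in v2))
        theta = math.acos(max(-1.0, min(1.0, dot / (n1 * n2))))
        key = min((types[i], types[j], types[k_]), (types[k_], types[j], types[i]))
        ap = params.angles[key]
        e_angle += ap.ktheta * (theta - ap.thetaeq) ** 2
    e_tors = 0.0
    for i, j, k_, l in guest.torsions:
        b0 = [placed[j][c] - placed[i][c] for c in range(3)]
        b1 = [placed[k_][c] - placed[j][c] for c in range(3)]
        b2 = [placed[l][c] - placed[k_][c] for c in range(3)]
        n1 = (b0[1] * b1[2] - b0[2] * b1[1], b0[2] * b1[0] - b0[0] * b1[2],
              b0[0] * b1[1] - b0[1] * b1[0])
        n2 = (b1[1] * b2[2] - b1[2] * b2[1], b1[2] * b2[0] - b1[0] * b2[2],
              b1[0] * b2[1] - b1[1] * b2[0])
        m1 = (n1[1] * b1[2] - n1[2] * b1[1], n1[2] * b1[0] - n1[0] * b1[2],
              n1[0] * b1[1] - n1[1] * b1[0])
        nb1 = math.sqrt(sum(v * v for v in b1))
        phi = math.atan2(sum(a * b for a, b in zip(m1, n2)) / nb1,
                         sum(a * b for a, b in zip(n1, n2)))
        key = min((types[i], types[j], types[k_], types[l]),
                  (types[l], types[k_], types[j], types[i]))
        terms = params.torsions.get(key)
        if terms is None:
            wkey = min(("*", types[j], types[k_], "*"), ("*", types[k_], types[j], "*"))
            terms = params.torsions[wkey]
        for t in terms:
            e_tors += 0.5 * t.vn * (1.0 + math.cos(t.n * phi - t.gamma))

    return EnergyBreakdown(lj=lj, ele=ele, hbond=hb,
                           bond=e_bond, angle=e_angle, torsion=e_tors)


# ---------------------------------------------------------------------------
# Best-effort real molecules (optional extra: needs RDKit)

#: Generic per-element 12-6 parameters (well depth kcal/mol, Rmin Å) for the
#: best-effort assets; roughly OPLS/AMBER-magnitude values.
_ELEMENT_LJ = {
    "C": (0.086, 3.82), "O": (0.17, 3.32), "H": (0.015, 2.6), "HO": (0.0, 1.2),
}


def _bcd_smiles() -> str:
    """Cyclic alpha-1,4 heptaglucan (no stereochemistry) as SMILES."""
    units = []
    for i in range(7):
        r = 30 + i
        head = f"C%11%{r}" if i == 0 else f"C%{r}"
        tail = "O%11" if i == 6 else "O"
        units.append(f"{head}C(O)C(O)C(OC%{r}CO){tail}")
    return "".join(units)


def _molecule_from_rdkit(mol, role: str, seed: int) -> ParameterizedMolecule:
    from rdkit.Chem import AllChem

    ps = AllChem.ETKDGv3()
    ps.randomSeed = seed
    if AllChem.EmbedMolecule(mol, ps) != 0:
        raise RuntimeError("3D embedding failed; use the toy systems instead")
    AllChem.MMFFOptimizeMolecule(mol, maxIters=2000)
    AllChem.ComputeGasteigerCharges(mol)
    conf = mol.GetConformer()
    atoms = []
    for at in mol.GetAtoms():
        elem = at.GetSymbol()
        pos = conf.GetAtomPosition(at.GetIdx())
        charge = float(at.GetDoubleProp("_GasteigerCharge"))
        role_hb, ff = "none", elem
        if elem == "O":
            role_hb = "acceptor"
        elif elem == "H" and any(n.GetSymbol() == "O" for n in at.GetNeighbors()):
            role_hb, ff = "donor-H", "HO"
        atoms.append(Atom(element=elem, name=f"{elem}{at.GetIdx() + 1}",
                          position=np.array([pos.x, pos.y, pos.z]),
                          charge=charge, ff_type=ff, hbond_role=role_hb))
    bonds = [(b.GetBeginAtomIdx(), b.GetEndAtomIdx()) for b in mol.GetBonds()]
    out = ParameterizedMolecule(atoms=atoms, bonds=bonds, role=role)
    com = out.reference_com
    return derive_topology(out.with_coords(out.coords - com))


def packaged_bcd_eugenol(seed: int = 2026) -> tuple[ParameterizedMolecule, ParameterizedMolecule, ParameterTable]:
    """Best-effort β-cyclodextrin and eugenol, built from connectivity.

    Both molecules are *synthetic reconstructions*: 3D conformers embedded
    from bond graphs (the host without stereochemistry) with Gasteiger
    point charges and generic element-based Lennard-Jones parameters.
    They reproduce composition and rough shape, not any literature
    coordinate or charge set.  Requires RDKit; raises an informative
    error steering to the toy systems when it is unavailable.
    """
    try:
        from rdkit import Chem
    except ImportError as exc:
        raise RuntimeError(
            "packaged β-CD/eugenol assets need RDKit; install the 'assets' extra "
            "or use fixtures.default_study_system() for the self-contained toys"
        ) from exc

    host_mol = Chem.AddHs(Chem.MolFromSmiles(_bcd_smiles()))
    guest_mol = Chem.AddHs(Chem.MolFromSmiles("COc1cc(CC=C)ccc1O"))
    host = _molecule_from_rdkit(host_mol, "host", seed)
    host = ParameterizedMolecule(atoms=host.atoms, bonds=host.bonds,
                                 angles=host.angles, torsions=host.torsions, role="host")
    guest = _molecule_from_rdkit(guest_mol, "guest", seed + 1)

    from .forcefield import AngleParam, BondParam, HBondParam, LJParam, TorsionTerm

    table = ParameterTable()
    for ff, (eps, rmin) in _ELEMENT_LJ.items():
        table.lj[ff] = LJParam.from_eps_rmin(eps, rmin) if eps > 0 else LJParam(A=1.0, B=0.0)
    table.hbond[("*", "*")] = HBondParam(C=7557.0, D=2385.0)

    # crude bonded parameters for the guest: equilibria are per-type means of
    # the embedded conformer, so the reference conformation sits near (not at)
    # its internal-energy minimum
    coords = guest.coords
    types = [a.ff_type for a in guest.atoms]
    by_key: dict[tuple, list[float]] = {}
    for i, j in guest.bonds:
        key = min((types[i], types[j]), (types[j], types[i]))
        by_key.setdefault(key, []).append(float(np.linalg.norm(coords[i] - coords[j])))
    for key, vals in by_key.items():
        table.bonds[key] = BondParam(kr=300.0, req=float(np.mean(vals)))
    by_key = {}
    for i, j, k in guest.angles:
        v1, v2 = coords[i] - coords[j], coords[k] - coords[j]
        cosang = float(v1 @ v2 / (np.linalg.norm(v1) * np.linalg.norm(v2)))
        theta = math.acos(max(-1.0, min(1.0, cosang)))
        key = min((types[i], types[j], types[k]), (types[k], types[j], types[i]))
        by_key.setdefault(key, []).append(theta)
    for key, vals in by_key.items():
        table.angles[key] = AngleParam(ktheta=60.0, thetaeq=float(np.mean(vals)))
    for i, j, k, l in guest.torsions:
        key = min(("*", types[j], types[k], "*"), ("*", types[k], types[j], "*"))
        table.torsions.setdefault(key, [TorsionTerm(vn=1.0, n=3, gamma=0.0)])
    return host, guest, table
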