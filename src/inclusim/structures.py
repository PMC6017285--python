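"""Molecular structures, reference frames and rigid placement.

Hosts and guests are :class:`ParameterizedMolecule` objects: ordered atoms
with coordinates (Å), partial charges (e), force-field atom types and a
bonded topology.  The host defines the laboratory frame: its centre of
mass is the origin and the cavity (cone) axis is Z, with +Z pointing
toward the wider rim.  A guest configuration is a :class:`Pose` — a
centre-of-mass position plus a unit quaternion orientation.

Orientation conventions
-----------------------
Quaternions are stored scalar-first ``(w, x, y, z)``.  Euler angles use
the intrinsic Z-Y-Z convention (alpha about Z, beta about the new Y,
gamma about the newest Z), the classic rigid-rotor convention.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field, replace

import numpy as np
from scipy.spatial.transform import Rotation

from .constants import ATOMIC_MASSES

logger = logging.getLogger(__name__)

__all__ = [
    "Atom",
    "ParameterizedMolecule",
    "Pose",
    "HostFrame",
    "read_structure",
    "write_structure",
    "derive_topology",
    "host_frame",
    "place_guest",
    "euler_to_quaternion",
    "quaternion_to_matrix",
]


class StructureError(ValueError):
    """Raised for malformed structure files or degenerate geometry."""


@dataclass
class Atom:
    """One atomic site.

    ``hbond_role`` marks participation in the 12-10 hydrogen-bond term:
    ``"donor-H"`` for a polar hydrogen, ``"acceptor"`` for a lone-pair
    bearing heavy atom, ``"none"`` otherwise.
    """

    element: str
    name: str
    position: np.ndarray
    charge: float = 0.0
    ff_type: str = ""
    hbond_role: str = "none"

    def __post_init__(self) -> None:
        self.position = np.asarray(self.position, dtype=float)
        if self.position.shape != (3,) or not np.all(np.isfinite(self.position)):
            raise StructureError(f"atom {self.name}: position must be a finite 3-vector")
        if not np.isfinite(self.charge):
            raise StructureError(f"atom {self.name}: charge must be finite")
        if self.hbond_role not in ("donor-H", "acceptor", "none"):
            raise StructureError(f"atom {self.name}: bad hbond_role {self.hbond_role!r}")

    @property
    def mass(self) -> float:
        try:
            return ATOMIC_MASSES[self.element]
        except KeyError:
            raise StructureError(f"unknown element {self.element!r}") from None


@dataclass
class ParameterizedMolecule:
    """An ordered collection of atoms with bonded topology.

    ``bonds``/``angles``/``torsions`` hold index tuples into ``atoms``.
    ``role`` is ``"host"`` or ``"guest"``.
    """

    atoms: list[Atom]
    bonds: list[tuple[int, int]] = field(default_factory=list)
    angles: list[tuple[int, int, int]] = field(default_factory=list)
    torsions: list[tuple[int, int, int, int]] = field(default_factory=list)
    role: str = "guest"

    def __post_init__(self) -> None:
        n = len(self.atoms)
        for group, width in ((self.bonds, 2), (self.angles, 3), (self.torsions, 4)):
            for idx in group:
                if len(idx) != width or any(i < 0 or i >= n for i in idx):
                    raise StructureError(f"topology index {idx} out of range for {n} atoms")
        if self.role not in ("host", "guest"):
            raise StructureError(f"role must be host|guest, got {self.role!r}")
        if n and self.total_mass <= 0:
            raise StructureError("total mass must be positive")

    def __len__(self) -> int:
        return len(self.atoms)

    @property
    def coords(self) -> np.ndarray:
        """(n, 3) coordinate array in Å."""
        return np.array([a.position for a in self.atoms], dtype=float)

    @property
    def charges(self) -> np.ndarray:
        return np.array([a.charge for a in self.atoms], dtype=float)

    @property
    def masses(self) -> np.ndarray:
        return np.array([a.mass for a in self.atoms], dtype=float)

    @property
    def total_mass(self) -> float:
        return float(self.masses.sum())

    @property
    def reference_com(self) -> np.ndarray:
        """Mass-weighted centroid of the stored coordinates (Å)."""
        m = self.masses
        return (self.coords * m[:, None]).sum(axis=0) / m.sum()

    def with_coords(self, coords: np.ndarray) -> "ParameterizedMolecule":
        """Copy of the molecule carrying new coordinates."""
        coords = np.asarray(coords, dtype=float)
        if coords.shape != (len(self.atoms), 3):
            raise StructureError("coordinate array shape mismatch")
        atoms = [replace(a, position=c.copy()) for a, c in zip(self.atoms, coords)]
        return replace(self, atoms=atoms)

    def inertia_tensor(self, about_com: bool = True) -> np.ndarray:
        """Inertia tensor (amu·Å²) about the COM (or the origin)."""
        r = self.coords
        if about_com:
            r = r - self.reference_com
        m = self.masses
        r2 = (r * r).sum(axis=1)
        eye = np.eye(3)
        return (m[:, None, None] * (r2[:, None, None] * eye - r[:, :, None] * r[:, None, :])).sum(axis=0)


# ---------------------------------------------------------------------------
# Orientation helpers

def _normalize_quat(q: np.ndarray) -> np.ndarray:
    q = np.asarray(q, dtype=float)
    norm = np.linalg.norm(q)
    if q.shape != (4,) or not np.isfinite(norm) or norm == 0.0:
        raise StructureError("quaternion must be a finite nonzero 4-vector")
    return q / norm


def euler_to_quaternion(alpha: float, beta: float, gamma: float) -> np.ndarray:
    """Intrinsic Z-Y-Z Euler angles (rad) → unit quaternion (w, x, y, z)."""
    rot = Rotation.from_euler("ZYZ", [alpha, beta, gamma])
    x, y, z, w = rot.as_quat()
    q = np.array([w, x, y, z])
    return q if w >= 0 else -q


def quaternion_to_matrix(q: np.ndarray) -> np.ndarray:
    """Unit quaternion (w, x, y, z) → 3×3 rotation matrix."""
    w, x, y, z = _normalize_quat(q)
    return Rotation.from_quat([x, y, z, w]).as_matrix()


@dataclass
class Pose:
    """Guest centre-of-mass position (Å) and orientation in the host frame."""

    com: np.ndarray
    quaternion: np.ndarray = field(default_factory=lambda: np.array([1.0, 0, 0, 0]))

    def __post_init__(self) -> None:
        self.com = np.asarray(self.com, dtype=float)
        if self.com.shape != (3,) or not np.all(np.isfinite(self.com)):
            raise StructureError("pose com must be a finite 3-vector")
        q = np.asarray(self.quaternion, dtype=float)
        if abs(np.linalg.norm(q) - 1.0) > 1e-12:
            q = _normalize_quat(q)
        self.quaternion = q

    @classmethod
    def from_euler(cls, com: np.ndarray, alpha: float, beta: float, gamma: float) -> "Pose":
        return cls(com=np.asarray(com, dtype=float), quaternion=euler_to_quaternion(alpha, beta, gamma))

    @property
    def rotation(self) -> np.ndarray:
        return quaternion_to_matrix(self.quaternion)


@dataclass
class HostFrame:
    """Host-fixed reference frame: origin at host COM, Z along the cone axis."""

    origin: np.ndarray
    axes: np.ndarray  # rows are the X, Y, Z unit vectors in lab coordinates

    def __post_init__(self) -> None:
        self.origin = np.asarray(self.origin, dtype=float)
        self.axes = np.asarray(self.axes, dtype=float)
        if not np.allclose(self.axes @ self.axes.T, np.eye(3), atol=1e-12):
            raise StructureError("frame axes must be orthonormal")
        if np.linalg.det(self.axes) < 0:
            raise StructureError("frame axes must be right-handed (det +1)")

    def to_frame(self, coords: np.ndarray) -> np.ndarray:
        """Lab coordinates → host-frame coordinates."""
        return (np.asarray(coords) - self.origin) @ self.axes.T


def host_frame(host: ParameterizedMolecule) -> HostFrame:
    """Principal-axes frame of the host with Z along the cavity axis.

    The cone axis is identified as the unique principal axis — the
    eigenvector whose moment of inertia is farthest from the other two
    (for an axisymmetric cone two moments are degenerate).  The +Z sign
    is fixed so that the wider rim lies at positive Z, detected from the
    mass-weighted correlation between axial position and radial spread.
    """
    if len(host) < 3:
        raise StructureError("host frame needs at least 3 atoms")
    inertia = host.inertia_tensor()
    evals, evecs = np.linalg.eigh(inertia)
    spread = evals.max() - evals.min()
    if spread < 1e-10 * max(1.0, abs(evals).max()):
        raise StructureError("degenerate inertia tensor: cavity axis undefined")
    if evals.min() < 1e-10 * evals.max():
        raise StructureError("collinear host: cavity axis undefined")
    # distance of each eigenvalue to its nearest neighbour → unique axis
    gaps = [min(abs(evals[i] - evals[j]) for j in range(3) if j != i) for i in range(3)]
    z_idx = int(np.argmax(gaps))
    z_axis = evecs[:, z_idx]
    x_axis = evecs[:, (z_idx + 1) % 3]

    com = host.reference_com
    rel = host.coords - com
    z_coord = rel @ z_axis
    radial = np.linalg.norm(rel - np.outer(z_coord, z_axis), axis=1)
    m = host.masses
    corr = float((m * z_coord * radial).sum())
    if corr < 0:  # wider rim currently at -Z: flip
        z_axis = -z_axis
    y_axis = np.cross(z_axis, x_axis)
    axes = np.vstack([x_axis, y_axis, z_axis])
    if np.linalg.det(axes) < 0:
        axes[0] = -axes[0]
    return HostFrame(origin=com, axes=axes)


def place_guest(guest: ParameterizedMolecule, pose: Pose) -> np.ndarray:
    """Rigidly place the guest at a pose; returns (n, 3) coordinates in Å.

    The stored conformation is rotated about its own centre of mass and
    translated so the placed centre of mass equals ``pose.com``.
    """
    rel = guest.coords - guest.reference_com
    return rel @ pose.rotation.T + pose.com


# ---------------------------------------------------------------------------
# Topology

def derive_topology(molecule: ParameterizedMolecule) -> ParameterizedMolecule:
    """Enumerate angles and torsions from the bond graph.

    Every simple 2-bond path i-j-k becomes one angle and every simple
    3-bond path i-j-k-l one torsion, deduplicated under reversal.
    Disconnected atoms simply contribute no bonded terms.
    """
    n = len(molecule)
    adj: list[set[int]] = [set() for _ in range(n)]
    for i, j in molecule.bonds:
        adj[i].add(j)
        adj[j].add(i)

    angles = []
    for j in range(n):
        nb = sorted(adj[j])
        for a in range(len(nb)):
            for b in range(a + 1, len(nb)):
                angles.append((nb[a], j, nb[b]))

    torsions = []
    for j, k in sorted({tuple(sorted(b)) for b in molecule.bonds}):
        for i in sorted(adj[j] - {k}):
            for l in sorted(adj[k] - {j}):
                if i == l:
                    continue  # 3-ring: i-j-k-i is not a proper torsion
                quad = (i, j, k, l)
                if quad[::-1] < quad:
                    quad = quad[::-1]
                torsions.append(quad)
    torsions = sorted(set(torsions))
    return replace(molecule, angles=angles, torsions=torsions)


# ---------------------------------------------------------------------------
# File I/O (XYZ, mol2, PDB)

_MOL2_SYBYL_ELEMENTS = {
    "C": "C.3", "H": "H", "O": "O.3", "N": "N.3", "S": "S.3", "P": "P.3",
    "F": "F", "Cl": "Cl", "Br": "Br", "I": "I", "X": "Du",
}


def _element_from_label(label: str) -> str:
    label = label.strip()
    if not label:
        raise StructureError("empty atom label")
    if label in ("Du", "DU", "du"):  # SYBYL dummy atom → generic toy site
        return "X"
    sym = label[0].upper()
    if len(label) > 1 and label[:2].capitalize() in ATOMIC_MASSES:
        sym = label[:2].capitalize()
    if sym not in ATOMIC_MASSES:
        raise StructureError(f"unknown element in label {label!r}")
    return sym


def _infer_format(path: str, fmt: str | None) -> str:
    if fmt:
        return fmt.lower()
    for ext in ("xyz", "mol2", "pdb"):
        if str(path).lower().endswith("." + ext):
            return ext
    raise StructureError(f"cannot infer format of {path}; pass format=")


def read_structure(path: str, format: str | None = None, role: str = "guest") -> ParameterizedMolecule:
    """Read a molecule from XYZ, mol2 (SYBYL) or PDB.

    Partial charges are trusted only from mol2; PDB/XYZ atoms get zero
    charge.  Topology is populated where the format carries bonds (mol2,
    PDB CONECT) and left empty otherwise.
    """
    fmt = _infer_format(path, format)
    if fmt == "xyz":
        return _read_xyz(path, role)
    if fmt == "mol2":
        return _read_mol2(path, role)
    if fmt == "pdb":
        return _read_pdb(path, role)
    raise StructureError(f"unsupported format {fmt!r}")


def _read_xyz(path: str, role: str) -> ParameterizedMolecule:
    with open(path) as fh:
        lines = fh.read().splitlines()
    try:
        count = int(lines[0].split()[0])
    except (IndexError, ValueError):
        raise StructureError(f"{path}:1: malformed XYZ atom count") from None
    atoms = []
    for ln, line in enumerate(lines[2:2 + count], start=3):
        parts = line.split()
        if len(parts) < 4:
            raise StructureError(f"{path}:{ln}: malformed XYZ record")
        elem = _element_from_label(parts[0])
        try:
            xyz = [float(v) for v in parts[1:4]]
        except ValueError:
            raise StructureError(f"{path}:{ln}: non-numeric coordinate") from None
        atoms.append(Atom(element=elem, name=f"{elem}{ln - 2}", position=np.array(xyz), ff_type=elem))
    if len(atoms) != count:
        raise StructureError(f"{path}: expected {count} atoms, found {len(atoms)}")
    return ParameterizedMolecule(atoms=atoms, role=role)


def _read_mol2(path: str, role: str) -> ParameterizedMolecule:
    atoms: list[Atom] = []
    bonds: list[tuple[int, int]] = []
    section = None
    with open(path) as fh:
        for ln, raw in enumerate(fh, start=1):
            line = raw.strip()
            if not line or line.startswith("#"):
                continue
            if line.startswith("@<TRIPOS>"):
                section = line[len("@<TRIPOS>"):].upper()
                continue
            if section == "ATOM":
                parts = line.split()
                if len(parts) < 6:
                    raise StructureError(f"{path}:{ln}: malformed mol2 ATOM record")
                name, x, y, z, sybyl = parts[1], parts[2], parts[3], parts[4], parts[5]
                charge = float(parts[8]) if len(parts) >= 9 else 0.0
                elem = _element_from_label(sybyl.split(".")[0])
                try:
                    pos = np.array([float(x), float(y), float(z)])
                except ValueError:
                    raise StructureError(f"{path}:{ln}: non-numeric coordinate") from None
                atoms.append(Atom(element=elem, name=name, position=pos, charge=charge, ff_type=sybyl))
            elif section == "BOND":
                parts = line.split()
                if len(parts) < 3:
                    raise StructureError(f"{path}:{ln}: malformed mol2 BOND record")
                bonds.append((int(parts[1]) - 1, int(parts[2]) - 1))
    if not atoms:
        raise StructureError(f"{path}: no ATOM section found")
    return ParameterizedMolecule(atoms=atoms, bonds=bonds, role=role)


def _read_pdb(path: str, role: str) -> ParameterizedMolecule:
    atoms: list[Atom] = []
    bonds: set[tuple[int, int]] = set()
    serial_to_index: dict[int, int] = {}
    with open(path) as fh:
        for ln, line in enumerate(fh, start=1):
            rec = line[:6].strip()
            if rec in ("ATOM", "HETATM"):
                try:
                    serial = int(line[6:11])
                    name = line[12:16].strip()
                    pos = np.array([float(line[30:38]), float(line[38:46]), float(line[46:54])])
                except ValueError:
                    raise StructureError(f"{path}:{ln}: malformed PDB coordinate record") from None
                elem_field = line[76:78].strip()
                elem = _element_from_label(elem_field or name)
                serial_to_index[serial] = len(atoms)
                atoms.append(Atom(element=elem, name=name or elem, position=pos, ff_type=elem))
            elif rec == "CONECT":
                serials = [int(line[i:i + 5]) for i in range(6, min(len(line.rstrip()), 31), 5)
                           if line[i:i + 5].strip()]
                for other in serials[1:]:
                    pair = tuple(sorted((serials[0], other)))
                    bonds.add(pair)
    if not atoms:
        raise StructureError(f"{path}: no ATOM/HETATM records")
    bond_idx = []
    for a, b in sorted(bonds):
        if a in serial_to_index and b in serial_to_index:
            bond_idx.append((serial_to_index[a], serial_to_index[b]))
    if not bond_idx:
        logger.warning("%s: no CONECT records; topology left empty", path)
    return ParameterizedMolecule(atoms=atoms, bonds=bond_idx, role=role)


def write_structure(molecule: ParameterizedMolecule, path: str, format: str | None = None) -> None:
    """Write a molecule as XYZ or mol2 (charges only persist in mol2)."""
    fmt = _infer_format(path, format)
    if fmt == "xyz":
        _write_xyz(molecule, path)
    elif fmt == "mol2":
        _write_mol2(molecule, path)
    else:
        raise StructureError(f"unsupported output format {fmt!r}")


def _write_xyz(molecule: ParameterizedMolecule, path: str) -> None:
    with open(path, "w") as fh:
        fh.write(f"{len(molecule)}\n")
        fh.write("written by inclusim\n")
        for a in molecule.atoms:
            x, y, z = a.position
            fh.write(f"{a.element:<3s} {x:18.10f} {y:18.10f} {z:18.10f}\n")


def _write_mol2(molecule: ParameterizedMolecule, path: str) -> None:
    with open(path, "w") as fh:
        fh.write("@<TRIPOS>MOLECULE\n")
        fh.write(f"{molecule.role}\n")
        fh.write(f"{len(molecule)} {len(molecule.bonds)} 0 0 0\n")
        fh.write("SMALL\nUSER_CHARGES\n")
        fh.write("@<TRIPOS>ATOM\n")
        for i, a in enumerate(molecule.atoms, start=1):
            sybyl = a.ff_type if "." in a.ff_type or a.ff_type in _MOL2_SYBYL_ELEMENTS.values() \
                else _MOL2_SYBYL_ELEMENTS.get(a.element, a.element)
            x, y, z = a.position
            fh.write(f"{i:>6d} {a.name:<8s} {x:12.6f} {y:12.6f} {z:12.6f} "
                     f"{sybyl:<8s} 1 MOL {a.charge:12.8f}\n")
        fh.write("@<TRIPOS>BOND\n")
        for n, (i, j) in enumerate(molecule.bonds, start=1):
            fh.write(f"{n:>6d} {i + 1:>6d} {j + 1:>6d} 1\n")
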