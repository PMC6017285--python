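"""Shared fixtures: toy systems and random-system generators for oracle tests."""

import math

import numpy as np
import pytest

from inclusim import fixtures
from inclusim.forcefield import (AngleParam, BondParam, HBondParam, LJParam,
                                 ParameterTable, SolventModel, TorsionTerm)
from inclusim.structures import Atom, ParameterizedMolecule, derive_topology


@pytest.fixture(scope="session")
def toy_system():
    """Default study system: (host, guest, parameter table)."""
    return fixtures.default_study_system()


@pytest.fixture(scope="session")
def water():
    return SolventModel(epsilon=80.0)


@pytest.fixture
def rng():
    return np.random.default_rng(20260926)


def random_system(rng, n_host=5, n_guest=5, charged=True, with_hbond=True,
                  with_torsion=True, spread=6.0):
    """A small random host/guest pair exercising every energy code path.

    Host atoms sit in a shell at ≥ 2.5 Å from the origin region where the
    guest is placed, so pair distances stay in a numerically sane range.
    """
    types_h = ["RH1", "RH2"]
    types_g = ["RG1", "RG2"]
    table = ParameterTable()
    for t in types_h + types_g + ["RHD", "ROA"]:
        table.lj[t] = LJParam(A=float(rng.uniform(1e4, 1e6)),
                              B=float(rng.uniform(10, 500)))
    table.hbond[("RHD", "ROA")] = HBondParam(C=float(rng.uniform(5e3, 1e4)),
                                             D=float(rng.uniform(1e3, 3e3)))

    host_atoms = []
    for i in range(n_host):
        direction = rng.normal(size=3)
        direction /= np.linalg.norm(direction)
        pos = direction * rng.uniform(2.5, spread)
        ff = types_h[i % 2]
        role = "none"
        if with_hbond and i == 0:
            ff, role = "ROA", "acceptor"
        host_atoms.append(Atom(element="X", name=f"H{i}", position=pos,
                               charge=float(rng.uniform(-0.3, 0.3)) if charged else 0.0,
                               ff_type=ff, hbond_role=role))
    host = ParameterizedMolecule(atoms=host_atoms, role="host")

    guest_atoms = []
    for i in range(n_guest):
        pos = np.array([i * 1.4, 0.25 * ((-1) ** i), 0.1 * i])
        ff = types_g[i % 2]
        role = "none"
        if with_hbond and i == n_guest - 1:
            ff, role = "RHD", "donor-H"
        guest_atoms.append(Atom(element="X", name=f"G{i}", position=pos,
                                charge=float(rng.uniform(-0.3, 0.3)) if charged else 0.0,
                                ff_type=ff, hbond_role=role))
    bonds = [(i, i + 1) for i in range(n_guest - 1)] if with_torsion else []
    guest = ParameterizedMolecule(atoms=guest_atoms, bonds=bonds, role="guest")
    if with_torsion and n_guest >= 2:
        guest = derive_topology(guest)
        seen = set()
        for i, j in guest.bonds:
            key = min((guest.atoms[i].ff_type, guest.atoms[j].ff_type),
                      (guest.atoms[j].ff_type, guest.atoms[i].ff_type))
            if key not in seen:
                table.bonds[key] = BondParam(kr=float(rng.uniform(100, 400)),
                                             req=float(rng.uniform(1.2, 1.6)))
                seen.add(key)
        seen = set()
        for i, j, k in guest.angles:
            key = min((guest.atoms[i].ff_type, guest.atoms[j].ff_type, guest.atoms[k].ff_type),
                      (guest.atoms[k].ff_type, guest.atoms[j].ff_type, guest.atoms[i].ff_type))
            if key not in seen:
                table.angles[key] = AngleParam(ktheta=float(rng.uniform(20, 80)),
                                               thetaeq=float(rng.uniform(1.5, 2.8)))
                seen.add(key)
        if guest.torsions:
            for i, j, k, l in guest.torsions:
                key = min(("*", guest.atoms[j].ff_type, guest.atoms[k].ff_type, "*"),
                          ("*", guest.atoms[k].ff_type, guest.atoms[j].ff_type, "*"))
                table.torsions.setdefault(key, [
                    TorsionTerm(vn=float(rng.uniform(0.5, 3.0)), n=int(rng.integers(1, 4)),
                                gamma=float(rng.uniform(0, 2 * math.pi)))])
    return host, guest, table


def random_pose(rng, max_offset=4.0):
    from inclusim.structures import Pose
    q = rng.normal(size=4)
    q /= np.linalg.norm(q)
    return Pose(com=rng.uniform(-max_offset, max_offset, 3), quaternion=q)
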