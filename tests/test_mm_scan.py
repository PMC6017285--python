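"""Grid scan, penetration potential, Boltzmann PES, inclusion classification."""

import math

import numpy as np
import pytest

from inclusim import fixtures, mm_scan
from inclusim.constants import KB
from inclusim.forcefield import LJParam, ParameterTable, SolventModel
from inclusim.mm_scan import (ScanGrid, boltzmann_average, boltzmann_pes,
                              classify_inclusion, generate_orientations,
                              global_minimum, penetration_potential, scan)
from inclusim.structures import Atom, ParameterizedMolecule, Pose, place_guest

WATER = SolventModel(80.0)


def single_site_guest(eps=0.1, rmin=3.4, charge=0.0):
    spec = fixtures.ToyGuestSpec(n_sites=1, epsilon_site=eps, rmin_site=rmin,
                                 polar_charge=charge, torsion=None)
    return fixtures.make_toy_guest(spec), spec


def symmetric_system():
    """Z-symmetric host (equal rims, no acceptors/charges) + symmetric guest."""
    host_spec = fixtures.ToyHostSpec(narrow_radius=3.4, wide_radius=3.4,
                                     rim_charge=0.0, n_rim_acceptors=0)
    host = fixtures.make_toy_host(host_spec)
    guest, guest_spec = single_site_guest()
    table = fixtures.toy_parameter_table(host_spec, guest_spec)
    return host, guest, table


class TestOrientations:
    def test_default_target_gives_23328(self):
        ors = generate_orientations("euler-lattice", 23000)
        assert len(ors) == 36 * 18 * 36 == 23328
        assert ors.descriptor["counts"] == [36, 18, 36]

    def test_count_one_is_identity(self):
        ors = generate_orientations("euler-lattice", 1)
        np.testing.assert_allclose(ors.quaternions, [[1, 0, 0, 0]])

    def test_random_scheme_deterministic_per_seed(self):
        a = generate_orientations("random", 50, seed=9)
        b = generate_orientations("random", 50, seed=9)
        np.testing.assert_array_equal(a.quaternions, b.quaternions)
        c = generate_orientations("random", 50, seed=10)
        assert not np.array_equal(a.quaternions, c.quaternions)

    def test_all_unit_norm(self):
        ors = generate_orientations("euler-lattice", 500)
        np.testing.assert_allclose(np.linalg.norm(ors.quaternions, axis=1), 1.0,
                                   atol=1e-12)


class TestScan:
    def test_single_site_guest_matches_pairwise_oracle(self):
        host, guest, table = symmetric_system()
        grid = ScanGrid(bounds=((-1, 1), (-1, 1), (-1, 1)), spacing=1.0)
        ors = generate_orientations("euler-lattice", 8)
        res = scan(host, guest, grid, ors, table, WATER)
        # orientation-invariant guest: direct per-point pair sum
        for idx, point in enumerate(grid.points()):
            br = fixtures.brute_force_energy(host, guest, Pose(com=point), table, WATER)
            assert res.min_einter.ravel()[idx] == pytest.approx(br.einter, rel=1e-10)

    def test_zero_parameter_guest_gives_zero_everywhere(self):
        host, _, table = symmetric_system()
        guest = ParameterizedMolecule(
            atoms=[Atom(element="X", name="g", position=[0, 0, 0], ff_type="NUL")],
            role="guest")
        table.lj["NUL"] = LJParam(A=0.0, B=0.0)
        grid = ScanGrid(bounds=((-1, 1), (-1, 1), (-1, 1)), spacing=1.0)
        res = scan(host, guest, grid, generate_orientations("euler-lattice", 4), table, WATER)
        np.testing.assert_allclose(res.min_e, 0.0, atol=1e-15)

    def test_refining_orientations_never_raises_minima(self, toy_system):
        host, guest, table = toy_system
        grid = ScanGrid(bounds=((0, 0), (0, 0), (-4, 4)), spacing=1.0)
        coarse = generate_orientations("euler-lattice", 32)
        fine_q = np.vstack([coarse.quaternions,
                            generate_orientations("random", 64, seed=3).quaternions])
        fine = mm_scan.OrientationSet(fine_q, {"scheme": "superset"})
        r1 = scan(host, guest, grid, coarse, table, WATER)
        r2 = scan(host, guest, grid, fine, table, WATER)
        assert np.all(r2.min_einter <= r1.min_einter + 1e-12)


class TestPenetrationPotential:
    def test_symmetric_host_symmetric_w(self):
        host, guest, table = symmetric_system()
        grid = ScanGrid(bounds=((-1, 1), (-1, 1), (-5, 5)), spacing=0.5)
        res = scan(host, guest, grid, generate_orientations("euler-lattice", 4),
                   table, WATER)
        pen = penetration_potential(res)
        np.testing.assert_allclose(pen.w, pen.w[::-1], atol=1e-9)

    def test_well_shape_for_attractive_host(self, toy_system):
        host, guest, table = toy_system
        grid = ScanGrid(bounds=((-1.5, 1.5), (-1.5, 1.5), (-5, 5)), spacing=0.5)
        res = scan(host, guest, grid, generate_orientations("euler-lattice", 108),
                   table, WATER)
        pen = penetration_potential(res)
        inside = pen.w[np.abs(pen.z) < 2.0]
        assert inside.min() < pen.w[0] and inside.min() < pen.w[-1]

    def test_repulsive_guest_nonnegative_w(self):
        host, _, table = symmetric_system()
        guest = ParameterizedMolecule(
            atoms=[Atom(element="X", name="g", position=[0, 0, 0], ff_type="REP")],
            role="guest")
        table.lj["REP"] = LJParam(A=5e4, B=0.0)
        grid = ScanGrid(bounds=((0, 0), (0, 0), (-5, 5)), spacing=1.0)
        res = scan(host, guest, grid, generate_orientations("euler-lattice", 4),
                   table, WATER)
        pen = penetration_potential(res)
        assert np.all(pen.w >= 0.0)

    def test_w_components_sum_to_w(self, toy_system):
        host, guest, table = toy_system
        grid = ScanGrid(bounds=((0, 0), (0, 0), (-4, 4)), spacing=2.0)
        res = scan(host, guest, grid, generate_orientations("euler-lattice", 32),
                   table, WATER)
        pen = penetration_potential(res)
        np.testing.assert_allclose(pen.lj + pen.ele + pen.hbond, pen.w, atol=1e-9)


class TestBoltzmannPES:
    def test_equal_energies_average_to_same(self):
        assert boltzmann_average([2.5, 2.5, 2.5], 293.0) == pytest.approx(2.5)

    def test_two_level_closed_form(self):
        kt = KB * 293.0
        w = math.exp(-1.0 / kt)
        expected = (0.0 + 1.0 * w) / (1.0 + w)
        assert boltzmann_average([0.0, 1.0], 293.0) == pytest.approx(expected, rel=1e-12)

    def test_low_temperature_limit_is_minimum(self, rng):
        e = rng.uniform(-5, 5, 50)
        assert boltzmann_average(e, 1e-6) == pytest.approx(e.min(), abs=1e-6)

    def test_bounds_min_le_avg_le_mean(self, rng):
        for _ in range(20):
            e = rng.uniform(-10, 10, 30)
            avg = boltzmann_average(e, 293.0)
            assert e.min() - 1e-12 <= avg <= e.mean() + 1e-12

    def test_pes_map_bounds_and_domains(self, toy_system):
        host, guest, table = toy_system
        grid = ScanGrid(bounds=((-1, 1), (-1, 1), (-4, 4)), spacing=1.0)
        ors = generate_orientations("euler-lattice", 32)
        pes = boltzmann_pes(host, guest, grid, ors, table, WATER, temperature=293.0)
        assert np.all(pes.min_e <= pes.avg_e + 1e-9)
        assert len(pes.domain_surfaces) == 4
        widths = [hi - lo for lo, hi in pes.domain_bounds]
        assert all(w == pytest.approx(widths[0]) for w in widths)
        # domains tile the host Z extent (8 Å → 2 Å slabs for the toy host)
        assert pes.domain_bounds[0][0] == pytest.approx(host.coords[:, 2].min())
        assert pes.domain_bounds[-1][1] == pytest.approx(host.coords[:, 2].max())


class TestGlobalMinimum:
    def test_analytic_minimum_of_lj_pair_found_within_spacing(self):
        host_spec = fixtures.ToyHostSpec(narrow_radius=3.4, wide_radius=3.4,
                                         rim_charge=0.0, n_rim_acceptors=0)
        host = fixtures.make_toy_host(host_spec)
        guest, guest_spec = single_site_guest()
        table = fixtures.toy_parameter_table(host_spec, guest_spec)
        grid = ScanGrid(bounds=((-1, 1), (-1, 1), (-3, 3)), spacing=0.25)
        res = scan(host, guest, grid, generate_orientations("euler-lattice", 1),
                   table, WATER)
        emin, pose, _ = global_minimum(res)
        # independent dense-z brute force on the axis region
        best = (np.inf, None)
        for z in np.arange(-3, 3.001, 0.01):
            for x in np.arange(-1, 1.001, 0.05):
                br = fixtures.brute_force_energy(host, guest, Pose(com=[x, 0, z]),
                                                 table, WATER)
                if br.total < best[0]:
                    best = (br.total, (x, 0.0, z))
        assert emin == pytest.approx(best[0], abs=0.2)
        assert np.linalg.norm(pose.com - np.array(best[1])) <= 0.3  # within grid spacing

    def test_monotone_field_minimizer_on_boundary(self):
        # purely attractive (B-only) interaction decays with distance → the
        # minimizer sits on the grid boundary nearest the host
        host = ParameterizedMolecule(
            atoms=[Atom(element="X", name="h", position=[0, 0, 10.0], ff_type="ATT")],
            role="host")
        guest = ParameterizedMolecule(
            atoms=[Atom(element="X", name="g", position=[0, 0, 0], ff_type="ATT")],
            role="guest")
        table = ParameterTable()
        table.lj["ATT"] = LJParam(A=0.0, B=100.0)
        grid = ScanGrid(bounds=((-1, 1), (-1, 1), (-2, 2)), spacing=1.0)
        res = scan(host, guest, grid, generate_orientations("euler-lattice", 1),
                   table, WATER)
        _, pose, _ = global_minimum(res)
        assert pose.com[2] == pytest.approx(2.0)

    def test_breakdown_closure_at_minimum(self, toy_system):
        host, guest, table = toy_system
        grid = ScanGrid(bounds=((0, 0), (0, 0), (-3, 3)), spacing=1.0)
        res = scan(host, guest, grid, generate_orientations("euler-lattice", 16),
                   table, WATER)
        emin, _, br = global_minimum(res)
        assert br.total == pytest.approx(br.einter + br.eintra, abs=1e-10)
        assert emin == pytest.approx(br.total, abs=1e-8)


class TestInclusion:
    def test_short_guest_at_cavity_centre_fully_inside(self, toy_system):
        host, _, _ = toy_system
        guest = fixtures.make_toy_guest(fixtures.ToyGuestSpec(
            n_sites=4, spacing=1.0, polar_charge=0.0, torsion=None))
        coords = place_guest(guest, Pose(com=[0, 0, 0]))
        incl, frac = classify_inclusion(coords, host)
        assert incl and frac == 1.0

    def test_default_guest_protrudes_at_centre(self, toy_system):
        # the 9.9 Å rod in the 8 Å host: 8 of 10 sites inside at the centre
        host, guest, _ = toy_system
        _, frac = classify_inclusion(place_guest(guest, Pose(com=[0, 0, 0])), host)
        assert frac == pytest.approx(0.8)

    def test_guest_far_away(self, toy_system):
        host, guest, _ = toy_system
        coords = place_guest(guest, Pose(com=[100.0, 0, 0]))
        incl, frac = classify_inclusion(coords, host)
        assert not incl and frac == 0.0

    def test_rod_straddling_rim_counts_inside_atoms(self):
        host, _, table = symmetric_system()
        spec = fixtures.ToyGuestSpec(n_sites=5, spacing=2.0, polar_charge=0.0,
                                     torsion=None)
        guest = fixtures.make_toy_guest(spec)
        # COM at the wide rim plane (z=4): atoms at z = 0,2,4,6,8 → inside
        # requires z in [-4,4] and r=0 < cavity radius: atoms at 0,2,4 → 3/5
        coords = place_guest(guest, Pose(com=[0, 0, 4.0]))
        _, frac = classify_inclusion(coords, host)
        assert frac == pytest.approx(3 / 5)
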