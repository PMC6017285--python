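"""Rigid-body integrator: conservation, isokinetic constraint, protocol."""

import math

import numpy as np
import pytest

import inclusim.md_engine as me
from inclusim import fixtures
from inclusim.constants import KB, KCAL_PER_MOL_TO_AMU_A2_FS2
from inclusim.forcefield import SolventModel
from inclusim.md_engine import (InitialDisposition, RigidBodyState,
                                ThermostatSpec, Trajectory, initial_velocities,
                                residence_time, run_trajectory, step)
from inclusim.structures import Pose

WATER = SolventModel(80.0)


def free_state(guest, com=(0.0, 0.0, 0.0), v=(1e-3, 0, 0), L=(0, 0, 0)):
    return RigidBodyState.from_molecule(guest, Pose(com=np.array(com, dtype=float)),
                                        velocity=np.array(v, dtype=float),
                                        ang_mom=np.array(L, dtype=float))


class TestInitialVelocities:
    def test_exact_equipartition_magnitudes(self, toy_system):
        _, guest, _ = toy_system
        rng = np.random.default_rng(11)
        v, L = initial_velocities(293.0, guest.total_mass, guest.inertia_tensor(), rng)
        ke_t = 0.5 * guest.total_mass * float(v @ v) / KCAL_PER_MOL_TO_AMU_A2_FS2
        assert ke_t == pytest.approx(1.5 * KB * 293.0, abs=1e-10)
        assert ke_t == pytest.approx(0.87337, abs=5e-5)  # 1.5 · 1.9872041e-3 · 293
        omega = np.linalg.solve(guest.inertia_tensor(), L)
        ke_r = 0.5 * float(L @ omega) / KCAL_PER_MOL_TO_AMU_A2_FS2
        assert ke_r == pytest.approx(1.5 * KB * 293.0, abs=1e-10)

    def test_same_seed_reproducible(self, toy_system):
        _, guest, _ = toy_system
        a = initial_velocities(293.0, guest.total_mass, guest.inertia_tensor(),
                               np.random.default_rng(5))
        b = initial_velocities(293.0, guest.total_mass, guest.inertia_tensor(),
                               np.random.default_rng(5))
        np.testing.assert_array_equal(a[0], b[0])
        np.testing.assert_array_equal(a[1], b[1])

    def test_speed_scales_with_sqrt_temperature(self, toy_system):
        _, guest, _ = toy_system
        v1, _ = initial_velocities(293.0, guest.total_mass, guest.inertia_tensor(),
                                   np.random.default_rng(5))
        v2, _ = initial_velocities(586.0, guest.total_mass, guest.inertia_tensor(),
                                   np.random.default_rng(5))
        assert np.linalg.norm(v2) == pytest.approx(math.sqrt(2) * np.linalg.norm(v1),
                                                   rel=1e-12)


class TestStep:
    def test_free_motion_is_uniform(self, toy_system):
        _, guest, _ = toy_system
        st = free_state(guest, v=(2e-3, -1e-3, 5e-4), L=(10.0, -4.0, 2.0))
        l_lab0 = st.rotation @ st.ang_mom
        for _ in range(200):
            st = step(st, np.zeros(3), np.zeros(3), dt=1.0)
        np.testing.assert_allclose(st.com, np.array([2e-3, -1e-3, 5e-4]) * 200,
                                   atol=1e-12)
        # lab-frame angular momentum conserved under zero torque
        np.testing.assert_allclose(st.rotation @ st.ang_mom, l_lab0, atol=1e-9)

    def test_harmonic_period_matches_closed_form(self):
        probe = fixtures.make_harmonic_probe(k=1.0, m=12.0)
        st = RigidBodyState(com=np.array([1.0, 0, 0]), velocity=np.zeros(3),
                            quaternion=np.array([1.0, 0, 0, 0]),
                            ang_mom=np.zeros(3), mass=probe.m, inertia=np.zeros((3, 3)))
        n_steps = int(100 * probe.period)
        xs = np.empty(n_steps + 1)
        xs[0] = st.com[0]
        for i in range(n_steps):
            st = step(st, probe.force(st.com), np.zeros(3), dt=1.0)
            xs[i + 1] = st.com[0]
        # period from interpolated downward zero crossings, first vs last
        down = np.where((xs[:-1] > 0) & (xs[1:] <= 0))[0]
        t_first = down[0] + xs[down[0]] / (xs[down[0]] - xs[down[0] + 1])
        t_last = down[-1] + xs[down[-1]] / (xs[down[-1]] - xs[down[-1] + 1])
        period = (t_last - t_first) / (len(down) - 1)
        assert abs(period - probe.period) / probe.period < 1e-3

    def test_thermostat_pins_both_reservoirs(self, toy_system):
        host, guest, table = toy_system
        from inclusim.forcefield import force_and_torque
        thermo = ThermostatSpec(293.0)
        rng = np.random.default_rng(3)
        v0, l0 = initial_velocities(293.0, guest.total_mass, guest.inertia_tensor(), rng)
        st = RigidBodyState.from_molecule(guest, Pose(com=[0, 0, 5.5]),
                                          velocity=v0, ang_mom=l0)
        for _ in range(300):
            f, tq = force_and_torque(host, guest, st.pose, table, WATER)
            st = step(st, f, tq, dt=1.0, thermostat=thermo)
            assert st.kinetic_translational == pytest.approx(thermo.ke_target, abs=1e-9)
            assert st.kinetic_rotational == pytest.approx(thermo.ke_target, abs=1e-9)

    def test_nve_energy_drift_small(self):
        probe = fixtures.make_harmonic_probe(k=1.0, m=12.0)
        st = RigidBodyState(com=np.array([1.0, 0, 0]), velocity=np.zeros(3),
                            quaternion=np.array([1.0, 0, 0, 0]),
                            ang_mom=np.zeros(3), mass=probe.m, inertia=np.zeros((3, 3)))
        e0 = probe.energy(st.com) + st.kinetic_translational
        for _ in range(20_000):
            st = step(st, probe.force(st.com), np.zeros(3), dt=1.0)
        e1 = probe.energy(st.com) + st.kinetic_translational
        assert abs(e1 - e0) < 1e-3

    def test_time_reversal_retraces_path(self):
        probe = fixtures.make_harmonic_probe(k=1.0, m=12.0)
        st = RigidBodyState(com=np.array([0.7, -0.3, 0.4]),
                            velocity=np.array([5e-4, 1e-3, -2e-4]),
                            quaternion=np.array([1.0, 0, 0, 0]),
                            ang_mom=np.zeros(3), mass=probe.m, inertia=np.zeros((3, 3)))
        path = [st.com.copy()]
        for _ in range(1000):
            st = step(st, probe.force(st.com), np.zeros(3), dt=1.0)
            path.append(st.com.copy())
        # negate the half-step velocity advanced through the final position
        v_next = st.velocity + 1.0 * probe.force(st.com) * KCAL_PER_MOL_TO_AMU_A2_FS2 / probe.m
        st = RigidBodyState(com=st.com, velocity=-v_next, quaternion=st.quaternion,
                            ang_mom=st.ang_mom, mass=st.mass, inertia=st.inertia)
        back = [st.com.copy()]
        for _ in range(1000):
            st = step(st, probe.force(st.com), np.zeros(3), dt=1.0)
            back.append(st.com.copy())
        fwd = np.array(path)[::-1]
        assert np.abs(np.array(back) - fwd).max() < 1e-6

    def test_nonfinite_force_raises(self, toy_system):
        _, guest, _ = toy_system
        st = free_state(guest)
        with pytest.raises(FloatingPointError):
            step(st, np.array([np.nan, 0, 0]), np.zeros(3))


class TestQuaternionHygiene:
    def test_norm_preserved_over_many_free_rotation_steps(self, toy_system):
        _, guest, _ = toy_system
        st = free_state(guest, L=(30.0, -12.0, 7.0))
        worst = 0.0
        for _ in range(50_000):
            st = step(st, np.zeros(3), np.zeros(3), dt=1.0)
            worst = max(worst, abs(float(np.linalg.norm(st.quaternion)) - 1.0))
        assert worst < 1e-12


class TestTrajectoryProtocol:
    def test_repulsive_host_immediate_departure(self):
        host_spec = fixtures.ToyHostSpec(rim_charge=0.0, n_rim_acceptors=0)
        host = fixtures.make_toy_host(host_spec)
        guest_spec = fixtures.ToyGuestSpec(n_sites=2, polar_charge=0.0, torsion=None)
        guest = fixtures.make_toy_guest(guest_spec)
        table = fixtures.toy_parameter_table(host_spec, guest_spec)
        from inclusim.forcefield import LJParam
        table.lj["TG"] = LJParam(A=5e4, B=0.0)   # purely repulsive guest
        table.lj["HD"] = LJParam(A=5e4, B=0.0)
        traj = run_trajectory(host, guest, table, WATER,
                              InitialDisposition(region="narrow-rim", seed=1),
                              max_steps=100_000, exit_patience=5)
        assert traj.terminated and traj.reason == "departed"
        assert residence_time(traj)[0] == 0.0

    def test_deep_well_flagged_non_terminated(self, toy_system):
        host, guest, table = toy_system
        traj = run_trajectory(host, guest, table, WATER,
                              InitialDisposition(seed=2), max_steps=2000)
        assert not traj.terminated and traj.reason == "max_steps"

    def test_same_seed_identical_trajectories(self, toy_system):
        host, guest, table = toy_system
        a = run_trajectory(host, guest, table, WATER, InitialDisposition(seed=7),
                           max_steps=5000)
        b = run_trajectory(host, guest, table, WATER, InitialDisposition(seed=7),
                           max_steps=5000)
        np.testing.assert_array_equal(a.coms, b.coms)
        np.testing.assert_array_equal(a.quaternions, b.quaternions)

    def test_times_increase_in_sampling_increments(self, toy_system):
        host, guest, table = toy_system
        traj = run_trajectory(host, guest, table, WATER, InitialDisposition(seed=1),
                              max_steps=3000)
        np.testing.assert_allclose(np.diff(traj.times), 0.1, atol=1e-12)

    def test_frame_energies_reproducible_from_states(self, toy_system):
        from inclusim.forcefield import total_energy
        host, guest, table = toy_system
        traj = run_trajectory(host, guest, table, WATER, InitialDisposition(seed=4),
                              max_steps=2000)
        for i in range(0, len(traj.times), 7):
            pose = Pose(com=traj.coms[i], quaternion=traj.quaternions[i])
            br = total_energy(host, guest, pose, table, WATER)
            assert br.total == pytest.approx(traj.energies[i].total, abs=1e-8)

    def test_kernel_and_python_paths_agree_closely(self, toy_system, monkeypatch):
        host, guest, table = toy_system
        a = run_trajectory(host, guest, table, WATER, InitialDisposition(seed=9),
                           max_steps=500)
        monkeypatch.setattr(me, "_HAVE_NUMBA", False)
        b = run_trajectory(host, guest, table, WATER, InitialDisposition(seed=9),
                           max_steps=500)
        np.testing.assert_allclose(a.coms, b.coms, atol=1e-8)


class TestResidenceTime:
    def _synthetic(self, einter):
        from inclusim.forcefield import EnergyBreakdown
        n = len(einter)
        return Trajectory(times=0.1 * np.arange(n), coms=np.zeros((n, 3)),
                          quaternions=np.tile([1.0, 0, 0, 0], (n, 1)),
                          energies=[EnergyBreakdown(lj=e) for e in einter],
                          disposition=InitialDisposition(), temperature=293.0,
                          dt=1.0, sample_every=100, terminated=True, reason="departed")

    def test_no_bound_frames_zero(self):
        traj = self._synthetic(np.ones(100))
        assert residence_time(traj)[0] == 0.0

    def test_counting_qualifying_frames(self):
        e = np.full(1500, 1.0)
        e[100:1100] = -5.0  # exactly 1000 bound frames at 0.1 ps sampling
        traj = self._synthetic(e)
        t, segments = residence_time(traj)
        assert t == pytest.approx(100.0)
        assert len(segments) == 1

    def test_monotone_in_threshold(self, rng):
        e = rng.uniform(-3, 1, 400)
        traj = self._synthetic(e)
        times = [residence_time(traj, threshold=th)[0]
                 for th in (-2.0, -1.0, -0.5, 0.0)]
        assert all(a <= b for a, b in zip(times, times[1:]))
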