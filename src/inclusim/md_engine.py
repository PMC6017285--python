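"""Constant-temperature rigid-body dynamics of the guest in the host field.

The guest moves as a rigid body: its centre of mass obeys the net
intermolecular force, its orientation — parameterized by a unit
quaternion to avoid the Euler-angle singularity — obeys the net torque
about the COM.  The host is fixed.  Integration is a leap-frog with
1 fs steps; constant temperature is maintained by an isokinetic
constraint that rescales the translational and rotational velocities
*separately* to their equipartition targets (3/2 kBT each) after every
velocity update, a Brown-Clarke-style constrained leap-frog.  With the
thermostat off the scheme reduces to plain (energy-conserving)
leap-frog.

A trajectory records configuration and energies every 100 steps and
terminates once the guest has left the host envelope and its
interaction is no longer attractive enough (Einter above −kBT) for a
sustained stretch — the guest has diffused away for good.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field, replace

import numpy as np

from .constants import DEFAULT_TEMPERATURE, KB, KCAL_PER_MOL_TO_AMU_A2_FS2
from .forcefield import (EnergyBreakdown, InteractionModel, ParameterTable,
                         SolventModel, intramolecular_energy)
from .structures import ParameterizedMolecule, Pose, quaternion_to_matrix

__all__ = [
    "ThermostatSpec",
    "RigidBodyState",
    "InitialDisposition",
    "Trajectory",
    "initial_velocities",
    "step",
    "run_trajectory",
    "residence_time",
    "DISPOSITION_CLASSES",
]

_CONV = KCAL_PER_MOL_TO_AMU_A2_FS2          # kcal/mol → amu Å²/fs²
_INERTIA_EPS = 1e-10

#: the four canonical starting classes: (region, heading)
DISPOSITION_CLASSES = [
    ("narrow-rim", "radical-first"),
    ("wide-rim", "radical-first"),
    ("narrow-rim", "phenyl-first"),
    ("wide-rim", "phenyl-first"),
]


@dataclass(frozen=True)
class ThermostatSpec:
    """Separate isokinetic constraints on translational and rotational KE."""

    temperature: float = DEFAULT_TEMPERATURE

    def __post_init__(self):
        if self.temperature <= 0:
            raise ValueError("temperature must be positive")

    @property
    def ke_target(self) -> float:
        """Per-reservoir target (3/2) kBT in kcal/mol."""
        return 1.5 * KB * self.temperature


def _quat_to_mat(q: np.ndarray) -> np.ndarray:
    """Rotation matrix of a unit quaternion (w, x, y, z); hot-path helper."""
    w, x, y, z = q
    xx, yy, zz = x * x, y * y, z * z
    wx, wy, wz = w * x, w * y, w * z
    xy, xz, yz = x * y, x * z, y * z
    return np.array([
        [1 - 2 * (yy + zz), 2 * (xy - wz), 2 * (xz + wy)],
        [2 * (xy + wz), 1 - 2 * (xx + zz), 2 * (yz - wx)],
        [2 * (xz - wy), 2 * (yz + wx), 1 - 2 * (xx + yy)],
    ])


def _quat_multiply(q1: np.ndarray, q2: np.ndarray) -> np.ndarray:
    w1, x1, y1, z1 = q1
    w2, x2, y2, z2 = q2
    return np.array([
        w1 * w2 - x1 * x2 - y1 * y2 - z1 * z2,
        w1 * x2 + x1 * w2 + y1 * z2 - z1 * y2,
        w1 * y2 - x1 * z2 + y1 * w2 + z1 * x2,
        w1 * z2 + x1 * y2 - y1 * x2 + z1 * w2,
    ])


def _rotation_quat(axis_angle: np.ndarray) -> np.ndarray:
    """Unit quaternion for a rotation vector (axis × angle, rad)."""
    angle = float(np.linalg.norm(axis_angle))
    if angle < 1e-300:
        return np.array([1.0, 0, 0, 0])
    axis = axis_angle / angle
    half = 0.5 * angle
    return np.concatenate([[math.cos(half)], math.sin(half) * axis])


@dataclass
class RigidBodyState:
    """Rigid-body phase-space point in the leap-frog staggering.

    ``com``/``quaternion`` live at full steps, ``velocity`` (Å/fs) and the
    body-frame angular momentum ``ang_mom`` (amu·Å²/fs) at half steps.
    The body frame is the guest's stored reference conformation about its
    COM; ``inertia`` is the (constant) body-frame inertia tensor.
    """

    com: np.ndarray
    velocity: np.ndarray
    quaternion: np.ndarray
    ang_mom: np.ndarray
    mass: float
    inertia: np.ndarray
    inertia_inv: np.ndarray | None = None  # cached; None for singular inertia

    def __post_init__(self):
        self.com = np.asarray(self.com, dtype=float)
        self.velocity = np.asarray(self.velocity, dtype=float)
        self.quaternion = np.asarray(self.quaternion, dtype=float)
        self.ang_mom = np.asarray(self.ang_mom, dtype=float)
        if self.inertia_inv is None:  # first construction, not a step replace
            self.inertia = np.asarray(self.inertia, dtype=float)
            if float(abs(np.linalg.det(self.inertia))) > _INERTIA_EPS:
                self.inertia_inv = np.linalg.inv(self.inertia)
        if self.mass <= 0:
            raise ValueError("mass must be positive")

    @classmethod
    def from_molecule(cls, guest: ParameterizedMolecule, pose: Pose,
                      velocity: np.ndarray | None = None,
                      ang_mom: np.ndarray | None = None) -> "RigidBodyState":
        inertia = guest.inertia_tensor()
        return cls(com=pose.com.copy(), velocity=np.zeros(3) if velocity is None else velocity,
                   quaternion=pose.quaternion.copy(),
                   ang_mom=np.zeros(3) if ang_mom is None else ang_mom,
                   mass=guest.total_mass, inertia=inertia)

    @property
    def has_rotation(self) -> bool:
        """False for point particles / linear bodies with singular inertia."""
        return self.inertia_inv is not None

    @property
    def rotation(self) -> np.ndarray:
        return _quat_to_mat(self.quaternion)

    @property
    def omega_body(self) -> np.ndarray:
        """Body-frame angular velocity (rad/fs)."""
        if self.inertia_inv is None:
            return np.zeros(3)
        return self.inertia_inv @ self.ang_mom

    @property
    def kinetic_translational(self) -> float:
        """Translational kinetic energy, kcal/mol."""
        return 0.5 * self.mass * float(self.velocity @ self.velocity) / _CONV

    @property
    def kinetic_rotational(self) -> float:
        """Rotational kinetic energy, kcal/mol."""
        return 0.5 * float(self.ang_mom @ self.omega_body) / _CONV

    @property
    def pose(self) -> Pose:
        return Pose(com=self.com.copy(), quaternion=self.quaternion.copy())


def initial_velocities(temperature: float, mass: float, inertia: np.ndarray,
                       rng: np.random.Generator) -> tuple[np.ndarray, np.ndarray]:
    """Draw random directions; magnitudes fix each KE at exactly (3/2) kBT.

    Returns (COM velocity Å/fs, body-frame angular momentum amu·Å²/fs).
    A singular inertia tensor yields zero angular momentum.
    """
    if temperature <= 0:
        raise ValueError("temperature must be positive")
    target = 1.5 * KB * temperature * _CONV  # amu Å²/fs²

    def unit(v: np.ndarray) -> np.ndarray:
        return v / np.linalg.norm(v)

    u = unit(rng.normal(size=3))
    v = math.sqrt(2.0 * target / mass) * u

    inertia = np.asarray(inertia, dtype=float)
    if float(np.linalg.det(inertia)) <= _INERTIA_EPS:
        return v, np.zeros(3)
    w = unit(rng.normal(size=3))
    quad = float(w @ np.linalg.solve(inertia, w))
    lam = math.sqrt(2.0 * target / quad)
    return v, lam * w


def step(state: RigidBodyState, force: np.ndarray, torque: np.ndarray,
         dt: float = 1.0, thermostat: ThermostatSpec | None = None) -> RigidBodyState:
    """One leap-frog step.

    ``force`` in kcal/mol/Å and ``torque`` in kcal/mol, both lab-frame,
    evaluated at the current configuration.  With a thermostat, the
    half-step velocities are rescaled so translational and rotational
    kinetic energies sit exactly at (3/2) kBT each.
    """
    if dt <= 0:
        raise ValueError("dt must be positive")
    force = np.asarray(force, dtype=float)
    torque = np.asarray(torque, dtype=float)
    if not (np.all(np.isfinite(force)) and np.all(np.isfinite(torque))):
        raise FloatingPointError(
            f"non-finite force/torque at com={state.com}, q={state.quaternion}")

    v = state.velocity + dt * force * (_CONV / state.mass)
    if thermostat is not None:
        ke = 0.5 * state.mass * float(v @ v) / _CONV
        if ke > 0:
            v = v * math.sqrt(thermostat.ke_target / ke)
    com = state.com + dt * v

    q = state.quaternion
    ang_mom = state.ang_mom
    if state.inertia_inv is not None:
        rot = _quat_to_mat(q)
        # lab-frame angular momentum update: dL/dt = torque
        l_space = rot @ ang_mom + dt * _CONV * torque
        l_body = rot.T @ l_space
        if thermostat is not None:
            ke = 0.5 * float(l_body @ (state.inertia_inv @ l_body)) / _CONV
            if ke > 0:
                scale = math.sqrt(thermostat.ke_target / ke)
                l_body = l_body * scale
                l_space = l_space * scale
        omega = state.inertia_inv @ l_body  # body frame, rad/fs
        q = _quat_multiply(q, _rotation_quat(dt * omega))
        q = q / math.sqrt(float(q @ q))
        # re-express the (lab-conserved) angular momentum in the new body frame
        ang_mom = _quat_to_mat(q).T @ l_space
        if thermostat is not None:
            # the body frame rotated under q: project back onto the exact
            # isokinetic shell in the frame the state is stored in
            ke = 0.5 * float(ang_mom @ (state.inertia_inv @ ang_mom)) / _CONV
            if ke > 0:
                ang_mom = ang_mom * math.sqrt(thermostat.ke_target / ke)
    return replace(state, com=com, velocity=v, quaternion=q, ang_mom=ang_mom)


# ---------------------------------------------------------------------------
# Compiled integration kernel
#
# The inner loop (pair forces + leap-frog update) is also provided as a
# numba-jitted kernel that advances a whole sampling interval at once; it
# mirrors :func:`step` exactly and is used by :func:`run_trajectory` when
# numba is importable.  The pure-numpy path remains the reference.

try:
    from numba import njit as _njit
    _HAVE_NUMBA = True
except ImportError:  # pragma: no cover - numba is an optional accelerator
    _HAVE_NUMBA = False

    def _njit(*args, **kwargs):
        def deco(fn):
            return fn
        return deco if not args else args[0]


@_njit(cache=False)
def _integrate_block(n_steps, host, A, B, C, D, qq, epsilon, rel_ref,
                     mass, inertia_inv, rotatable, com, v, q, l_body,
                     dt, conv, isokinetic, ke_target):  # pragma: no cover - exercised via run_trajectory
    nh = host.shape[0]
    ng = rel_ref.shape[0]
    coords = np.empty((ng, 3))
    f = np.empty((ng, 3))
    rot = np.empty((3, 3))
    for _ in range(n_steps):
        # rotation matrix of q (w, x, y, z)
        w, x, y, z = q[0], q[1], q[2], q[3]
        rot[0, 0] = 1 - 2 * (y * y + z * z)
        rot[0, 1] = 2 * (x * y - w * z)
        rot[0, 2] = 2 * (x * z + w * y)
        rot[1, 0] = 2 * (x * y + w * z)
        rot[1, 1] = 1 - 2 * (x * x + z * z)
        rot[1, 2] = 2 * (y * z - w * x)
        rot[2, 0] = 2 * (x * z - w * y)
        rot[2, 1] = 2 * (y * z + w * x)
        rot[2, 2] = 1 - 2 * (x * x + y * y)
        for j in range(ng):
            for a in range(3):
                coords[j, a] = (rot[a, 0] * rel_ref[j, 0] + rot[a, 1] * rel_ref[j, 1]
                                + rot[a, 2] * rel_ref[j, 2] + com[a])
        # pair forces on guest atoms
        for j in range(ng):
            f[j, 0] = f[j, 1] = f[j, 2] = 0.0
        for i in range(nh):
            for j in range(ng):
                dx = coords[j, 0] - host[i, 0]
                dy = coords[j, 1] - host[i, 1]
                dz = coords[j, 2] - host[i, 2]
                r2 = dx * dx + dy * dy + dz * dz
                r = math.sqrt(r2)
                inv2 = 1.0 / r2
                inv6 = inv2 * inv2 * inv2
                inv8 = inv6 * inv2
                inv12 = inv6 * inv6
                inv14 = inv12 * inv2
                coeff = (12.0 * A[i, j] * inv14 - 6.0 * B[i, j] * inv8
                         + 12.0 * C[i, j] * inv14 - 10.0 * D[i, j] * inv12
                         + qq[i, j] / epsilon * inv2 / r)
                f[j, 0] += coeff * dx
                f[j, 1] += coeff * dy
                f[j, 2] += coeff * dz
        fx = fy = fz = 0.0
        tx = ty = tz = 0.0
        for j in range(ng):
            fx += f[j, 0]
            fy += f[j, 1]
            fz += f[j, 2]
            rx = coords[j, 0] - com[0]
            ry = coords[j, 1] - com[1]
            rz = coords[j, 2] - com[2]
            tx += ry * f[j, 2] - rz * f[j, 1]
            ty += rz * f[j, 0] - rx * f[j, 2]
            tz += rx * f[j, 1] - ry * f[j, 0]
        # translational half-step + isokinetic rescale
        v[0] += dt * fx * conv / mass
        v[1] += dt * fy * conv / mass
        v[2] += dt * fz * conv / mass
        if isokinetic:
            ke = 0.5 * mass * (v[0] * v[0] + v[1] * v[1] + v[2] * v[2]) / conv
            if ke > 0.0:
                s = math.sqrt(ke_target / ke)
                v[0] *= s
                v[1] *= s
                v[2] *= s
        com[0] += dt * v[0]
        com[1] += dt * v[1]
        com[2] += dt * v[2]
        if rotatable:
            # lab-frame L update, re-expressed in the body frame
            lsx = (rot[0, 0] * l_body[0] + rot[0, 1] * l_body[1]
                   + rot[0, 2] * l_body[2] + dt * conv * tx)
            lsy = (rot[1, 0] * l_body[0] + rot[1, 1] * l_body[1]
                   + rot[1, 2] * l_body[2] + dt * conv * ty)
            lsz = (rot[2, 0] * l_body[0] + rot[2, 1] * l_body[1]
                   + rot[2, 2] * l_body[2] + dt * conv * tz)
            lbx = rot[0, 0] * lsx + rot[1, 0] * lsy + rot[2, 0] * lsz
            lby = rot[0, 1] * lsx + rot[1, 1] * lsy + rot[2, 1] * lsz
            lbz = rot[0, 2] * lsx + rot[1, 2] * lsy + rot[2, 2] * lsz
            if isokinetic:
                ox = inertia_inv[0, 0] * lbx + inertia_inv[0, 1] * lby + inertia_inv[0, 2] * lbz
                oy = inertia_inv[1, 0] * lbx + inertia_inv[1, 1] * lby + inertia_inv[1, 2] * lbz
                oz = inertia_inv[2, 0] * lbx + inertia_inv[2, 1] * lby + inertia_inv[2, 2] * lbz
                ke = 0.5 * (lbx * ox + lby * oy + lbz * oz) / conv
                if ke > 0.0:
                    s = math.sqrt(ke_target / ke)
                    lbx *= s
                    lby *= s
                    lbz *= s
                    lsx *= s
                    lsy *= s
                    lsz *= s
            ox = inertia_inv[0, 0] * lbx + inertia_inv[0, 1] * lby + inertia_inv[0, 2] * lbz
            oy = inertia_inv[1, 0] * lbx + inertia_inv[1, 1] * lby + inertia_inv[1, 2] * lbz
            oz = inertia_inv[2, 0] * lbx + inertia_inv[2, 1] * lby + inertia_inv[2, 2] * lbz
            ang = math.sqrt(ox * ox + oy * oy + oz * oz) * dt
            if ang > 1e-300:
                half = 0.5 * ang
                sw = math.cos(half)
                omega_norm = ang / dt
                dqx = math.sin(half) * ox / omega_norm
                dqy = math.sin(half) * oy / omega_norm
                dqz = math.sin(half) * oz / omega_norm
                nw = w * sw - x * dqx - y * dqy - z * dqz
                nx = w * dqx + x * sw + y * dqz - z * dqy
                ny = w * dqy - x * dqz + y * sw + z * dqx
                nz = w * dqz + x * dqy - y * dqx + z * sw
                norm = math.sqrt(nw * nw + nx * nx + ny * ny + nz * nz)
                q[0], q[1], q[2], q[3] = nw / norm, nx / norm, ny / norm, nz / norm
            # re-express the (lab-conserved) L in the new body frame
            w, x, y, z = q[0], q[1], q[2], q[3]
            rot[0, 0] = 1 - 2 * (y * y + z * z)
            rot[0, 1] = 2 * (x * y - w * z)
            rot[0, 2] = 2 * (x * z + w * y)
            rot[1, 0] = 2 * (x * y + w * z)
            rot[1, 1] = 1 - 2 * (x * x + z * z)
            rot[1, 2] = 2 * (y * z - w * x)
            rot[2, 0] = 2 * (x * z - w * y)
            rot[2, 1] = 2 * (y * z + w * x)
            rot[2, 2] = 1 - 2 * (x * x + y * y)
            l_body[0] = rot[0, 0] * lsx + rot[1, 0] * lsy + rot[2, 0] * lsz
            l_body[1] = rot[0, 1] * lsx + rot[1, 1] * lsy + rot[2, 1] * lsz
            l_body[2] = rot[0, 2] * lsx + rot[1, 2] * lsy + rot[2, 2] * lsz
            if isokinetic:
                ox = (inertia_inv[0, 0] * l_body[0] + inertia_inv[0, 1] * l_body[1]
                      + inertia_inv[0, 2] * l_body[2])
                oy = (inertia_inv[1, 0] * l_body[0] + inertia_inv[1, 1] * l_body[1]
                      + inertia_inv[1, 2] * l_body[2])
                oz = (inertia_inv[2, 0] * l_body[0] + inertia_inv[2, 1] * l_body[1]
                      + inertia_inv[2, 2] * l_body[2])
                ke = 0.5 * (l_body[0] * ox + l_body[1] * oy + l_body[2] * oz) / conv
                if ke > 0.0:
                    s = math.sqrt(ke_target / ke)
                    l_body[0] *= s
                    l_body[1] *= s
                    l_body[2] *= s


# ---------------------------------------------------------------------------
# Trajectory protocol

@dataclass(frozen=True)
class InitialDisposition:
    """One of the four canonical approach geometries.

    ``region`` picks the rim the guest starts from (narrow = −Z, wide =
    +Z); ``heading`` picks which end points toward the cavity: the
    "radical" (polar tail, last site / substituent end) or the "phenyl"
    end (first site).  The azimuthal orientation and velocity directions
    are drawn from ``seed``.
    """

    region: str = "narrow-rim"
    heading: str = "radical-first"
    com_offset: float = 1.0
    seed: int = 0

    def __post_init__(self):
        if self.region not in ("narrow-rim", "wide-rim"):
            raise ValueError(f"bad region {self.region!r}")
        if self.heading not in ("radical-first", "phenyl-first"):
            raise ValueError(f"bad heading {self.heading!r}")


@dataclass
class Trajectory:
    """Sampled rigid-body trajectory with per-frame energy decomposition."""

    times: np.ndarray                      # ps
    coms: np.ndarray                       # (n, 3) Å
    quaternions: np.ndarray                # (n, 4)
    energies: list[EnergyBreakdown]
    disposition: InitialDisposition
    temperature: float
    dt: float                              # fs
    sample_every: int
    terminated: bool
    reason: str

    @property
    def einter(self) -> np.ndarray:
        return np.array([e.einter for e in self.energies])

    @property
    def etotal(self) -> np.ndarray:
        return np.array([e.total for e in self.energies])

    def to_frame(self):
        import pandas as pd
        rows = {"time_ps": self.times,
                "x": self.coms[:, 0], "y": self.coms[:, 1], "z": self.coms[:, 2],
                "qw": self.quaternions[:, 0], "qx": self.quaternions[:, 1],
                "qy": self.quaternions[:, 2], "qz": self.quaternions[:, 3]}
        for key in ("E", "Einter", "Eintra", "lj", "ele", "hbond"):
            rows[key] = np.array([e.as_dict()[key] for e in self.energies])
        return pd.DataFrame(rows)

    def save(self, path_prefix: str) -> None:
        """Write the state/energy table (CSV) and metadata (JSON)."""
        self.to_frame().to_csv(str(path_prefix) + ".csv", index=False)
        meta = {"disposition": {"region": self.disposition.region,
                                "heading": self.disposition.heading,
                                "com_offset": self.disposition.com_offset,
                                "seed": self.disposition.seed},
                "temperature": self.temperature, "dt_fs": self.dt,
                "sample_every": self.sample_every,
                "terminated": self.terminated, "reason": self.reason,
                "n_frames": int(len(self.times))}
        with open(str(path_prefix) + ".json", "w") as fh:
            json.dump(meta, fh, indent=1)


def _initial_pose(host: ParameterizedMolecule, guest: ParameterizedMolecule,
                  disp: InitialDisposition, rng: np.random.Generator) -> Pose:
    """COM on the cavity axis just beyond the chosen rim, long axis along
    ±Z per the heading, random azimuth about the axis."""
    from scipy.spatial.transform import Rotation

    host_z = host.coords[:, 2]
    if disp.region == "narrow-rim":
        z0 = float(host_z.min()) - disp.com_offset
        toward_cavity = +1.0
    else:
        z0 = float(host_z.max()) + disp.com_offset
        toward_cavity = -1.0
    # body +Z runs from the phenyl-like head (site 0) to the radical tail
    sign = toward_cavity if disp.heading == "radical-first" else -toward_cavity
    tilt = Rotation.identity() if sign > 0 else Rotation.from_euler("Y", math.pi)
    azimuth = Rotation.from_euler("Z", rng.uniform(0, 2 * math.pi))
    x, y, z, w = (azimuth * tilt).as_quat()
    return Pose(com=np.array([0.0, 0.0, z0]), quaternion=np.array([w, x, y, z]))


def _host_envelope(host: ParameterizedMolecule, margin: float = 2.0) -> tuple[float, float, float]:
    """(max radius, z_lo, z_hi) of the termination envelope."""
    coords = host.coords
    r = float(np.linalg.norm(coords[:, :2], axis=1).max()) + margin
    return r, float(coords[:, 2].min()) - margin, float(coords[:, 2].max()) + margin


def run_trajectory(host: ParameterizedMolecule, guest: ParameterizedMolecule,
                   params: ParameterTable, solvent: SolventModel,
                   disposition: InitialDisposition,
                   thermostat: ThermostatSpec | None = None,
                   dt: float = 1.0, sample_every: int = 100,
                   max_steps: int = 1_000_000,
                   exit_patience: int = 50) -> Trajectory:
    """Integrate one approach trajectory until the guest departs.

    Termination: the guest COM is outside the host envelope (cylinder of
    max host radius + 2 Å over the host Z extent + 2 Å) *and* Einter is
    above −kBT, for ``exit_patience`` consecutive sampled frames.  If
    ``max_steps`` is reached first the trajectory is flagged
    non-terminated.
    """
    thermostat = thermostat or ThermostatSpec()
    rng = np.random.default_rng(disposition.seed)
    pose = _initial_pose(host, guest, disposition, rng)
    v0, l0 = initial_velocities(thermostat.temperature, guest.total_mass,
                                guest.inertia_tensor(), rng)
    state = RigidBodyState.from_molecule(guest, pose, velocity=v0, ang_mom=l0)

    model = InteractionModel(host, guest, params, solvent)
    rel_ref = guest.coords - guest.reference_com
    if guest.bonds or guest.angles or guest.torsions:
        eb, ea, et = intramolecular_energy(guest, guest.coords, params)
    else:
        eb = ea = et = 0.0

    kt = KB * thermostat.temperature
    r_env, z_lo, z_hi = _host_envelope(host)

    times, coms, quats, energies = [], [], [], []
    departed_streak = 0
    terminated, reason = False, "max_steps"

    def sample(istep: int, coords: np.ndarray) -> bool:
        nonlocal departed_streak, terminated, reason
        lj, ele, hb = model.energy_components(coords)
        br = EnergyBreakdown(lj=float(lj), ele=float(ele), hbond=float(hb),
                             bond=eb, angle=ea, torsion=et)
        times.append(istep * dt / 1000.0)
        coms.append(state.com.copy())
        quats.append(state.quaternion.copy())
        energies.append(br)
        com = state.com
        outside = (com[2] < z_lo or com[2] > z_hi
                   or math.hypot(com[0], com[1]) > r_env)
        if outside and br.einter > -kt:
            departed_streak += 1
        else:
            departed_streak = 0
        if departed_streak >= exit_patience:
            terminated, reason = True, "departed"
            return True
        return False

    istep = 0
    coords = rel_ref @ state.rotation.T + state.com
    sample(0, coords)
    use_kernel = _HAVE_NUMBA
    inertia_inv = state.inertia_inv if state.inertia_inv is not None else np.eye(3)
    while istep < max_steps and not terminated:
        n_block = min(sample_every, max_steps - istep)
        if use_kernel:
            com = state.com.copy()
            v = state.velocity.copy()
            q = state.quaternion.copy()
            l_body = state.ang_mom.copy()
            _integrate_block(n_block, model.host_coords, model.A, model.B,
                             model.C, model.D, model.qq, solvent.epsilon,
                             rel_ref, state.mass, inertia_inv,
                             state.has_rotation, com, v, q, l_body,
                             dt, _CONV, thermostat is not None,
                             thermostat.ke_target if thermostat else 0.0)
            if not (np.all(np.isfinite(com)) and np.all(np.isfinite(q))):
                raise FloatingPointError(f"integration diverged near t={istep * dt / 1000.0} ps")
            state = replace(state, com=com, velocity=v, quaternion=q, ang_mom=l_body)
        else:
            for _ in range(n_block):
                f_atoms = model.guest_forces(coords)
                force = f_atoms.sum(axis=0)
                rel = coords - state.com
                torque = np.array([
                    (rel[:, 1] * f_atoms[:, 2] - rel[:, 2] * f_atoms[:, 1]).sum(),
                    (rel[:, 2] * f_atoms[:, 0] - rel[:, 0] * f_atoms[:, 2]).sum(),
                    (rel[:, 0] * f_atoms[:, 1] - rel[:, 1] * f_atoms[:, 0]).sum(),
                ])
                state = step(state, force, torque, dt=dt, thermostat=thermostat)
                coords = rel_ref @ state.rotation.T + state.com
        istep += n_block
        coords = rel_ref @ state.rotation.T + state.com
        if sample(istep, coords):
            break

    return Trajectory(times=np.array(times), coms=np.array(coms),
                      quaternions=np.array(quats), energies=energies,
                      disposition=disposition, temperature=thermostat.temperature,
                      dt=dt, sample_every=sample_every,
                      terminated=terminated, reason=reason)


def residence_time(traj: Trajectory, threshold: float | None = None
                   ) -> tuple[float, list[tuple[float, float]]]:
    """Total sampled time (ps) with Einter below the threshold.

    The default threshold is −kBT at the trajectory temperature: the
    interaction is "attractive enough" when it beats thermal energy.
    Also returns the contiguous bound segments as (t_start, t_end) pairs.
    """
    if threshold is None:
        threshold = -KB * traj.temperature
    bound = traj.einter < threshold
    dt_frame = traj.dt * traj.sample_every / 1000.0  # ps
    segments = []
    start = None
    for i, b in enumerate(bound):
        if b and start is None:
            start = traj.times[i]
        elif not b and start is not None:
            segments.append((float(start), float(traj.times[i])))
            start = None
    if start is not None:
        segments.append((float(start), float(traj.times[-1]) + dt_frame))
    return float(bound.sum() * dt_frame), segments
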