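"""Brownian dynamics propagation in (quaternion, z) coordinates.

The state is a unit quaternion Q (scalar-first) for the orientation of the
molecule-fixed frame plus the dimensionless internal coordinates z.  A step
of the Euler scheme forms the increment

    [dQ; dz] = -dt W(Q) D [0_3; z] + sqrt(2 dt) W(Q) D^{1/2} n

with standard-Gaussian noise n, W block-diagonal with the quaternion
kinematics matrix b(Q) on the rotational rows and the identity on the
internal rows, and D^{1/2} the (cached) Cholesky factor of D.  The new
internal coordinates are z + dz — the discretized Ornstein-Uhlenbeck update
whose stationary density is the standard Gaussian — and the new quaternion is
dQ + lambda Q with the Lagrange multiplier lambda solving

    lambda^2 + 2 lambda (Q . dQ) + |dQ|^2 = 1

(root closest to +1), which renormalizes the quaternion exactly at every
step.  The Runge-Kutta variant takes a virtual Euler step with the *same*
noise vector, then averages drift and noise-projection matrices between the
start and virtual points; it is stable up to dt = 1/(2 omega_max) versus
1/(10 omega_max) for Euler.

Randomness comes from numpy's PCG64 generator with explicit seeding;
trajectory i of an ensemble uses seed = master_seed + i.  Identical seed and
schedule give bit-identical trajectories.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np

from .errors import StepSizeError
from .model import Schedule, SFBModel

__all__ = [
    "BDConfig",
    "BDTrajectory",
    "b_matrix",
    "w_matrix",
    "lagrange_renormalize",
    "euler_step",
    "rk_step",
    "run_trajectory",
    "run_ensemble",
]

_Z_ABORT = 10.0  # |z_i| beyond 10 standard deviations: step-size diagnosis
_NOISE_BLOCK = 8192  # Gaussian variates are drawn in blocks of this many steps


@dataclass
class BDConfig:
    schedule: Schedule
    seed: int = 123456789


@dataclass
class BDTrajectory:
    """Dump-resolution BD trajectory."""

    times: np.ndarray  # (n_dumps,)
    quaternions: np.ndarray  # (n_dumps, 4), scalar-first
    z: np.ndarray  # (n_dumps, Ns)
    seed: int
    schedule: Schedule

    @property
    def n_dumps(self) -> int:
        return self.times.size


def b_matrix(Q: np.ndarray) -> np.ndarray:
    """Quaternion kinematics matrix b(Q) (4x3): dQ = b(Q) omega dt for
    body-frame angular velocity omega."""
    q0, q1, q2, q3 = Q
    return 0.5 * np.array(
        [
            [-q1, -q2, -q3],
            [q0, -q3, q2],
            [q3, q0, -q1],
            [-q2, q1, q0],
        ]
    )


def w_matrix(Q: np.ndarray, n_internal: int) -> np.ndarray:
    """(4+Ns) x (3+Ns) projection: b(Q) on rotational rows, identity on
    internal rows."""
    W = np.zeros((4 + n_internal, 3 + n_internal))
    W[:4, :3] = b_matrix(Q)
    if n_internal:
        W[4:, 3:] = np.eye(n_internal)
    return W


def lagrange_renormalize(Q_prev: np.ndarray, Q_tilde: np.ndarray):
    """Solve the renormalization multiplier and return (lambda, Q_new).

    lambda^2 + 2 lambda (Q_prev . Q_tilde) + |Q_tilde|^2 = 1; the root
    closest to +1 is taken for continuity, and |Q_tilde + lambda Q_prev| = 1
    exactly.
    """
    s = float(Q_prev @ Q_tilde)
    disc = s * s - float(Q_tilde @ Q_tilde) + 1.0
    if disc < 0.0:
        raise StepSizeError(
            "quaternion renormalization has no real solution: "
            "the integration step is too large, reduce dt"
        )
    lam = -s + math.sqrt(disc)
    return lam, Q_tilde + lam * Q_prev


def _increment(Q, z, D, L, noise, dt):
    """Shared Euler-type increment: (dQ (4,), dz (Ns,))."""
    v = np.concatenate([np.zeros(3), z])
    vec = -dt * (D @ v) + math.sqrt(2.0 * dt) * (L @ noise)
    return b_matrix(Q) @ vec[:3], vec[3:]


def euler_step(Q, z, model: SFBModel, dt, noise):
    """One Euler step; returns (Q_new, z_new)."""
    dQ, dz = _increment(Q, z, model.D, model.cholesky, noise, dt)
    _, Q_new = lagrange_renormalize(Q, dQ)
    return Q_new, z + dz


def rk_step(Q, z, model: SFBModel, dt, noise):
    """One Runge-Kutta step (virtual Euler point, same noise; averaged drift
    and noise projection); returns (Q_new, z_new)."""
    D, L = model.D, model.cholesky
    Q_e, z_e = euler_step(Q, z, model, dt, noise)  # renormalized virtual point
    v0 = np.concatenate([np.zeros(3), z])
    v1 = np.concatenate([np.zeros(3), z_e])
    drift = -0.5 * dt * (D @ (v0 + v1))
    noise_vec = 0.5 * math.sqrt(2.0 * dt) * (L @ noise)
    b0 = b_matrix(Q)
    b1 = b_matrix(Q_e)
    dQ = b0 @ drift[:3] + (b0 + b1) @ noise_vec[:3]
    # internal rows of W are the identity at both points: their average is 1
    dz = drift[3:] + 2.0 * noise_vec[3:]
    _, Q_new = lagrange_renormalize(Q, dQ)
    return Q_new, z + dz


def _initial_state(model: SFBModel, rng: np.random.Generator):
    """Equilibrium initial condition: z ~ N(0, I), orientation uniform on
    SO(3) (quaternion = normalized 4D Gaussian)."""
    Q = rng.standard_normal(4)
    Q /= np.linalg.norm(Q)
    z = rng.standard_normal(model.n_internal)
    return Q, z


def _b_apply(q0, q1, q2, q3, w1, w2, w3):
    """b(Q) @ w as scalar arithmetic (hot path)."""
    return (
        0.5 * (-q1 * w1 - q2 * w2 - q3 * w3),
        0.5 * (q0 * w1 - q3 * w2 + q2 * w3),
        0.5 * (q3 * w1 + q0 * w2 - q1 * w3),
        0.5 * (-q2 * w1 + q1 * w2 + q0 * w3),
    )


def run_trajectory(model: SFBModel, config: BDConfig) -> BDTrajectory:
    """Propagate one seeded trajectory and return it at dump resolution.

    The inner loop inlines the Euler/Runge-Kutta updates of
    :func:`euler_step`/:func:`rk_step` (same arithmetic, exercised against
    them in the tests) to keep the per-step cost low.
    """
    sched = config.schedule
    ns = model.n_internal
    dim = 3 + ns
    rng = np.random.default_rng(config.seed)
    Q, z = _initial_state(model, rng)
    rk = sched.scheme == "runge_kutta"
    dt = sched.dt
    sq = math.sqrt(2.0 * dt)
    D, L = model.D, model.cholesky
    Dz = np.ascontiguousarray(D[:, 3:])  # drift only acts on the z part

    n_dumps = sched.n_steps // sched.dump_stride + 1
    times = np.empty(n_dumps)
    quats = np.empty((n_dumps, 4))
    zs = np.empty((n_dumps, ns))
    times[0], quats[0], zs[0] = 0.0, Q, z
    idump = 1

    q0, q1, q2, q3 = (float(v) for v in Q)
    noise_buf = np.empty((0, dim))
    buf_pos = 0
    for istep in range(1, sched.n_steps + 1):
        if buf_pos >= noise_buf.shape[0]:
            noise_buf = rng.standard_normal(
                (min(_NOISE_BLOCK, sched.n_steps - istep + 1), dim)
            )
            buf_pos = 0
        Ln = L @ noise_buf[buf_pos]
        buf_pos += 1
        if ns:
            euler_vec = sq * Ln - dt * (Dz @ z)
        else:
            euler_vec = sq * Ln
        e1, e2, e3, e4 = _b_apply(
            q0, q1, q2, q3, euler_vec[0], euler_vec[1], euler_vec[2]
        )
        s = q0 * e1 + q1 * e2 + q2 * e3 + q3 * e4
        disc = s * s - (e1 * e1 + e2 * e2 + e3 * e3 + e4 * e4) + 1.0
        if disc < 0.0:
            raise StepSizeError("quaternion renormalization failed: reduce dt")
        lam = -s + math.sqrt(disc)
        p0, p1, p2, p3 = e1 + lam * q0, e2 + lam * q1, e3 + lam * q2, e4 + lam * q3

        if not rk:
            q0, q1, q2, q3 = p0, p1, p2, p3
            if ns:
                z = z + euler_vec[3:]
        else:
            z_e = z + euler_vec[3:] if ns else z
            if ns:
                drift = (-0.5 * dt) * (Dz @ (z + z_e))
                nv = (0.5 * sq) * Ln
                w1, w2, w3 = drift[0] + nv[0], drift[1] + nv[1], drift[2] + nv[2]
                a1, a2, a3, a4 = _b_apply(q0, q1, q2, q3, w1, w2, w3)
                c1, c2, c3, c4 = _b_apply(p0, p1, p2, p3, nv[0], nv[1], nv[2])
                d1, d2, d3, d4 = a1 + c1, a2 + c2, a3 + c3, a4 + c4
                z = z + drift[3:] + 2.0 * nv[3:]
            else:
                nv1, nv2, nv3 = 0.5 * sq * Ln[0], 0.5 * sq * Ln[1], 0.5 * sq * Ln[2]
                a1, a2, a3, a4 = _b_apply(q0, q1, q2, q3, nv1, nv2, nv3)
                c1, c2, c3, c4 = _b_apply(p0, p1, p2, p3, nv1, nv2, nv3)
                d1, d2, d3, d4 = a1 + c1, a2 + c2, a3 + c3, a4 + c4
            s = q0 * d1 + q1 * d2 + q2 * d3 + q3 * d4
            disc = s * s - (d1 * d1 + d2 * d2 + d3 * d3 + d4 * d4) + 1.0
            if disc < 0.0:
                raise StepSizeError("quaternion renormalization failed: reduce dt")
            lam = -s + math.sqrt(disc)
            q0, q1, q2, q3 = (
                d1 + lam * q0,
                d2 + lam * q1,
                d3 + lam * q2,
                d4 + lam * q3,
            )

        if ns and np.max(np.abs(z)) > _Z_ABORT:
            raise StepSizeError(
                f"|z| exceeded {_Z_ABORT} standard deviations at step {istep}: "
                "the trajectory is unstable, reduce dt"
            )
        if istep % sched.dump_stride == 0:
            times[idump] = istep * dt
            quats[idump, 0] = q0
            quats[idump, 1] = q1
            quats[idump, 2] = q2
            quats[idump, 3] = q3
            zs[idump] = z
            idump += 1
    return BDTrajectory(
        times=times[:idump],
        quaternions=quats[:idump],
        z=zs[:idump],
        seed=config.seed,
        schedule=sched,
    )


def run_ensemble(model: SFBModel, config: BDConfig) -> list[BDTrajectory]:
    """Independent trajectories with seeds master_seed + 0, 1, 2, ..."""
    return [
        run_trajectory(
            model, BDConfig(schedule=config.schedule, seed=config.seed + i)
        )
        for i in range(config.schedule.n_trajectories)
    ]
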