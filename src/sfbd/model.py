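"""Assembly of the semiflexible-body (SFB) diffusion tensor.

The SFB model describes a molecule as a freely tumbling rigid frame
hydrodynamically coupled to Ns = 3N-6 harmonic internal coordinates.  In the
shifted coordinates z = (kBT)^{-1/2} T' K^{1/2} (q - q0) each internal mode is
dimensionless with a standard-Gaussian equilibrium density, and the full
(3+Ns) diffusion tensor D — rotational block diagonal in its own frame,
internal block diagonal, full coupling block — carries every time scale of
the dynamics as an eigenvalue.

The thermal scaling K^{1/2}/sqrt(kBT) is applied symmetrically to the
internal rows and columns only; the rotational block is left unscaled.  This
is the dimensionally consistent reading of the assembly (rotation already
has units of 1/s) and reproduces the analytic 4x4 sandbox tensor exactly:
internal entry 10k, coupling c sqrt(k), rotation unscaled.

A one-internal-coordinate sandbox system with isotropic unit rotational
diffusion, internal hydrodynamic coefficient 10 and coupling c on the ZZ
rotational entry is provided with closed-form eigenvalues; it exercises the
whole pipeline without any molecular input.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field

import numpy as np

from .errors import ModelError
from .hydrodynamics import GeneralizedDiffusionTensor
from .internal_coords import CurvatureMatrix, InternalCoordinates, ZMatrixDefinition

__all__ = [
    "SFBModel",
    "ModeSpectrum",
    "Schedule",
    "SandboxParams",
    "assemble_diffusion",
    "mode_spectrum",
    "coupling_index",
    "make_schedule",
    "sandbox_model",
    "sandbox_eigenvalues",
]


def _fix_eigvec_signs(V: np.ndarray) -> np.ndarray:
    """Sign convention: largest-magnitude component of each column positive."""
    V = V.copy()
    for j in range(V.shape[1]):
        i = int(np.argmax(np.abs(V[:, j])))
        if V[i, j] < 0:
            V[:, j] = -V[:, j]
    return V


@dataclass
class SFBModel:
    """Assembled SFB diffusion model in (rotation, z) coordinates.

    D : (3+Ns, 3+Ns) diffusion tensor, 1/s (dimensionless for the sandbox).
    E : 3x3 rotation diagonalizing the rotational block of D_hydro.
    T : Ns x Ns orthogonal matrix (columns = eigenvectors) diagonalizing the
        thermally scaled internal block.
    K_sqrt : symmetric square root of the curvature matrix.
    q0 : reference internal coordinates (minimum-energy geometry).
    kBT : thermal energy, J (1 for the dimensionless sandbox).
    """

    D: np.ndarray
    E: np.ndarray
    T: np.ndarray
    K_sqrt: np.ndarray
    q0: np.ndarray | None = None
    kBT: float = 1.0
    zdef: ZMatrixDefinition | None = None
    D_hydro: GeneralizedDiffusionTensor | None = None
    _chol: np.ndarray | None = field(default=None, repr=False)

    @property
    def n_internal(self) -> int:
        return self.D.shape[0] - 3

    @property
    def cholesky(self) -> np.ndarray:
        """Lower-triangular factor L with D = L L^T (cached; D is
        configuration independent so it is computed once)."""
        if self._chol is None:
            self._chol = np.linalg.cholesky(self.D)
        return self._chol

    # -- z <-> q ------------------------------------------------------------
    def to_z(self, q: InternalCoordinates | np.ndarray) -> np.ndarray:
        """Shifted coordinates z = (kBT)^{-1/2} T^T K^{1/2} (q - q0)."""
        qv = q.values if isinstance(q, InternalCoordinates) else np.asarray(q, float)
        if self.q0 is None:
            raise ModelError("model has no reference coordinates q0")
        return (self.T.T @ (self.K_sqrt @ (qv - self.q0))) / math.sqrt(self.kBT)

    def from_z(self, z: np.ndarray) -> np.ndarray:
        """Inverse of :meth:`to_z` (exact)."""
        if self.q0 is None:
            raise ModelError("model has no reference coordinates q0")
        rhs = self.T @ (np.asarray(z, float) * math.sqrt(self.kBT))
        return self.q0 + np.linalg.solve(self.K_sqrt, rhs)

    def spectrum(self) -> "ModeSpectrum":
        return mode_spectrum(self)

    def coupling_index(self) -> np.ndarray:
        return coupling_index(self)


@dataclass
class ModeSpectrum:
    """Eigenvalues of D: the frequencies of the motions, ascending (1/s)."""

    omegas: np.ndarray
    eigenvectors: np.ndarray

    @property
    def omega_min(self) -> float:
        return float(self.omegas[0])

    @property
    def omega_max(self) -> float:
        return float(self.omegas[-1])

    @property
    def tau_rank2(self) -> float:
        """Slowest rank-2 orientational correlation time, 1/(6 omega_min)."""
        return 1.0 / (6.0 * self.omega_min)

    @property
    def tau_bare(self) -> float:
        """Bare slowest time 1/omega_min."""
        return 1.0 / self.omega_min

    @property
    def t_fast(self) -> float:
        return 1.0 / self.omega_max


@dataclass
class Schedule:
    """BD integration schedule.

    dt in seconds (model time units); ``n_steps`` per trajectory;
    configurations dumped every ``dump_stride`` steps.
    """

    dt: float
    n_steps: int
    dump_stride: int
    n_trajectories: int = 20
    scheme: str = "runge_kutta"

    @property
    def n_dumps(self) -> int:
        return self.n_steps // self.dump_stride + 1

    @property
    def traj_time(self) -> float:
        return self.dt * self.n_steps

    @property
    def dump_resolution(self) -> float:
        return self.dt * self.dump_stride


@dataclass
class SandboxParams:
    """Parameters of the analytic one-coordinate sandbox system.

    c : dimensionless hydrodynamic coupling of the internal coordinate to the
        ZZ rotational rate, in [0, 1] in the intended regime.
    k : dimensionless harmonic force constant (kBT units), > 0.
    The rotational coefficients are fixed at 1 and the internal hydrodynamic
    coefficient at 10; all frequencies are in units of the isotropic
    rotational rate.
    """

    c: float = 0.0
    k: float = 1.0

    def __post_init__(self):
        if self.k <= 0:
            raise ValueError("k must be > 0")


# ---------------------------------------------------------------------------
# assembly
# ---------------------------------------------------------------------------

def assemble_diffusion(
    D_hydro: GeneralizedDiffusionTensor,
    K: CurvatureMatrix | np.ndarray,
    kBT: float,
    q0: InternalCoordinates | np.ndarray | None = None,
    zdef: ZMatrixDefinition | None = None,
) -> SFBModel:
    """Assemble the SFB diffusion tensor in shifted coordinates.

    D = blockdiag(E, T)^T S D_hydro S blockdiag(E, T) with
    S = blockdiag(I3, K^{1/2}/sqrt(kBT)); E diagonalizes the rotational
    block, T the scaled internal block.
    """
    Kmat = K if isinstance(K, CurvatureMatrix) else CurvatureMatrix(np.asarray(K, float))
    ns = Kmat.K.shape[0]
    if D_hydro.n_internal != ns:
        raise ModelError(
            f"curvature ({ns}) and diffusion ({D_hydro.n_internal}) sizes differ"
        )
    if np.linalg.eigvalsh(Kmat.K)[0] <= 0:
        raise ModelError("curvature matrix must be positive definite")
    K_sqrt = Kmat.sqrt()
    S_int = K_sqrt / math.sqrt(kBT)

    D_rr = D_hydro.D_RR
    D_rs = D_hydro.D_RS @ S_int
    D_ss = S_int @ D_hydro.D_SS @ S_int

    w_r, E = np.linalg.eigh(D_rr)
    E = _fix_eigvec_signs(E)
    if np.linalg.det(E) < 0:  # keep E a proper rotation
        E[:, 2] = -E[:, 2]
    w_s, T = np.linalg.eigh(D_ss) if ns else (np.zeros(0), np.zeros((0, 0)))
    T = _fix_eigvec_signs(T) if ns else T

    top = np.hstack([np.diag(w_r), E.T @ D_rs @ T]) if ns else np.diag(w_r)
    if ns:
        bot = np.hstack([(E.T @ D_rs @ T).T, np.diag(w_s)])
        D = np.vstack([top, bot])
    else:
        D = top
    D = 0.5 * (D + D.T)
    w = np.linalg.eigvalsh(D)
    if w[0] <= 0:
        raise ModelError(
            f"assembled diffusion tensor not positive definite (min eig {w[0]:.6g})"
        )
    q0v = None
    if q0 is not None:
        q0v = q0.values if isinstance(q0, InternalCoordinates) else np.asarray(q0, float)
    return SFBModel(
        D=D, E=E, T=T, K_sqrt=K_sqrt, q0=q0v, kBT=kBT, zdef=zdef, D_hydro=D_hydro
    )


def mode_spectrum(model: SFBModel) -> ModeSpectrum:
    w, V = np.linalg.eigh(model.D)
    order = np.argsort(w)
    w, V = w[order], _fix_eigvec_signs(V[:, order])
    if w[0] <= 0:
        raise ModelError("non-positive eigenvalue in diffusion tensor")
    return ModeSpectrum(omegas=w, eigenvectors=V)


def coupling_index(model: SFBModel) -> np.ndarray:
    """Coupling index CI_j of each internal mode z_j with rotation.

    T_ij = |D_{i,3+j}| / sqrt(D_ii D_{3+j,3+j}) is the dimensionless
    normalized rotational-internal coupling; CI_j sums T_ij over the three
    rotational rows and normalizes by the total coupling, so CI_j in [0, 1],
    CI_j = 0 iff column j of the coupling block vanishes, and a single
    coupled coordinate carries CI = 1.
    """
    ns = model.n_internal
    D = model.D
    Tmat = np.empty((3, ns))
    for i in range(3):
        for j in range(ns):
            Tmat[i, j] = abs(D[i, 3 + j]) / math.sqrt(D[i, i] * D[3 + j, 3 + j])
    total = Tmat.sum()
    if total == 0.0:
        return np.zeros(ns)
    return Tmat.sum(axis=0) / total


def make_schedule(
    spectrum: ModeSpectrum,
    scheme: str = "runge_kutta",
    dt: float | None = None,
    traj_time: float | None = None,
    length_factor: float = 1000.0,
    n_snapshots: int = 10_000,
    n_trajectories: int = 20,
) -> Schedule:
    """Automatic BD schedule from the mode spectrum.

    dt = 1/(2 omega_max) for the Runge-Kutta scheme and 1/(10 omega_max) for
    Euler; each of the (default 20) trajectories runs ``length_factor`` times
    the slowest rank-2 correlation time tau = 1/(6 omega_min), and the dump
    stride targets ``n_snapshots`` dumps per trajectory.  Every quantity can
    be overridden; an overridden dt above the stability bound only warns.
    """
    if scheme not in ("runge_kutta", "euler"):
        raise ValueError(f"unknown scheme {scheme!r}")
    bound = 1.0 / (2.0 * spectrum.omega_max) if scheme == "runge_kutta" else 1.0 / (
        10.0 * spectrum.omega_max
    )
    if dt is None:
        dt = bound
    elif dt > bound * (1 + 1e-12):
        warnings.warn(
            f"dt = {dt:.4g} exceeds the {scheme} stability bound {bound:.4g}",
            stacklevel=2,
        )
    if traj_time is None:
        traj_time = length_factor * spectrum.tau_rank2
    n_steps = max(1, int(math.ceil(traj_time / dt)))
    dump_stride = max(1, round(n_steps / n_snapshots))
    return Schedule(
        dt=dt,
        n_steps=n_steps,
        dump_stride=dump_stride,
        n_trajectories=n_trajectories,
        scheme=scheme,
    )


# ---------------------------------------------------------------------------
# sandbox system
# ---------------------------------------------------------------------------

def sandbox_model(params: SandboxParams) -> SFBModel:
    """4x4 sandbox diffusion tensor (dimensionless units).

    D = [[1,0,0,0], [0,1,0,0], [0,0,1,c sqrt(k)], [0,0,c sqrt(k),10 k]]
    """
    c, k = params.c, params.k
    sk = math.sqrt(k)
    D = np.array(
        [
            [1.0, 0.0, 0.0, 0.0],
            [0.0, 1.0, 0.0, 0.0],
            [0.0, 0.0, 1.0, c * sk],
            [0.0, 0.0, c * sk, 10.0 * k],
        ]
    )
    if np.linalg.eigvalsh(D)[0] <= 0:
        raise ModelError(f"sandbox tensor not positive definite for c={c}, k={k}")
    return SFBModel(
        D=D,
        E=np.eye(3),
        T=np.eye(1),
        K_sqrt=np.array([[sk]]),
        q0=np.zeros(1),
        kBT=1.0,
    )


def sandbox_eigenvalues(params: SandboxParams) -> np.ndarray:
    """Closed-form eigenvalues of the sandbox tensor, ascending.

    omega_1,4 = [(1 + 10k) -/+ sqrt((1 - 10k)^2 + 4 k c^2)]/2, omega_2 =
    omega_3 = 1.
    """
    c, k = params.c, params.k
    disc = math.sqrt((1.0 - 10.0 * k) ** 2 + 4.0 * k * c * c)
    w1 = ((1.0 + 10.0 * k) - disc) / 2.0
    w4 = ((1.0 + 10.0 * k) + disc) / 2.0
    return np.sort(np.array([w1, 1.0, 1.0, w4]))
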