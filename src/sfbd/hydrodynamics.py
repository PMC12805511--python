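"""Hydrodynamic bead-model diffusion tensors.

The molecule is represented as a set of beads (the atoms), all with the same
effective hydrodynamic radius, translating in a continuous medium.  Each bead
carries a Stokes-Einstein friction xi = C pi R eta (C = 6 stick, C = 4 slip)
and beads are coupled through the Rotne-Prager-Yamakawa mobility tensor.  A
geometric matrix converts bead velocities into generalized velocities of
centre-of-mass translation, global rotation and internal Z-matrix coordinate
rates; the generalized friction is Xi = A^T M^-1 A and the generalized
diffusion tensor D = kB T Xi^-1.  Translation is projected out by taking the
rotational + internal sub-block of kB T Xi^-1 (the Schur-complement
projection of the friction).

Units: user-facing radius in angstrom, viscosity in Pa s, temperature in K.
The returned blocks are D_RR in 1/s (rad^2/s), D_SS in (angstrom, rad)^2/s —
directly compatible with curvature matrices in J/(angstrom, rad)^2.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .constants import ANGSTROM, KB
from .errors import GeometryError, ModelError
from .internal_coords import ZMatrixDefinition, cartesian_to_zmatrix, coordinate_jacobian
from .structure import CartesianStructure

__all__ = [
    "HydroParams",
    "GeneralizedDiffusionTensor",
    "bead_friction",
    "rotne_prager_mobility",
    "generalized_geometry_matrix",
    "hydro_diffusion_tensor",
]


@dataclass
class HydroParams:
    """Hydrodynamic parameters.

    R_eff : effective bead radius, angstrom.
    C : boundary-condition coefficient (6 stick, 4 slip; any positive value
        is accepted — only the product C R eta enters).
    eta : solvent viscosity, Pa s.
    T : temperature, K.
    """

    R_eff: float = 2.0
    C: float = 6.0
    eta: float = 8.9e-4
    T: float = 298.15
    include_hi: bool = True  # Rotne-Prager cross coupling on/off

    def __post_init__(self):
        for name in ("R_eff", "C", "eta", "T"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be strictly positive")

    @property
    def kBT(self) -> float:
        return KB * self.T


@dataclass
class GeneralizedDiffusionTensor:
    """(3+Ns) generalized diffusion tensor with labelled blocks."""

    D: np.ndarray  # (3+Ns, 3+Ns)
    n_internal: int
    D_trans: np.ndarray | None = None  # reported 3x3 translational block, m^2/s

    @property
    def D_RR(self) -> np.ndarray:
        return self.D[:3, :3]

    @property
    def D_RS(self) -> np.ndarray:
        return self.D[:3, 3:]

    @property
    def D_SS(self) -> np.ndarray:
        return self.D[3:, 3:]


def bead_friction(params: HydroParams) -> float:
    """Stokes-Einstein translational friction per bead, kg/s."""
    return params.C * np.pi * (params.R_eff * ANGSTROM) * params.eta


def rotne_prager_mobility(coords: np.ndarray, params: HydroParams) -> np.ndarray:
    """Cartesian 3N x 3N mobility matrix (SI, s/kg) for equal-radius beads.

    Self blocks are 1/xi identity with xi = C pi R eta; cross blocks are the
    Rotne-Prager-Yamakawa tensor for stick spheres of radius R_eff, with the
    RPY overlapping-sphere branch for separations below 2 R_eff.  With
    ``include_hi=False`` the matrix is the free-draining diagonal.
    """
    X = np.asarray(coords, dtype=float) * ANGSTROM
    n = X.shape[0]
    xi = bead_friction(params)
    a = params.R_eff * ANGSTROM
    eta = params.eta
    M = np.zeros((3 * n, 3 * n))
    for i in range(n):
        M[3 * i : 3 * i + 3, 3 * i : 3 * i + 3] = np.eye(3) / xi
    if not params.include_hi:
        return M
    for i in range(n):
        for j in range(i + 1, n):
            rij = X[j] - X[i]
            r = np.linalg.norm(rij)
            if r < 1e-14:
                raise GeometryError(f"beads {i} and {j} coincide")
            rhat = rij / r
            P = np.outer(rhat, rhat)
            if r >= 2 * a:
                pre = 1.0 / (8 * np.pi * eta * r)
                blk = pre * (
                    (1 + 2 * a * a / (3 * r * r)) * np.eye(3)
                    + (1 - 2 * a * a / (r * r)) * P
                )
            else:
                pre = 1.0 / (6 * np.pi * eta * a)
                blk = pre * (
                    (1 - 9 * r / (32 * a)) * np.eye(3) + (3 * r / (32 * a)) * P
                )
            M[3 * i : 3 * i + 3, 3 * j : 3 * j + 3] = blk
            M[3 * j : 3 * j + 3, 3 * i : 3 * i + 3] = blk
    return M


def _skew(v: np.ndarray) -> np.ndarray:
    return np.array([[0, -v[2], v[1]], [v[2], 0, -v[0]], [-v[1], v[0], 0]])


def generalized_geometry_matrix(
    structure: CartesianStructure,
    zdef: ZMatrixDefinition | None,
    weights: np.ndarray | None = None,
    check_rank: bool = True,
) -> np.ndarray:
    """Geometry matrix A (3N x (3+3+Ns)) mapping (v_cm, omega, qdot) to bead
    velocities (SI).

    Columns: identity stack (translation, m/s), cross-product operators
    -[r_i - r_ref]x (rotation about the weighted centre, rad/s), and the
    internal-coordinate Jacobian expressed in the input structure's frame
    (internal rates in angstrom/s and rad/s).  ``zdef=None`` builds the rigid
    (Ns = 0) matrix.
    """
    X = structure.coords
    n = X.shape[0]
    w = np.full(n, 1.0 / n) if weights is None else np.asarray(weights, float) / np.sum(weights)
    r_ref = w @ X
    ns = 0 if zdef is None else zdef.n_coords
    A = np.zeros((3 * n, 6 + ns))
    if ns:
        q = cartesian_to_zmatrix(zdef, structure)
        B = coordinate_jacobian(zdef, q, frame=structure)
    for i in range(n):
        rows = slice(3 * i, 3 * i + 3)
        A[rows, :3] = np.eye(3)
        A[rows, 3:6] = -_skew((X[i] - r_ref) * ANGSTROM)
        if ns:
            A[rows, 6:] = B[rows, :] * ANGSTROM
    if check_rank:
        rank = np.linalg.matrix_rank(A, tol=1e-12 * max(1.0, np.abs(A).max()))
        if rank < 6 + ns:
            raise GeometryError(
                f"geometry matrix rank {rank} < {6 + ns}: degenerate configuration"
            )
    return A


def hydro_diffusion_tensor(
    structure: CartesianStructure,
    zdef: ZMatrixDefinition | None,
    params: HydroParams,
    weights: np.ndarray | None = None,
) -> GeneralizedDiffusionTensor:
    """Generalized (3+Ns) hydrodynamic diffusion tensor.

    Forms the generalized friction Xi = A^T M^-1 A over (translation,
    rotation, internal) and returns kB T times the rotational+internal block
    of Xi^-1, which is exactly the Schur-complement projection of
    translational motion; the translational 3x3 diffusion block is reported
    alongside.
    """
    A = generalized_geometry_matrix(structure, zdef, weights=weights)
    M = rotne_prager_mobility(structure.coords, params)
    Minv = np.linalg.inv(M)
    Xi = A.T @ Minv @ A
    Xi = 0.5 * (Xi + Xi.T)
    try:
        D_full = params.kBT * np.linalg.inv(Xi)
    except np.linalg.LinAlgError as exc:
        raise ModelError("generalized friction is singular") from exc
    D_full = 0.5 * (D_full + D_full.T)
    D = D_full[3:, 3:]
    w = np.linalg.eigvalsh(D)
    if w[0] <= 0:
        raise ModelError(f"diffusion tensor not positive definite (min eig {w[0]:.3g})")
    ns = 0 if zdef is None else zdef.n_coords
    return GeneralizedDiffusionTensor(D=D, n_internal=ns, D_trans=D_full[:3, :3])
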