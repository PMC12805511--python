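"""Synthetic molecules and Hessians with known ground truth.

Real applications obtain the minimum-energy geometry and the Cartesian
Hessian from an external force-field engine; these generators build both from
*chosen* internal force constants so that every downstream stage can be
verified against a known curvature matrix.  The Cartesian Hessian is
constructed as H = C^T diag(k_q) C with C = dq/dx the Wilson B-matrix of the
same Z-matrix, which makes the internal curvature exactly diag(k_q) and keeps
H invariant under rigid motions.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .constants import KCAL_PER_MOL
from .internal_coords import (
    ZMatrixDefinition,
    cartesian_to_zmatrix,
    zmatrix_to_cartesian,
)
from .structure import CartesianStructure

__all__ = ["FixtureSpec", "Fixture", "make_fixture", "wilson_b", "fibonacci_sphere"]

DEG = np.pi / 180.0


@dataclass
class FixtureSpec:
    """Recipe for a synthetic chain molecule H-(C)n-H.

    Distances in angstrom, force constants in kcal/mol per (angstrom or
    rad)^2.  ``jitter`` scatters the force constants uniformly by the given
    relative amount using ``seed`` (distinct seeds give distinct but valid
    fixtures).
    """

    n_heavy: int = 2
    ch_length: float = 1.09
    cc_length: float = 1.53
    angle_deg: float = 109.47
    dihedral_deg: float = 170.0
    k_bond: float = 300.0
    k_angle: float = 80.0
    k_dihedral: float = 10.0
    jitter: float = 0.0
    seed: int = 0

    def __post_init__(self):
        if self.n_heavy < 1:
            raise ValueError("need at least one heavy atom")


@dataclass
class Fixture:
    structure: CartesianStructure
    zdef: ZMatrixDefinition
    q0: np.ndarray
    hessian: np.ndarray  # Cartesian, J/angstrom^2 (per molecule)
    k_internal: np.ndarray  # ground-truth internal constants, J/(unit)^2
    sidecar: dict = field(default_factory=dict)


def wilson_b(zdef: ZMatrixDefinition, structure, step: float = 1e-6) -> np.ndarray:
    """Wilson matrix C[k, 3i+a] = dq_k/dx_{i,a} by central finite differences.

    Dihedral rows are wrapped across the branch cut at +-pi.
    """
    X0 = structure.coords if isinstance(structure, CartesianStructure) else np.asarray(structure, float)
    n = X0.shape[0]
    kinds = [k for k, _ in zdef.coordinate_labels]
    nq = len(kinds)
    C = np.empty((nq, 3 * n))
    for i in range(n):
        for a in range(3):
            Xp = X0.copy()
            Xp[i, a] += step
            Xm = X0.copy()
            Xm[i, a] -= step
            qp = cartesian_to_zmatrix(zdef, Xp).values
            qm = cartesian_to_zmatrix(zdef, Xm).values
            dq = qp - qm
            for k, kind in enumerate(kinds):
                if kind == "dihedral":
                    dq[k] = (dq[k] + np.pi) % (2 * np.pi) - np.pi
            C[:, 3 * i + a] = dq / (2 * step)
    return C


def make_fixture(spec: FixtureSpec) -> Fixture:
    """Build geometry + Cartesian Hessian from known internal force constants."""
    n_c = spec.n_heavy
    elements = ["H"] + ["C"] * n_c + ["H"]
    n = len(elements)
    bonds = [(i, i + 1) for i in range(n - 1)]
    # reference internal coordinates of the chain Z-matrix
    theta = spec.angle_deg * DEG
    phi = spec.dihedral_deg * DEG
    lengths = [spec.ch_length] + [spec.cc_length] * (n_c - 1) + [spec.ch_length]
    q0_list = [lengths[0]]
    q0_list += [lengths[1], theta]
    for i in range(3, n):
        q0_list += [lengths[i - 1], theta, phi]
    # chain Z-matrix: atom i defined against its three predecessors
    from .internal_coords import ZMatrixEntry

    entries = [ZMatrixEntry(0), ZMatrixEntry(1, dist_ref=0)]
    if n > 2:
        entries.append(ZMatrixEntry(2, dist_ref=1, angle_ref=0))
    for i in range(3, n):
        entries.append(
            ZMatrixEntry(i, dist_ref=i - 1, angle_ref=i - 2, dihedral_ref=i - 3)
        )
    zdef = ZMatrixDefinition(entries=entries)
    q0 = np.array(q0_list)
    X = zmatrix_to_cartesian(zdef, q0)
    structure = CartesianStructure(
        elements=elements, coords=X, bonds=bonds, title="synthetic chain fixture"
    )

    kinds = [k for k, _ in zdef.coordinate_labels]
    base = {
        "distance": spec.k_bond,
        "angle": spec.k_angle,
        "dihedral": spec.k_dihedral,
    }
    kq = np.array([base[k] for k in kinds])
    if spec.jitter > 0:
        rng = np.random.default_rng(spec.seed)
        kq = kq * (1.0 + spec.jitter * rng.uniform(-1.0, 1.0, size=kq.size))
    kq_joule = kq * KCAL_PER_MOL

    C = wilson_b(zdef, structure)
    H = C.T @ np.diag(kq_joule) @ C
    H = 0.5 * (H + H.T)
    return Fixture(
        structure=structure,
        zdef=zdef,
        q0=q0,
        hessian=H,
        k_internal=kq_joule,
        sidecar={
            "k_internal_kcal": kq.tolist(),
            "coordinate_kinds": kinds,
            "n_internal": zdef.n_coords,
        },
    )


def fibonacci_sphere(n: int, radius: float) -> np.ndarray:
    """Quasi-uniform points on a sphere surface (angstrom), for rigid-body
    hydrodynamic shell models."""
    i = np.arange(n, dtype=float)
    golden = (1 + 5**0.5) / 2
    zc = 1 - 2 * (i + 0.5) / n
    r = np.sqrt(1 - zc * zc)
    phi = 2 * np.pi * i / golden
    return radius * np.column_stack([r * np.cos(phi), r * np.sin(phi), zc])
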