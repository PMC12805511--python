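"""Z-matrix internal coordinates.

A Z-matrix describes a molecule of N atoms by 3N-6 natural internal
coordinates: bond lengths (angstrom), bond angles and dihedral angles
(radians).  The first atom is placed freely, the second by a distance, the
third by a distance and an angle, and every later atom by a distance to a
reference atom, an angle and a dihedral.  Conversions between Cartesian and
internal coordinates, the Jacobian B = dx/dq of the placement map, and the
transformation of a Cartesian Hessian into the internal curvature matrix K
live here.

Conventions
-----------
* Placement frame: atom 1 at the origin, atom 2 on +z, atom 3 in the xz
  plane with positive x.  Only internal motion and a separately tracked
  global rotation are physical, so any fixed convention is acceptable.
* Dihedral sign: IUPAC right-handed convention (looking from the second to
  the third atom of the chain); trans-planar chains have phi = pi.
* Angles are stored in radians; file I/O uses degrees only where the Tinker
  dialect demands it.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np

from .errors import GeometryError, TopologyError
from .structure import CartesianStructure

__all__ = [
    "ZMatrixDefinition",
    "InternalCoordinates",
    "CurvatureMatrix",
    "build_zmatrix",
    "zmatrix_to_cartesian",
    "cartesian_to_zmatrix",
    "coordinate_jacobian",
    "hessian_to_curvature",
    "bond_angle",
    "dihedral_angle",
]

_COLLINEAR_TOL = 1e-8


# ---------------------------------------------------------------------------
# elementary vector algebra (complex-safe: used by the complex-step Jacobian)
# ---------------------------------------------------------------------------

def _vnorm(v):
    # no abs(): keeps the map holomorphic for complex-step differentiation
    return np.sqrt(np.sum(v * v, axis=-1))


def _unit(v):
    return v / _vnorm(v)


def bond_angle(a, b, c) -> float:
    """Angle at vertex b of the triplet (a, b, c), in (0, pi)."""
    u = np.asarray(a, dtype=float) - b
    v = np.asarray(c, dtype=float) - b
    cross = np.linalg.norm(np.cross(u, v))
    dot = float(np.dot(u, v))
    return float(np.arctan2(cross, dot))


def dihedral_angle(p0, p1, p2, p3) -> float:
    """Signed dihedral of the chain p0-p1-p2-p3, in (-pi, pi].

    Right-handed looking from p1 to p2; trans-planar chains give pi.
    """
    p0, p1, p2, p3 = (np.asarray(p, dtype=float) for p in (p0, p1, p2, p3))
    u1, u2, u3 = p1 - p0, p2 - p1, p3 - p2
    n1 = np.cross(u1, u2)
    n2 = np.cross(u2, u3)
    x = float(np.dot(n1, n2))
    y = float(np.dot(np.cross(n1, n2), u2 / np.linalg.norm(u2)))
    phi = float(np.arctan2(y, x))
    return np.pi if phi == -np.pi else phi


def _collinear(a, b, c, tol=_COLLINEAR_TOL) -> bool:
    u = np.asarray(b, dtype=float) - a
    v = np.asarray(c, dtype=float) - a
    denom = np.linalg.norm(u) * np.linalg.norm(v)
    if denom == 0.0:
        return True
    return np.linalg.norm(np.cross(u, v)) < tol * denom


# ---------------------------------------------------------------------------
# domain types
# ---------------------------------------------------------------------------

@dataclass
class ZMatrixEntry:
    atom: int
    dist_ref: int | None = None
    angle_ref: int | None = None
    dihedral_ref: int | None = None


@dataclass
class ZMatrixDefinition:
    """Per-atom internal-coordinate topology.

    ``entries`` are in placement order; every reference atom precedes the
    atom it defines.  ``extra_atom`` carries an optional fourth reference
    atom (a dihedral of interest) as metadata with no computational role.
    """

    entries: list[ZMatrixEntry]
    extra_atom: int | None = None

    @property
    def n_atoms(self) -> int:
        return len(self.entries)

    @property
    def n_coords(self) -> int:
        # 3N-6 for N >= 3; a hand-built 2-atom definition has one coordinate
        return sum(min(i, 3) for i in range(self.n_atoms))

    @property
    def atom_order(self) -> list[int]:
        return [e.atom for e in self.entries]

    @property
    def coordinate_labels(self) -> list[tuple[str, tuple[int, ...]]]:
        labels: list[tuple[str, tuple[int, ...]]] = []
        for i, e in enumerate(self.entries):
            if i == 0:
                continue
            labels.append(("distance", (e.atom, e.dist_ref)))
            if i >= 2:
                labels.append(("angle", (e.atom, e.dist_ref, e.angle_ref)))
            if i >= 3:
                labels.append(
                    ("dihedral", (e.atom, e.dist_ref, e.angle_ref, e.dihedral_ref))
                )
        return labels

    def validate(self) -> None:
        placed: set[int] = set()
        for i, e in enumerate(self.entries):
            refs = [e.dist_ref, e.angle_ref, e.dihedral_ref][: min(i, 3)]
            for r in refs:
                if r is None or r not in placed:
                    raise TopologyError(
                        f"atom {e.atom}: reference {r} not placed before it"
                    )
            placed.add(e.atom)


@dataclass
class InternalCoordinates:
    """Vector of internal coordinates (distances angstrom, angles rad)."""

    values: np.ndarray
    zdef: ZMatrixDefinition | None = None

    def __post_init__(self):
        self.values = np.asarray(self.values, dtype=float).ravel()

    def validate(self) -> None:
        if self.zdef is None:
            return
        if self.values.size != self.zdef.n_coords:
            raise GeometryError(
                f"expected {self.zdef.n_coords} coordinates, got {self.values.size}"
            )
        for (kind, _), v in zip(self.zdef.coordinate_labels, self.values):
            if kind == "distance" and v <= 0:
                raise GeometryError(f"non-positive distance {v}")
            if kind == "angle" and not (0.0 < v < np.pi):
                raise GeometryError(f"angle {v} outside (0, pi)")
            if kind == "dihedral" and not (-np.pi < v <= np.pi + 1e-12):
                raise GeometryError(f"dihedral {v} outside (-pi, pi]")


@dataclass
class CurvatureMatrix:
    """Internal curvature matrix K (J per squared coordinate unit)."""

    K: np.ndarray
    eigenvalues: np.ndarray = field(default=None)  # type: ignore[assignment]

    def __post_init__(self):
        self.K = np.asarray(self.K, dtype=float)
        if self.eigenvalues is None:
            self.eigenvalues = np.linalg.eigvalsh(self.K)

    def sqrt(self) -> np.ndarray:
        w, V = np.linalg.eigh(self.K)
        return (V * np.sqrt(np.clip(w, 0.0, None))) @ V.T


# ---------------------------------------------------------------------------
# Z-matrix construction
# ---------------------------------------------------------------------------

def build_zmatrix(
    structure: CartesianStructure,
    bonds: list[tuple[int, int]] | None = None,
    ref_atoms: tuple[int, ...] = (0, 1, 2),
) -> ZMatrixDefinition:
    """Build a Z-matrix over the bond graph.

    ``ref_atoms`` gives the three (non-collinear) atoms that define the
    molecule-fixed frame; a fourth entry, if present, is kept as metadata
    only.  Later atoms are defined relative to previously placed,
    bond-connected atoms where possible.
    """
    if bonds is None:
        bonds = structure.bonds
    n = structure.n_atoms
    if n < 3:
        raise TopologyError("need at least 3 atoms for a Z-matrix")
    extra = None
    if len(ref_atoms) == 4:
        extra = int(ref_atoms[3])
        ref_atoms = tuple(ref_atoms[:3])
    if len(ref_atoms) != 3 or len(set(ref_atoms)) != 3:
        raise TopologyError("ref_atoms must name three distinct atoms")
    r0, r1, r2 = (int(a) for a in ref_atoms)
    X = structure.coords
    if _collinear(X[r0], X[r1], X[r2]):
        raise GeometryError("reference atoms are collinear")

    adj: list[set[int]] = [set() for _ in range(n)]
    for i, j in bonds:
        adj[i].add(j)
        adj[j].add(i)
    seen = {r0}
    stack = [r0]
    while stack:
        for j in adj[stack.pop()]:
            if j not in seen:
                seen.add(j)
                stack.append(j)
    if len(seen) != n:
        raise TopologyError("bond graph is not connected")

    entries = [ZMatrixEntry(r0)]
    placed = [r0]
    placed_set = {r0}

    def _noncollinear_with(a: int, b: int, c: int) -> bool:
        return not _collinear(X[a], X[b], X[c])

    # second reference atom: distance to the first
    entries.append(ZMatrixEntry(r1, dist_ref=r0))
    placed.append(r1)
    placed_set.add(r1)

    # third reference atom: prefer a bonded placed anchor
    dref = r0 if r0 in adj[r2] else (r1 if r1 in adj[r2] else r0)
    aref = r1 if dref == r0 else r0
    entries.append(ZMatrixEntry(r2, dist_ref=dref, angle_ref=aref))
    placed.append(r2)
    placed_set.add(r2)

    while len(placed) < n:
        frontier = sorted(
            a for a in range(n) if a not in placed_set and adj[a] & placed_set
        )
        a = frontier[0]
        dref = min(adj[a] & placed_set)
        # angle reference: placed neighbours of dref first, then any placed atom
        cand_a = sorted(adj[dref] & placed_set - {a}) + [
            p for p in placed if p not in adj[dref]
        ]
        aref = next(
            (
                c
                for c in cand_a
                if c != a and c != dref
                and _noncollinear_with(a, dref, c)
            ),
            None,
        )
        if aref is None:
            raise GeometryError(f"no non-collinear angle reference for atom {a}")
        cand_d = (
            sorted((adj[aref] & placed_set) - {a, dref})
            + sorted((adj[dref] & placed_set) - {a, aref})
            + [p for p in placed if p not in (a, dref, aref)]
        )
        dhref = next(
            (
                c
                for c in cand_d
                if c not in (a, dref, aref)
                and _noncollinear_with(dref, aref, c)
            ),
            None,
        )
        if dhref is None:
            raise GeometryError(f"no non-collinear dihedral reference for atom {a}")
        entries.append(
            ZMatrixEntry(a, dist_ref=dref, angle_ref=aref, dihedral_ref=dhref)
        )
        placed.append(a)
        placed_set.add(a)

    zdef = ZMatrixDefinition(entries=entries, extra_atom=extra)
    zdef.validate()
    return zdef


# ---------------------------------------------------------------------------
# coordinate transformations
# ---------------------------------------------------------------------------

def cartesian_to_zmatrix(
    zdef: ZMatrixDefinition, structure: CartesianStructure | np.ndarray
) -> InternalCoordinates:
    """Measure the internal coordinates of ``structure`` under ``zdef``."""
    X = structure.coords if isinstance(structure, CartesianStructure) else np.asarray(structure, dtype=float)
    vals: list[float] = []
    for i, e in enumerate(zdef.entries):
        if i == 0:
            continue
        d = float(np.linalg.norm(X[e.atom] - X[e.dist_ref]))
        if d < 1e-12:
            raise GeometryError(f"atoms {e.atom} and {e.dist_ref} coincide")
        vals.append(d)
        if i >= 2:
            vals.append(bond_angle(X[e.atom], X[e.dist_ref], X[e.angle_ref]))
        if i >= 3:
            vals.append(
                dihedral_angle(
                    X[e.dihedral_ref], X[e.angle_ref], X[e.dist_ref], X[e.atom]
                )
            )
    return InternalCoordinates(np.array(vals), zdef=zdef)


def _place(zdef: ZMatrixDefinition, q: np.ndarray) -> np.ndarray:
    """Placement map q -> Cartesian coordinates (complex-safe).

    Atom order per ``zdef``; frame convention: first atom at the origin,
    second on +z, third in the xz plane with positive x.
    """
    dtype = np.asarray(q).dtype
    n = zdef.n_atoms
    X = np.zeros((n, 3), dtype=dtype)
    k = 0
    for i, e in enumerate(zdef.entries):
        if i == 0:
            continue
        if i == 1:
            d = q[k]; k += 1
            X[e.atom] = X[e.dist_ref] + np.array([0, 0, 1], dtype=dtype) * d
            continue
        if i == 2:
            d, theta = q[k], q[k + 1]; k += 2
            b, c = X[e.dist_ref], X[e.angle_ref]
            e1 = _unit(c - b)
            xhat = np.array([1, 0, 0], dtype=dtype)
            p = xhat - (xhat @ e1) * e1
            pn = _vnorm(p)
            if abs(pn) < 1e-12:  # e1 along x cannot occur with this frame
                p = np.array([0, 1, 0], dtype=dtype)
                pn = 1.0
            X[e.atom] = b + d * (np.cos(theta) * e1 + np.sin(theta) * (p / pn))
            continue
        d, theta, phi = q[k], q[k + 1], q[k + 2]; k += 3
        A, B, C = X[e.dihedral_ref], X[e.angle_ref], X[e.dist_ref]
        bc = _unit(C - B)
        nvec = np.cross(B - A, bc)
        nn = _vnorm(nvec)
        if abs(nn) < 1e-10:
            raise GeometryError(
                f"degenerate dihedral frame for atom {e.atom} (collinear references)"
            )
        nvec = nvec / nn
        m = np.cross(nvec, bc)
        local = d * np.array(
            [-np.cos(theta), np.sin(theta) * np.cos(phi), np.sin(theta) * np.sin(phi)],
            dtype=dtype,
        )
        X[e.atom] = C + local[0] * bc + local[1] * m + local[2] * nvec
    return X


def zmatrix_to_cartesian(
    zdef: ZMatrixDefinition, q: InternalCoordinates | np.ndarray
) -> np.ndarray:
    """Rebuild Cartesian coordinates (angstrom) in the placement frame."""
    qv = q.values if isinstance(q, InternalCoordinates) else np.asarray(q, dtype=float)
    if qv.size != zdef.n_coords:
        raise GeometryError(f"expected {zdef.n_coords} coordinates, got {qv.size}")
    labels = zdef.coordinate_labels
    for (kind, _), v in zip(labels, qv):
        if kind == "angle" and (v <= 1e-9 or v >= np.pi - 1e-9):
            raise GeometryError(
                f"bond angle {v:.3g} at the placement boundary (0 or pi): "
                "the dihedral of a dependent atom is undefined"
            )
    return _place(zdef, qv)


def coordinate_jacobian(
    zdef: ZMatrixDefinition,
    q: InternalCoordinates | np.ndarray,
    frame: CartesianStructure | np.ndarray | None = None,
) -> np.ndarray:
    """Jacobian B[3i+a, k] = dx_{i,a}/dq_k of the placement map (3N x Ns).

    Derivatives are obtained by complex-step differentiation of the placement
    map and are exact to machine precision.  By default B is expressed in the
    placement frame; passing ``frame`` (a structure consistent with ``zdef``)
    rotates B into the frame of that structure via rigid superposition.
    """
    qv = q.values if isinstance(q, InternalCoordinates) else np.asarray(q, dtype=float)
    ns = zdef.n_coords
    eps = 1e-200
    B = np.empty((3 * zdef.n_atoms, ns))
    for k in range(ns):
        qc = qv.astype(complex)
        qc[k] += 1j * eps
        B[:, k] = _place(zdef, qc).imag.ravel() / eps
    if frame is not None:
        Xf = frame.coords if isinstance(frame, CartesianStructure) else np.asarray(frame, dtype=float)
        Xp = _place(zdef, qv)
        R = _kabsch(Xf, Xp)
        n = zdef.n_atoms
        B = (R @ B.reshape(n, 3, ns)).reshape(3 * n, ns)
    return B


def _kabsch(target: np.ndarray, source: np.ndarray) -> np.ndarray:
    """Proper rotation R minimizing |target_c - R source_c| (centred)."""
    from scipy.spatial.transform import Rotation

    tc = target - target.mean(axis=0)
    sc = source - source.mean(axis=0)
    rot, _ = Rotation.align_vectors(tc, sc)
    return rot.as_matrix()


# ---------------------------------------------------------------------------
# Hessian -> curvature
# ---------------------------------------------------------------------------

def hessian_to_curvature(
    H_cart: np.ndarray,
    B: np.ndarray,
    sym_tol: float = 1e-8,
    floor_ratio: float = 1e-8,
) -> CurvatureMatrix:
    """Transform a Cartesian Hessian into the internal curvature matrix.

    K = B^T H B.  At a stationary point the gradient term of the exact
    second-derivative chain rule vanishes, so the first-derivative term is
    the whole transformation.  The six rigid-body modes are absent from K by
    construction (B spans internal displacements only).  Eigenvalues below
    ``floor_ratio`` times the largest are floored to that threshold with a
    warning, so the returned K is strictly positive definite; a negative
    eigenvalue beyond tolerance signals a non-minimum and raises.
    """
    H = np.asarray(H_cart, dtype=float)
    if H.shape[0] != H.shape[1]:
        raise ValueError("Hessian must be square")
    asym = np.max(np.abs(H - H.T))
    scale = max(np.max(np.abs(H)), 1.0)
    if asym > sym_tol * scale:
        raise ValueError(f"Hessian is not symmetric (max asymmetry {asym:.3g})")
    H = 0.5 * (H + H.T)
    K = B.T @ H @ B
    K = 0.5 * (K + K.T)
    w, V = np.linalg.eigh(K)
    wmax = float(w[-1])
    if wmax <= 0:
        raise ValueError(
            "curvature matrix has no positive eigenvalue: "
            "the structure is not at a minimum"
        )
    if w[0] < -1e-6 * wmax:
        raise ValueError(
            f"curvature matrix has negative eigenvalue {w[0]:.6g}: "
            "the structure is not at a minimum"
        )
    floor = floor_ratio * wmax
    if np.any(w < floor):
        warnings.warn(
            f"{int(np.sum(w < floor))} curvature eigenvalue(s) below "
            f"{floor:.3g} floored for positive definiteness",
            stacklevel=2,
        )
        w = np.clip(w, floor, None)
        K = (V * w) @ V.T
        K = 0.5 * (K + K.T)
    return CurvatureMatrix(K=K, eigenvalues=w)
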