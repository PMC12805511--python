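"""Z-matrix construction, coordinate transformations and the curvature matrix."""

import numpy as np
import pytest

from sfbd import CartesianStructure
from sfbd.errors import GeometryError, TopologyError
from sfbd.internal_coords import (
    ZMatrixDefinition,
    ZMatrixEntry,
    build_zmatrix,
    cartesian_to_zmatrix,
    coordinate_jacobian,
    dihedral_angle,
    hessian_to_curvature,
    zmatrix_to_cartesian,
    _kabsch,
    _place,
)


def _random_structure(rng, n):
    """Random non-degenerate chain geometry."""
    while True:
        X = rng.normal(size=(n, 3)) * 2.0
        ok = all(
            np.linalg.norm(X[i] - X[j]) > 0.3 for i in range(n) for j in range(i)
        )
        if ok:
            return CartesianStructure(
                elements=["C"] * n, coords=X, bonds=[(i, i + 1) for i in range(n - 1)]
            )


class TestBuildZMatrix:
    def test_four_atom_star_coordinate_kinds(self):
        # topology 1-2, 1-3, 3-4: distances d12, d13, angle, d34, angle, dihedral
        X = np.array([[0.0, 0, 0], [0, 0, 1.5], [1.2, 0, -0.5], [2.0, 0.9, -0.8]])
        s = CartesianStructure(
            elements=["C"] * 4, coords=X, bonds=[(0, 1), (0, 2), (2, 3)]
        )
        zdef = build_zmatrix(s, ref_atoms=(0, 1, 2))
        kinds = [k for k, _ in zdef.coordinate_labels]
        assert kinds == ["distance", "distance", "angle", "distance", "angle", "dihedral"]
        assert zdef.n_coords == 6
        # bond-connected references where possible
        assert zdef.entries[1].dist_ref == 0
        assert zdef.entries[3].dist_ref == 2

    def test_three_atoms_give_three_coordinates(self):
        X = np.array([[0.0, 0, 0], [0, 0, 1.0], [1.0, 0, 0]])
        s = CartesianStructure(elements=["O", "H", "H"], coords=X, bonds=[(0, 1), (0, 2)])
        zdef = build_zmatrix(s, ref_atoms=(0, 1, 2))
        kinds = [k for k, _ in zdef.coordinate_labels]
        assert kinds == ["distance", "distance", "angle"]

    def test_six_atom_chain_coordinate_counts(self):
        rng = np.random.default_rng(5)
        s = _random_structure(rng, 6)
        zdef = build_zmatrix(s, ref_atoms=(0, 1, 2))
        kinds = [k for k, _ in zdef.coordinate_labels]
        assert len(kinds) == 12
        assert kinds.count("distance") == 5
        assert kinds.count("angle") == 4
        assert kinds.count("dihedral") == 3

    def test_collinear_reference_atoms_rejected(self):
        X = np.array([[0.0, 0, 0], [0, 0, 1], [0, 0, 2], [1, 0, 0]])
        s = CartesianStructure(elements=["C"] * 4, coords=X, bonds=[(0, 1), (1, 2), (2, 3)])
        with pytest.raises(GeometryError):
            build_zmatrix(s, ref_atoms=(0, 1, 2))

    def test_disconnected_graph_rejected(self):
        X = np.array([[0.0, 0, 0], [0, 0, 1], [1, 0, 0], [5, 5, 5]])
        s = CartesianStructure(elements=["C"] * 4, coords=X, bonds=[(0, 1), (0, 2)])
        with pytest.raises(TopologyError):
            build_zmatrix(s, ref_atoms=(0, 1, 2))

    def test_fourth_ref_atom_is_metadata(self):
        rng = np.random.default_rng(6)
        s = _random_structure(rng, 5)
        zdef = build_zmatrix(s, ref_atoms=(0, 1, 2, 4))
        assert zdef.extra_atom == 4
        assert zdef.n_coords == 9


class TestTransformations:
    def test_right_angle_triatomic_placement(self):
        zdef = ZMatrixDefinition(
            entries=[
                ZMatrixEntry(0),
                ZMatrixEntry(1, dist_ref=0),
                ZMatrixEntry(2, dist_ref=0, angle_ref=1),
            ]
        )
        X = zmatrix_to_cartesian(zdef, np.array([1.0, 1.0, np.pi / 2]))
        r12, r13 = X[1] - X[0], X[2] - X[0]
        assert np.linalg.norm(r12) == pytest.approx(1.0, abs=1e-12)
        assert np.linalg.norm(r13) == pytest.approx(1.0, abs=1e-12)
        assert abs(r12 @ r13) < 1e-12

    def test_two_atom_distance_measurement(self):
        zdef = ZMatrixDefinition(entries=[ZMatrixEntry(0), ZMatrixEntry(1, dist_ref=0)])
        q = cartesian_to_zmatrix(zdef, np.array([[0.0, 0, 0], [0, 0, 1.5]]))
        assert q.values == pytest.approx([1.5])

    def test_trans_planar_dihedral_is_pi(self):
        X = np.array([[0.0, 0, 0], [0, 0, 1.5], [1.2, 0, 2.0], [1.2, 0, 3.5]])
        assert dihedral_angle(X[0], X[1], X[2], X[3]) == pytest.approx(np.pi)

    def test_dihedral_pi_and_minus_pi_coincide(self):
        zdef = ZMatrixDefinition(
            entries=[
                ZMatrixEntry(0),
                ZMatrixEntry(1, dist_ref=0),
                ZMatrixEntry(2, dist_ref=1, angle_ref=0),
                ZMatrixEntry(3, dist_ref=2, angle_ref=1, dihedral_ref=0),
            ]
        )
        base = [1.5, 1.4, 1.9, 1.45, 2.0]
        Xp = zmatrix_to_cartesian(zdef, np.array(base + [np.pi]))
        Xm = zmatrix_to_cartesian(zdef, np.array(base + [-np.pi]))
        assert np.max(np.abs(Xp - Xm)) < 1e-12

    def test_roundtrip_random_geometries(self):
        rng = np.random.default_rng(42)
        for _ in range(25):
            s = _random_structure(rng, int(rng.integers(4, 9)))
            zdef = build_zmatrix(s, ref_atoms=(0, 1, 2))
            q = cartesian_to_zmatrix(zdef, s)
            X2 = zmatrix_to_cartesian(zdef, q)
            q2 = cartesian_to_zmatrix(zdef, X2)
            dq = q2.values - q.values
            # dihedrals may differ by full turns across the branch cut
            dq = (dq + np.pi) % (2 * np.pi) - np.pi
            assert np.max(np.abs(dq)) < 1e-12
            # Cartesian recovery after optimal rigid superposition
            R = _kabsch(s.coords, X2)
            X2a = (X2 - X2.mean(0)) @ R.T + s.coords.mean(0)
            assert np.max(np.abs(X2a - s.coords)) < 1e-10

    def test_measurement_against_brute_force_vector_algebra(self):
        """Distances/angles/dihedrals vs an independent arccos/triple-product
        implementation on 100 random geometries."""
        rng = np.random.default_rng(7)
        for _ in range(100):
            s = _random_structure(rng, 5)
            zdef = build_zmatrix(s, ref_atoms=(0, 1, 2))
            q = cartesian_to_zmatrix(zdef, s).values
            X = s.coords
            expected = []
            for kind, atoms in zdef.coordinate_labels:
                if kind == "distance":
                    a, b = atoms
                    expected.append(np.sqrt(np.sum((X[a] - X[b]) ** 2)))
                elif kind == "angle":
                    a, b, c = atoms
                    u, v = X[a] - X[b], X[c] - X[b]
                    cosang = u @ v / (np.linalg.norm(u) * np.linalg.norm(v))
                    expected.append(np.arccos(np.clip(cosang, -1, 1)))
                else:
                    a, b, c, d = atoms  # chain d-c-b-a in measurement order
                    p0, p1, p2, p3 = X[d], X[c], X[b], X[a]
                    n1 = np.cross(p1 - p0, p2 - p1)
                    n2 = np.cross(p2 - p1, p3 - p2)
                    cosphi = n1 @ n2 / (np.linalg.norm(n1) * np.linalg.norm(n2))
                    phi = np.arccos(np.clip(cosphi, -1, 1))
                    if np.dot(np.cross(n1, n2), p2 - p1) < 0:
                        phi = -phi
                    expected.append(phi)
            assert np.allclose(q, expected, atol=1e-10)

    def test_degenerate_angle_rejected(self):
        zdef = ZMatrixDefinition(
            entries=[
                ZMatrixEntry(0),
                ZMatrixEntry(1, dist_ref=0),
                ZMatrixEntry(2, dist_ref=1, angle_ref=0),
            ]
        )
        with pytest.raises(GeometryError):
            zmatrix_to_cartesian(zdef, np.array([1.5, 1.4, np.pi]))


class TestJacobian:
    def test_diatomic_distance_column(self):
        zdef = ZMatrixDefinition(entries=[ZMatrixEntry(0), ZMatrixEntry(1, dist_ref=0)])
        B = coordinate_jacobian(zdef, np.array([1.3]))
        expected = np.zeros((6, 1))
        expected[5, 0] = 1.0  # atom 2 sits on +z in the placement frame
        assert np.allclose(B, expected, atol=1e-12)

    def test_matches_central_finite_differences(self):
        rng = np.random.default_rng(11)
        for _ in range(5):
            s = _random_structure(rng, 6)
            zdef = build_zmatrix(s, ref_atoms=(0, 1, 2))
            q = cartesian_to_zmatrix(zdef, s)
            B = coordinate_jacobian(zdef, q)
            h = 1e-6
            scale = max(1.0, np.abs(B).max())
            for k in range(q.values.size):
                qp, qm = q.values.copy(), q.values.copy()
                qp[k] += h
                qm[k] -= h
                col = (_place(zdef, qp) - _place(zdef, qm)).ravel() / (2 * h)
                assert np.max(np.abs(B[:, k] - col)) < 1e-6 * scale

    def test_full_rank(self):
        rng = np.random.default_rng(12)
        s = _random_structure(rng, 7)
        zdef = build_zmatrix(s, ref_atoms=(0, 1, 2))
        q = cartesian_to_zmatrix(zdef, s)
        B = coordinate_jacobian(zdef, q)
        assert np.linalg.matrix_rank(B, tol=1e-9) == zdef.n_coords


class TestCurvature:
    def test_diatomic_spring_constant(self):
        # Cartesian spring k_s along the bond (z axis): K must be [k_s]
        ks = 300.0
        u = np.array([0.0, 0, 0, 0, 0, 1.0])  # relative displacement direction
        H = ks * np.outer(u - np.roll(u, 3), u - np.roll(u, 3)) / 2
        # explicit two-body spring Hessian: k_s * [[P, -P], [-P, P]] with P = zz
        P = np.zeros((3, 3))
        P[2, 2] = 1.0
        H = ks * np.block([[P, -P], [-P, P]])
        zdef = ZMatrixDefinition(entries=[ZMatrixEntry(0), ZMatrixEntry(1, dist_ref=0)])
        B = coordinate_jacobian(zdef, np.array([1.1]))
        K = hessian_to_curvature(H, B)
        assert K.K.shape == (1, 1)
        assert K.K[0, 0] == pytest.approx(ks, rel=1e-12)

    def test_constructed_fixture_recovers_constants(self, toy_fixture):
        fx = toy_fixture
        q0 = cartesian_to_zmatrix(fx.zdef, fx.structure)
        B = coordinate_jacobian(fx.zdef, q0, frame=fx.structure)
        K = hessian_to_curvature(fx.hessian, B)
        scale = np.max(fx.k_internal)
        assert np.max(np.abs(np.diag(K.K) - fx.k_internal)) < 1e-8 * scale
        off = K.K - np.diag(np.diag(K.K))
        assert np.max(np.abs(off)) < 1e-8 * scale

    def test_rigid_body_invariance(self, toy_fixture):
        from scipy.spatial.transform import Rotation

        fx = toy_fixture
        q0 = cartesian_to_zmatrix(fx.zdef, fx.structure)
        B = coordinate_jacobian(fx.zdef, q0, frame=fx.structure)
        K0 = hessian_to_curvature(fx.hessian, B).K
        R = Rotation.from_euler("zyx", [0.4, -1.1, 2.2]).as_matrix()
        n = fx.structure.n_atoms
        Xr = fx.structure.coords @ R.T + np.array([1.0, -2.0, 0.5])
        Rblk = np.kron(np.eye(n), R)
        Hr = Rblk @ fx.hessian @ Rblk.T
        sr = CartesianStructure(
            elements=fx.structure.elements, coords=Xr, bonds=fx.structure.bonds
        )
        qr = cartesian_to_zmatrix(fx.zdef, sr)
        Br = coordinate_jacobian(fx.zdef, qr, frame=sr)
        Kr = hessian_to_curvature(Hr, Br).K
        assert np.max(np.abs(Kr - K0)) < 1e-8 * np.max(np.abs(K0))

    def test_asymmetric_hessian_rejected(self):
        zdef = ZMatrixDefinition(entries=[ZMatrixEntry(0), ZMatrixEntry(1, dist_ref=0)])
        B = coordinate_jacobian(zdef, np.array([1.1]))
        H = np.eye(6)
        H[0, 1] = 1.0
        with pytest.raises(ValueError, match="symmetric"):
            hessian_to_curvature(H, B)

    def test_negative_curvature_rejected(self):
        zdef = ZMatrixDefinition(entries=[ZMatrixEntry(0), ZMatrixEntry(1, dist_ref=0)])
        B = coordinate_jacobian(zdef, np.array([1.1]))
        P = np.zeros((3, 3))
        P[2, 2] = 1.0
        H = -5.0 * np.block([[P, -P], [-P, P]])
        with pytest.raises(ValueError, match="minimum"):
            hessian_to_curvature(H, B)

    def test_small_eigenvalues_floored_with_warning(self, toy_fixture):
        fx = toy_fixture
        q0 = cartesian_to_zmatrix(fx.zdef, fx.structure)
        B = coordinate_jacobian(fx.zdef, q0, frame=fx.structure)
        K0 = hessian_to_curvature(fx.hessian, B).K
        w, V = np.linalg.eigh(K0)
        w[0] = 0.0  # flat mode
        Kflat = (V * w) @ V.T
        Hflat = np.linalg.pinv(B).T @ Kflat @ np.linalg.pinv(B)
        with pytest.warns(UserWarning, match="floored"):
            K = hessian_to_curvature(Hflat, B)
        assert np.linalg.eigvalsh(K.K)[0] > 0
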