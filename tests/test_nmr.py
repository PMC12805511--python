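"""Probe detection, Wigner functions, ACF estimation, fits and relaxation."""

import numpy as np
import pytest
from scipy.spatial.transform import Rotation

from sfbd import CartesianStructure
from sfbd.constants import GAMMA, HBAR, MU0
from sfbd.errors import GeometryError
from sfbd.nmr import (
    Acf,
    Probe,
    SpectralDensityModel,
    autocorrelation,
    d200_from_quaternions,
    detect_probes,
    dipolar_frame,
    multiexp_fit,
    relaxation,
    spectral_density,
    wigner_d2_00,
    wigner_d2_0m,
)


def _ethane_like():
    # H3C-CH3 skeleton reduced to H-C-C-H for probe topology tests
    X = np.array([[0.0, 0, 0], [0, 0, 1.1], [1.0, 0, 1.9], [1.0, 0, 3.0]])
    return CartesianStructure(
        elements=["H", "C", "C", "H"], coords=X, bonds=[(0, 1), (1, 2), (2, 3)]
    )


class TestProbeDetection:
    def test_ch_probe_with_carbon_substituent(self):
        probes = detect_probes(_ethane_like(), nucleus="13C1H")
        assert len(probes) == 2
        p = probes[0]
        assert p.kind == "CH"
        assert p.h_atom == 0 and p.heavy_atom == 1 and p.x_atom == 2

    def test_ch2_group_flagged_as_paired(self):
        X = np.array(
            [[0.0, 0, 0], [1.0, 0, 0], [1.6, 0.9, 0], [1.6, -0.9, 0], [2.0, 0, 1.0]]
        )
        s = CartesianStructure(
            elements=["C", "C", "H", "H", "O"],
            coords=X,
            bonds=[(0, 1), (1, 2), (1, 3), (1, 4)],
        )
        probes = detect_probes(s, nucleus="13C1H")
        ch2 = [p for p in probes if p.kind == "CH2"]
        assert len(ch2) == 2
        assert {p.h_atom for p in ch2} == {2, 3}
        assert all(p.heavy_atom == 1 for p in ch2)

    def test_nh_probe(self):
        X = np.array([[0.0, 0, 0], [0, 0, 1.0], [1.0, 0, 1.5]])
        s = CartesianStructure(
            elements=["H", "N", "C"], coords=X, bonds=[(0, 1), (1, 2)]
        )
        probes = detect_probes(s, nucleus="15N1H")
        assert len(probes) == 1 and probes[0].kind == "NH"
        assert detect_probes(s, nucleus="13C1H") == []

    def test_heavy_atom_without_substituent_skipped_with_warning(self):
        # methane: carbon has only hydrogens, X is undefined
        X = np.vstack([np.zeros(3), np.eye(3), [[-1, -1, -1]]]) * 1.1
        s = CartesianStructure(
            elements=["C", "H", "H", "H", "H"],
            coords=X,
            bonds=[(0, i) for i in range(1, 5)],
        )
        with pytest.warns(UserWarning, match="substituent"):
            probes = detect_probes(s, nucleus="13C1H")
        assert probes == []

    def test_unknown_nucleus_rejected(self):
        with pytest.raises(ValueError):
            detect_probes(_ethane_like(), nucleus="31P1H")


class TestDipolarFrame:
    def test_bond_along_lab_z_gives_beta_zero(self):
        M, ang = dipolar_frame([0, 0, 1.1], [0, 0, 0], [1.0, 0, -0.4])
        assert ang[1] == pytest.approx(0.0, abs=1e-12)
        assert M[:, 2] == pytest.approx([0, 0, 1])

    def test_rotation_composition(self):
        H, C, X = np.array([0.3, 0.2, 1.0]), np.zeros(3), np.array([1.0, 0.1, -0.4])
        M, _ = dipolar_frame(H, C, X)
        R = Rotation.from_euler("zxz", [1.1, 0.5, -2.0]).as_matrix()
        M2, _ = dipolar_frame(R @ H, R @ C, R @ X)
        assert np.max(np.abs(M2 - R @ M)) < 1e-12

    def test_orthonormality_random_geometries(self):
        rng = np.random.default_rng(3)
        for _ in range(30):
            H, C, X = rng.normal(size=(3, 3))
            M, _ = dipolar_frame(H, C, X)
            assert np.max(np.abs(M.T @ M - np.eye(3))) < 1e-12
            assert np.linalg.det(M) == pytest.approx(1.0, abs=1e-12)

    def test_collinear_atoms_rejected(self):
        with pytest.raises(GeometryError):
            dipolar_frame([0, 0, 1.0], [0, 0, 0], [0, 0, -1.0])


class TestWigner:
    def test_special_values(self):
        assert wigner_d2_00(np.array([0.3, 0.0, -1.0])) == pytest.approx(1.0)
        magic = np.arccos(1.0 / np.sqrt(3.0))
        assert wigner_d2_00(np.array([0.0, magic, 0.0])) == pytest.approx(0.0, abs=1e-15)

    def test_unitarity(self):
        rng = np.random.default_rng(4)
        for _ in range(20):
            om = np.array(
                [rng.uniform(-np.pi, np.pi), rng.uniform(0, np.pi), rng.uniform(-np.pi, np.pi)]
            )
            total = sum(abs(wigner_d2_0m(om, m)) ** 2 for m in range(-2, 3))
            assert total == pytest.approx(1.0, abs=1e-13)


class TestAutocorrelation:
    def test_iid_uniform_orientations(self):
        """Independent uniform orientations: C(0) = 1 (the factor 5 cancels
        <|D200|^2> = 1/5) and C(t>0) ~ 0."""
        rng = np.random.default_rng(5)
        Q = rng.standard_normal((40_000, 4))
        Q /= np.linalg.norm(Q, axis=1)[:, None]
        d200 = d200_from_quaternions(Q)
        acf = autocorrelation(d200, dt=1.0, max_lags=50)
        assert acf.values[0] == pytest.approx(1.0, abs=0.02)
        assert np.max(np.abs(acf.values[1:])) < 0.05

    def test_frozen_orientation(self):
        # constant beta = 0: D200 = 1, so the unnormalized C(t) = 5
        acf = autocorrelation(np.ones(200), dt=0.1)
        assert np.allclose(acf.values, 5.0)

    def test_too_short_series_rejected(self):
        with pytest.raises(ValueError):
            autocorrelation(np.ones(1), dt=1.0)

    def test_isotropic_rotor_exponential_decay(self, rotor_ensemble):
        dt = rotor_ensemble[0].times[1] - rotor_ensemble[0].times[0]
        series = [d200_from_quaternions(tr.quaternions) for tr in rotor_ensemble]
        acf = autocorrelation(series, dt, max_lags=120)
        ref = np.exp(-6.0 * acf.lags)
        assert np.max(np.abs(acf.values - ref)) < 0.05


class TestMultiExpFit:
    def test_single_exponential_recovery(self):
        t = np.linspace(0, 8, 400)
        fit = multiexp_fit(Acf(lags=t, values=np.exp(-t / 1.0)), n_exp=4)
        dominant = np.argmax(fit.weights)
        assert abs(fit.taus[dominant] - 1.0) < 1e-6
        assert fit.weights.sum() - fit.weights[dominant] < 1e-6
        assert fit.residual < 1e-10

    def test_two_exponential_recovery_with_noise(self):
        rng = np.random.default_rng(6)
        t = np.linspace(0, 5, 2000)
        y = 0.8 * np.exp(-t / 1.0) + 0.2 * np.exp(-t / 0.01)
        fit = multiexp_fit(Acf(lags=t, values=y + 0.01 * rng.standard_normal(t.size)), n_exp=2)
        assert fit.taus[0] == pytest.approx(1.0, rel=0.05)
        assert fit.taus[1] == pytest.approx(0.01, rel=0.05)

    def test_weights_sum_to_c0(self):
        t = np.linspace(0, 6, 600)
        y = 0.6 * np.exp(-t / 0.8) + 0.4 * np.exp(-t / 0.05)
        fit = multiexp_fit(Acf(lags=t, values=y), n_exp=3)
        assert fit.c0 == pytest.approx(1.0, abs=1e-6)

    def test_invalid_inputs(self):
        t = np.linspace(0, 1, 50)
        with pytest.raises(ValueError):
            multiexp_fit(Acf(lags=t, values=-np.ones(50)), n_exp=2)
        with pytest.raises(ValueError):
            multiexp_fit(Acf(lags=t, values=np.exp(-t)), n_exp=6)


class TestSpectralDensity:
    def test_closed_form_values(self):
        J = SpectralDensityModel(weights=np.array([1.0]), taus=np.array([2.0]))
        assert J(0.0) == pytest.approx(4.0)  # J(0) = 2 tau
        assert J(0.5) == pytest.approx(2.0)  # omega tau = 1 halves J(0)
        assert J.j0 == pytest.approx(4.0)

    def test_numeric_cosine_transform_agreement(self):
        from scipy.integrate import quad

        fit = SpectralDensityModel(weights=np.array([0.7, 0.3]), taus=np.array([1.5, 0.1]))
        for omega in (0.0, 0.8, 3.0):
            val, _ = quad(
                lambda t: 2
                * (0.7 * np.exp(-t / 1.5) + 0.3 * np.exp(-t / 0.1))
                * np.cos(omega * t),
                0,
                np.inf,
                limit=200,
            )
            assert fit(omega) == pytest.approx(val, rel=1e-8)

    def test_nonnegative_and_decreasing(self):
        J = SpectralDensityModel(weights=np.array([0.5, 0.5]), taus=np.array([1.0, 0.01]))
        om = np.linspace(0, 50, 200)
        vals = J(om)
        assert np.all(vals >= 0)
        assert np.all(np.diff(vals) <= 1e-15)


class TestRelaxation:
    def _probe(self, delta_csa=0.0):
        return Probe(kind="CH", h_atom=0, heavy_atom=1, x_atom=2,
                     bond_length=1.13, delta_csa=delta_csa)

    def test_extreme_narrowing_noe_plateau(self):
        J = SpectralDensityModel(weights=np.array([1.0]), taus=np.array([1e-14]))
        res = relaxation(J, self._probe(), [600.132])
        assert res.NOE[0] == pytest.approx(1 + GAMMA["1H"] / (2 * GAMMA["13C"]), rel=1e-4)
        assert res.T1_ms[0] == pytest.approx(res.T2_ms[0], rel=1e-4)

    def test_zero_csa_has_no_csa_contribution(self):
        J = SpectralDensityModel(weights=np.array([1.0]), taus=np.array([0.2e-9]))
        r0 = relaxation(J, self._probe(0.0), [600.132])
        r1 = relaxation(J, self._probe(50.0), [600.132])
        assert r1.T1_ms[0] < r0.T1_ms[0]  # CSA adds relaxation when present

    def test_against_independent_brute_force_evaluation(self):
        """T1/T2/NOE from a single Lorentzian at tau = 0.218 ns, r = 1.13 A,
        600.132 MHz, recomputed inline from scratch."""
        tau = 0.218e-9
        J = SpectralDensityModel(weights=np.array([1.0]), taus=np.array([tau]))
        res = relaxation(J, self._probe(), [600.132])
        gh, gc = GAMMA["1H"], GAMMA["13C"]
        d = (MU0 / (4 * np.pi)) * gh * gc * HBAR / (1.13e-10) ** 3
        wh = 2 * np.pi * 600.132e6
        wc = wh * gc / gh

        def j(w):
            return 2 * tau / (1 + (w * tau) ** 2)

        r1 = (d * d / 20) * (j(wh - wc) + 3 * j(wc) + 6 * j(wh + wc))
        r2 = (d * d / 40) * (4 * j(0) + j(wh - wc) + 3 * j(wc) + 6 * j(wh) + 6 * j(wh + wc))
        noe = 1 + (gh / gc) * (d * d / 20) * (6 * j(wh + wc) - j(wh - wc)) / r1
        assert res.T1_ms[0] == pytest.approx(1e3 / r1, rel=1e-10)
        assert res.T2_ms[0] == pytest.approx(1e3 / r2, rel=1e-10)
        assert res.NOE[0] == pytest.approx(noe, rel=1e-10)

    def test_t2_not_exceeding_t1_outside_extreme_narrowing(self):
        J = SpectralDensityModel(weights=np.array([1.0]), taus=np.array([2e-9]))
        res = relaxation(J, self._probe(), [600.132, 699.973])
        assert np.all(res.T2_ms <= res.T1_ms)
        assert np.all(res.T1_ms > 0) and np.all(res.T2_ms > 0)

    def test_unsupported_probe_nucleus_rejected(self):
        J = SpectralDensityModel(weights=np.array([1.0]), taus=np.array([1e-9]))
        with pytest.raises(ValueError):
            relaxation(J, self._probe(), [600.0], nucleus="31P1H")


class TestEndToEndRotor:
    def test_rigid_rotor_t1_matches_analytic_lorentzian(self, rotor_ensemble):
        """BD -> ACF -> multiexponential fit -> J -> T1 for a rigid isotropic
        rotor agrees with the single-Lorentzian prediction at tau = 1/(6 D_R).

        The dimensionless rotor time unit is declared to be nanoseconds so
        the relaxation formulas operate at a physically relevant scale.
        """
        dt = rotor_ensemble[0].times[1] - rotor_ensemble[0].times[0]
        series = [d200_from_quaternions(tr.quaternions) for tr in rotor_ensemble]
        acf = autocorrelation(series, dt * 1e-9, max_lags=150)
        fit = multiexp_fit(acf, n_exp=2)
        probe = Probe(kind="CH", h_atom=0, heavy_atom=1, x_atom=2, bond_length=1.13)
        res = relaxation(spectral_density(fit), probe, [600.132])
        analytic = relaxation(
            SpectralDensityModel(weights=np.array([1.0]), taus=np.array([1e-9 / 6.0])),
            probe,
            [600.132],
        )
        assert res.T1_ms[0] == pytest.approx(analytic.T1_ms[0], rel=0.05)
        assert res.NOE[0] == pytest.approx(analytic.NOE[0], rel=0.05)
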