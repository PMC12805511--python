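"""NMR relaxation observables from orientational trajectories.

Pipeline: detect dipolar probes (N-H, C-H, -CH2) from the bond topology,
extract the dipolar-frame orientation for every trajectory frame, accumulate
the rank-2 autocorrelation function

    C(t) = 5 < D^2_00(Omega(t+s)) D^2_00(Omega(s)) >

(the factor 5 normalizes C(0) to 1 at equilibrium, since the isotropic
average of |D^2_00|^2 is 1/5), fit it with a sum of decaying exponentials,
form the Lorentzian spectral density and evaluate T1, T2 and the
heteronuclear NOE.

Spectral-density convention: J(omega) = 2 Int_0^inf C(t) cos(omega t) dt with
C(0) = 1, i.e. J(omega) = sum_k a_k 2 tau_k/(1 + omega^2 tau_k^2).  This is
five times the (2/5) tau Lorentzian of the standard treatments, so the
dipolar prefactor in the rate expressions is d^2/20 (not d^2/4) and the
axially symmetric CSA strength is c^2 = (omega_X delta)^2 / 15.  The set is
self-consistent: it reproduces the extreme-narrowing NOE plateau
1 + gamma_H/(2 gamma_X) and the absolute T1/T2 scale of the standard
equations.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
from scipy.optimize import least_squares, nnls
from scipy.spatial.transform import Rotation

from .constants import GAMMA, HBAR, MU0
from .errors import FitError, GeometryError
from .structure import CartesianStructure

__all__ = [
    "Probe",
    "Acf",
    "MultiExpModel",
    "SpectralDensityModel",
    "RelaxationResult",
    "detect_probes",
    "dipolar_frame",
    "wigner_d2_00",
    "wigner_d2_0m",
    "autocorrelation",
    "acf_from_trajectories",
    "multiexp_fit",
    "spectral_density",
    "relaxation",
]


# ---------------------------------------------------------------------------
# probes
# ---------------------------------------------------------------------------

@dataclass
class Probe:
    """A dipolar X-H probe: H, the heavy atom, and its substituent X."""

    kind: str  # "CH", "NH" or "CH2"
    h_atom: int
    heavy_atom: int
    x_atom: int
    bond_length: float = 1.13  # angstrom; effective, includes librations
    delta_csa: float = 0.0  # ppm
    csa_tilt: tuple[float, float, float] = (0.0, 0.0, 0.0)  # pass-through

    @property
    def label(self) -> str:
        return f"{self.kind}:{self.heavy_atom + 1}-{self.h_atom + 1}"


_NUCLEUS_HEAVY = {"13C1H": "C", "15N1H": "N"}


def detect_probes(
    structure: CartesianStructure,
    nucleus: str = "13C1H",
    bond_length: float = 1.13,
    delta_csa: float = 0.0,
) -> list[Probe]:
    """Recognize N-H, C-H and -CH2 probes from the bonding pattern.

    Every H bonded to the selected heavy-atom species yields a probe whose X
    atom is a non-hydrogen substituent of the heavy atom; heavy atoms with
    two hydrogens are flagged CH2 (paired probes sharing the heavy atom).
    Heavy atoms with no non-H substituent are skipped with a warning.
    """
    import warnings

    if nucleus not in _NUCLEUS_HEAVY:
        raise ValueError(f"unsupported nucleus {nucleus!r} (use 13C1H or 15N1H)")
    heavy_el = _NUCLEUS_HEAVY[nucleus]
    adj = structure.adjacency()
    el = structure.elements
    probes: list[Probe] = []
    for ih, e in enumerate(el):
        if e != "H":
            continue
        for ic in adj[ih]:
            if el[ic] != heavy_el:
                continue
            hydrogens = [j for j in adj[ic] if el[j] == "H"]
            substituents = sorted(j for j in adj[ic] if el[j] != "H")
            if not substituents:
                warnings.warn(
                    f"probe at atom {ic + 1} skipped: no non-H substituent",
                    stacklevel=2,
                )
                continue
            kind = "CH2" if (heavy_el == "C" and len(hydrogens) == 2) else (
                "CH" if heavy_el == "C" else "NH"
            )
            probes.append(
                Probe(
                    kind=kind,
                    h_atom=ih,
                    heavy_atom=ic,
                    x_atom=substituents[0],
                    bond_length=bond_length,
                    delta_csa=delta_csa,
                )
            )
    return probes


# ---------------------------------------------------------------------------
# dipolar frame and Wigner functions
# ---------------------------------------------------------------------------

def dipolar_frame(h_pos, c_pos, x_pos):
    """Rotation matrix and ZYZ Euler angles of the dipolar frame.

    Z along the heavy-atom -> H bond, Y perpendicular to the H-C-X plane, X
    by the right-hand rule.  The returned matrix has the frame axes as
    columns (active rotation taking laboratory axes into the dipolar axes);
    Euler angles follow the intrinsic ZYZ convention.
    """
    h_pos, c_pos, x_pos = (np.asarray(p, float) for p in (h_pos, c_pos, x_pos))
    zax = h_pos - c_pos
    nz = np.linalg.norm(zax)
    if nz < 1e-12:
        raise GeometryError("H and heavy atom coincide")
    zax /= nz
    yax = np.cross(zax, x_pos - c_pos)
    ny = np.linalg.norm(yax)
    if ny < 1e-10 * max(np.linalg.norm(x_pos - c_pos), 1.0):
        raise GeometryError("H, heavy atom and substituent are collinear")
    yax /= ny
    xax = np.cross(yax, zax)
    M = np.column_stack([xax, yax, zax])
    alpha, beta, gamma = Rotation.from_matrix(M).as_euler("ZYZ")
    return M, np.array([alpha, beta, gamma])


def wigner_d2_00(omega) -> float:
    """D^2_00(Omega) = (3 cos^2 beta - 1)/2 (depends on beta only)."""
    beta = np.asarray(omega, float)[..., 1] if np.ndim(omega) else float(omega)
    c = np.cos(beta)
    return (3.0 * c * c - 1.0) / 2.0


def wigner_d2_0m(omega, m: int):
    """Rank-2 Wigner function D^2_{0m}(alpha, beta, gamma) (complex)."""
    if abs(m) > 2:
        raise ValueError("m must be in [-2, 2]")
    omega = np.asarray(omega, float)
    beta, gamma = omega[..., 1], omega[..., 2]
    c, s = np.cos(beta), np.sin(beta)
    if m == 0:
        d = (3.0 * c * c - 1.0) / 2.0
    elif abs(m) == 1:
        d = -np.sign(m) * math.sqrt(1.5) * s * c
    else:
        d = math.sqrt(3.0 / 8.0) * s * s
    return d * np.exp(-1j * m * gamma)


# ---------------------------------------------------------------------------
# autocorrelation
# ---------------------------------------------------------------------------

@dataclass
class Acf:
    """Rank-2 orientational autocorrelation function (factor-5 convention)."""

    lags: np.ndarray  # time lags, same units as the trajectory
    values: np.ndarray
    n_trajectories: int = 1

    def __post_init__(self):
        self.lags = np.asarray(self.lags, float)
        self.values = np.asarray(self.values, float)


def _acf_fft(x: np.ndarray, n_lags: int) -> np.ndarray:
    """All-origins autocorrelation <x(s) x(s+t)> via FFT."""
    n = x.size
    f = np.fft.rfft(x, 2 * n)
    c = np.fft.irfft(f * np.conj(f))[:n_lags]
    return c / (n - np.arange(n_lags))


def autocorrelation(
    d200_series: list[np.ndarray] | np.ndarray,
    dt: float,
    max_lags: int | None = None,
) -> Acf:
    """C(t) = 5 <D^2_00(t+s) D^2_00(s)>, averaged over time origins and
    trajectories.

    ``d200_series``: one array of D^2_00 values per trajectory, at equal
    time spacing ``dt``.  Lags are capped at half the (shortest) trajectory
    so every estimate averages at least half the available origins.
    """
    series = [np.asarray(d200_series, float)] if np.ndim(d200_series) == 1 else [
        np.asarray(s, float) for s in d200_series
    ]
    n_min = min(s.size for s in series)
    if n_min < 2:
        raise ValueError("need at least 2 snapshots per trajectory")
    n_lags = n_min // 2 + 1
    if max_lags is not None:
        n_lags = min(n_lags, max_lags)
    acc = np.zeros(n_lags)
    for s in series:
        acc += _acf_fft(s, n_lags)
    return Acf(
        lags=np.arange(n_lags) * dt,
        values=5.0 * acc / len(series),
        n_trajectories=len(series),
    )


def d200_from_quaternions(quaternions: np.ndarray) -> np.ndarray:
    """D^2_00 of the molecular frame orientation from scalar-first
    quaternions: (3 R_zz^2 - 1)/2 with R_zz = q0^2 - q1^2 - q2^2 + q3^2."""
    Q = np.asarray(quaternions, float)
    rzz = Q[:, 0] ** 2 - Q[:, 1] ** 2 - Q[:, 2] ** 2 + Q[:, 3] ** 2
    return 1.5 * rzz * rzz - 0.5


def acf_from_trajectories(trajectories, d200_fn=None, max_lags=None) -> Acf:
    """Ensemble ACF of D^2_00 from BD trajectories.

    ``d200_fn`` maps a trajectory to its D^2_00 time series; the default uses
    the orientation of the molecular frame itself (rigid-probe limit).
    """
    fn = d200_fn or (lambda tr: d200_from_quaternions(tr.quaternions))
    dt = float(trajectories[0].times[1] - trajectories[0].times[0])
    return autocorrelation([fn(tr) for tr in trajectories], dt, max_lags=max_lags)


# ---------------------------------------------------------------------------
# multiexponential fit
# ---------------------------------------------------------------------------

@dataclass
class MultiExpModel:
    """C(t) ~ sum_k a_k exp(-t/tau_k), a_k >= 0, tau_k > 0 (sorted
    descending in tau)."""

    weights: np.ndarray
    taus: np.ndarray
    residual: float = 0.0

    def __post_init__(self):
        order = np.argsort(self.taus)[::-1]
        self.weights = np.asarray(self.weights, float)[order]
        self.taus = np.asarray(self.taus, float)[order]

    def __call__(self, t):
        t = np.asarray(t, float)
        return np.sum(
            self.weights[:, None] * np.exp(-t[None, :] / self.taus[:, None]), axis=0
        )

    @property
    def c0(self) -> float:
        return float(np.sum(self.weights))


def multiexp_fit(
    acf: Acf, n_exp: int = 4, initial_taus: np.ndarray | None = None
) -> MultiExpModel:
    """Fit the ACF with ``n_exp`` decaying exponentials.

    Variable-projection least squares: the nonnegative weights are solved by
    NNLS at every iterate while log(tau) values are optimized by
    trust-region least squares, starting from logarithmically spaced time
    constants between the dump resolution and the trajectory length (or a
    user-supplied initial guess on failure).  Components closer than a
    relative 1e-6 in tau are merged.  Deterministic given the data and the
    initial guess.
    """
    if not 1 <= n_exp <= 5:
        raise ValueError("n_exp must be in [1, 5]")
    t = acf.lags
    y = acf.values
    if y[0] <= 0:
        raise ValueError("C(0) must be positive")
    t_res = max(t[1] - t[0], 1e-300)
    t_max = max(t[-1], t_res * 2)
    if initial_taus is None:
        initial_taus = np.geomspace(t_res, t_max, n_exp)
    lt0 = np.log(np.asarray(initial_taus, float))

    def _weights(ltaus):
        E = np.exp(-t[:, None] / np.exp(ltaus)[None, :])
        w, _ = nnls(E, y)
        return w, E

    def _resid(ltaus):
        w, E = _weights(ltaus)
        return E @ w - y

    lo = math.log(t_res) - math.log(10.0)
    hi = math.log(t_max) + math.log(100.0)
    sol = least_squares(
        _resid,
        np.clip(lt0, lo, hi),
        bounds=(lo, hi),
        xtol=1e-14,
        ftol=1e-14,
        gtol=1e-14,
    )
    if not sol.success:
        w, _ = _weights(sol.x)
        raise FitError(
            "multiexponential fit did not converge; supply a different "
            "initial guess via initial_taus",
            best=MultiExpModel(weights=w, taus=np.exp(sol.x)),
        )
    w, E = _weights(sol.x)
    taus = np.exp(sol.x)
    resid = float(np.sqrt(np.mean((E @ w - y) ** 2)))
    # merge components with coincident time constants
    order = np.argsort(taus)
    taus, w = taus[order], w[order]
    keep_t, keep_w = [taus[0]], [w[0]]
    for tau_k, w_k in zip(taus[1:], w[1:]):
        if abs(tau_k - keep_t[-1]) <= 1e-6 * keep_t[-1]:
            keep_w[-1] += w_k
        else:
            keep_t.append(tau_k)
            keep_w.append(w_k)
    return MultiExpModel(weights=np.array(keep_w), taus=np.array(keep_t), residual=resid)


# ---------------------------------------------------------------------------
# spectral density and relaxation
# ---------------------------------------------------------------------------

@dataclass
class SpectralDensityModel:
    """J(omega) = sum_k a_k 2 tau_k / (1 + omega^2 tau_k^2)."""

    weights: np.ndarray
    taus: np.ndarray

    def __call__(self, omega):
        omega = np.asarray(omega, float)
        a = self.weights[:, None]
        tau = self.taus[:, None]
        J = np.sum(a * 2.0 * tau / (1.0 + (omega.ravel()[None, :] * tau) ** 2), axis=0)
        return J.reshape(omega.shape) if omega.shape else float(J[0])

    @property
    def j0(self) -> float:
        return float(2.0 * np.sum(self.weights * self.taus))


def spectral_density(fit: MultiExpModel) -> SpectralDensityModel:
    """Cosine Fourier transform of the fitted multiexponential ACF."""
    return SpectralDensityModel(weights=fit.weights, taus=fit.taus)


@dataclass
class RelaxationResult:
    """T1, T2 (ms) and NOE per probe per 1H spectrometer frequency (MHz)."""

    probe: Probe
    fields_mhz: list[float]
    T1_ms: np.ndarray
    T2_ms: np.ndarray
    NOE: np.ndarray

    def to_frame(self):
        import pandas as pd

        return pd.DataFrame(
            {
                "probe": self.probe.label,
                "frequency_MHz": self.fields_mhz,
                "T1_ms": self.T1_ms,
                "T2_ms": self.T2_ms,
                "NOE": self.NOE,
            }
        )


def relaxation(
    J: SpectralDensityModel,
    probe: Probe,
    fields_mhz,
    nucleus: str = "13C1H",
) -> RelaxationResult:
    """T1, T2 and NOE from the spectral density (dipolar + optional CSA).

    With d = (mu0/4pi) gamma_H gamma_X hbar / r^3 and the C(0)=1 spectral
    density convention of this module:

        1/T1 = (d^2/20)[J(wH-wX) + 3 J(wX) + 6 J(wH+wX)] + c^2 J(wX)
        1/T2 = (d^2/40)[4 J(0) + J(wH-wX) + 3 J(wX) + 6 J(wH) + 6 J(wH+wX)]
               + (c^2/6)[4 J(0) + 3 J(wX)]
        NOE  = 1 + (gamma_H/gamma_X)(d^2/20)[6 J(wH+wX) - J(wH-wX)] T1

    with the axially symmetric CSA strength c^2 = (wX delta)^2/15 (zero when
    delta_csa = 0).
    """
    if nucleus not in _NUCLEUS_HEAVY:
        raise ValueError(f"unsupported nucleus {nucleus!r}")
    gamma_h = GAMMA["1H"]
    gamma_x = GAMMA["13C"] if nucleus == "13C1H" else GAMMA["15N"]
    r = probe.bond_length * 1e-10
    d = (MU0 / (4 * np.pi)) * gamma_h * gamma_x * HBAR / r**3
    d2 = d * d
    fields = np.atleast_1d(np.asarray(fields_mhz, float))
    if np.any(fields <= 0):
        raise ValueError("spectrometer frequencies must be positive")
    T1, T2, NOE = [], [], []
    for f in fields:
        wh = 2 * np.pi * f * 1e6
        wx = wh * gamma_x / gamma_h
        c2 = (wx * probe.delta_csa * 1e-6) ** 2 / 15.0
        j0 = J(0.0)
        jx = J(wx)
        jh = J(wh)
        jm = J(wh - wx)
        jp = J(wh + wx)
        r1 = (d2 / 20.0) * (jm + 3 * jx + 6 * jp) + c2 * jx
        r2 = (d2 / 40.0) * (4 * j0 + jm + 3 * jx + 6 * jh + 6 * jp) + (c2 / 6.0) * (
            4 * j0 + 3 * jx
        )
        t1 = 1.0 / r1
        noe = 1.0 + (gamma_h / gamma_x) * (d2 / 20.0) * (6 * jp - jm) * t1
        T1.append(t1 * 1e3)
        T2.append(1e3 / r2)
        NOE.append(noe)
    return RelaxationResult(
        probe=probe,
        fields_mhz=list(fields),
        T1_ms=np.array(T1),
        T2_ms=np.array(T2),
        NOE=np.array(NOE),
    )
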