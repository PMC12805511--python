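"""Pipeline orchestration: configuration parsing, stage execution, and
convergence diagnostics.

The run configuration is a whitespace-separated keyword file.  The core
keywords are::

    project      <name>            # base name of the Tinker XYZ input
    refAtoms     i j k [l]         # 1-based; first three define the frame,
                                   # an optional fourth is metadata only
    ff           <name>            # metadata (external minimization engine)
    grad         <value>           # metadata (external gradient tolerance)
    Reff         <angstrom>
    C            <4|6>
    viscosity    <Pa s>
    temperature  <K>
    seed         <int>
    nucleus      13C1H | 15N1H
    bondLength   <angstrom>
    deltaCSA     <ppm>
    frequency    <MHz> [<MHz> ...]
    calculate    T1 T2 NOE

plus the artifact extensions ``hessianFile`` (path to the Cartesian Hessian),
``scheme`` (runge_kutta | euler) and the schedule overrides ``lengthFactor``,
``nTrajectories``, ``nSnapshots`` and ``dt``.

Pipeline stages (each stage reads/writes serialized artifacts so it can be
re-run independently): (ii) diffusion tensors and the SFB model, (iii) BD
trajectories, (iv) correlation functions, spectral densities and relaxation
data.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from scipy.spatial.transform import Rotation
from scipy.stats import kstwo, norm

from . import __version__
from .constants import KB
from .errors import ConfigError
from .fixtures import FixtureSpec, make_fixture
from .hydrodynamics import HydroParams, hydro_diffusion_tensor
from .integrator import BDConfig, BDTrajectory, run_ensemble, run_trajectory
from .internal_coords import (
    ZMatrixDefinition,
    ZMatrixEntry,
    build_zmatrix,
    cartesian_to_zmatrix,
    coordinate_jacobian,
    hessian_to_curvature,
    zmatrix_to_cartesian,
)
from .internal_coords import _kabsch  # rigid superposition helper
from .model import (
    Schedule,
    SFBModel,
    assemble_diffusion,
    coupling_index,
    make_schedule,
    mode_spectrum,
    sandbox_model,
    SandboxParams,
)
from .nmr import (
    acf_from_trajectories,
    detect_probes,
    multiexp_fit,
    relaxation,
    spectral_density,
)
from .structure import CartesianStructure, read_hessian, read_tinker_xyz, write_hessian, write_tinker_xyz

__all__ = [
    "RunConfig",
    "parse_config",
    "run_pipeline",
    "prepare_model",
    "run_bd_stage",
    "analyze_stage",
    "convergence_report",
    "run_length_study",
    "probe_d200_series",
    "save_model",
    "load_model",
    "save_trajectories",
    "load_trajectories",
]

_REQUIRED = [
    "project",
    "refAtoms",
    "Reff",
    "C",
    "viscosity",
    "temperature",
    "seed",
    "nucleus",
    "bondLength",
    "deltaCSA",
    "frequency",
    "calculate",
]
_OPTIONAL = [
    "ff",
    "grad",
    "hessianFile",
    "scheme",
    "lengthFactor",
    "nTrajectories",
    "nSnapshots",
    "dt",
]


@dataclass
class RunConfig:
    project: str
    ref_atoms: tuple[int, ...]  # 0-based
    reff: float
    c_coeff: float
    viscosity: float
    temperature: float
    seed: int
    nucleus: str
    bond_length: float
    delta_csa: float
    frequencies: list[float]
    calculate: list[str]
    ff: str | None = None
    grad: float | None = None
    hessian_file: str | None = None
    scheme: str = "runge_kutta"
    length_factor: float = 1000.0
    n_trajectories: int = 20
    n_snapshots: int = 10_000
    dt: float | None = None

    @property
    def kBT(self) -> float:
        return KB * self.temperature

    def hydro_params(self) -> HydroParams:
        return HydroParams(
            R_eff=self.reff, C=self.c_coeff, eta=self.viscosity, T=self.temperature
        )


def parse_config(text: str) -> RunConfig:
    """Parse a keyword configuration (order-free lines; '#' comments)."""
    values: dict[str, list[str]] = {}
    for lineno, raw in enumerate(text.splitlines(), start=1):
        line = raw.split("#", 1)[0].strip()
        if not line:
            continue
        parts = line.split()
        key = parts[0]
        if key not in _REQUIRED and key not in _OPTIONAL:
            raise ConfigError(f"line {lineno}: unknown keyword {key!r}")
        if key in values:
            raise ConfigError(f"line {lineno}: duplicate keyword {key!r}")
        if len(parts) < 2:
            raise ConfigError(f"line {lineno}: keyword {key!r} has no value")
        values[key] = parts[1:]
    for key in _REQUIRED:
        if key not in values:
            raise ConfigError(f"missing required keyword {key!r}")

    def _one(key, cast, default=None):
        if key not in values:
            return default
        try:
            return cast(values[key][0])
        except ValueError as exc:
            raise ConfigError(f"keyword {key!r}: malformed value {values[key][0]!r}") from exc

    ref = values["refAtoms"]
    if len(ref) not in (3, 4):
        raise ConfigError("refAtoms must list 3 or 4 atom indices")
    try:
        ref_atoms = tuple(int(a) - 1 for a in ref)
    except ValueError as exc:
        raise ConfigError(f"refAtoms: malformed value {ref!r}") from exc
    try:
        freqs = [float(v) for v in values["frequency"]]
    except ValueError as exc:
        raise ConfigError(f"frequency: malformed value {values['frequency']!r}") from exc
    calc = [v.upper() for v in values["calculate"]]
    bad = set(calc) - {"T1", "T2", "NOE"}
    if bad:
        raise ConfigError(f"calculate: unknown observable(s) {sorted(bad)}")
    scheme = _one("scheme", str, "runge_kutta")
    if scheme not in ("runge_kutta", "euler"):
        raise ConfigError(f"scheme must be runge_kutta or euler, got {scheme!r}")
    return RunConfig(
        project=values["project"][0],
        ref_atoms=ref_atoms,
        reff=_one("Reff", float),
        c_coeff=_one("C", float),
        viscosity=_one("viscosity", float),
        temperature=_one("temperature", float),
        seed=_one("seed", int),
        nucleus=values["nucleus"][0],
        bond_length=_one("bondLength", float),
        delta_csa=_one("deltaCSA", float),
        frequencies=freqs,
        calculate=calc,
        ff=_one("ff", str),
        grad=_one("grad", float),
        hessian_file=_one("hessianFile", str),
        scheme=scheme,
        length_factor=_one("lengthFactor", float, 1000.0),
        n_trajectories=_one("nTrajectories", int, 20),
        n_snapshots=_one("nSnapshots", int, 10_000),
        dt=_one("dt", float, None),
    )


# ---------------------------------------------------------------------------
# serialization
# ---------------------------------------------------------------------------

def save_model(model: SFBModel, path) -> None:
    import h5py

    with h5py.File(path, "w") as fh:
        fh.attrs["kBT"] = model.kBT
        fh.attrs["version"] = __version__
        for name in ("D", "E", "T", "K_sqrt"):
            fh.create_dataset(name, data=getattr(model, name))
        if model.q0 is not None:
            fh.create_dataset("q0", data=model.q0)
        if model.zdef is not None:
            ent = np.array(
                [
                    [
                        e.atom,
                        -1 if e.dist_ref is None else e.dist_ref,
                        -1 if e.angle_ref is None else e.angle_ref,
                        -1 if e.dihedral_ref is None else e.dihedral_ref,
                    ]
                    for e in model.zdef.entries
                ],
                dtype=np.int64,
            )
            fh.create_dataset("zmatrix", data=ent)


def load_model(path) -> SFBModel:
    import h5py

    with h5py.File(path, "r") as fh:
        kw = {name: np.asarray(fh[name]) for name in ("D", "E", "T", "K_sqrt")}
        q0 = np.asarray(fh["q0"]) if "q0" in fh else None
        zdef = None
        if "zmatrix" in fh:
            ent = np.asarray(fh["zmatrix"])
            zdef = ZMatrixDefinition(
                entries=[
                    ZMatrixEntry(
                        int(a),
                        None if d < 0 else int(d),
                        None if an < 0 else int(an),
                        None if dh < 0 else int(dh),
                    )
                    for a, d, an, dh in ent
                ]
            )
        return SFBModel(q0=q0, kBT=float(fh.attrs["kBT"]), zdef=zdef, **kw)


def save_trajectories(trajectories: list[BDTrajectory], path) -> None:
    import h5py

    with h5py.File(path, "w") as fh:
        fh.attrs["n_trajectories"] = len(trajectories)
        for i, tr in enumerate(trajectories):
            g = fh.create_group(f"traj{i:03d}")
            g.attrs["seed"] = tr.seed
            g.attrs["dt"] = tr.schedule.dt
            g.attrs["dump_stride"] = tr.schedule.dump_stride
            g.attrs["scheme"] = tr.schedule.scheme
            g.attrs["n_steps"] = tr.schedule.n_steps
            g.create_dataset("times", data=tr.times)
            g.create_dataset("quaternions", data=tr.quaternions)
            g.create_dataset("z", data=tr.z)


def load_trajectories(path) -> list[BDTrajectory]:
    import h5py

    out = []
    with h5py.File(path, "r") as fh:
        for name in sorted(fh):
            g = fh[name]
            sched = Schedule(
                dt=float(g.attrs["dt"]),
                n_steps=int(g.attrs["n_steps"]),
                dump_stride=int(g.attrs["dump_stride"]),
                scheme=str(g.attrs["scheme"]),
            )
            out.append(
                BDTrajectory(
                    times=np.asarray(g["times"]),
                    quaternions=np.asarray(g["quaternions"]),
                    z=np.asarray(g["z"]),
                    seed=int(g.attrs["seed"]),
                    schedule=sched,
                )
            )
    return out


# ---------------------------------------------------------------------------
# stages
# ---------------------------------------------------------------------------

@dataclass
class PipelineResult:
    model: SFBModel
    spectrum: object
    schedule: Schedule
    trajectories: list[BDTrajectory]
    acf: dict
    fits: dict
    relaxation: pd.DataFrame
    files: dict = field(default_factory=dict)


def prepare_model(
    config: RunConfig, structure: CartesianStructure, hessian: np.ndarray
) -> SFBModel:
    """Stage (ii): hydrodynamic tensor + curvature -> assembled SFB model."""
    zdef = build_zmatrix(structure, ref_atoms=config.ref_atoms)
    q0 = cartesian_to_zmatrix(zdef, structure)
    d_hydro = hydro_diffusion_tensor(structure, zdef, config.hydro_params())
    B = coordinate_jacobian(zdef, q0, frame=structure)
    K = hessian_to_curvature(hessian, B)
    return assemble_diffusion(d_hydro, K, config.kBT, q0=q0, zdef=zdef)


def run_bd_stage(model: SFBModel, config: RunConfig) -> tuple[Schedule, list[BDTrajectory]]:
    """Stage (iii): BD trajectory ensemble from the automatic schedule."""
    spec = mode_spectrum(model)
    sched = make_schedule(
        spec,
        scheme=config.scheme,
        dt=config.dt,
        length_factor=config.length_factor,
        n_snapshots=config.n_snapshots,
        n_trajectories=config.n_trajectories,
    )
    return sched, run_ensemble(model, BDConfig(schedule=sched, seed=config.seed))


def _body_frame_map(model: SFBModel, structure: CartesianStructure):
    """Fixed rotation taking placement-frame coordinates into the frame that
    diagonalizes the rotational diffusion block."""
    q0 = model.q0
    X_pl = zmatrix_to_cartesian(model.zdef, q0)
    R0 = _kabsch(structure.coords, X_pl)  # placement -> input frame
    return model.E.T @ R0


def probe_d200_series(
    model: SFBModel,
    structure: CartesianStructure,
    trajectories: list[BDTrajectory],
    probe,
) -> list[np.ndarray]:
    """D^2_00 of the probe's dipolar frame, per trajectory.

    For every dump the internal coordinates are recovered from z, the
    Cartesian geometry rebuilt, mapped into the rotational eigenframe, and
    rotated into the laboratory frame by the trajectory quaternion.  Only the
    H-heavy bond direction enters D^2_00 (cylindrical symmetry of the dipolar
    interaction).
    """
    F = _body_frame_map(model, structure)
    # linear map z -> q: q = q0 + K^{-1/2} T sqrt(kBT) z
    lin = np.linalg.solve(model.K_sqrt, model.T) * math.sqrt(model.kBT)
    out = []
    for tr in trajectories:
        n = tr.n_dumps
        u_mf = np.empty((n, 3))
        for i in range(n):
            q = model.q0 + lin @ tr.z[i]
            X = zmatrix_to_cartesian(model.zdef, q)
            u_mf[i] = F @ (X[probe.h_atom] - X[probe.heavy_atom])
        # scalar-first -> scalar-last for scipy
        rot = Rotation.from_quat(tr.quaternions[:, [1, 2, 3, 0]])
        u_lab = rot.apply(u_mf)
        u_lab /= np.linalg.norm(u_lab, axis=1)[:, None]
        out.append(1.5 * u_lab[:, 2] ** 2 - 0.5)
    return out


def analyze_stage(
    model: SFBModel,
    structure: CartesianStructure,
    trajectories: list[BDTrajectory],
    config: RunConfig,
    n_exp: int = 4,
):
    """Stage (iv): probes -> ACF -> multiexponential fit -> J -> relaxation."""
    probes = detect_probes(
        structure,
        nucleus=config.nucleus,
        bond_length=config.bond_length,
        delta_csa=config.delta_csa,
    )
    if not probes:
        raise ConfigError(f"no {config.nucleus} probes found in the structure")
    dt = float(trajectories[0].times[1] - trajectories[0].times[0])
    acfs, fits, rows = {}, {}, []
    from .nmr import autocorrelation

    for probe in probes:
        series = probe_d200_series(model, structure, trajectories, probe)
        acf = autocorrelation(series, dt)
        fit = multiexp_fit(acf, n_exp=n_exp)
        J = spectral_density(fit)
        res = relaxation(J, probe, config.frequencies, nucleus=config.nucleus)
        acfs[probe.label] = acf
        fits[probe.label] = fit
        frame = res.to_frame()
        rows.append(frame)
    report = pd.concat(rows, ignore_index=True)
    keep = ["probe", "frequency_MHz"] + [
        {"T1": "T1_ms", "T2": "T2_ms", "NOE": "NOE"}[c] for c in config.calculate
    ]
    return acfs, fits, report[keep]


def run_pipeline(
    config: RunConfig,
    structure: CartesianStructure,
    hessian: np.ndarray,
    outdir=None,
) -> PipelineResult:
    """Full pipeline: model -> BD ensemble -> NMR relaxation report.

    With ``outdir`` every stage's artifacts are serialized (HDF5 model and
    trajectories, TSV spectrum/ACF/fit/relaxation tables, JSON manifest) so
    stages can be re-run independently; re-running with the same
    configuration reproduces the outputs exactly (seeded).
    """
    model = prepare_model(config, structure, hessian)
    spec = mode_spectrum(model)
    sched, trajectories = run_bd_stage(model, config)
    acfs, fits, report = analyze_stage(model, structure, trajectories, config)
    files = {}
    if outdir is not None:
        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        save_model(model, outdir / "model.h5")
        save_trajectories(trajectories, outdir / "trajectories.h5")
        spec_df = pd.DataFrame({"omega_per_s": spec.omegas})
        ci = coupling_index(model)
        ci_df = pd.DataFrame(
            {"mode": np.arange(1, ci.size + 1), "coupling_index": ci}
        )
        spec_df.to_csv(outdir / "spectrum.tsv", sep="\t", index=False)
        ci_df.to_csv(outdir / "coupling_index.tsv", sep="\t", index=False)
        for label, acf in acfs.items():
            safe = label.replace(":", "_").replace("-", "_")
            pd.DataFrame({"lag_s": acf.lags, "C": acf.values}).to_csv(
                outdir / f"acf_{safe}.tsv", sep="\t", index=False
            )
            fit = fits[label]
            pd.DataFrame({"weight": fit.weights, "tau_s": fit.taus}).to_csv(
                outdir / f"fit_{safe}.tsv", sep="\t", index=False
            )
        report.to_csv(outdir / "relaxation.tsv", sep="\t", index=False, float_format="%.6g")
        manifest = {
            "version": __version__,
            "seed": config.seed,
            "scheme": sched.scheme,
            "dt": sched.dt,
            "n_steps": sched.n_steps,
            "dump_stride": sched.dump_stride,
            "n_trajectories": sched.n_trajectories,
            "probes": list(acfs),
            "frequencies_MHz": config.frequencies,
        }
        (outdir / "manifest.json").write_text(json.dumps(manifest, indent=2))
        files = {p.name: str(p) for p in outdir.iterdir()}
    return PipelineResult(
        model=model,
        spectrum=spec,
        schedule=sched,
        trajectories=trajectories,
        acf=acfs,
        fits=fits,
        relaxation=report,
        files=files,
    )


# ---------------------------------------------------------------------------
# convergence diagnostics
# ---------------------------------------------------------------------------

def _euler_angles(quaternions: np.ndarray) -> np.ndarray:
    """ZYZ Euler angles (alpha, beta, gamma) from scalar-first quaternions."""
    rot = Rotation.from_quat(np.asarray(quaternions)[:, [1, 2, 3, 0]])
    return rot.as_euler("ZYZ")


def convergence_report(
    trajectories: list[BDTrajectory],
    model: SFBModel,
    alpha_level: float = 0.01,
    min_neff: int = 25,
) -> pd.DataFrame:
    """Histogram convergence diagnostics for a BD run.

    At equilibrium the Euler angles alpha and gamma are uniform on [-pi, pi],
    cos(beta) is uniform on [-1, 1] and every z_i is standard normal.  Each
    coordinate's empirical distribution is tested with a Kolmogorov-Smirnov
    statistic evaluated at the number of *effective* samples the run affords,
    n_eff = min(n_samples, T_total * omega_rel / 2), where omega_rel is the
    model's own relaxation rate for that coordinate (the slowest eigenvalue
    of D for orientation, the diagonal D entry for each z).  A coordinate
    passes only if n_eff >= ``min_neff`` (a shorter run cannot demonstrate
    convergence) and the KS test does not reject at ``alpha_level``.
    """
    spec = mode_spectrum(model)
    t_total = sum(tr.times[-1] for tr in trajectories)
    euler = np.concatenate([_euler_angles(tr.quaternions) for tr in trajectories])
    zs = np.concatenate([tr.z for tr in trajectories])
    ns = model.n_internal

    def _uniform_cdf(lo, hi):
        return lambda x: np.clip((x - lo) / (hi - lo), 0.0, 1.0)

    checks = [
        ("alpha", euler[:, 0], _uniform_cdf(-np.pi, np.pi), spec.omega_min),
        ("cos_beta", np.cos(euler[:, 1]), _uniform_cdf(-1.0, 1.0), spec.omega_min),
        ("gamma", euler[:, 2], _uniform_cdf(-np.pi, np.pi), spec.omega_min),
    ]
    for i in range(ns):
        checks.append((f"z{i + 1}", zs[:, i], norm.cdf, model.D[3 + i, 3 + i]))

    rows = []
    for name, samples, cdf, omega in checks:
        n = samples.size
        x = np.sort(samples)
        ecdf = np.arange(1, n + 1) / n
        tc = cdf(x)
        stat = float(max(np.max(ecdf - tc), np.max(tc - (ecdf - 1.0 / n))))
        n_eff = min(n, t_total * omega / 2.0)
        n_eff_i = max(int(n_eff), 1)
        pvalue = float(kstwo.sf(stat, n_eff_i))
        passed = (n_eff >= min_neff) and (pvalue > alpha_level)
        rows.append(
            {
                "coordinate": name,
                "ks_stat": stat,
                "n_eff": n_eff,
                "p_value": pvalue,
                "converged": bool(passed),
            }
        )
    return pd.DataFrame(rows)


def run_length_study(
    params: SandboxParams,
    alphas=(1, 10, 100, 1000),
    seed: int = 123456789,
    n_snapshots: int = 10_000,
):
    """ACF of D^2_00 from sandbox runs of total length alpha * tau.

    Longer runs show progressively smaller tail noise in the correlation
    function; returns {alpha: (Acf, BDTrajectory)}.
    """
    model = sandbox_model(params)
    spec = mode_spectrum(model)
    out = {}
    for a in alphas:
        sched = make_schedule(
            spec,
            scheme="runge_kutta",
            length_factor=float(a),
            n_snapshots=n_snapshots,
            n_trajectories=1,
        )
        traj = run_trajectory(model, BDConfig(schedule=sched, seed=seed))
        acf = acf_from_trajectories([traj])
        out[a] = (acf, traj)
    return out


def write_fixture(spec: FixtureSpec, outdir, name: str = "toy") -> dict:
    """Materialize a synthetic fixture: XYZ + Hessian + ground-truth sidecar."""
    fx = make_fixture(spec)
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    xyz = outdir / f"{name}.xyz"
    hess = outdir / f"{name}.hess"
    side = outdir / f"{name}_truth.json"
    write_tinker_xyz(fx.structure, xyz)
    write_hessian(fx.hessian, hess)
    side.write_text(json.dumps(fx.sidecar, indent=2))
    return {"xyz": str(xyz), "hessian": str(hess), "sidecar": str(side)}


def load_inputs(config: RunConfig, basedir="."):
    """Resolve the XYZ and Hessian files named by a configuration."""
    basedir = Path(basedir)
    xyz = basedir / f"{config.project}.xyz"
    if not xyz.exists():
        raise ConfigError(f"structure file {xyz} not found")
    structure = read_tinker_xyz(xyz)
    if config.hessian_file is None:
        raise ConfigError("hessianFile keyword is required to build the model")
    hpath = Path(config.hessian_file)
    if not hpath.is_absolute():
        hpath = basedir / hpath
    hessian = read_hessian(hpath)
    return structure, hessian
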