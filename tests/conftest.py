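import numpy as np
import pytest

from sfbd import (
    BDConfig,
    FixtureSpec,
    SandboxParams,
    Schedule,
    SFBModel,
    make_fixture,
    make_schedule,
    mode_spectrum,
    run_ensemble,
    run_trajectory,
    sandbox_model,
)

MASTER_SEED = 123456789  # reference seed of the shipped configuration


@pytest.fixture(scope="session")
def toy_fixture():
    """H-C-C-H synthetic molecule with known internal force constants."""
    return make_fixture(FixtureSpec(n_heavy=2))


@pytest.fixture(scope="session")
def sandbox_c1k10():
    return sandbox_model(SandboxParams(c=1.0, k=10.0))


@pytest.fixture(scope="session")
def sandbox_long_run(sandbox_c1k10):
    """Single 1000-tau Runge-Kutta sandbox trajectory (c=1, k=10)."""
    spec = mode_spectrum(sandbox_c1k10)
    sched = make_schedule(spec, length_factor=1000.0, n_trajectories=1)
    return run_trajectory(sandbox_c1k10, BDConfig(schedule=sched, seed=MASTER_SEED))


@pytest.fixture(scope="session")
def rotor_model():
    """Rigid isotropic rotor, D_R = 1 (dimensionless units)."""
    return SFBModel(
        D=np.eye(3),
        E=np.eye(3),
        T=np.zeros((0, 0)),
        K_sqrt=np.zeros((0, 0)),
        kBT=1.0,
    )


@pytest.fixture(scope="session")
def rotor_ensemble(rotor_model):
    """20 seeded rotor trajectories of length 1000/(6 D_R).

    dt = 0.01/D_R resolves the rank-2 decay (correlation time 1/6) well below
    the stability bound; every dump is kept.
    """
    sched = Schedule(
        dt=0.01, n_steps=16700, dump_stride=1, scheme="runge_kutta", n_trajectories=20
    )
    return run_ensemble(rotor_model, BDConfig(schedule=sched, seed=MASTER_SEED))
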