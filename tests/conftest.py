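import numpy as np
import pytest

from sffc.arm import ArmParams, NoiseParams
from sffc import planner as pl

# reference reaching task: 7.4 cm N-W reach from q = (50, 100) deg with
# sigma = 0.005, d = 0.01, r = 2000, alpha = 0.02
REF_NOISE = dict(sigma=0.005, d=0.01)
REF_COST = dict(r=2000.0, alpha=0.02)


def make_nw_spec(**overrides) -> pl.OCPSpec:
    params = overrides.pop("params", ArmParams())
    x0, target = pl.make_task([50.0, 100.0], 135.0, 0.074, params)
    kw = dict(r=REF_COST["r"], alpha=REF_COST["alpha"], params=params,
              noise=NoiseParams.symmetric(**REF_NOISE))
    kw.update(overrides)
    return pl.OCPSpec(x0=x0, target=target, **kw)


# scaled-down transcription for structural tests (documented problem sizes)
COARSE = dict(n_controls=13, n_steps=60)


@pytest.fixture(scope="session")
def nw_spec():
    return make_nw_spec()


@pytest.fixture(scope="session")
def nw_spec_coarse():
    return make_nw_spec(**COARSE)


@pytest.fixture(scope="session")
def free_plan(nw_spec):
    """Free-final-time plan of the reference task at default resolution."""
    return pl.solve_free_time(nw_spec, T_guess=1.1)


@pytest.fixture(scope="session")
def free_plan_coarse(nw_spec_coarse):
    return pl.solve_free_time(nw_spec_coarse, T_guess=1.1)


@pytest.fixture()
def rng():
    return np.random.default_rng(12345)
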