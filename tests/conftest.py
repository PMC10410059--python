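import warnings

import numpy as np
import pytest
from hypothesis import settings

import psen1traj as pt
from psen1traj.synthetic_cohort import OUTCOMES

settings.register_profile("repeatable", derandomize=True)
settings.load_profile("repeatable")


def noiseless_config(**overrides) -> pt.SimConfig:
    """A cohort with every noise source switched off: observations must equal
    the group mean curves exactly."""
    zeros = {k: 0.0 for k in OUTCOMES}
    base = dict(
        n_per_group={"NC": 20, "CY": 15, "TM": 15},
        sigma_family=dict(zeros),
        sigma_subject=dict(zeros),
        sigma_resid=dict(zeros),
        covariate_effects={},
        lr_asym_sd=0.0,
        suvr_region_sd=0.0,
        seed=7,
    )
    base.update(overrides)
    return pt.SimConfig(**base)


@pytest.fixture(scope="session")
def demo_cohort():
    cfg = pt.SimConfig(n_per_group={"NC": 60, "CY": 40, "TM": 60}, seed=42)
    return pt.simulate_cohort(cfg)


@pytest.fixture(scope="session")
def prepared(demo_cohort):
    return pt.assemble(demo_cohort[0])


@pytest.fixture(scope="session")
def mmse_fit_rcs(prepared):
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        return pt.fit_lmem(prepared, pt.ModelSpec("mmse", eyo_form="rcs"))


@pytest.fixture(scope="session")
def mmse_posterior(prepared):
    return pt.sample_posterior(
        prepared, pt.ModelSpec("mmse"), n_draws=2000, seed=11
    )


@pytest.fixture
def rng():
    return np.random.default_rng(20240917)
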