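import numpy as np
import pytest

from otpred.alphabet import PositionConvention
from otpred.priors import build_drics_init, build_mtp_init, normalize_drics
from otpred.simdata import SyntheticSpec, gen_dataset, gen_prior_table


@pytest.fixture(scope="session")
def conv() -> PositionConvention:
    return PositionConvention()


@pytest.fixture(scope="session")
def mtp_prior(conv):
    return build_mtp_init(gen_prior_table("MTP", seed=101), conv)


@pytest.fixture(scope="session")
def drics_prior(conv):
    return normalize_drics(build_drics_init(gen_prior_table("DRICS", seed=102), conv))


@pytest.fixture(scope="session")
def tiny_dataset():
    """Small planted-effect dataset shared by the training-level tests."""
    spec = SyntheticSpec(
        n_guides=6, sites_per_guide=300, target_prevalence=0.05, seed=7
    )
    return gen_dataset(spec)


@pytest.fixture(scope="session")
def rng() -> np.random.Generator:
    return np.random.default_rng(20240901)
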