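import numpy as np
import pytest

from wmarc.likelihood import LikelihoodConfig
from wmarc.observer import ModelSpec, ObserverParams
from wmarc.simulate import ExperimentDesign, simulate_dataset


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture(scope="session")
def base_params():
    return ObserverParams(gamma_mean=8.0, gamma_scale=2.0, est_exponent=1.5,
                          softmax_temp=5.0, risk_alpha=1.0, lapse_rate=0.05,
                          kappa_fixed=8.0, kappa_threshold=2.0, kappa_w=0.8,
                          kappa_const=8.0)


@pytest.fixture(scope="session")
def fast_config():
    return LikelihoodConfig.fast()


@pytest.fixture(scope="session")
def known_uniform_table(base_params):
    """Small synthetic dataset from the Known model, 3 participants."""
    design = ExperimentDesign(n_participants=3, trials_uniform=240,
                              trials_von_mises=0, seed=42)
    table = simulate_dataset(design, base_params, ModelSpec("known", "uniform_only"))
    return table


@pytest.fixture(scope="session")
def yy_joint_table(base_params):
    """Joint uniform + von Mises dataset from the Known-YY model."""
    design = ExperimentDesign(n_participants=3, trials_uniform=200,
                              trials_von_mises=200, seed=43)
    return simulate_dataset(design, base_params, ModelSpec("known", "YY"))
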