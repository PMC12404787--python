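import warnings

import numpy as np
import pytest

from fovadapt.curves import MeasureFamily
from fovadapt.inference import SamplerConfig, build_model, sample_posterior
from fovadapt.simulate import default_measure_truths, draw_measures

warnings.filterwarnings("ignore", category=FutureWarning)


@pytest.fixture
def rng():
    return np.random.default_rng(20240915)


@pytest.fixture(scope="session")
def measure_truths():
    return default_measure_truths()


@pytest.fixture(scope="session")
def small_success_obs(measure_truths):
    """A compact success-count cohort (5 fish x 10 sessions)."""
    obs, truth, _ = draw_measures(
        measure_truths[MeasureFamily.SUCCESS_POISSON], n_fish=5, n_sessions=10, seed=11
    )
    return obs, truth


@pytest.fixture(scope="session")
def small_success_fit(small_success_obs):
    """One reduced-budget posterior fit shared across read-only tests."""
    obs, _ = small_success_obs
    model = build_model(obs, MeasureFamily.SUCCESS_POISSON)
    fit = sample_posterior(
        model, SamplerConfig(chains=2, tune=600, draws=500, seed=3, thin=2), stage="rotation"
    )
    return model, fit
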