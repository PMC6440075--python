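import numpy as np
import pytest

from tempmort.fit import ModelSpec, fit_model
from tempmort.synthetic import SurfaceParams, TruthScenario, generate_region


@pytest.fixture(scope="session")
def scenario():
    """Default-sized truth with a clear cold effect, small enough for fast fits."""
    return TruthScenario(
        n_days=1460,
        surface_params=SurfaceParams(cold_log_rr=0.6, heat_log_rr=0.1, lag_decay=4.0),
        seed=42,
    )


@pytest.fixture(scope="session")
def region(scenario):
    return generate_region(scenario)


@pytest.fixture(scope="session")
def fitted(region, scenario):
    """Default (quadratic x quadratic, 8 df/yr) fit, reference at the truth's."""
    return fit_model(region, ModelSpec(), reference_temp=scenario.reference_temp)


@pytest.fixture()
def rng():
    return np.random.default_rng(12345)
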