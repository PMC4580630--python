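import numpy as np
import pytest

import txdeter as td


@pytest.fixture(scope="session")
def null_panel():
    """Panel generated under the clean null: homicide dynamics + trend only,
    every covariate effect zero, so the execution transfer-function model
    matches the generating process exactly."""
    cfg = td.SyntheticConfig(
        seed=5, trend=-0.29, beta_exec=(0.0, 0.0), beta_prisoners=0.0, beta_unemp=0.0
    )
    return td.generate_panel(cfg)


@pytest.fixture(scope="session")
def tf1_null_fit(null_panel):
    """Execution transfer-function model fitted once on the null panel."""
    return td.fit(
        null_panel.homicides, td.MODEL_PRESETS["tf1"], exog=null_panel.as_dict()
    )


@pytest.fixture(scope="session")
def default_panel():
    """Panel at the default (covariate-effect) configuration."""
    return td.generate_panel(td.SyntheticConfig(seed=20240909))


@pytest.fixture()
def rng():
    return np.random.default_rng(12345)
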