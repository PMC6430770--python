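import numpy as np
import pytest

import spatialflux as sf


@pytest.fixture(scope="session")
def default_cfg():
    return sf.default_synthetic_config(seed=1)


@pytest.fixture(scope="session")
def noiseless_cfg():
    return sf.default_synthetic_config(seed=1, noise_sd_mid=0.0, noise_cv=0.0)


@pytest.fixture(scope="session")
def noiseless_study(noiseless_cfg):
    """Truth, measurements and exact labeling for a noise-free study."""
    truth, meas, true_lab = sf.generate_dataset(noiseless_cfg)
    return truth, meas, true_lab


@pytest.fixture(scope="session")
def model_setup(default_cfg):
    """Model config and true forcings for simulator-level tests."""
    forcings = sf.generate_forcings(default_cfg)
    return default_cfg.model_config(), forcings


def random_feasible_fluxes(rng, cfg=None):
    """Uniform random flux vector projected onto the citrate mass balances."""
    from spatialflux.kfp import _random_feasible_start

    if cfg is None:
        cfg = sf.ModelConfig(u_cit_mito=0.12, u_cit_cyto=0.35)
    return _random_feasible_start(rng, cfg)
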