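import numpy as np
import pytest

import gutfuse as gf


@pytest.fixture(scope="session")
def strong_cohort():
    """One strong-signal cohort (fold 3, low noise) shared across tests."""
    cfg = gf.CohortConfig(seed=11, noise_sigma=0.3)
    genus, metab, meta, truth = gf.generate_cohort(cfg)
    return cfg, genus, metab, meta, truth


@pytest.fixture(scope="session")
def strong_models(strong_cohort):
    _, genus, metab, meta, _ = strong_cohort
    gm = gf.fit_channel_model(genus, meta)
    mm = gf.fit_channel_model(metab, meta)
    return gm, mm


@pytest.fixture()
def rng():
    return np.random.default_rng(12345)
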