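import numpy as np
import pytest

import gaitadapt as ga


@pytest.fixture()
def rng():
    return np.random.default_rng(1234)


@pytest.fixture(scope="session")
def small_cohort():
    """Short study-like cohort (3 groups x 6 x 120 steps, jump at 61)."""
    cfg = ga.SynthConfig(seed=11, T=120, n_per_group=6, jump_step=61)
    trials, truth = ga.generate_cohort(cfg)
    return cfg, trials, truth


@pytest.fixture(scope="session")
def study_like_cohort():
    """Full-size default cohort (3 x 11 x 500, jump at 251)."""
    cfg = ga.SynthConfig(seed=5)
    trials, truth = ga.generate_cohort(cfg)
    return cfg, trials, truth
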