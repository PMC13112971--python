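import numpy as np
import pytest

from gripcurve import AnalysisConfig, GeneratorConfig, HandgripAnalysis


@pytest.fixture(scope="session")
def small_cohort_results():
    """A small fitted cohort shared by tests that only read from it."""
    gen = GeneratorConfig(n_per_group={"F": 6, "M": 5}, seed=11)
    ana = AnalysisConfig(n_perm=300, seed=11)
    return HandgripAnalysis.from_simulation(gen, ana).fit()


@pytest.fixture()
def rng():
    return np.random.default_rng(1234)


def noiseless_config(**kw) -> GeneratorConfig:
    """Generator config with every random component switched off."""
    base = dict(
        n_per_group={"F": 2, "M": 2},
        amp_cv=0.0,
        tau_cv=0.0,
        decay_cv=0.0,
        trial_amp_jitter_cv=0.0,
        trial_onset_jitter_sd=0.0,
        noise_sd=0.0,
        seed=0,
    )
    base.update(kw)
    return GeneratorConfig(**base)


@pytest.fixture()
def noiseless_cfg_factory():
    return noiseless_config
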