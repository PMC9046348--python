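import numpy as np
import pytest

from trajmix import gmm, synth


@pytest.fixture(scope="session")
def default_cfg():
    return synth.GeneratorConfig()


@pytest.fixture(scope="session")
def small_cohort():
    """A mid-sized cohort with dropout, reused across read-only tests."""
    cfg = synth.GeneratorConfig(n_participants=300, seed=42)
    return synth.generate(cfg)


@pytest.fixture(scope="session")
def clean_cohort():
    """No-missingness cohort for tests that need complete panels."""
    cfg = synth.GeneratorConfig(
        n_participants=600,
        seed=7,
        missingness_model=synth.MissingnessModel(enabled=False),
    )
    return synth.generate(cfg)


@pytest.fixture(scope="session")
def clean_panel(clean_cohort):
    return gmm.VisitPanel(clean_cohort.panel())


@pytest.fixture(scope="session")
def norm_sample(default_cfg):
    return synth.generate_norm_sample(default_cfg, n=4000, seed=11)


@pytest.fixture(scope="session")
def norm_models(norm_sample):
    from trajmix.norming import fit_all_norms

    return fit_all_norms(norm_sample)


@pytest.fixture
def rng():
    # function-scoped so statistical tests are order-independent
    return np.random.default_rng(20260921)
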