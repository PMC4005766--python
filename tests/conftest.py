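import numpy as np
import pytest

from hr2ee import GeneratorConfig, VarianceComponents, simulate_cohort

#: Reference fixed effects of the continuous-age model
#: (intercept, hr, male, age, age*hr).
M2_FIXED = (-23.046, 0.339, 2.241, 0.099, -0.0007)
#: Reference variance components of the continuous-age model.
M2_VC = VarianceComponents(sd_b0=3.966, sd_b1=0.062, corr_b=-0.874, sd_resid=2.787)


@pytest.fixture(scope="session")
def default_config() -> GeneratorConfig:
    return GeneratorConfig(seed=11)


@pytest.fixture(scope="session")
def cohort(default_config):
    """One default 290-subject cohort, shared across tests."""
    return simulate_cohort(default_config)


@pytest.fixture(scope="session")
def small_cohort():
    """40 subjects: enough to fit reliably, fast enough for repeated use."""
    return simulate_cohort(GeneratorConfig(n_subjects=40, seed=5))


@pytest.fixture(scope="session")
def noise_free_cohort():
    """All variance components zero: measurements lie exactly on the
    fixed-effect surface."""
    return simulate_cohort(
        GeneratorConfig(n_subjects=25, sd_b0=0.0, sd_b1=0.0, corr_b=0.0,
                        sd_resid=0.0, seed=3)
    )


@pytest.fixture(scope="session")
def m2_fit(small_cohort):
    from hr2ee import ModelSpec, fit_lmm

    return fit_lmm(small_cohort, ModelSpec("m2"), method="ML")


@pytest.fixture(scope="session")
def reference_m2_fit():
    """Model object at the published continuous-age parameters."""
    from hr2ee import FittedLMM

    return FittedLMM.from_parameters("m2", M2_FIXED, M2_VC)
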