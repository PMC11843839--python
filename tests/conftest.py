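import numpy as np
import pytest

from demnorms import GenerativeParams, load_published_norms, simulate_cohort


@pytest.fixture(scope="session")
def published_norms():
    return load_published_norms()


@pytest.fixture(scope="session")
def default_cohort():
    """One normative-sized cohort under default generative conditions."""
    return simulate_cohort(n=521, seed=20260927 % (2**31))


@pytest.fixture(scope="session")
def large_cohort():
    """A large cohort for law-of-large-numbers checks."""
    return simulate_cohort(n=5000, seed=42)


@pytest.fixture()
def rng():
    return np.random.default_rng(1234)


@pytest.fixture()
def null_params():
    """Generative parameters with every demographic effect switched off."""
    from demnorms import SubtestEffects

    return GenerativeParams(
        vt=SubtestEffects(intercept=30.0),
        aht=SubtestEffects(intercept=33.0),
        ratio=SubtestEffects(intercept=1.09),
        errors=SubtestEffects(intercept=0.38),
        resid_family="student_t",
        resid_shape=10.0,
    )
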