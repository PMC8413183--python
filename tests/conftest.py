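import pytest

from uveaclass.clinical_vocab import default_vocabulary
from uveaclass.criteria_engine import shipped_ruleset, shipped_rulesets
from uveaclass.synthetic_cohort import (
    CohortSpec,
    demo_viral_anterior_ruleset,
    generate_cohort,
)


@pytest.fixture(scope="session")
def vocab():
    return default_vocabulary()


@pytest.fixture(scope="session")
def spa():
    return shipped_ruleset("spa_hla_b27")


@pytest.fixture(scope="session")
def fuchs():
    return shipped_ruleset("fuchs_uveitis")


@pytest.fixture(scope="session")
def arn():
    return shipped_ruleset("arn")


@pytest.fixture(scope="session")
def all_rulesets():
    return shipped_rulesets()


@pytest.fixture(scope="session")
def noisy_cohort(all_rulesets):
    """Small mixed cohort with noise and missingness, for I/O and report tests."""
    spec = CohortSpec(
        diseases=[(rs, 1.0) for rs in all_rulesets],
        n_cases=60,
        flip_noise=0.1,
        missing_rate=0.15,
        train_fraction=0.7,
        seed=7,
    )
    return generate_cohort(spec)


@pytest.fixture(scope="session")
def anterior_cohort():
    """Noise-free three-class anterior cohort (small, for unit tests)."""
    from uveaclass.synthetic_cohort import derivation_demo_spec

    return generate_cohort(derivation_demo_spec(n_cases=300, seed=11))


@pytest.fixture(scope="session")
def viral_demo():
    return demo_viral_anterior_ruleset()
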