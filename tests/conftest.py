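import numpy as np
import pandas as pd
import pytest

from riskdomains import CohortSpec, CohortTable, DomainMap, generate_cohort


@pytest.fixture(scope="session")
def small_cohort():
    """2 000-row cohort from the default planted process (7 domains)."""
    spec = CohortSpec(n=2000, seed=11)
    return generate_cohort(spec)


@pytest.fixture(scope="session")
def three_domain_cohort():
    """Compact 3-domain cohort for coalition tests (7 coalitions only)."""
    spec = CohortSpec(
        n=1200,
        domain_sizes={"demography": 2, "socioeconomic": 3, "health_behaviors": 2},
        domain_betas={
            "demography": (),
            "socioeconomic": (0.6, 0.6, 0.6),
            "health_behaviors": (0.2, 0.2),
        },
        target_prevalence=0.3,
        missing_rate=0.0,
        seed=5,
    )
    return generate_cohort(spec)


def make_table(n=60, p=3, seed=0, prevalence=0.4):
    """Plain hand-rolled cohort with no planted structure."""
    rng = np.random.default_rng(seed)
    feats = pd.DataFrame(
        {f"x{j}": rng.normal(size=n) for j in range(p)}
        | {"age": rng.uniform(50, 100, n), "gender": rng.binomial(1, 0.5, n).astype(float)}
    )
    outcome = rng.binomial(1, prevalence, n)
    return CohortTable(
        ids=pd.Index([f"r{i}" for i in range(n)]),
        features=feats,
        outcome=pd.Series(outcome),
        age_col="age",
        gender_col="gender",
    )


@pytest.fixture
def plain_table():
    return make_table()
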