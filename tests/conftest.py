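import numpy as np
import pandas as pd
import pytest

from voiredist import (
    AffectGenParams,
    CohortConfig,
    NeuralGenParams,
    build_payoff_scheme,
    generate_cohort,
)


@pytest.fixture(scope="session")
def scheme():
    return build_payoff_scheme(2100, 1300, 700, 0.25)


@pytest.fixture(scope="session")
def small_config():
    """A reduced cohort for fast end-to-end tests."""
    return CohortConfig(n_participants=8, rounds_per_session=9, n_lottery=2, seed=7)


@pytest.fixture(scope="session")
def small_dataset(small_config):
    return generate_cohort(small_config)


@pytest.fixture(scope="session")
def default_dataset():
    return generate_cohort(CohortConfig(seed=11))


# A hand-made 4x3 cell table used as an arithmetic fixture: values chosen
# small and uneven so every estimator is exercised with non-trivial weights.
FIXTURE_MEANS = {
    ("voi", "inequality"): 0.5,
    ("voi", "intermediate"): -0.2,
    ("voi", "equality"): 1.1,
    ("high", "inequality"): 1.6,
    ("high", "intermediate"): 0.3,
    ("high", "equality"): -0.4,
    ("middle", "inequality"): 0.0,
    ("middle", "intermediate"): 0.7,
    ("middle", "equality"): 0.2,
    ("low", "inequality"): -0.8,
    ("low", "intermediate"): 0.9,
    ("low", "equality"): 0.4,
}
FIXTURE_COUNTS = {
    ("voi", "inequality"): 40,
    ("voi", "intermediate"): 25,
    ("voi", "equality"): 15,
    ("high", "inequality"): 30,
    ("high", "intermediate"): 6,
    ("high", "equality"): 4,
    ("middle", "inequality"): 12,
    ("middle", "intermediate"): 14,
    ("middle", "equality"): 10,
    ("low", "inequality"): 3,
    ("low", "intermediate"): 7,
    ("low", "equality"): 28,
}


@pytest.fixture(scope="session")
def fixture_trials():
    """Per-trial records realising FIXTURE_MEANS / FIXTURE_COUNTS exactly.

    Each cell holds `count` trials whose values average to the cell mean
    (mean + d and mean - d pairs, plus the mean itself for odd counts).
    """
    rows = []
    for (cond, rule), n in FIXTURE_COUNTS.items():
        m = FIXTURE_MEANS[(cond, rule)]
        vals = []
        for k in range(n // 2):
            d = 0.1 * (k + 1)
            vals += [m - d, m + d]
        if n % 2:
            vals.append(m)
        for v in vals:
            rows.append({"condition": cond, "chosen_rule": rule, "signal": v})
    return pd.DataFrame(rows)
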