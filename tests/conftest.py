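import dataclasses

import pytest

from pcps.simulate import (METASTATIC_DEFAULTS, NONMETASTATIC_DEFAULTS,
                           default_config, simulate_cohort)


@pytest.fixture(scope="session")
def small_cohort():
    """A 50-patient synthetic cohort (30 metastatic / 20 nonmetastatic)."""
    cfg = default_config(
        seed=7,
        metastatic=dataclasses.replace(METASTATIC_DEFAULTS, n=30),
        nonmetastatic=dataclasses.replace(NONMETASTATIC_DEFAULTS, n=20),
    )
    return simulate_cohort(cfg)


@pytest.fixture(scope="session")
def large_cohort():
    """A 20k-per-group complete-data cohort for Monte-Carlo checks."""
    cfg = default_config(
        seed=20240101,
        metastatic=dataclasses.replace(METASTATIC_DEFAULTS, n=20_000),
        nonmetastatic=dataclasses.replace(NONMETASTATIC_DEFAULTS, n=20_000),
        biomarker_missing_rate=0.0,
    )
    return simulate_cohort(cfg)
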