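import numpy as np
import pytest
from hypothesis import settings

from triagecut.simulate import GeneratorConfig, generate_cohort

settings.register_profile("default", derandomize=True, deadline=None)
settings.load_profile("default")


@pytest.fixture(scope="session")
def default_cohort():
    """One study-condition synthetic cohort shared across tests."""
    return generate_cohort(GeneratorConfig.default(), seed=11)


@pytest.fixture(scope="session")
def large_cohort():
    """n=10,000 cohort for distribution-calibration checks."""
    return generate_cohort(GeneratorConfig.default(n=10_000), seed=11)


@pytest.fixture()
def rng():
    return np.random.default_rng(20260927)


def printed(value_pct: str) -> tuple[float, float]:
    """Parse a printed percentage cell into (value, half-ulp tolerance).

    "82.4" -> (82.4, 0.05); "100" -> (100.0, 0.5).  Used to compare
    recomputed metrics against published table cells at their printed
    rounding.
    """
    v = float(value_pct)
    decimals = len(value_pct.split(".")[1]) if "." in value_pct else 0
    return v, 0.5 * 10 ** (-decimals) + 1e-9
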