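import numpy as np
import pandas as pd
import pytest

from phenocurve import SimulationConfig, simulate_campaign, simulate_population

WEEKLY_DAYS = np.arange(7, 141, 7.0)


@pytest.fixture(scope="session")
def small_campaign():
    """A small but complete two-protocol, two-year campaign."""
    cfg = SimulationConfig(n_lines=12, seed=11)
    return simulate_campaign(cfg)


@pytest.fixture(scope="session")
def population_2022():
    """Single-year population table, 80 lines + parents, both protocols."""
    cfg = SimulationConfig(n_lines=80, years=(2022,), seed=5)
    return simulate_population(cfg)


def make_correlated_pair(n: int, r: float, seed: int = 0) -> pd.DataFrame:
    """Two predictors with *exact* sample correlation r (via orthonormalised
    Gaussian draws), for closed-form VIF checks."""
    rng = np.random.default_rng(seed)
    a = rng.standard_normal(n)
    b = rng.standard_normal(n)
    a = (a - a.mean()) / a.std()
    b = b - b.mean()
    b -= a * (a @ b) / (a @ a)  # exactly orthogonal to a
    b /= b.std()
    return pd.DataFrame({"x1": a, "x2": r * a + np.sqrt(1 - r**2) * b})
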