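import dataclasses

import numpy as np
import pandas as pd
import pytest

from bipolar_rf.simulate import GeneratorConfig, generate_cohort


@pytest.fixture(scope="session")
def config() -> GeneratorConfig:
    return GeneratorConfig(seed=11)


@pytest.fixture(scope="session")
def dev_cohort(config) -> pd.DataFrame:
    """Moderate grid (development-style) cohort shared across tests."""
    return generate_cohort(config, n_total=420)


@pytest.fixture(scope="session")
def val_cohort(config) -> pd.DataFrame:
    """Boundary-adjacent (validation-style) cohort: duration fixed at 60 s."""
    vcfg = dataclasses.replace(config, design="boundary_adjacent")
    return generate_cohort(vcfg, n_total=260, cohort="validation", seed=12)


@pytest.fixture()
def rng() -> np.random.Generator:
    return np.random.default_rng(2026)


def two_by_two(a: int, b: int, c: int, d: int) -> pd.DataFrame:
    """Binary predictor/outcome table with cell counts
    a=(x=1,y=1), b=(x=1,y=0), c=(x=0,y=1), d=(x=0,y=0)."""
    x = [1] * (a + b) + [0] * (c + d)
    y = [1] * a + [0] * b + [1] * c + [0] * d
    return pd.DataFrame({"x": x, "y": y})
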