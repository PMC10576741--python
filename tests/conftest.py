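import numpy as np
import pandas as pd
import pytest

from gifluid import GeneratorConfig, generate_study, generate_worked_fixture


@pytest.fixture(scope="session")
def fixture_records() -> pd.DataFrame:
    """Noiseless 30-record worked study (3 regions x 5 times x 2 markers)."""
    return generate_worked_fixture()


@pytest.fixture(scope="session")
def noisy_study() -> pd.DataFrame:
    """One noisy single-region study at the reference design."""
    cfg = GeneratorConfig(
        regions=("jejunum",),
        k_abs={"jejunum": 0.136},
        k_sec={"jejunum": 7.05e-3},
        times=(5.0, 10.0, 20.0, 30.0),
        animals_per_time=5,
        seed=123,
    )
    return generate_study(cfg)


@pytest.fixture()
def rng() -> np.random.Generator:
    return np.random.default_rng(0)
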