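import numpy as np
import pandas as pd
import pytest

from floralwastage import SimulationParams, SugarDensityTable, generate_study
from floralwastage.stats import nectar_sugar_rates


@pytest.fixture(scope="session")
def sugar_table() -> SugarDensityTable:
    return SugarDensityTable.packaged()


@pytest.fixture(scope="session")
def study_tables() -> dict[str, pd.DataFrame]:
    """One default synthetic study, shared read-only across tests."""
    return generate_study(SimulationParams(), seed=42)


@pytest.fixture(scope="session")
def nectar_rates(study_tables, sugar_table) -> pd.DataFrame:
    return nectar_sugar_rates(study_tables["nectar"], sugar_table)


@pytest.fixture()
def rng() -> np.random.Generator:
    return np.random.default_rng(20240521)
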