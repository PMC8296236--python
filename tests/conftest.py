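import numpy as np
import pandas as pd
import pytest

from heatattr.config import StudyConfig
from heatattr.synthetic import GeneratorTruth, generate_panel


@pytest.fixture(scope="session")
def small_truth():
    return GeneratorTruth(seed=42, n_years=4, baseline_deaths=25.0)


@pytest.fixture(scope="session")
def small_panel(small_truth):
    return generate_panel(small_truth, city_id="city01", country_id="testland")


@pytest.fixture(scope="session")
def small_config():
    return StudyConfig(baseline_years=(1995, 1998))


@pytest.fixture
def rng():
    return np.random.default_rng(2024)


def make_toy_csv(tmp_path, rows, name="toy.csv"):
    """Write a minimal city CSV from (date, deaths) pairs plus weather."""
    df = pd.DataFrame(rows)
    path = tmp_path / name
    df.to_csv(path, index=False)
    return path
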