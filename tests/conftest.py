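import numpy as np
import pandas as pd
import pytest
from hypothesis import settings

import facepref as fp

settings.register_profile("ci", deadline=None, derandomize=True, max_examples=50)
settings.load_profile("ci")


@pytest.fixture(scope="session")
def small_config():
    return fp.GeneratorConfig(n_countries=4, participants_per_country=30, seed=11)


@pytest.fixture(scope="session")
def small_dataset(small_config):
    return fp.generate_dataset(small_config)


@pytest.fixture()
def participants_frame():
    """Hand-built participant table exercising every exclusion rule."""

    def build(rows):
        return pd.DataFrame(rows, columns=["participant_id", "country_id", "sex", "kinsey", "age"])

    rows = []
    pid = 0
    # country A: 50 straight females -> retained
    for _ in range(50):
        rows.append((pid, "A", "female", 0, 30.0)); pid += 1
    # country B: 12 raters, 2 will fall to kinsey, 1 to sex -> 9 left -> dropped
    for _ in range(9):
        rows.append((pid, "B", "male", 1, 25.0)); pid += 1
    rows.append((pid, "B", "female", 5, 25.0)); pid += 1
    rows.append((pid, "B", "male", 4, 25.0)); pid += 1
    rows.append((pid, "B", "other", 0, 25.0)); pid += 1
    # country C: exactly 10 retained
    for _ in range(10):
        rows.append((pid, "C", "female", 2, 40.0)); pid += 1
    # one missing-kinsey rater in A: retained
    rows.append((pid, "A", "male", np.nan, 33.0)); pid += 1
    return build(rows)
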