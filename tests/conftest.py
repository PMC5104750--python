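import dataclasses

import numpy as np
import pandas as pd
import pytest

from methanox.profiles import Profile
from methanox.simulate import ColumnScenario, generate_column


@pytest.fixture(scope="session")
def clean_scenario() -> ColumnScenario:
    """Default water-column conditions with all noise switched off."""
    return ColumnScenario(
        conc_noise_rel=0.0, delta_ch4_noise=0.0, delta_dic_noise=0.0, seed=0
    )


@pytest.fixture(scope="session")
def clean_column(clean_scenario) -> Profile:
    return generate_column(clean_scenario)


@pytest.fixture(scope="session")
def noisy_column() -> Profile:
    return generate_column(ColumnScenario(seed=42))


def make_profile(**columns) -> Profile:
    """Small helper: build a Profile from keyword columns incl. depth_m."""
    return Profile(pd.DataFrame(columns))
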