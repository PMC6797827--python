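import pandas as pd
import pytest

import mofette as m


@pytest.fixture(scope="session")
def gas_profiles():
    return m.datasets.load_gas_profiles()


@pytest.fixture(scope="session")
def pair():
    return m.default_pair(m.datasets.load_bubbling_pool())


@pytest.fixture(scope="session")
def soil_samples():
    return m.datasets.load_soil_profiles()


@pytest.fixture
def small_otu_table():
    """Two single-sample groups with hand-checkable counts."""
    counts = pd.DataFrame(
        [[3, 0, 1], [1, 2, 1]], index=["s1", "s2"], columns=["o1", "o2", "o3"]
    )
    groups = pd.Series({"s1": "HC", "s2": "LC"})
    return m.OtuTable(counts=counts, groups=groups)
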