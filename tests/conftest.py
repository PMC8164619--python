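import hypothesis
import numpy as np
import pytest

import dietpra as dp
from dietpra.synthetic import ConsumptionGroup

hypothesis.settings.register_profile(
    "ci", derandomize=True, max_examples=50, deadline=None
)
hypothesis.settings.load_profile("ci")

#: master seed used by every stochastic test in the suite
SEED = 1


@pytest.fixture(scope="session")
def table1():
    """All printed regional summaries, pooled row included."""
    return dp.load_table1_summaries()


@pytest.fixture(scope="session")
def regional_targets(table1):
    return [t for t in table1 if t.region != "Total"]


@pytest.fixture(scope="session")
def total_summary(table1):
    (total,) = [t for t in table1 if t.region == "Total"]
    return total


@pytest.fixture(scope="session")
def total_model(total_summary):
    """Pooled-survey concentration model used by the headline simulations."""
    return dp.from_summary(total_summary)


@pytest.fixture(scope="session")
def groups():
    """All 14 age–gender consumption strata."""
    return [
        ConsumptionGroup.from_row(row)
        for row in dp.load_table2_groups().itertuples(index=False)
    ]


@pytest.fixture(scope="session")
def group_by_label(groups):
    return {g.label: g for g in groups}


@pytest.fixture
def rng():
    return np.random.default_rng(SEED)
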