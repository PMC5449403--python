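import pytest

import vegextent as vx
from vegextent.data import TABLE1_CLUSTERS


@pytest.fixture(scope="session")
def table1():
    return vx.table1_fixture()


@pytest.fixture(scope="session")
def s1_layout():
    return vx.table1_layout()


@pytest.fixture(scope="session")
def published_partition():
    return {frozenset(v) for v in TABLE1_CLUSTERS.values()}


@pytest.fixture(scope="session")
def table1_iiv(table1):
    return vx.integrated_iv(table1, TABLE1_CLUSTERS)


@pytest.fixture
def two_plot_dataset():
    """The worked two-plot example: species A in one plot, B in both.

    Hand-computed importance values: Rd_A = 4/12, Rf_A = 1/3,
    Rc_A = 20/60, hence IV_A = 1/3 and IV_B = 2/3.
    """
    plots = [
        vx.PlotRecord("p1", "T", {"A": 4, "B": 4}, {"A": 20.0, "B": 20.0}, 40.0),
        vx.PlotRecord("p2", "T", {"B": 4}, {"B": 20.0}, 20.0),
    ]
    layout = [vx.Transect("T", vx.Zone.DISTANCE, 10.0, 2)]
    return vx.CommunityDataset(plots, layout)


def make_random_dataset(seed: int, preset: str = "s1_like") -> vx.CommunityDataset:
    return vx.generate(vx.load_preset(preset, seed=seed))


@pytest.fixture
def random_dataset():
    return make_random_dataset
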