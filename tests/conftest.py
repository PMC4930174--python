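import pandas as pd
import pytest

from netpd.game_core import GroupConfig, PDPayoffs
from netpd.synthetic_data import records_to_rows


@pytest.fixture
def payoffs() -> PDPayoffs:
    """Experimental payoffs: T=60, R=40, P=20, S=0, Q=30."""
    return PDPayoffs()


@pytest.fixture
def group_config() -> GroupConfig:
    """Experimental group: 6 actors, degree 2, 40 periods."""
    return GroupConfig()


def records_to_dataset(records, experiment_id="expT", group_id="g1", condition="atomized"):
    """Tabulate one simulated group into the flat dataset format."""
    return pd.DataFrame(records_to_rows(records, experiment_id, group_id, condition))
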