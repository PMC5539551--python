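import numpy as np
import pandas as pd
import pytest

from crustscreen import OtuTable, ScreenConfig


def make_table(counts, otu_ids=None, sample_ids=None, control=None) -> OtuTable:
    """Build an OtuTable from a nested list (OTU rows x sample columns)."""
    arr = np.asarray(counts, dtype=np.int64)
    otu_ids = otu_ids or [f"Otu{i:04d}" for i in range(arr.shape[0])]
    sample_ids = sample_ids or [f"S{j}" for j in range(arr.shape[1])]
    table = OtuTable(pd.DataFrame(arr, index=otu_ids, columns=sample_ids))
    if control is not None:
        table = table.with_control(control)
    return table


@pytest.fixture
def small_table() -> OtuTable:
    # 4 OTUs x 3 libraries; CTRL is the background control
    return make_table(
        [
            [0, 20, 5],   # samples only
            [10, 0, 0],   # control only
            [2, 40, 30],  # shared, strongly sample-enriched
            [20, 6, 5],   # shared, comparable abundance
        ],
        otu_ids=["OtuA", "OtuB", "OtuC", "OtuD"],
        sample_ids=["CTRL", "S1", "S2"],
        control="CTRL",
    )


@pytest.fixture
def default_config() -> ScreenConfig:
    return ScreenConfig()
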