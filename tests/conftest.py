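import numpy as np
import pandas as pd
import pytest

from mycoflow.otu import OtuTable


def make_table(counts: dict[str, list[int]], otu_ids=None,
               environments=None, taxonomy=None) -> OtuTable:
    """Small OtuTable from a {sample: counts} dict."""
    frame = pd.DataFrame(counts)
    if otu_ids is not None:
        frame.index = otu_ids
    else:
        frame.index = [f"OTU{i}" for i in range(frame.shape[0])]
    envs = environments or {s: "env1" for s in frame.columns}
    meta = pd.DataFrame({"environment": pd.Series(envs)})
    meta.index.name = "sample_id"
    tax = None
    if taxonomy is not None:
        tax = pd.Series(taxonomy, index=frame.index)
    return OtuTable(frame, meta, tax)


@pytest.fixture
def toy_table():
    """3 OTUs x 4 samples across two environments."""
    return make_table(
        {"s1": [5, 0, 2], "s2": [1, 3, 0], "s3": [0, 7, 1], "s4": [2, 2, 2]},
        environments={"s1": "air", "s2": "air", "s3": "leaf", "s4": "leaf"},
        taxonomy=["k__Fungi;p__Asco", "k__Fungi;p__Basidio", "k__Fungi;p__Asco"],
    )


@pytest.fixture(scope="session")
def rng():
    return np.random.default_rng(20240901)
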