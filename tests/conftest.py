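import numpy as np
import pandas as pd
import pytest

from exoref import CountMatrix, CtTable, SampleSheet


@pytest.fixture
def toy_counts() -> CountMatrix:
    df = pd.DataFrame(
        [[10, 20, 30], [5, 0, 15], [100, 200, 300]],
        index=["miR-a", "miR-b", "miR-c"],
        columns=["s1", "s2", "s3"],
    )
    return CountMatrix(df)


@pytest.fixture
def toy_sheet() -> SampleSheet:
    return SampleSheet(pd.DataFrame(
        {"batch": ["b1", "b1", "b2", "b2"],
         "group": ["HD", "HD", "HD", "HD"],
         "timepoint": ["none"] * 4},
        index=pd.Index(["s1", "s2", "s3", "s4"], name="sample_id")))


def make_ct_table(rows) -> CtTable:
    df = pd.DataFrame(rows, columns=["sample_id", "target", "replicate", "ct"])
    return CtTable(df)


@pytest.fixture
def rng() -> np.random.Generator:
    return np.random.default_rng(20210108)
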