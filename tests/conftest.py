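import numpy as np
import pandas as pd
import pytest

from rnachase.core_io import CountMatrix, SampleSheet


@pytest.fixture
def tiny_sheet() -> SampleSheet:
    return SampleSheet(pd.DataFrame({
        "sample_id": ["a_T0_r1", "a_T0_r2", "b_T0_r1", "b_T0_r2"],
        "strain": ["a", "a", "b", "b"],
        "timepoint": ["T0"] * 4,
        "replicate": [1, 2, 1, 2],
    }))


@pytest.fixture
def tiny_matrix(tiny_sheet) -> CountMatrix:
    rng = np.random.default_rng(42)
    counts = rng.poisson(100, size=(10, 4))
    return CountMatrix(
        gene_ids=[f"g{i}" for i in range(10)],
        sample_ids=tiny_sheet.sample_ids,
        counts=counts,
    )


def write_tsv(path, frame):
    frame.to_csv(path, sep="\t", index=False)
    return path
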