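import numpy as np
import pandas as pd
import pytest

from nucmir import CtMatrix, SampleMeta


def make_ct(values_by_sample, metas, assay_names, assay_class=None):
    """Build a CtMatrix from {sample_id: [ct per assay]} and SampleMeta list."""
    df = pd.DataFrame(values_by_sample, index=assay_names)
    return CtMatrix(df, metas, assay_class)


@pytest.fixture
def whole_cell_collapsed():
    """One column per stage (whole cell), 4 assays incl. an undetectable one."""
    stages = ["LSK", "promyelocyte", "myelocyte", "granulocyte"]
    metas = [SampleMeta(f"{s}:whole", s, "whole", 1) for s in stages]
    vals = {
        "LSK:whole": [24.0, 31.0, 29.9, 24.0],
        "promyelocyte:whole": [24.0, 33.0, 33.0, 24.0],
        "myelocyte:whole": [25.0, 32.0, 34.0, 24.0],
        "granulocyte:whole": [26.0, 33.0, 35.0, 25.0],
    }
    return make_ct(vals, metas, ["mirA", "mirB", "mirC", "mirD"])


@pytest.fixture
def rng():
    return np.random.default_rng(12345)
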