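import numpy as np
import pandas as pd
import pytest

from episeq import DETable, merge_by_gene


@pytest.fixture
def small_de_table() -> DETable:
    return DETable(
        pd.DataFrame(
            {
                "gene": ["Ccna2", "Meiosin", "Stra8", "Rec8", "Sycp3"],
                "log2fc": [-1.2, 2.0, 0.5, 1.1, -0.3],
                "padj": [0.001, 0.01, 0.2, 0.04, np.nan],
                "base_mean": [150.0, 40.0, 300.0, 12.0, 8.0],
            }
        ),
        label="demo",
    )


@pytest.fixture
def merged_identical(small_de_table):
    b = DETable(small_de_table.data.copy(), label="other")
    return merge_by_gene(small_de_table, b)


def make_de_table(genes, log2fc, padj=None, label="T") -> DETable:
    n = len(genes)
    return DETable(
        pd.DataFrame(
            {
                "gene": list(genes),
                "log2fc": list(log2fc),
                "padj": list(padj) if padj is not None else [np.nan] * n,
            }
        ),
        label=label,
    )
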