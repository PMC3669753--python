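import numpy as np
import pandas as pd
import pytest

from ferronet.io_formats import ExpressionTable


def make_expression(values: np.ndarray, genes, conditions, replicates, scale="rpkm"):
    """Build an ExpressionTable from a raw matrix and sample labels."""
    sample_ids = [f"{c}_r{r}" for c, r in zip(conditions, replicates)]
    meta = pd.DataFrame(
        {"condition": conditions, "replicate": replicates},
        index=pd.Index(sample_ids, name="sample_id"),
    )
    df = pd.DataFrame(values, index=pd.Index(genes, name="gene_id"), columns=sample_ids)
    return ExpressionTable(df, scale, meta)


@pytest.fixture
def two_condition_table():
    """3 genes x 6 samples (3 -Fe, 3 +Fe), noise-free fixture."""
    values = np.array(
        [
            [10.0, 10.0, 10.0, 5.0, 5.0, 5.0],   # clean 2-fold induction
            [8.0, 10.0, 12.0, 4.0, 5.0, 6.0],    # 2-fold, paired across replicates
            [7.0, 7.0, 7.0, 7.0, 7.0, 7.0],      # unchanged
        ]
    )
    return make_expression(
        values,
        ["GUP", "GPAIR", "GFLAT"],
        ["minusFe"] * 3 + ["plusFe"] * 3,
        [1, 2, 3, 1, 2, 3],
    )
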