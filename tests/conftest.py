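import numpy as np
import pandas as pd
import pytest

from critcell.dataio import ExpressionMatrix, SampleSheet


def make_sheet(n_case_donors, n_ctrl_donors, reps=2):
    """Sample sheet with fixed replicate counts; sample ids '<donor>_r<k>'."""
    rows = []
    for group, prefix, n in (("case", "CASE", n_case_donors), ("control", "CTRL", n_ctrl_donors)):
        for d in range(n):
            for r in range(reps):
                rows.append(
                    {
                        "sample_id": f"{prefix}{d:02d}_r{r + 1}",
                        "donor_id": f"{prefix}{d:02d}",
                        "replicate_index": r + 1,
                        "group": group,
                    }
                )
    return SampleSheet(pd.DataFrame(rows))


def make_matrix(values, genes=None, samples=None):
    values = np.asarray(values, dtype=float)
    genes = genes or [f"g{i}" for i in range(values.shape[0])]
    samples = samples or [f"s{j}" for j in range(values.shape[1])]
    return ExpressionMatrix(pd.DataFrame(values, index=genes, columns=samples))


@pytest.fixture
def small_sheet():
    return make_sheet(2, 3, reps=2)


@pytest.fixture
def rng():
    return np.random.default_rng(20260920)
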