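import numpy as np
import pandas as pd
import pytest

from rcctriad.io_core import ExpressionMatrix
from rcctriad.synthetic_cohort import CohortSpec, generate_study


@pytest.fixture(scope="session")
def default_study():
    """One default synthetic study shared by read-only tests."""
    return generate_study(CohortSpec(seed=1))


@pytest.fixture(scope="session")
def tumor_matrix(default_study):
    """Primary-tumor expression submatrix and its true labels."""
    truth = default_study["truth"]
    primaries = [s for s in truth.sample_labels.index if s.startswith("P")]
    matrix = default_study["matrix"].subset_samples(primaries)
    labels = truth.sample_labels.loc[primaries]
    return matrix, labels


def make_matrix(values, sample_ids=None, gene_ids=None) -> ExpressionMatrix:
    values = np.asarray(values, dtype=float)
    n, p = values.shape
    sample_ids = sample_ids or [f"S{i}" for i in range(n)]
    gene_ids = gene_ids or [f"g{j}" for j in range(p)]
    return ExpressionMatrix(
        pd.DataFrame(values, index=sample_ids, columns=gene_ids)
    )
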