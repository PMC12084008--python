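import numpy as np
import pandas as pd
import pytest

import ribosig as r


@pytest.fixture
def small_matrix():
    """6-sample log2 matrix with a hand-built missingness pattern."""
    values = pd.DataFrame(
        {
            "c1": [20.0, 21.0, 19.0, np.nan],
            "c2": [20.5, 21.5, np.nan, 18.0],
            "c3": [19.5, 20.5, 19.5, np.nan],
            "t1": [22.0, 21.0, 19.2, 18.5],
            "t2": [22.5, 21.2, np.nan, np.nan],
            "t3": [21.5, 20.8, 19.1, 18.2],
        },
        index=pd.Index(["A", "B", "C", "D"], name="protein_id"),
    )
    conditions = pd.Series(
        ["control"] * 3 + ["treatment"] * 3,
        index=["c1", "c2", "c3", "t1", "t2", "t3"],
    )
    return r.QuantMatrix(values, conditions, log2_transformed=True)


@pytest.fixture(scope="session")
def random_transcripts():
    """A mid-sized synthetic transcript set shared across feature tests."""
    records, truth = r.generate_transcriptome(
        r.SimTranscriptomeParams(n_genes=600, seed=11)
    )
    return records, truth
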