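import numpy as np
import pandas as pd
import pytest

from milknet.containers import AbundanceTable


def make_table(values, kind="protein", sample_prefix="S", feature_prefix="F", meta=None):
    """Small AbundanceTable from a 2-D array; NaN cells become missing."""
    values = np.asarray(values, dtype=float)
    n, p = values.shape
    samples = [f"{sample_prefix}{i+1}" for i in range(n)]
    features = [f"{feature_prefix}{j+1}" for j in range(p)]
    intensities = pd.DataFrame(values, index=samples, columns=features)
    mask = intensities.isna()
    if meta is None:
        meta = pd.DataFrame(
            {"gene_name": features, "is_contaminant": False, "is_reverse": False},
            index=features,
        )
    return AbundanceTable(
        intensities=intensities,
        mask=mask,
        kind=pd.Series(kind, index=features),
        meta=meta,
    )


@pytest.fixture
def rng():
    return np.random.default_rng(0)


@pytest.fixture
def toy_ladder_coords():
    """Five overlapping peptides forming one exoproteolytic ladder."""
    return [(10, 25), (11, 25), (12, 25), (10, 24), (10, 23)]
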