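import numpy as np
import pandas as pd
import pytest

from microstates import tables as tb
from microstates.synth import SynthConfig, generate_cohort


@pytest.fixture(scope="session")
def cohort():
    """Default synthetic cohort (15 patients x 3 sites x 4 occasions)."""
    return generate_cohort(SynthConfig(seed=1))


@pytest.fixture(scope="session")
def rarefied_cohort(cohort):
    table, meta, truth = cohort
    filtered, _ = tb.filter_contaminants(table, truth.negative_controls)
    rarefied = tb.rarefy(filtered, 600, seed=1)
    meta_r = meta[meta["sample_id"].isin(rarefied.sample_ids)].reset_index(drop=True)
    return rarefied, meta_r, truth


def toy_table(counts, sample_ids=None, asv_ids=None, taxonomy=None):
    counts = np.asarray(counts)
    n, m = counts.shape
    sample_ids = sample_ids or [f"S{i + 1}" for i in range(n)]
    asv_ids = asv_ids or [f"ASV_{j + 1}" for j in range(m)]
    tax = pd.Series(taxonomy if taxonomy is not None else "", index=asv_ids)
    return tb.CountTable(
        pd.DataFrame(counts, index=sample_ids, columns=asv_ids, dtype=np.int64), tax
    )
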