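import numpy as np
import pandas as pd
import pytest

from phyllocore.io_model import AbundanceTable, parse_taxonomy


def make_table(counts: dict[str, list[int]], taxa: list[str], taxonomy=None) -> AbundanceTable:
    """Small abundance table from a {sample: column} mapping."""
    frame = pd.DataFrame(counts, index=taxa, dtype=np.int64)
    taxonomy = taxonomy or {t: parse_taxonomy(t.capitalize()) for t in taxa}
    return AbundanceTable(frame, taxonomy)


@pytest.fixture
def small_table() -> AbundanceTable:
    return make_table(
        {"s1": [5, 0, 3], "s2": [2, 2, 2], "s3": [0, 7, 1]},
        taxa=["alpha", "beta", "gamma"],
    )


@pytest.fixture
def rng() -> np.random.Generator:
    return np.random.default_rng(20_240_101)
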