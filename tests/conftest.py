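import numpy as np
import pandas as pd
import pytest

import roostcount as rc
from roostcount.counts import CANONICAL_COLUMNS


def make_table(rows: list[dict]) -> rc.CountTable:
    """Build a CountTable from sparse row dicts (absent strata -> NaN)."""
    df = pd.DataFrame(rows)
    for col in CANONICAL_COLUMNS:
        if col not in df.columns:
            df[col] = np.nan
    return rc.CountTable(df)


@pytest.fixture(scope="session")
def tiny_table() -> rc.CountTable:
    """Two roosts, one breeding season, strata consistent by construction."""
    rows = []
    for roost, scale in (("1", 1), ("2", 2)):
        for month, total in ((6, 300), (7, 300), (8, 120), (9, 120)):
            singles = (10 if month in (8, 9) else 2) * scale
            pairs = 40 * scale
            n_flocks, fledglings = 3 * scale, 5 * scale
            ff = 2 * n_flocks + fledglings
            large = total * scale - singles - 2 * pairs - ff
            rows.append(
                dict(roost=roost, year=2005, month=month,
                     all_parrots=total * scale, singles=singles, pairs=pairs,
                     fledglings=fledglings, family_flock_birds=ff,
                     large_flock_birds=large)
            )
    return make_table(rows)


@pytest.fixture(scope="session")
def study_table() -> rc.CountTable:
    """One draw from the study-shaped synthetic generator."""
    return rc.generate(rc.default_config(), seed=20240917)


@pytest.fixture()
def counts_csv(tmp_path, tiny_table):
    path = tmp_path / "counts.csv"
    tiny_table.to_csv(path)
    return path
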