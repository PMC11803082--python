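import numpy as np
import pandas as pd
import pytest

from abxdemog.core_ingest import RECORD_COLUMNS, period_year


def make_records(rows):
    """Canonical record table from (period, drug, family, band, sex,
    region, items) tuples; items None means redacted."""
    df = pd.DataFrame(rows, columns=RECORD_COLUMNS)
    df["items"] = df["items"].astype("Int64")
    return df


def uniform_population(records, count=100_000):
    """A population table with ``count`` persons in every demographic
    cell appearing in the records."""
    rec = records.copy()
    rec["year"] = period_year(rec["period"])
    cells = rec[["age_band", "sex", "region", "year"]].drop_duplicates()
    cells = cells.reset_index(drop=True)
    cells["count"] = count
    return cells


@pytest.fixture
def rng():
    return np.random.default_rng(20250928)
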