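from __future__ import annotations

import datetime

import numpy as np
import pandas as pd
import pytest

from fishway_edna.types import ReadCountTable, SampleRecord, Station


@pytest.fixture
def rng() -> np.random.Generator:
    return np.random.default_rng(20240601)


def make_samples(
    dates: list[datetime.date],
    hours: list[int],
    stations: list[Station] = list(Station),
    dilution: float = 1.0,
    volume: float = 1.0,
) -> list[SampleRecord]:
    return [
        SampleRecord(
            sample_id=f"{st.value}_{d.isoformat()}_{h:02d}",
            station=st, date=d, hour=h, volume=volume, dilution=dilution,
        )
        for d in dates for h in hours for st in stations
    ]


def make_count_table(
    rng: np.random.Generator,
    taxa: list[str],
    sample_ids: list[str],
    max_count: int = 1000,
) -> ReadCountTable:
    counts = rng.integers(0, max_count + 1, size=(len(taxa), len(sample_ids)))
    return ReadCountTable(
        pd.DataFrame(counts, index=pd.Index(taxa, name="taxon"), columns=sample_ids)
    )


@pytest.fixture
def june_dates() -> list[datetime.date]:
    start = datetime.date(2021, 6, 6)
    return [start + datetime.timedelta(days=i) for i in range(8)]
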