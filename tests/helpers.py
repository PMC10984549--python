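"""Independent oracles and builders shared by the test suite.

The oracles here deliberately avoid the library's own code paths: edit
distance is a plain O(nm) numpy dynamic program (the implementation uses
edlib), and Pearson r is the direct covariance formula (the implementation
uses centered dot products plus the t transform).
"""

from __future__ import annotations

import datetime

import numpy as np

from fishway_edna.types import CaptureRecord, FishwayType


def dp_edit_distance(a: str, b: str) -> int:
    """Full-matrix Levenshtein dynamic program, unit costs."""
    la, lb = len(a), len(b)
    prev = np.arange(lb + 1)
    for i in range(1, la + 1):
        cur = np.empty(lb + 1, dtype=np.int64)
        cur[0] = i
        ai = a[i - 1]
        for j in range(1, lb + 1):
            cur[j] = min(
                prev[j] + 1,
                cur[j - 1] + 1,
                prev[j - 1] + (ai != b[j - 1]),
            )
        prev = cur
    return int(prev[lb])


def dp_identity(a: str, b: str) -> float:
    return 1.0 - dp_edit_distance(a, b) / max(len(a), len(b))


def pearson_direct(x, y) -> float:
    """cov(x, y) / (sigma_x sigma_y), the defining formula."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    cov = np.mean((x - x.mean()) * (y - y.mean()))
    return float(cov / (x.std() * y.std()))


def random_captures(rng: np.random.Generator, n_days: int = 12,
                    n_species: int = 8) -> list[CaptureRecord]:
    """A random sparse capture table over all fishways and basket hours."""
    start = datetime.date(2021, 6, 6)
    records = []
    for _ in range(rng.integers(10, 60)):
        records.append(
            CaptureRecord(
                fishway=rng.choice(list(FishwayType)),
                date=start + datetime.timedelta(days=int(rng.integers(0, n_days))),
                hour=int(rng.integers(10, 18)),
                taxon=f"sp{int(rng.integers(0, n_species))}",
                count=int(rng.integers(0, 5)),
            )
        )
    return records
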