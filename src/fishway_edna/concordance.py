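"""eDNA-vs-capture concordance across temporal windows.

A water sample integrates eDNA over some upstream time span, so a
detection at one 15:00 index slot need not match the trap catch of that
exact hour.  The analysis therefore pairs each index slot's eDNA result
with capture results over four nested windows — the same hour, the same
day, +/-3 days (a 7-day span) and +/-7 days (a 15-day span), both closed —
and asks at which span Pearson correlation between eDNA and capture
results is strongest, per fishway and per focal species.
"""

from __future__ import annotations

import datetime
import enum
from dataclasses import dataclass
from typing import Iterable, Mapping, Optional, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .types import CaptureRecord, FishwayType


class WindowKind(str, enum.Enum):
    THAT_TIME = "that_time"
    THAT_DAY = "that_day"
    PM3D = "pm3d"  # +/-3 days: a 7-day span centered on the index date
    PM7D = "pm7d"  # +/-7 days: a 15-day span

    @property
    def half_span_days(self) -> int:
        return {"that_time": 0, "that_day": 0, "pm3d": 3, "pm7d": 7}[self.value]


ALL_WINDOWS: tuple[WindowKind, ...] = tuple(WindowKind)

#: Default index slots: the 15:00 samples of the eight analysed dates
#: (four per survey year).  Configurable, not hard-coded into operations.
DEFAULT_INDEX_SLOTS: tuple[tuple[datetime.date, int], ...] = tuple(
    (datetime.date.fromisoformat(d), 15)
    for d in (
        "2021-06-17", "2021-06-21", "2021-06-28", "2021-06-30",
        "2022-06-20", "2022-06-22", "2022-06-30", "2022-07-02",
    )
)


@dataclass(frozen=True)
class Window:
    """A closed date range, optionally restricted to a single hour slot."""

    dates: tuple[datetime.date, ...]
    hour: Optional[int]  # None = all hourly slots on each date

    def contains(self, date: datetime.date, hour: int) -> bool:
        return date in self.dates and (self.hour is None or hour == self.hour)


def build_window(center_date: datetime.date, center_hour: int, kind: WindowKind) -> Window:
    """Window of capture records matched to an index slot."""
    if kind is WindowKind.THAT_TIME:
        return Window(dates=(center_date,), hour=center_hour)
    half = kind.half_span_days
    dates = tuple(
        center_date + datetime.timedelta(days=d) for d in range(-half, half + 1)
    )
    return Window(dates=dates, hour=None)


def capture_species_richness(
    captures: Iterable[CaptureRecord],
    fishway: Optional[FishwayType],
    window: Window,
) -> int:
    """Distinct taxa with at least one individual caught in the window.

    ``fishway=None`` pools all fishways.
    """
    taxa = {
        rec.taxon
        for rec in captures
        if rec.count >= 1
        and (fishway is None or rec.fishway is fishway)
        and window.contains(rec.date, rec.hour)
    }
    return len(taxa)


def captured_individuals(
    captures: Iterable[CaptureRecord],
    taxon: str,
    window: Window,
    fishway: Optional[FishwayType] = None,
) -> int:
    """Total individuals of one taxon caught in the window (pooling fishways
    unless one is given)."""
    return sum(
        rec.count
        for rec in captures
        if rec.taxon == taxon
        and (fishway is None or rec.fishway is fishway)
        and window.contains(rec.date, rec.hour)
    )


# ---------------------------------------------------------------------------
# Pearson statistics

@dataclass(frozen=True)
class ConcordanceResult:
    stratum: str  # "all" | fishway name | focal species label
    window: WindowKind
    r: float
    R2: float
    p: float
    n: int
    ok: bool  # False when undefined (constant vector or n < 3)
    note: str = ""


def pearson(x: Sequence[float], y: Sequence[float]) -> tuple[float, float, float]:
    """Sample Pearson r, R^2 = r^2, and the two-sided p from the t transform
    with n-2 degrees of freedom.

    Raises for length mismatch, n < 3, or a constant vector (r undefined).
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape:
        raise ValueError("x and y must have equal length")
    n = x.size
    if n < 3:
        raise ValueError("pearson needs n >= 3")
    if np.ptp(x) == 0 or np.ptp(y) == 0:
        raise ValueError("constant vector: correlation undefined")
    xc = x - x.mean()
    yc = y - y.mean()
    r = float(np.dot(xc, yc) / np.sqrt(np.dot(xc, xc) * np.dot(yc, yc)))
    r = max(-1.0, min(1.0, r))
    if abs(r) == 1.0:
        p = 0.0
    else:
        t = r * np.sqrt((n - 2) / (1.0 - r * r))
        p = float(2.0 * stats.t.sf(abs(t), df=n - 2))
    return r, r * r, p


def t_critical(df: int, alpha: float = 0.05) -> float:
    """Two-sided Student-t critical value at level ``alpha``."""
    if df < 1:
        raise ValueError("df must be >= 1")
    return float(stats.t.ppf(1.0 - alpha / 2.0, df))


def _result(stratum: str, kind: WindowKind, x: list[float], y: list[float]) -> ConcordanceResult:
    n = len(x)
    try:
        r, r2, p = pearson(x, y)
        return ConcordanceResult(stratum, kind, r, r2, p, n, ok=True)
    except ValueError as exc:
        return ConcordanceResult(stratum, kind, float("nan"), float("nan"), float("nan"),
                                 n, ok=False, note=str(exc))


# ---------------------------------------------------------------------------
# Concordance analyses

def richness_concordance(
    edna_richness: Mapping[tuple[str, str, int], int],
    captures: Sequence[CaptureRecord],
    index_slots: Sequence[tuple[datetime.date, int]],
    windows: Sequence[WindowKind] = ALL_WINDOWS,
    fishways: Sequence[FishwayType] = tuple(FishwayType),
) -> list[ConcordanceResult]:
    """Correlate eDNA species richness at index slots with capture richness
    per window, for the pooled system and per fishway.

    ``edna_richness`` maps (fishway name, ISO date, hour) -> number of
    species detected in the fishway's attributed eDNA at that slot (the
    richness of a `DetectionMatrix`).  One paired point per index slot;
    the "all" stratum pools the fishways (union of detected/captured
    species).
    """
    results: list[ConcordanceResult] = []
    for kind in windows:
        xs_all: list[float] = []
        ys_all: list[float] = []
        per_fishway: dict[FishwayType, tuple[list[float], list[float]]] = {
            fw: ([], []) for fw in fishways
        }
        for date, hour in index_slots:
            window = build_window(date, hour, kind)
            pooled_edna = 0
            for fw in fishways:
                e = edna_richness.get((fw.value, date.isoformat(), hour), 0)
                c = capture_species_richness(captures, fw, window)
                per_fishway[fw][0].append(float(e))
                per_fishway[fw][1].append(float(c))
                pooled_edna += e
            xs_all.append(float(pooled_edna))
            ys_all.append(float(capture_species_richness(captures, None, window)))
        results.append(_result("all", kind, xs_all, ys_all))
        for fw in fishways:
            xs, ys = per_fishway[fw]
            results.append(_result(fw.value, kind, xs, ys))
    return results


def species_concordance(
    attributed: pd.DataFrame,
    captures: Sequence[CaptureRecord],
    index_slots: Sequence[tuple[datetime.date, int]],
    focal: Sequence[str],
    windows: Sequence[WindowKind] = ALL_WINDOWS,
) -> list[ConcordanceResult]:
    """Correlate a focal species' attributed eDNA concentration at each
    index slot with its captured individuals in each window.

    Entrance signals and captures are pooled across the three fishways
    (one paired point per index slot).
    """
    if not focal:
        raise ValueError("focal species list must be nonempty")
    results: list[ConcordanceResult] = []
    for species in focal:
        for kind in windows:
            xs: list[float] = []
            ys: list[float] = []
            for date, hour in index_slots:
                iso = date.isoformat()
                cols = [c for c in attributed.columns if c[1] == iso and c[2] == hour]
                signal = float(attributed.loc[species, cols].sum()) if species in attributed.index else 0.0
                window = build_window(date, hour, kind)
                xs.append(signal)
                ys.append(float(captured_individuals(captures, species, window)))
            results.append(_result(species, kind, xs, ys))
    return results


# ---------------------------------------------------------------------------
# Overlap summaries

@dataclass(frozen=True)
class OverlapSummary:
    n_both: int
    n_edna_only: int
    n_capture_only: int

    @property
    def n_edna(self) -> int:
        return self.n_both + self.n_edna_only

    @property
    def proportion_both_of_edna(self) -> float:
        """Share of eDNA-confirmed species also confirmed by capture.

        NaN when no species were confirmed by eDNA at all.
        """
        if self.n_edna == 0:
            return float("nan")
        return self.n_both / self.n_edna


def overlap_summary(edna_taxa: Iterable[str], captured_taxa: Iterable[str]) -> OverlapSummary:
    edna = set(edna_taxa)
    captured = set(captured_taxa)
    return OverlapSummary(
        n_both=len(edna & captured),
        n_edna_only=len(edna - captured),
        n_capture_only=len(captured - edna),
    )


def results_to_frame(results: Sequence[ConcordanceResult]) -> pd.DataFrame:
    return pd.DataFrame(
        [
            {
                "stratum": res.stratum,
                "window": res.window.value,
                "r": res.r,
                "R2": res.R2,
                "p": res.p,
                "n": res.n,
                "ok": res.ok,
                "note": res.note,
            }
            for res in results
        ]
    )
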