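"""Fishway-attributable eDNA signal.

Read counts are first converted to reads per liter using each sample's
dilution factor and filtered volume (raw read counts are not comparable
between samples; per-unit-volume values are).  The upstream control
station st1 measures the eDNA flowing into all three fishways, so the
fishway-attributable signal at an entrance station is the entrance
concentration minus the matched st1 concentration at the same (date,
hour), clipped at zero — negative differences carry no information about
fish in the fishway.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Mapping, Optional

import numpy as np
import pandas as pd

from .types import (
    DEFAULT_STATION_MAP,
    FishwayType,
    ReadCountTable,
    SampleRecord,
    Station,
)

#: Columns of an attributed table: one per (fishway, date, hour) slot.
SLOT_LEVELS = ["fishway", "date", "hour"]


def normalize_per_volume(
    table: ReadCountTable,
    samples: Iterable[SampleRecord],
) -> pd.DataFrame:
    """Convert read counts to reads per liter: count * dilution / volume."""
    by_id = {s.sample_id: s for s in samples}
    missing = [sid for sid in table.samples if sid not in by_id]
    if missing:
        raise KeyError(f"no SampleRecord for sample(s): {missing}")
    factors = np.array(
        [by_id[sid].dilution / by_id[sid].volume for sid in table.samples]
    )
    conc = table.counts.astype(float) * factors[np.newaxis, :]
    return conc


@dataclass
class AttributionResult:
    """Fishway-attributable concentrations plus the slots that were skipped
    for lack of a matched control sample."""

    attributed: pd.DataFrame  # taxa x MultiIndex(fishway, date, hour), >= 0
    skipped_slots: list[tuple[str, str, int]] = field(default_factory=list)


def attribute_fishway_signal(
    concentrations: pd.DataFrame,
    samples: Iterable[SampleRecord],
    station_map: Mapping[Station, FishwayType] = DEFAULT_STATION_MAP,
) -> AttributionResult:
    """Subtract the control-station concentration from each entrance sample.

    attributed(taxon, fishway, date, hour) =
        max(0, conc(entrance sample) - conc(control sample at same slot)).

    Entrance samples with no same-slot control partner are skipped and
    reported in ``skipped_slots``.
    """
    by_id = {s.sample_id: s for s in samples}
    control_by_slot: dict[tuple, str] = {}
    entrance: list[tuple[SampleRecord, FishwayType]] = []
    for sid in concentrations.columns:
        rec = by_id.get(sid)
        if rec is None:
            raise KeyError(f"no SampleRecord for sample {sid!r}")
        if rec.station is Station.ST1:
            control_by_slot[(rec.date, rec.hour)] = sid
        elif rec.station in station_map:
            entrance.append((rec, station_map[rec.station]))

    columns: list[tuple[str, str, int]] = []
    values: list[np.ndarray] = []
    skipped: list[tuple[str, str, int]] = []
    for rec, fishway in sorted(
        entrance, key=lambda e: (e[0].date, e[0].hour, e[1].value)
    ):
        control_sid = control_by_slot.get((rec.date, rec.hour))
        slot = (fishway.value, rec.date.isoformat(), rec.hour)
        if control_sid is None:
            skipped.append(slot)
            continue
        diff = concentrations[rec.sample_id] - concentrations[control_sid]
        values.append(np.maximum(diff.to_numpy(), 0.0))
        columns.append(slot)
    attributed = pd.DataFrame(
        np.column_stack(values) if values else np.empty((len(concentrations.index), 0)),
        index=concentrations.index,
        columns=pd.MultiIndex.from_tuples(columns, names=SLOT_LEVELS)
        if columns
        else pd.MultiIndex.from_arrays([[], [], []], names=SLOT_LEVELS),
    )
    return AttributionResult(attributed=attributed, skipped_slots=skipped)


@dataclass
class DetectionMatrix:
    """Boolean detections per (taxon, slot) with the threshold that made them."""

    detected: pd.DataFrame  # same shape as the attributed table, bool
    threshold: float

    @property
    def richness(self) -> pd.Series:
        """Number of detected taxa per (fishway, date, hour) slot."""
        return self.detected.sum(axis=0)


def detect_species(attributed: pd.DataFrame, threshold: float = 0.0) -> DetectionMatrix:
    """Detection iff attributed concentration strictly exceeds ``threshold``.

    The default 0 treats any positive attributable signal as a detection;
    richness per slot is the column sum of the boolean matrix and is
    non-increasing in the threshold.
    """
    if threshold < 0:
        raise ValueError("detection threshold must be >= 0")
    return DetectionMatrix(detected=attributed > threshold, threshold=threshold)
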