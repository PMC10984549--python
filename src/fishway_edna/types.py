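"""Domain types for the fishway eDNA monitoring pipeline.

The study system is a river intake dam with three parallel fishways of
different hydraulic character (an ice-harbor type with high discharge and
velocity, a stair type, and a low-flow rock-ramp type), each sampled for
eDNA at its downstream entrance (stations st2-st4) while a single upstream
station (st1) measures the background eDNA flowing into all three.  Trap
surveys at the upstream end of each fishway provide the capture comparator.

Everything downstream of raw reads is expressed in terms of these types:
species x sample read-count tables, per-sample metadata, capture records,
and species trait assignments (focal species, usage groups G1-G4,
midwater/benthic lifestyle).
"""

from __future__ import annotations

import datetime
import enum
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Optional, Sequence

import numpy as np
import pandas as pd


class Station(str, enum.Enum):
    ST1 = "st1"  # upstream control, above the split into the three fishways
    ST2 = "st2"
    ST3 = "st3"
    ST4 = "st4"


class FishwayType(str, enum.Enum):
    ICE_HARBOR = "ice_harbor"
    STAIR = "stair"
    ROCK_RAMP = "rock_ramp"


class Group(str, enum.Enum):
    """Fishway-usage group of a non-focal taxon.

    G1: mainly the ice-harbor fishway; G2: ice-harbor and stair; G3: mainly
    the rock-ramp fishway; G4: no clear fishway preference.  Focal taxa are
    reported individually rather than through a group.
    """

    FOCAL = "focal"
    G1 = "G1"
    G2 = "G2"
    G3 = "G3"
    G4 = "G4"


class Lifestyle(str, enum.Enum):
    MIDWATER = "midwater"
    BENTHIC = "benthic"
    UNASSIGNED = "unassigned"


#: The five focal species reported individually in composition and
#: per-species concordance analyses.
FOCAL_SPECIES: tuple[str, ...] = (
    "O. platypus",
    "T. hakonensis",
    "P. altivelis",
    "C. biwae",
    "R. kurodai",
)

#: Delimiter used when indistinguishable candidate species are merged into a
#: single taxon label.  Merged labels are never split downstream.
MERGED_LABEL_DELIMITER = " / "


@dataclass(frozen=True)
class FishwaySpec:
    """Hydraulic description of one fishway.

    discharge in m^3/s, velocities in m/s, length in m.
    """

    name: FishwayType
    discharge: float
    velocity_min: float
    velocity_max: float
    length: float

    def __post_init__(self) -> None:
        if self.discharge <= 0:
            raise ValueError(f"{self.name}: discharge must be > 0")
        if not (0 < self.velocity_min <= self.velocity_max):
            raise ValueError(f"{self.name}: need 0 < velocity_min <= velocity_max")
        if self.length <= 0:
            raise ValueError(f"{self.name}: length must be > 0")

    @property
    def mean_velocity(self) -> float:
        return 0.5 * (self.velocity_min + self.velocity_max)

    @property
    def residence_time_h(self) -> float:
        """Water transit time through the fishway, in hours."""
        return self.length / self.mean_velocity / 3600.0


#: Default hydraulic specs of the three fishways.
DEFAULT_FISHWAYS: dict[FishwayType, FishwaySpec] = {
    FishwayType.ICE_HARBOR: FishwaySpec(FishwayType.ICE_HARBOR, 1.637, 1.27, 2.43, 210.0),
    FishwayType.STAIR: FishwaySpec(FishwayType.STAIR, 0.133, 0.87, 1.05, 240.0),
    FishwayType.ROCK_RAMP: FishwaySpec(FishwayType.ROCK_RAMP, 0.071, 0.64, 0.64, 260.0),
}

#: Default station -> fishway mapping (configurable; the assignment of
#: station indices to fishway types is a survey-design convention).
DEFAULT_STATION_MAP: dict[Station, FishwayType] = {
    Station.ST2: FishwayType.ICE_HARBOR,
    Station.ST3: FishwayType.STAIR,
    Station.ST4: FishwayType.ROCK_RAMP,
}


@dataclass(frozen=True)
class SampleRecord:
    """Metadata of one water sample."""

    sample_id: str
    station: Station
    date: datetime.date
    hour: int
    volume: float = 1.0  # liters filtered
    dilution: float = 1.0  # template dilution factor applied during analysis
    flood_excluded: bool = False

    def __post_init__(self) -> None:
        if not 9 <= self.hour <= 17:
            raise ValueError(f"{self.sample_id}: hour {self.hour} outside 9-17")
        if self.volume <= 0:
            raise ValueError(f"{self.sample_id}: volume must be > 0")
        if self.dilution < 1:
            raise ValueError(f"{self.sample_id}: dilution must be >= 1")


@dataclass(frozen=True)
class SpeciesTaxon:
    """A taxon label as it appears in read tables, with trait assignments."""

    label: str
    group: Group = Group.G4
    focal_name: Optional[str] = None
    lifestyle: Lifestyle = Lifestyle.UNASSIGNED

    def __post_init__(self) -> None:
        if self.group is Group.FOCAL:
            if self.focal_name not in FOCAL_SPECIES:
                raise ValueError(
                    f"{self.label}: focal taxa must carry a focal_name from "
                    f"{FOCAL_SPECIES}, got {self.focal_name!r}"
                )
        elif self.focal_name is not None:
            raise ValueError(f"{self.label}: focal_name set on non-focal taxon")


@dataclass(frozen=True)
class CaptureRecord:
    """One hourly trap record: count of one taxon in one fishway basket."""

    fishway: FishwayType
    date: datetime.date
    hour: int
    taxon: str
    count: int

    def __post_init__(self) -> None:
        if not 10 <= self.hour <= 17:
            raise ValueError(f"capture hour {self.hour} outside survey slots 10-17")
        if self.count < 0:
            raise ValueError("capture count must be >= 0")


@dataclass(frozen=True)
class SamplingDesignTerm:
    """One term of the water-sampling design: sites x times/day x days."""

    sites: int
    times_per_day: int
    days: int

    def __post_init__(self) -> None:
        for name in ("sites", "times_per_day", "days"):
            if getattr(self, name) < 1:
                raise ValueError(f"{name} must be >= 1")

    @property
    def n_samples(self) -> int:
        return self.sites * self.times_per_day * self.days


class ReadCountTable:
    """Species x sample table of nonnegative integer read counts.

    Thin wrapper over a pandas DataFrame (rows = taxon labels, columns =
    sample ids) that enforces the table invariants at construction.
    """

    def __init__(self, counts: pd.DataFrame):
        if counts.index.has_duplicates:
            dupes = counts.index[counts.index.duplicated()].unique().tolist()
            raise ValueError(f"duplicate taxon labels: {dupes}")
        if counts.columns.has_duplicates:
            dupes = counts.columns[counts.columns.duplicated()].unique().tolist()
            raise ValueError(f"duplicate sample ids: {dupes}")
        values = counts.to_numpy()
        if values.size and not np.issubdtype(values.dtype, np.integer):
            if not np.all(np.equal(np.mod(values, 1), 0)):
                raise ValueError("read counts must be integral")
        if values.size and (values < 0).any():
            rows, cols = np.nonzero(values < 0)
            first = (counts.index[rows[0]], counts.columns[cols[0]])
            raise ValueError(f"negative read count at {first}")
        self.counts = counts.astype(np.int64)
        self.counts.index.name = "taxon"

    @property
    def taxa(self) -> list[str]:
        return list(self.counts.index)

    @property
    def samples(self) -> list[str]:
        return list(self.counts.columns)

    @property
    def shape(self) -> tuple[int, int]:
        return self.counts.shape

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, ReadCountTable):
            return NotImplemented
        return self.counts.equals(other.counts)

    def __repr__(self) -> str:
        return f"ReadCountTable({self.shape[0]} taxa x {self.shape[1]} samples)"


def traits_by_label(taxa: Iterable[SpeciesTaxon]) -> dict[str, SpeciesTaxon]:
    out: dict[str, SpeciesTaxon] = {}
    for t in taxa:
        if t.label in out:
            raise ValueError(f"duplicate taxon label {t.label!r}")
        out[t.label] = t
    return out
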