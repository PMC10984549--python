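"""TSV readers/writers for all pipeline tables, with row-level validation.

All files are UTF-8 TSV with a header row.  Dates are ISO-8601 strings;
hours are integer slots (the survey operates hourly).  Parsing errors are
reported with the offending file, row and column so that malformed field
sheets are caught before any analysis runs.
"""

from __future__ import annotations

import datetime
from pathlib import Path
from typing import Iterable, Sequence, Union

import pandas as pd

from .types import (
    CaptureRecord,
    FishwayType,
    Group,
    Lifestyle,
    ReadCountTable,
    SampleRecord,
    SpeciesTaxon,
    Station,
)

PathLike = Union[str, Path]


class ValidationError(ValueError):
    """Raised when an input table violates its schema or invariants."""


def _require_columns(df: pd.DataFrame, required: Sequence[str], path: PathLike) -> None:
    missing = [c for c in required if c not in df.columns]
    if missing:
        raise ValidationError(f"{path}: missing column(s) {missing}")


def _parse_date(value: str, where: str) -> datetime.date:
    try:
        return datetime.date.fromisoformat(str(value))
    except ValueError as exc:
        raise ValidationError(f"{where}: bad ISO date {value!r}") from exc


# ---------------------------------------------------------------------------
# Read-count tables

def read_count_table(path: PathLike) -> ReadCountTable:
    """Read a species x sample TSV (first column ``taxon``) into a table."""
    df = pd.read_csv(path, sep="\t", dtype=str)
    _require_columns(df, ["taxon"], path)
    df = df.set_index("taxon")
    try:
        counts = df.apply(pd.to_numeric)
    except ValueError as exc:
        raise ValidationError(f"{path}: non-numeric read count: {exc}") from exc
    try:
        return ReadCountTable(counts)
    except ValueError as exc:
        raise ValidationError(f"{path}: {exc}") from exc


def write_count_table(table: ReadCountTable, path: PathLike) -> None:
    table.counts.to_csv(path, sep="\t")


# ---------------------------------------------------------------------------
# Sample metadata

SAMPLE_COLUMNS = ["sample_id", "station", "date", "hour", "volume", "dilution", "flood_excluded"]


def read_samples(path: PathLike) -> list[SampleRecord]:
    df = pd.read_csv(path, sep="\t", dtype=str)
    _require_columns(df, SAMPLE_COLUMNS, path)
    records: list[SampleRecord] = []
    seen: set[str] = set()
    for i, row in df.iterrows():
        where = f"{path} row {i + 2}"  # +2: header + 1-based
        sid = str(row["sample_id"])
        if sid in seen:
            raise ValidationError(f"{where}: duplicate sample_id {sid!r}")
        seen.add(sid)
        try:
            station = Station(str(row["station"]))
        except ValueError as exc:
            raise ValidationError(f"{where}: unknown station {row['station']!r}") from exc
        try:
            records.append(
                SampleRecord(
                    sample_id=sid,
                    station=station,
                    date=_parse_date(row["date"], where),
                    hour=int(row["hour"]),
                    volume=float(row["volume"]),
                    dilution=float(row["dilution"]),
                    flood_excluded=str(row["flood_excluded"]).lower() in ("true", "1", "yes"),
                )
            )
        except ValueError as exc:
            raise ValidationError(f"{where}: {exc}") from exc
    return records


def write_samples(samples: Iterable[SampleRecord], path: PathLike) -> None:
    rows = [
        {
            "sample_id": s.sample_id,
            "station": s.station.value,
            "date": s.date.isoformat(),
            "hour": s.hour,
            "volume": s.volume,
            "dilution": s.dilution,
            "flood_excluded": s.flood_excluded,
        }
        for s in samples
    ]
    pd.DataFrame(rows, columns=SAMPLE_COLUMNS).to_csv(path, sep="\t", index=False)


# ---------------------------------------------------------------------------
# Capture records

CAPTURE_COLUMNS = ["fishway", "date", "hour", "taxon", "count"]


def read_captures(path: PathLike) -> list[CaptureRecord]:
    df = pd.read_csv(path, sep="\t", dtype=str)
    _require_columns(df, CAPTURE_COLUMNS, path)
    records: list[CaptureRecord] = []
    for i, row in df.iterrows():
        where = f"{path} row {i + 2}"
        try:
            fishway = FishwayType(str(row["fishway"]))
        except ValueError as exc:
            raise ValidationError(f"{where}: unknown fishway {row['fishway']!r}") from exc
        try:
            records.append(
                CaptureRecord(
                    fishway=fishway,
                    date=_parse_date(row["date"], where),
                    hour=int(row["hour"]),
                    taxon=str(row["taxon"]),
                    count=int(row["count"]),
                )
            )
        except ValueError as exc:
            raise ValidationError(f"{where}: {exc}") from exc
    return records


def write_captures(captures: Iterable[CaptureRecord], path: PathLike) -> None:
    rows = [
        {
            "fishway": c.fishway.value,
            "date": c.date.isoformat(),
            "hour": c.hour,
            "taxon": c.taxon,
            "count": c.count,
        }
        for c in captures
    ]
    pd.DataFrame(rows, columns=CAPTURE_COLUMNS).to_csv(path, sep="\t", index=False)


# ---------------------------------------------------------------------------
# Species trait table

TRAIT_COLUMNS = ["taxon", "group", "focal_name", "lifestyle"]


def read_traits(path: PathLike) -> list[SpeciesTaxon]:
    df = pd.read_csv(path, sep="\t", dtype=str, keep_default_na=False)
    _require_columns(df, TRAIT_COLUMNS, path)
    taxa: list[SpeciesTaxon] = []
    seen: set[str] = set()
    for i, row in df.iterrows():
        where = f"{path} row {i + 2}"
        label = str(row["taxon"])
        if label in seen:
            raise ValidationError(f"{where}: duplicate taxon {label!r}")
        seen.add(label)
        try:
            taxa.append(
                SpeciesTaxon(
                    label=label,
                    group=Group(row["group"]),
                    focal_name=row["focal_name"] or None,
                    lifestyle=Lifestyle(row["lifestyle"] or "unassigned"),
                )
            )
        except ValueError as exc:
            raise ValidationError(f"{where}: {exc}") from exc
    return taxa


def write_traits(taxa: Iterable[SpeciesTaxon], path: PathLike) -> None:
    rows = [
        {
            "taxon": t.label,
            "group": t.group.value,
            "focal_name": t.focal_name or "",
            "lifestyle": t.lifestyle.value,
        }
        for t in taxa
    ]
    pd.DataFrame(rows, columns=TRAIT_COLUMNS).to_csv(path, sep="\t", index=False)
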