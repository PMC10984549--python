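"""Per-fishway composition profiles from eDNA and from captures.

Case 1 reports the share of the five focal species individually and pools
every other taxon into its fishway-usage group (G1-G4).  Case 2 refines
Case 1 by splitting G2 and G3 into midwater (middle-level swimming) and
benthic (bottom-dwelling) subcategories, the axis along which the low-flow
rock-ramp fishway differs most from the other two.

eDNA profiles average the per-day share vectors over the index days (not
pooled reads): each analysed day contributes one compositional observation.
Capture profiles pool the total individuals over the whole survey period.
"""

from __future__ import annotations

import datetime
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

from .types import (
    FOCAL_SPECIES,
    CaptureRecord,
    FishwayType,
    Group,
    Lifestyle,
    SpeciesTaxon,
)

CASE1_CATEGORIES: tuple[str, ...] = FOCAL_SPECIES + ("G1", "G2", "G3", "G4")
#: Case 2 replaces G2 and G3 by lifestyle subcategories.
SPLIT_GROUPS = ("G2", "G3")
CASE2_CATEGORIES: tuple[str, ...] = FOCAL_SPECIES + (
    "G1",
    "G2_midwater", "G2_benthic",
    "G3_midwater", "G3_benthic",
    "G4",
)


def category_of(label: str, traits: Mapping[str, SpeciesTaxon]) -> str:
    """Case 1 category of a taxon: its focal name, or its group."""
    t = traits.get(label)
    if t is None:
        return Group.G4.value  # unknown species default to the no-preference group
    if t.group is Group.FOCAL:
        return t.focal_name
    return t.group.value


@dataclass
class CompositionProfile:
    fishway: FishwayType
    source: str  # "edna" | "capture"
    case: int
    proportions: pd.Series  # indexed by category, sums to 1
    taxon_shares: pd.Series  # underlying per-taxon shares, sums to 1
    n_days_used: int = 0
    skipped_days: list[str] = field(default_factory=list)


def _aggregate(taxon_shares: pd.Series, traits: Mapping[str, SpeciesTaxon]) -> pd.Series:
    props = pd.Series(0.0, index=list(CASE1_CATEGORIES))
    for label, share in taxon_shares.items():
        props[category_of(label, traits)] += share
    return props


def edna_composition(
    attributed: pd.DataFrame,
    fishway: FishwayType,
    index_days: Sequence[datetime.date],
    traits: Mapping[str, SpeciesTaxon],
) -> CompositionProfile:
    """Mean of per-day attributed-signal share vectors over the index days.

    For each day the taxon shares are the day's attributed concentrations
    (summed over that day's slots for the fishway) divided by their total;
    days with zero total signal are skipped and recorded.  Raises when every
    index day is signal-free.
    """
    if len(index_days) == 0:
        raise ValueError("index_days must be nonempty")
    day_vectors: list[pd.Series] = []
    skipped: list[str] = []
    for day in index_days:
        iso = day.isoformat()
        cols = [
            c for c in attributed.columns
            if c[0] == fishway.value and c[1] == iso
        ]
        if not cols:
            raise KeyError(f"no attributed slot for {fishway.value} on {iso}")
        totals = attributed[cols].sum(axis=1)
        total = float(totals.sum())
        if total <= 0:
            skipped.append(iso)
            continue
        day_vectors.append(totals / total)
    if not day_vectors:
        raise ValueError(f"no signal: all {len(index_days)} index days zero-total")
    taxon_shares = pd.concat(day_vectors, axis=1).mean(axis=1)
    return CompositionProfile(
        fishway=fishway,
        source="edna",
        case=1,
        proportions=_aggregate(taxon_shares, traits),
        taxon_shares=taxon_shares,
        n_days_used=len(day_vectors),
        skipped_days=skipped,
    )


def capture_composition(
    captures: Iterable[CaptureRecord],
    fishway: FishwayType,
    period: Iterable[datetime.date],
    traits: Mapping[str, SpeciesTaxon],
) -> CompositionProfile:
    """Shares of total individuals caught in the fishway, pooled over the period."""
    days = set(period)
    if not days:
        raise ValueError("period must cover at least one day")
    totals: dict[str, int] = {}
    for rec in captures:
        if rec.fishway is fishway and rec.date in days:
            totals[rec.taxon] = totals.get(rec.taxon, 0) + rec.count
    grand = sum(totals.values())
    if grand == 0:
        raise ValueError(f"no catch in {fishway.value} over the given period")
    taxon_shares = pd.Series({t: n / grand for t, n in sorted(totals.items())})
    return CompositionProfile(
        fishway=fishway,
        source="capture",
        case=1,
        proportions=_aggregate(taxon_shares, traits),
        taxon_shares=taxon_shares,
        n_days_used=len(days),
    )


def lifestyle_split(
    profile: CompositionProfile,
    traits: Mapping[str, SpeciesTaxon],
) -> CompositionProfile:
    """Case 2: split G2 and G3 proportions into midwater/benthic subcategories.

    Each split group's proportion is redistributed across the two lifestyles
    in proportion to the underlying per-taxon shares; every other category is
    untouched, so summing each pair of subcategories recovers the Case 1
    profile exactly.  A G2/G3 taxon carrying signal with an unassigned
    lifestyle is an error.
    """
    props = pd.Series(0.0, index=list(CASE2_CATEGORIES))
    for cat in CASE1_CATEGORIES:
        if cat not in SPLIT_GROUPS:
            props[cat] = profile.proportions[cat]
    for label, share in profile.taxon_shares.items():
        t = traits.get(label)
        cat = category_of(label, traits)
        if cat not in SPLIT_GROUPS:
            continue
        if share > 0 and (t is None or t.lifestyle is Lifestyle.UNASSIGNED):
            raise ValueError(f"taxon {label!r} in {cat} has no lifestyle assignment")
        if t is not None and t.lifestyle is not Lifestyle.UNASSIGNED:
            props[f"{cat}_{t.lifestyle.value}"] += share
    return CompositionProfile(
        fishway=profile.fishway,
        source=profile.source,
        case=2,
        proportions=props,
        taxon_shares=profile.taxon_shares,
        n_days_used=profile.n_days_used,
        skipped_days=list(profile.skipped_days),
    )


def merge_lifestyle(profile: CompositionProfile) -> pd.Series:
    """Collapse a Case 2 profile back to Case 1 categories (inverse of the split)."""
    if profile.case != 2:
        raise ValueError("merge_lifestyle expects a Case 2 profile")
    props = pd.Series(0.0, index=list(CASE1_CATEGORIES))
    for cat in CASE1_CATEGORIES:
        if cat in SPLIT_GROUPS:
            props[cat] = (
                profile.proportions[f"{cat}_midwater"] + profile.proportions[f"{cat}_benthic"]
            )
        else:
            props[cat] = profile.proportions[cat]
    return props
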