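"""Synthetic fishway/eDNA/capture data with known ground truth.

The generator emulates the study system end to end: species-specific
migration pulses through three hydraulically distinct fishways, eDNA
shedding diluted by fishway discharge, a fixed-depth multinomial
sequencing draw per water sample, and Poisson trap catches at the upstream
end of each fishway.  Every stage is seed-deterministic, and the generating
quantities (migrant counts, true concentrations) are returned alongside
the observables so that each pipeline stage can be tested against truth.

Model summary, per species s, fishway f, day d, hour h:

* daily migrants  M_s(d) ~ Poisson(mu_s(d)),
  mu_s(d) = daily_migrants_max * exp(-(d - peak)^2 / (2 sigma^2)),
  sigma = migration_duration_days / 4 (the pulse is ~95% contained in
  peak +/- duration/2); split over (fishway, hour) by a multinomial with
  weights preference_f x uniform hours.
* eDNA: residence time tau_f = length / mean velocity.  The standing stock
  in the fishway is (migrants/hour) * tau_f individuals; the entrance
  concentration adds their shedding, decayed over tau_f and diluted by the
  fishway discharge:
      C_entrance = C_background + m_h * tau_f * shed * exp(-decay * tau_f)
                                  / (Q * 3600 * 1000)
  with Q in m^3/s (so Q * 3.6e6 is L/h) and concentration in
  reads-equivalent units per liter (an arbitrary linear scale).
* reads: counts ~ Multinomial(depth, p), p proportional to per-species
  concentration at the station; the recorded dilution factor scales with
  total sample DNA (concentrated samples are diluted more before PCR), so
  count * dilution / volume recovers a common linear scale across samples.
* captures: hourly catch ~ Poisson(migrants_that_hour * trap_efficiency),
  with an optional transit lag for benthic species and an exact
  (deterministic) mode for fixtures.
"""

from __future__ import annotations

import datetime
from dataclasses import dataclass, field, replace
from typing import Iterable, Mapping, Optional, Sequence

import numpy as np
import pandas as pd

from .read_processing import MIFISH_U, PrimerSet, ReadPair, revcomp
from .types import (
    DEFAULT_FISHWAYS,
    DEFAULT_STATION_MAP,
    FishwaySpec,
    FishwayType,
    Group,
    Lifestyle,
    ReadCountTable,
    SampleRecord,
    CaptureRecord,
    SpeciesTaxon,
    Station,
)

SAMPLING_HOURS: tuple[int, ...] = tuple(range(9, 18))  # water samples 9:00-17:00
CAPTURE_HOURS: tuple[int, ...] = tuple(range(10, 18))  # baskets checked 10:00-17:00
LITERS_PER_M3_HOUR = 3600.0 * 1000.0  # m^3/s -> L/h


@dataclass(frozen=True)
class SpeciesTraits:
    """Generating traits of one simulated species."""

    taxon: str
    shedding_rate: float  # eDNA units per individual per hour
    migration_peak_day: float  # day index within the survey period
    migration_duration_days: float
    daily_migrants_max: float  # peak of the seasonal mean, individuals/day
    fishway_preference: Mapping[FishwayType, float]
    trap_efficiency: float = 0.5
    lifestyle: Lifestyle = Lifestyle.MIDWATER
    group: Group = Group.G4
    focal_name: Optional[str] = None

    def __post_init__(self) -> None:
        if self.shedding_rate < 0 or self.daily_migrants_max < 0:
            raise ValueError(f"{self.taxon}: rates must be >= 0")
        if not 0 <= self.trap_efficiency <= 1:
            raise ValueError(f"{self.taxon}: trap_efficiency must be in [0, 1]")
        w = np.array([self.fishway_preference.get(f, 0.0) for f in FishwayType])
        if (w < 0).any() or not np.isclose(w.sum(), 1.0):
            raise ValueError(f"{self.taxon}: fishway preference weights must be >= 0 and sum to 1")

    def to_taxon(self) -> SpeciesTaxon:
        return SpeciesTaxon(
            label=self.taxon, group=self.group,
            focal_name=self.focal_name, lifestyle=self.lifestyle,
        )

    def seasonal_mean(self, day_index: int) -> float:
        sigma = self.migration_duration_days / 4.0
        z = (day_index - self.migration_peak_day) / sigma
        return self.daily_migrants_max * float(np.exp(-0.5 * z * z))


@dataclass
class SimConfig:
    """Study conditions for one simulated survey season."""

    species: list[SpeciesTraits]
    n_days: int = 29
    start_date: datetime.date = datetime.date(2021, 6, 6)
    hours: tuple[int, ...] = SAMPLING_HOURS
    read_depth: int = 100_000
    background: Mapping[str, float] = field(default_factory=dict)  # units/L at st1
    decay_rate: float = 0.1  # per hour, first-order decay inside the fishway
    fishways: Mapping[FishwayType, FishwaySpec] = field(
        default_factory=lambda: dict(DEFAULT_FISHWAYS)
    )
    station_map: Mapping[Station, FishwayType] = field(
        default_factory=lambda: dict(DEFAULT_STATION_MAP)
    )
    trap_deterministic: bool = False
    benthic_lag_hours: int = 0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.read_depth <= 0:
            raise ValueError("read_depth must be > 0")
        if self.decay_rate < 0:
            raise ValueError("decay_rate must be >= 0")
        for spec in self.fishways.values():
            if spec.discharge <= 0:
                raise ValueError("fishway discharge must be > 0")

    def dates(self) -> list[datetime.date]:
        return [self.start_date + datetime.timedelta(days=i) for i in range(self.n_days)]


# ---------------------------------------------------------------------------
# Migration

def simulate_migration(
    species: Sequence[SpeciesTraits],
    n_days: int,
    seed: int,
    start_date: datetime.date = datetime.date(2021, 6, 6),
    hours: Sequence[int] = SAMPLING_HOURS,
) -> pd.DataFrame:
    """Hourly migrant counts per (species, fishway, date, hour).

    Daily totals are Poisson around the Gaussian seasonal mean; each day's
    migrants are split over (fishway, hour) cells by a multinomial with
    fishway-preference x uniform-hour weights.  Deterministic per seed.
    """
    rng = np.random.default_rng(seed)
    fishway_list = list(FishwayType)
    n_cells = len(fishway_list) * len(hours)
    rows: list[tuple] = []
    for traits in species:
        weights = np.repeat(
            [traits.fishway_preference.get(f, 0.0) for f in fishway_list], len(hours)
        ) / len(hours)
        for d in range(n_days):
            mu = traits.seasonal_mean(d)
            total = int(rng.poisson(mu)) if mu > 0 else 0
            if total == 0:
                continue
            cells = rng.multinomial(total, weights)
            date = start_date + datetime.timedelta(days=d)
            for idx in np.nonzero(cells)[0]:
                f = fishway_list[idx // len(hours)]
                h = hours[idx % len(hours)]
                rows.append((traits.taxon, f.value, date, int(h), int(cells[idx])))
    return pd.DataFrame(rows, columns=["species", "fishway", "date", "hour", "migrants"])


# ---------------------------------------------------------------------------
# eDNA concentrations (ground truth)

def edna_concentration(
    migrants: pd.DataFrame,
    species: Sequence[SpeciesTraits],
    fishways: Mapping[FishwayType, FishwaySpec],
    background: Mapping[str, float],
    decay_rate: float,
    dates: Sequence[datetime.date],
    hours: Sequence[int] = SAMPLING_HOURS,
) -> pd.DataFrame:
    """True entrance/control concentrations per (species, fishway, date, hour).

    Returns a long DataFrame with columns species, fishway, date, hour,
    migrants, entrance_conc, control_conc (units/L).  The control station
    carries the background concentration only.
    """
    for f, spec in fishways.items():
        if spec.discharge <= 0:
            raise ValueError(f"{f}: discharge must be > 0")
    mig = {
        (r.species, r.fishway, r.date, r.hour): r.migrants
        for r in migrants.itertuples(index=False)
    }
    rows = []
    for traits in species:
        bg = float(background.get(traits.taxon, 0.0))
        for f, spec in fishways.items():
            tau = spec.residence_time_h
            dilution_lph = spec.discharge * LITERS_PER_M3_HOUR
            retained = float(np.exp(-decay_rate * tau))
            for date in dates:
                for h in hours:
                    m = mig.get((traits.taxon, f.value, date, int(h)), 0)
                    added = m * tau * traits.shedding_rate * retained / dilution_lph
                    rows.append(
                        (traits.taxon, f.value, date, int(h), m, bg + added, bg)
                    )
    return pd.DataFrame(
        rows,
        columns=["species", "fishway", "date", "hour", "migrants",
                 "entrance_conc", "control_conc"],
    )


# ---------------------------------------------------------------------------
# Sequencing reads

def sample_reads(
    ground_truth: pd.DataFrame,
    depth: int,
    seed: int,
    station_map: Mapping[Station, FishwayType] = DEFAULT_STATION_MAP,
) -> tuple[ReadCountTable, list[SampleRecord]]:
    """Draw per-sample read counts from the true station concentrations.

    Each water sample yields ``depth`` reads distributed multinomially in
    proportion to the per-species concentration at its station (st1 sees
    the control concentration, st2-st4 the entrance concentration of their
    fishway).  The recorded dilution factor is total-DNA proportional
    (dilution = sample total / smallest positive sample total), so
    count * dilution / volume reconstructs concentrations on one common
    linear scale.  All-zero samples yield all-zero counts at dilution 1.
    """
    if depth <= 0:
        raise ValueError("depth must be > 0")
    rng = np.random.default_rng(seed)
    species = sorted(ground_truth["species"].unique())
    fishway_to_station = {f.value: st for st, f in station_map.items()}

    # Per-sample concentration vectors.
    conc_by_sample: dict[str, np.ndarray] = {}
    meta: dict[str, tuple[Station, datetime.date, int]] = {}
    gt = ground_truth.set_index(["species", "fishway", "date", "hour"])
    dates = sorted(ground_truth["date"].unique())
    hours = sorted(ground_truth["hour"].unique())
    fishway_values = sorted(ground_truth["fishway"].unique())
    entrance = gt["entrance_conc"]
    control = gt["control_conc"]
    for date in dates:
        for h in hours:
            # control station: background only (same for every fishway row)
            vec = np.array(
                [control.get((s, fishway_values[0], date, h), 0.0) for s in species]
            )
            sid = f"st1_{date.isoformat()}_{h:02d}"
            conc_by_sample[sid] = vec
            meta[sid] = (Station.ST1, date, h)
            for f in fishway_values:
                st = fishway_to_station.get(f)
                if st is None:
                    continue
                vec = np.array([entrance.get((s, f, date, h), 0.0) for s in species])
                sid = f"{st.value}_{date.isoformat()}_{h:02d}"
                conc_by_sample[sid] = vec
                meta[sid] = (st, date, h)

    totals = {sid: float(v.sum()) for sid, v in conc_by_sample.items()}
    positive = [t for t in totals.values() if t > 0]
    ref_total = min(positive) if positive else 1.0

    sample_ids = sorted(conc_by_sample)
    counts = np.zeros((len(species), len(sample_ids)), dtype=np.int64)
    records: list[SampleRecord] = []
    for j, sid in enumerate(sample_ids):
        vec, total = conc_by_sample[sid], totals[sid]
        if total > 0:
            counts[:, j] = rng.multinomial(depth, vec / total)
            dilution = max(1.0, total / ref_total)
        else:
            dilution = 1.0
        st, date, h = meta[sid]
        records.append(
            SampleRecord(sample_id=sid, station=st, date=date, hour=h,
                         volume=1.0, dilution=dilution)
        )
    table = ReadCountTable(
        pd.DataFrame(counts, index=pd.Index(species, name="taxon"), columns=sample_ids)
    )
    return table, records


# ---------------------------------------------------------------------------
# Trap captures

def sample_captures(
    migrants: pd.DataFrame,
    species: Sequence[SpeciesTraits],
    seed: int,
    deterministic: bool = False,
    benthic_lag_hours: int = 0,
) -> list[CaptureRecord]:
    """Hourly trap catches per fishway: Poisson(migrants x efficiency).

    In deterministic mode the catch is round(migrants x efficiency)
    exactly.  Benthic species are optionally lagged by a transit delay
    before reaching the upstream trap.  Catches are recorded in the basket
    slots 10:00-17:00 (arrival hours outside the slots are clamped).
    """
    rng = np.random.default_rng(seed)
    traits_by_name = {t.taxon: t for t in species}
    accum: dict[tuple, int] = {}
    for r in migrants.sort_values(["species", "fishway", "date", "hour"]).itertuples(index=False):
        traits = traits_by_name[r.species]
        if traits.trap_efficiency == 0:
            continue
        mean = r.migrants * traits.trap_efficiency
        catch = int(round(mean)) if deterministic else int(rng.poisson(mean))
        if catch == 0:
            continue
        lag = benthic_lag_hours if traits.lifestyle is Lifestyle.BENTHIC else 0
        hour = min(max(r.hour + lag, CAPTURE_HOURS[0]), CAPTURE_HOURS[-1])
        key = (FishwayType(r.fishway), r.date, hour, r.species)
        accum[key] = accum.get(key, 0) + catch
    return [
        CaptureRecord(fishway=f, date=d, hour=h, taxon=s, count=n)
        for (f, d, h, s), n in sorted(
            accum.items(), key=lambda kv: (kv[0][1], kv[0][2], kv[0][0].value, kv[0][3])
        )
    ]


# ---------------------------------------------------------------------------
# Synthetic amplicons (fixture generator for read processing)

BASES = np.frombuffer(b"ACGT", dtype=np.uint8)


def make_reference_set(
    n_species: int,
    insert_len: int = 120,
    seed: int = 0,
    label_prefix: str = "Species",
) -> dict[str, str]:
    """Random, mutually distant reference inserts (the 12S target region
    without primers), labelled ``Species_01`` ... deterministically."""
    rng = np.random.default_rng(seed)
    refs: dict[str, str] = {}
    for i in range(n_species):
        seq = rng.choice(BASES, size=insert_len).tobytes().decode()
        refs[f"{label_prefix}_{i + 1:02d}"] = seq
    return refs


def simulate_amplicons(
    references: Mapping[str, str],
    abundances: Mapping[str, Mapping[str, int]],
    error_rate: float = 0.0,
    seed: int = 0,
    read_len: int = 150,
    primer_set: PrimerSet = MIFISH_U,
    clean_quality: int = 40,
) -> list[ReadPair]:
    """Paired reads from primer-flanked amplicon constructs.

    ``abundances`` maps reference label -> {sample_id: read count}.  Each
    amplicon is forward primer + insert + revcomp(reverse primer); the
    forward read is its first ``read_len`` bases and the reverse read the
    reverse complement of its last ``read_len`` bases, so the pair overlaps
    whenever the amplicon is shorter than 2 x read_len.  With
    ``error_rate=0`` reads are exact at Phred ``clean_quality``; otherwise
    substitutions are drawn per base at ``error_rate`` and Phred scores are
    set consistently to round(-10 log10(error_rate)).
    """
    if error_rate < 0 or error_rate >= 1:
        raise ValueError("error_rate must be in [0, 1)")
    rng = np.random.default_rng(seed)
    quality = clean_quality if error_rate == 0 else max(2, int(round(-10 * np.log10(error_rate))))
    pairs: list[ReadPair] = []
    for label in sorted(abundances):
        if label not in references:
            raise KeyError(f"no reference for {label!r}")
        amplicon = primer_set.forward + references[label] + revcomp(primer_set.reverse)
        fwd_template = amplicon[:read_len]
        rev_template = revcomp(amplicon[-read_len:])
        for sample_id in sorted(abundances[label]):
            n = abundances[label][sample_id]
            if n < 0:
                raise ValueError(f"negative abundance for {label!r} in {sample_id!r}")
            for _ in range(n):
                fwd = _mutate(fwd_template, error_rate, rng)
                rev = _mutate(rev_template, error_rate, rng)
                q = (quality,)
                pairs.append(
                    ReadPair(
                        forward=fwd, reverse=rev,
                        forward_quals=q * len(fwd), reverse_quals=q * len(rev),
                        sample_id=sample_id,
                    )
                )
    return pairs


def _mutate(seq: str, error_rate: float, rng: np.random.Generator) -> str:
    if error_rate == 0:
        return seq
    arr = np.frombuffer(seq.encode(), dtype=np.uint8).copy()
    hits = np.nonzero(rng.random(arr.size) < error_rate)[0]
    for i in hits:
        choices = BASES[BASES != arr[i]]
        arr[i] = rng.choice(choices)
    return arr.tobytes().decode()


def write_paired_fastq(pairs: Sequence[ReadPair], fwd_path, rev_path, seed: Optional[int] = None) -> None:
    """Write Phred+33 FASTQ; the generating seed is recorded on every read
    header so files are self-describing."""
    tag = f" seed={seed}" if seed is not None else ""
    with open(fwd_path, "w", encoding="utf-8") as fh, open(rev_path, "w", encoding="utf-8") as rh:
        for i, p in enumerate(pairs, start=1):
            name = f"read{i} sample={p.sample_id}{tag}"
            fh.write(f"@{name}\n{p.forward}\n+\n"
                     + "".join(chr(q + 33) for q in p.forward_quals) + "\n")
            rh.write(f"@{name}\n{p.reverse}\n+\n"
                     + "".join(chr(q + 33) for q in p.reverse_quals) + "\n")


# ---------------------------------------------------------------------------
# Whole-study simulation

@dataclass
class SimResult:
    """Observables plus ground truth for one simulated season."""

    config: SimConfig
    ground_truth: pd.DataFrame
    count_table: ReadCountTable
    samples: list[SampleRecord]
    captures: list[CaptureRecord]
    traits: list[SpeciesTaxon]


def simulate_study(config: SimConfig, seed: Optional[int] = None) -> SimResult:
    """Run migration -> concentrations -> reads -> captures for one season.

    Substream seeds are derived from the master seed so the stages are
    independently reproducible.
    """
    master = config.seed if seed is None else seed
    ss = np.random.SeedSequence(master).spawn(3)
    sub = [int(s.generate_state(1)[0] % (2**31)) for s in ss]
    dates = config.dates()
    migrants = simulate_migration(
        config.species, config.n_days, seed=sub[0],
        start_date=config.start_date, hours=config.hours,
    )
    ground_truth = edna_concentration(
        migrants, config.species, config.fishways, config.background,
        config.decay_rate, dates, hours=config.hours,
    )
    table, samples = sample_reads(
        ground_truth, config.read_depth, seed=sub[1], station_map=config.station_map
    )
    captures = sample_captures(
        migrants, config.species, seed=sub[2],
        deterministic=config.trap_deterministic,
        benthic_lag_hours=config.benthic_lag_hours,
    )
    return SimResult(
        config=config,
        ground_truth=ground_truth,
        count_table=table,
        samples=samples,
        captures=captures,
        traits=[t.to_taxon() for t in config.species],
    )


# ---------------------------------------------------------------------------
# Canned communities

def default_species() -> list[SpeciesTraits]:
    """A community emulating the study system: the five focal species with
    their reported fishway preferences plus group representatives.

    Shedding rates are order-of-magnitude placeholders on an arbitrary
    linear scale (absolute eDNA copy numbers never enter the analysis).
    """
    I, S, R = FishwayType.ICE_HARBOR, FishwayType.STAIR, FishwayType.ROCK_RAMP

    def pref(i: float, s: float, r: float) -> dict[FishwayType, float]:
        return {I: i, S: s, R: r}

    return [
        SpeciesTraits("O. platypus", 1e6, 12, 16, 150, pref(0.16, 0.82, 0.02),
                      0.5, Lifestyle.MIDWATER, Group.FOCAL, "O. platypus"),
        SpeciesTraits("T. hakonensis", 2e6, 8, 6, 300, pref(0.70, 0.29, 0.01),
                      0.5, Lifestyle.MIDWATER, Group.FOCAL, "T. hakonensis"),
        SpeciesTraits("P. altivelis", 1e6, 10, 12, 400, pref(0.63, 0.36, 0.01),
                      0.5, Lifestyle.MIDWATER, Group.FOCAL, "P. altivelis"),
        SpeciesTraits("C. biwae", 8e5, 14, 20, 8, pref(0.02, 0.03, 0.95),
                      0.5, Lifestyle.BENTHIC, Group.FOCAL, "C. biwae"),
        SpeciesTraits("R. kurodai", 8e5, 12, 24, 60, pref(0.15, 0.15, 0.70),
                      0.5, Lifestyle.BENTHIC, Group.FOCAL, "R. kurodai"),
        SpeciesTraits("O. masou", 1.5e6, 9, 10, 20, pref(0.60, 0.35, 0.05),
                      0.5, Lifestyle.MIDWATER, Group.G1),
        SpeciesTraits("S. biwae", 1e6, 15, 18, 40, pref(0.45, 0.45, 0.10),
                      0.5, Lifestyle.MIDWATER, Group.G2),
        SpeciesTraits("P. nudiceps", 1e6, 16, 18, 35, pref(0.40, 0.50, 0.10),
                      0.5, Lifestyle.BENTHIC, Group.G2),
        SpeciesTraits("P. parva", 8e5, 13, 20, 15, pref(0.05, 0.10, 0.85),
                      0.5, Lifestyle.MIDWATER, Group.G3),
        SpeciesTraits("M. anguillicaudatus", 8e5, 13, 20, 30, pref(0.03, 0.07, 0.90),
                      0.5, Lifestyle.BENTHIC, Group.G3),
        SpeciesTraits("L. reissneri", 8e5, 15, 22, 12, pref(0.02, 0.08, 0.90),
                      0.5, Lifestyle.BENTHIC, Group.G3),
        SpeciesTraits("Z. platypus generalist", 9e5, 14, 24, 25, pref(0.34, 0.33, 0.33),
                      0.5, Lifestyle.MIDWATER, Group.G4),
    ]


def strong_signal_config(seed: int = 0, n_days: int = 20, depth: int = 100_000) -> SimConfig:
    """The recovery-benchmark regime: zero background, uniform strong
    shedding (so rank recovery targets migrant counts), no decay, 10
    species, trap efficiency 0.5."""
    base = default_species()[:10]
    species = [
        replace(t, shedding_rate=1e7, trap_efficiency=0.5) for t in base
    ]
    return SimConfig(
        species=species,
        n_days=n_days,
        read_depth=depth,
        background={},
        decay_rate=0.0,
        seed=seed,
    )
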