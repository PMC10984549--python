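"""Ground-truth simulator: migration, concentrations, reads, captures,
amplicons — determinism and distributional correctness."""

from __future__ import annotations

import dataclasses
import datetime

import numpy as np
import pandas as pd
import pytest

from fishway_edna import read_processing as rp
from fishway_edna import simulate as sim
from fishway_edna.types import FishwayType, Group, Lifestyle, Station

I, S, R = FishwayType.ICE_HARBOR, FishwayType.STAIR, FishwayType.ROCK_RAMP


def traits(**overrides) -> sim.SpeciesTraits:
    base = dict(
        taxon="fish", shedding_rate=1e6, migration_peak_day=5,
        migration_duration_days=8, daily_migrants_max=100,
        fishway_preference={I: 0.5, S: 0.3, R: 0.2},
        trap_efficiency=0.5, lifestyle=Lifestyle.MIDWATER, group=Group.G4,
    )
    base.update(overrides)
    return sim.SpeciesTraits(**base)


class TestMigration:
    def test_zero_max_gives_all_zero(self):
        out = sim.simulate_migration([traits(daily_migrants_max=0)], 10, seed=1)
        assert out.empty or (out["migrants"] == 0).all()

    def test_seed_determinism(self):
        a = sim.simulate_migration([traits()], 10, seed=42)
        b = sim.simulate_migration([traits()], 10, seed=42)
        pd.testing.assert_frame_equal(a, b)
        c = sim.simulate_migration([traits()], 10, seed=43)
        assert not a.equals(c)

    def test_monte_carlo_mean_matches_closed_form(self):
        t = traits()
        n_days = 10
        expected = sum(t.seasonal_mean(d) for d in range(n_days))
        totals = [
            sim.simulate_migration([t], n_days, seed=s)["migrants"].sum()
            for s in range(500)
        ]
        assert np.mean(totals) == pytest.approx(expected, rel=0.05)

    def test_preference_weights_respected(self):
        t = traits(fishway_preference={I: 1.0, S: 0.0, R: 0.0})
        out = sim.simulate_migration([t], 10, seed=7)
        assert set(out["fishway"]) == {I.value}


class TestConcentration:
    def _gt(self, t, migrants, decay=0.0, background=None):
        dates = [datetime.date(2021, 6, 6)]
        return sim.edna_concentration(
            migrants, [t], sim.DEFAULT_FISHWAYS, background or {}, decay, dates,
            hours=(15,),
        )

    def test_zero_shedding_equals_background(self):
        t = traits(shedding_rate=0.0)
        mig = sim.simulate_migration([t], 1, seed=1, hours=(15,))
        gt = self._gt(t, mig, background={"fish": 0.7})
        assert (gt["entrance_conc"] == 0.7).all()
        assert (gt["control_conc"] == 0.7).all()

    def test_closed_form_single_migrant(self):
        # one migrant in the 15:00 hour at the stair fishway, no decay
        t = traits(shedding_rate=1e6)
        mig = pd.DataFrame(
            [("fish", S.value, datetime.date(2021, 6, 6), 15, 1)],
            columns=["species", "fishway", "date", "hour", "migrants"],
        )
        gt = self._gt(t, mig).set_index("fishway")
        spec = sim.DEFAULT_FISHWAYS[S]
        tau = spec.length / spec.mean_velocity / 3600.0
        expected = 1 * tau * 1e6 / (spec.discharge * 3600.0 * 1000.0)
        assert gt.loc[S.value, "entrance_conc"] == pytest.approx(expected, rel=1e-12)
        assert gt.loc[I.value, "entrance_conc"] == 0.0

    def test_doubling_discharge_halves_added_term(self):
        t = traits()
        mig = pd.DataFrame(
            [("fish", S.value, datetime.date(2021, 6, 6), 15, 3)],
            columns=["species", "fishway", "date", "hour", "migrants"],
        )
        spec = sim.DEFAULT_FISHWAYS[S]
        doubled = {
            **sim.DEFAULT_FISHWAYS,
            S: dataclasses.replace(spec, discharge=2 * spec.discharge),
        }
        dates = [datetime.date(2021, 6, 6)]
        gt1 = sim.edna_concentration(mig, [t], sim.DEFAULT_FISHWAYS, {}, 0.0, dates, hours=(15,))
        gt2 = sim.edna_concentration(mig, [t], doubled, {}, 0.0, dates, hours=(15,))
        v1 = gt1.set_index("fishway").loc[S.value, "entrance_conc"]
        v2 = gt2.set_index("fishway").loc[S.value, "entrance_conc"]
        assert v1 == pytest.approx(2 * v2, rel=1e-12)

    def test_decay_reduces_signal(self):
        t = traits()
        mig = sim.simulate_migration([t], 3, seed=2, hours=(15,))
        dates = [datetime.date(2021, 6, 6) + datetime.timedelta(days=i) for i in range(3)]
        g0 = sim.edna_concentration(mig, [t], sim.DEFAULT_FISHWAYS, {}, 0.0, dates, hours=(15,))
        g1 = sim.edna_concentration(mig, [t], sim.DEFAULT_FISHWAYS, {}, 5.0, dates, hours=(15,))
        assert (g1["entrance_conc"] <= g0["entrance_conc"] + 1e-15).all()

    def test_zero_discharge_rejected(self):
        with pytest.raises(ValueError):
            dataclasses.replace(sim.DEFAULT_FISHWAYS[S], discharge=0.0)


class TestSampleReads:
    def _ground_truth(self, species_conc: dict[str, float]):
        rows = []
        for taxon, conc in species_conc.items():
            for f in FishwayType:
                rows.append((taxon, f.value, datetime.date(2021, 6, 6), 15, 0, conc, 0.0))
        return pd.DataFrame(
            rows, columns=["species", "fishway", "date", "hour", "migrants",
                           "entrance_conc", "control_conc"],
        )

    def test_single_species_gets_all_depth(self):
        table, samples = sim.sample_reads(self._ground_truth({"only": 3.0}), 1000, seed=1)
        entrance_cols = [s.sample_id for s in samples if s.station is not Station.ST1]
        assert (table.counts.loc["only", entrance_cols] == 1000).all()

    def test_column_sums_equal_depth(self):
        gt = self._ground_truth({"a": 1.0, "b": 2.0, "c": 0.5})
        table, samples = sim.sample_reads(gt, 5000, seed=2)
        sums = table.counts.sum(axis=0)
        for s in samples:
            expected = 0 if s.station is Station.ST1 else 5000  # control has no eDNA here
            assert sums[s.sample_id] == expected

    def test_all_zero_sample_yields_zero_counts(self):
        table, samples = sim.sample_reads(self._ground_truth({"a": 0.0}), 100, seed=3)
        assert (table.counts.to_numpy() == 0).all()
        assert all(s.dilution == 1.0 for s in samples)

    def test_proportions_converge_at_high_depth(self):
        conc = {"a": 5.0, "b": 3.0, "c": 2.0}
        depth = 10**6
        table, samples = sim.sample_reads(self._ground_truth(conc), depth, seed=4)
        sid = [s.sample_id for s in samples if s.station is Station.ST2][0]
        total = sum(conc.values())
        for taxon, c in conc.items():
            p = c / total
            sigma = np.sqrt(p * (1 - p) / depth)
            assert abs(table.counts.loc[taxon, sid] / depth - p) < 3 * sigma

    def test_normalization_recovers_common_scale(self):
        """count * dilution / volume must be proportional to the true
        concentration with one constant across samples."""
        gt = self._ground_truth({"a": 4.0, "b": 1.0})
        # add a second slot with different total DNA
        gt2 = self._ground_truth({"a": 0.5, "b": 0.5})
        gt2["hour"] = 16
        table, samples = sim.sample_reads(pd.concat([gt, gt2], ignore_index=True),
                                          10**6, seed=5)
        by_id = {s.sample_id: s for s in samples}
        est = {}
        for sid in table.samples:
            s = by_id[sid]
            if s.station is Station.ST2:
                est[s.hour] = table.counts["" + sid] * s.dilution / s.volume
        ratio = est[15].sum() / est[16].sum()
        assert ratio == pytest.approx(5.0 / 1.0, rel=0.01)


class TestSampleCaptures:
    def _migrants(self, n=100):
        return pd.DataFrame(
            [("fish", S.value, datetime.date(2021, 6, 6), 12, n)],
            columns=["species", "fishway", "date", "hour", "migrants"],
        )

    def test_zero_efficiency_empty(self):
        records = sim.sample_captures(self._migrants(), [traits(trap_efficiency=0.0)], seed=1)
        assert records == []

    def test_full_efficiency_deterministic_equals_migrants(self):
        records = sim.sample_captures(
            self._migrants(100), [traits(trap_efficiency=1.0)], seed=1, deterministic=True
        )
        assert len(records) == 1 and records[0].count == 100

    def test_monte_carlo_mean(self):
        t = traits(trap_efficiency=0.5)
        counts = [
            sum(r.count for r in sim.sample_captures(self._migrants(100), [t], seed=s))
            for s in range(500)
        ]
        assert np.mean(counts) == pytest.approx(50.0, rel=0.05)

    def test_benthic_lag_shifts_hour(self):
        t = traits(lifestyle=Lifestyle.BENTHIC, trap_efficiency=1.0)
        records = sim.sample_captures(self._migrants(10), [t], seed=1,
                                      deterministic=True, benthic_lag_hours=3)
        assert records[0].hour == 15  # 12 + 3


class TestAmplicons:
    def test_error_free_reads_recovered_by_pipeline(self):
        refs = sim.make_reference_set(3, seed=1)
        abundances = {lab: {"s1": 10} for lab in refs}
        pairs = sim.simulate_amplicons(refs, abundances, error_rate=0.0, seed=2)
        result = rp.process_read_pairs(pairs, refs)
        assert len(result.asvs) == 3
        assert (result.table.counts["s1"] == 10).all()

    def test_spiked_singleton_contaminant_absent(self):
        refs = sim.make_reference_set(3, seed=1)
        contam = sim.make_reference_set(1, seed=50, label_prefix="Contam")
        pairs = sim.simulate_amplicons(refs, {lab: {"s1": 10} for lab in refs}, seed=2)
        pairs += sim.simulate_amplicons(contam, {lab: {"s1": 1} for lab in contam}, seed=3)
        result = rp.process_read_pairs(pairs, {**refs, **contam})
        assert set(result.table.taxa) == set(refs)

    def test_fixed_seed_byte_identical_fastq(self, tmp_path):
        refs = sim.make_reference_set(2, seed=1)
        abund = {lab: {"s1": 5} for lab in refs}
        for d in ("a", "b"):
            (tmp_path / d).mkdir()
            pairs = sim.simulate_amplicons(refs, abund, error_rate=0.01, seed=9)
            sim.write_paired_fastq(pairs, tmp_path / d / "r1.fq", tmp_path / d / "r2.fq", seed=9)
        assert (tmp_path / "a" / "r1.fq").read_bytes() == (tmp_path / "b" / "r1.fq").read_bytes()
        assert (tmp_path / "a" / "r2.fq").read_bytes() == (tmp_path / "b" / "r2.fq").read_bytes()

    def test_negative_abundance_rejected(self):
        refs = sim.make_reference_set(1, seed=1)
        with pytest.raises(ValueError):
            sim.simulate_amplicons(refs, {next(iter(refs)): {"s1": -1}}, seed=1)


class TestSimulateStudy:
    def test_seed_determinism_and_bundle_shape(self):
        cfg = sim.strong_signal_config(seed=5, n_days=6, depth=2000)
        a = sim.simulate_study(cfg)
        b = sim.simulate_study(cfg)
        pd.testing.assert_frame_equal(a.ground_truth, b.ground_truth)
        assert a.count_table == b.count_table
        assert a.captures == b.captures
        # 4 stations x 6 days x 9 hours
        assert len(a.samples) == 4 * 6 * 9
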