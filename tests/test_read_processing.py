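"""Amplicon pipeline stages: merging, primer trimming, quality filtering,
dereplication, denoising, taxonomy and the species table."""

from __future__ import annotations

import numpy as np
import pytest

from fishway_edna import read_processing as rp
from fishway_edna import simulate as sim
from fishway_edna.types import MERGED_LABEL_DELIMITER

from helpers import dp_identity


def perfect_pair(amplicon: str, read_len: int = 60, q: int = 40,
                 sample_id: str = "s1") -> rp.ReadPair:
    fwd = amplicon[:read_len]
    rev = rp.revcomp(amplicon[-read_len:])
    return rp.ReadPair(fwd, rev, (q,) * len(fwd), (q,) * len(rev), sample_id)


AMPLICON = (
    "ACGTACGGTTACACGTGGCATCAGTTACCGGATGCTAGCATCGGATTACGATCGGCATCA"
    "GGCTTACGATCAGGCTAACGGTTAACCGGT"
)  # 90 nt


class TestMergePair:
    def test_error_free_pair_reconstructs_amplicon(self):
        result = rp.merge_pair(perfect_pair(AMPLICON))
        assert result.ok
        assert result.sequence == AMPLICON

    def test_six_overlap_mismatches_rejected(self):
        pair = perfect_pair(AMPLICON)
        # corrupt 6 positions inside the forward read's overlap region
        fwd = list(pair.forward)
        for i in range(31, 55, 4):  # 6 positions within the 30nt overlap
            fwd[i] = "A" if fwd[i] != "A" else "C"
        bad = rp.ReadPair("".join(fwd), pair.reverse, pair.forward_quals,
                          pair.reverse_quals, pair.sample_id)
        result = rp.merge_pair(bad)
        assert not result.ok and result.reason == "too_many_diffs"
        # 5 mismatches is still acceptable (threshold is "> 5 positions")
        fwd = list(pair.forward)
        for i in range(31, 51, 4):
            fwd[i] = "A" if fwd[i] != "A" else "C"
        almost = rp.ReadPair("".join(fwd), pair.reverse, pair.forward_quals,
                             pair.reverse_quals, pair.sample_id)
        assert rp.merge_pair(almost).ok

    def test_short_merge_rejected(self):
        short = AMPLICON[:49]
        result = rp.merge_pair(perfect_pair(short, read_len=40))
        assert not result.ok and result.reason == "too_short"
        assert rp.merge_pair(perfect_pair(AMPLICON[:50], read_len=40)).ok

    def test_low_quality_tail_truncated_before_merge(self):
        pair = perfect_pair(AMPLICON)
        # push the forward tail to Q2: those bases must not poison the merge
        quals = list(pair.forward_quals)
        quals[-5:] = [2] * 5
        fwd = pair.forward[:-5] + "AAAAA"  # garbage under the Q2 tail
        trimmed = rp.ReadPair(fwd, pair.reverse, tuple(quals),
                              pair.reverse_quals, pair.sample_id)
        result = rp.merge_pair(trimmed)
        assert result.ok and result.sequence == AMPLICON

    def test_disagreement_takes_higher_quality_base(self):
        pair = perfect_pair(AMPLICON)
        i = 40  # inside the overlap
        fwd = pair.forward[:i] + ("A" if pair.forward[i] != "A" else "C") + pair.forward[i + 1:]
        quals = list(pair.forward_quals)
        quals[i] = 10  # reverse read keeps Q40 and must win
        noisy = rp.ReadPair(fwd, pair.reverse, tuple(quals),
                            pair.reverse_quals, pair.sample_id)
        result = rp.merge_pair(noisy)
        assert result.ok and result.sequence == AMPLICON


class TestTrimPrimers:
    def test_constructed_read_yields_insert(self):
        insert = AMPLICON
        read = rp.MIFISH_U.forward + insert + rp.revcomp(rp.MIFISH_U.reverse)
        result = rp.trim_primers(read, rp.MIFISH_U)
        assert result.ok and result.sequence == insert

    def test_missing_reverse_primer_rejected(self):
        read = rp.MIFISH_U.forward + AMPLICON  # no reverse primer
        result = rp.trim_primers(read, rp.MIFISH_U)
        assert not result.ok and result.reason == "primer_rev_not_found"

    def test_degenerate_primer_base_matches_either(self):
        primers = rp.PrimerSet("deg", forward="ARGCT", reverse="TTGCA")
        insert = "C" * 50  # no spurious primer sites
        for base in "AG":
            read = f"A{base}GCT" + insert + rp.revcomp("TTGCA")
            result = rp.trim_primers(read, primers, max_primer_mismatch=0)
            assert result.ok and result.sequence == insert
        read = "ATGCT" + insert + rp.revcomp("TTGCA")  # R vs T: mismatch
        assert not rp.trim_primers(read, primers, max_primer_mismatch=0).ok


class TestQualityFilter:
    def test_q20_exactly_one_percent_kept(self):
        # 100 bp all Q20: E = 100 * 10^-2 = 1.0, rate exactly 1% -> keep
        assert rp.quality_filter("A" * 100, [20] * 100)

    def test_q19_rejected(self):
        # oracle: E = 100 * 10^(-1.9), rate > 1%
        expected = 100 * 10 ** (-1.9)
        assert rp.expected_errors([19] * 100) == pytest.approx(expected, rel=1e-12)
        assert expected / 100 > 0.01
        assert not rp.quality_filter("A" * 100, [19] * 100)

    def test_short_read_rejected_regardless_of_quality(self):
        assert not rp.quality_filter("A" * 49, [40] * 49)

    def test_absolute_mode(self):
        # 200 bp all Q20: E = 2.0; rate mode keeps (1%), absolute maxEE=1 rejects
        assert rp.quality_filter("A" * 200, [20] * 200, mode="rate")
        assert not rp.quality_filter("A" * 200, [20] * 200, max_ee_rate=1.0, mode="absolute")


class TestDereplicate:
    def test_low_abundance_removed(self):
        reads = (
            [("AAAA", "s1")] * 5 + [("CCCC", "s1")] * 4 + [("GGGG", "s1")] * 3
            + [("TTTT", "s1")] * 2 + [("ACGT", "s1")]
        )
        uniques = rp.dereplicate(reads)
        assert [(u.sequence, u.abundance) for u in uniques] == [("AAAA", 5), ("CCCC", 4)]

    def test_empty_input(self):
        assert rp.dereplicate([]) == []

    def test_abundance_conservation_before_filter(self, rng):
        seqs = ["AAAA", "CCCC", "GGGG"]
        reads = [(seqs[rng.integers(0, 3)], f"s{rng.integers(0, 2)}") for _ in range(200)]
        uniques = rp.dereplicate(reads, min_abundance=1)
        assert sum(u.abundance for u in uniques) == len(reads)
        for u in uniques:
            assert u.abundance == sum(u.per_sample.values())


class TestDenoise:
    def test_one_mismatch_variant_absorbed(self):
        centroid = "ACGTACGTACGTACGTACGT"
        variant = "ACGTACGTACGAACGTACGT"  # distance 1
        uniques = [
            rp.UniqueSequence(centroid, 1000, {"s1": 1000}),
            rp.UniqueSequence(variant, 50, {"s1": 50}),
        ]
        # skew bound: 50 <= 1000 / 2^(2*1+1) = 125
        assert 50 <= 1000 / 2 ** 3
        asvs = rp.denoise(uniques)
        assert len(asvs) == 1
        assert asvs[0].sequence == centroid
        assert asvs[0].abundance == 1050

    def test_equal_abundance_distant_sequences_stay_separate(self):
        a = "AAAAAAAAAAAAAAAAAAAA"
        b = "CCCCCCCCCCCCCCCCCCCC"
        asvs = rp.denoise([rp.UniqueSequence(a, 100, {"s": 100}),
                           rp.UniqueSequence(b, 100, {"s": 100})])
        assert len(asvs) == 2

    def test_abundance_conserved(self, rng):
        bases = np.array(list("ACGT"))
        seqs = {"".join(rng.choice(bases, 30)) for _ in range(20)}
        uniques = [rp.UniqueSequence(s, int(rng.integers(4, 500)), {}) for s in seqs]
        total = sum(u.abundance for u in uniques)
        asvs = rp.denoise(uniques)
        assert sum(a.abundance for a in asvs) == total


class TestTaxonomy:
    def test_identical_sequence_full_identity(self):
        refs = {"fish A": AMPLICON, "fish B": AMPLICON[:50] + "A" * 40}
        assignment = rp.assign_taxonomy(AMPLICON, refs)
        assert assignment.identity == 1.0
        assert assignment.assigned
        assert assignment.best_reference_label == "fish A"

    def test_exact_eighty_percent_unassigned(self):
        ref = "ACGTACGTAC"  # 10 nt; query at distance 2 -> identity exactly 0.80
        query = "ACGTACGTGG"
        assignment = rp.assign_taxonomy(query, {"fish": ref})
        assert assignment.identity == pytest.approx(0.80, abs=1e-12)
        assert not assignment.assigned

    def test_ties_merge_labels(self):
        ref = "ACGTACGTACGTACGTACGT"
        refs = {"b fish": ref, "a fish": ref}
        assignment = rp.assign_taxonomy(ref, refs)
        assert assignment.best_reference_label == "a fish" + MERGED_LABEL_DELIMITER + "b fish"

    def test_empty_reference_set_rejected(self):
        with pytest.raises(ValueError):
            rp.assign_taxonomy(AMPLICON, {})

    def test_identity_matches_dp_oracle(self, rng):
        bases = np.array(list("ACGT"))
        for _ in range(30):
            a = "".join(rng.choice(bases, int(rng.integers(10, 60))))
            b = "".join(rng.choice(bases, int(rng.integers(10, 60))))
            assert rp.alignment_identity(a, b) == pytest.approx(dp_identity(a, b), abs=1e-12)


class TestSpeciesTable:
    def _asv(self, seq, per_sample):
        return rp.Asv(sequence=seq, centroid_abundance=sum(per_sample.values()),
                      abundance=sum(per_sample.values()),
                      per_sample=dict(per_sample))

    def _assignment(self, seq, label, assigned=True):
        return rp.TaxonAssignment(seq, label, 0.99 if assigned else 0.5, assigned)

    def test_same_species_asvs_sum(self):
        asvs = [self._asv("AAAA", {"s1": 10}), self._asv("AAAT", {"s1": 5})]
        assignments = [self._assignment(a.sequence, "fish A") for a in asvs]
        table = rp.build_species_table(asvs, assignments)
        assert table.counts.loc["fish A", "s1"] == 15

    def test_all_unassigned(self):
        asvs = [self._asv("AAAA", {"s1": 10})]
        assignments = [self._assignment("AAAA", "fish A", assigned=False)]
        table = rp.build_species_table(asvs, assignments)
        assert table.taxa == [rp.UNASSIGNED_LABEL]

    def test_column_sums_conserve_reads(self, rng):
        asvs, assignments = [], []
        for i in range(6):
            per_sample = {f"s{j}": int(rng.integers(0, 50)) for j in range(3)}
            per_sample = {k: v for k, v in per_sample.items() if v} or {"s0": 1}
            seq = "".join(rng.choice(np.array(list("ACGT")), 25))
            asvs.append(self._asv(seq, per_sample))
            assignments.append(self._assignment(seq, f"fish {i % 3}", assigned=i % 4 != 3))
        table = rp.build_species_table(asvs, assignments)
        expected = {}
        for a in asvs:
            for sid, n in a.per_sample.items():
                expected[sid] = expected.get(sid, 0) + n
        assert table.counts.sum(axis=0).to_dict() == expected

    def test_fauna_allowlist_resolves_merged_label(self):
        label = "a fish" + MERGED_LABEL_DELIMITER + "b fish"
        asvs = [self._asv("AAAA", {"s1": 7})]
        assignments = [self._assignment("AAAA", label)]
        table = rp.build_species_table(asvs, assignments, fauna={"a fish", "other"})
        assert table.taxa == ["a fish"]


class TestEndToEnd:
    def test_error_free_amplicons_recovered_exactly(self, rng):
        refs = sim.make_reference_set(5, seed=1)
        abundances = {lab: {"s1": int(n)} for lab, n in zip(refs, rng.integers(4, 100, 5))}
        pairs = sim.simulate_amplicons(refs, abundances, error_rate=0.0, seed=2)
        result = rp.process_read_pairs(pairs, refs)
        assert len(result.asvs) == 5
        for assignment in result.assignments:
            assert assignment.assigned and assignment.identity == 1.0
        for label, per_sample in abundances.items():
            assert result.table.counts.loc[label, "s1"] == per_sample["s1"]

    def test_read_count_conservation_log(self, rng):
        refs = sim.make_reference_set(4, seed=3)
        abundances = {lab: {"s1": int(n)} for lab, n in zip(refs, [50, 10, 3, 1])}
        pairs = sim.simulate_amplicons(refs, abundances, error_rate=0.0, seed=4)
        # a pair that cannot merge: unrelated reads
        junk = rp.ReadPair("A" * 100, "G" * 100, (40,) * 100, (40,) * 100, "s1")
        # a merged read without primers: abundant enough to matter
        bare = sim.make_reference_set(1, seed=9, label_prefix="NoPrimer")
        naked = [
            rp.ReadPair(seq[:80], rp.revcomp(seq[-80:]), (40,) * 80, (40,) * 80, "s1")
            for seq in bare.values() for _ in range(6)
        ]
        result = rp.process_read_pairs(pairs + [junk] + naked, refs)
        log = result.log
        assert log["n_input"] == len(pairs) + 1 + 6
        assert (
            log["n_input"]
            == log["rejected_merge"] + log["rejected_primer"] + log["rejected_quality"]
            + log["removed_low_abundance"] + log["n_tabulated"]
        )
        # the abundance-3 and abundance-1 references were removed
        assert log["removed_low_abundance"] >= 4


class TestFastqIO:
    def test_roundtrip_through_files(self, tmp_path):
        refs = sim.make_reference_set(2, seed=5)
        abundances = {lab: {"stA": 4, "stB": 2} for lab in refs}
        pairs = sim.simulate_amplicons(refs, abundances, seed=6)
        sim.write_paired_fastq(pairs, tmp_path / "r1.fastq", tmp_path / "r2.fastq", seed=6)
        loaded = rp.read_paired_fastq(tmp_path / "r1.fastq", tmp_path / "r2.fastq")
        assert loaded == pairs

    def test_reference_fasta(self, tmp_path):
        path = tmp_path / "ref.fasta"
        path.write_text(">fish A\nACGT\n>fish B\nGGCC\n")
        refs = rp.read_reference_fasta(path)
        assert refs == {"fish A": "ACGT", "fish B": "GGCC"}
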