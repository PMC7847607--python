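import numpy as np
import pytest

from phasloc.rddm import (
    classify_context,
    compare_tissues,
    expression_rpm,
    find_promoter_hits,
    map_bisulfite_reads,
    methylation_profile,
)
from phasloc.seq_io import (
    SequenceRecord,
    SmallRNALibrary,
    SmallRNARead,
    normalize_rpm,
    revcomp,
    to_dna,
)
from phasloc.simulate import random_sequence
from phasloc.tasirna import PhasiRNA

from published_sites import PROMOTER_HIT_SPAN, PROMOTER_PHASIRNA_RNA


def _phasirna24(seq_dna, locus="PHAS24_L", anchor=1684, index=12):
    return PhasiRNA(locus, anchor, 24, index, "+", "5'", seq_dna)


class TestContext:
    @pytest.mark.parametrize(
        "seq,pos,expected",
        [("ACGTA", 2, "CG"), ("ACAGT", 2, "CHG"), ("ACATT", 2, "CHH")],
    )
    def test_trinucleotide_rule(self, seq, pos, expected):
        assert classify_context(seq, pos) == expected

    def test_truncated_triplet_defaults_chh(self):
        assert classify_context("AAC", 3) == "CHH"
        assert classify_context("AACA", 3) == "CHH"
        assert classify_context("AACG", 3) == "CG"

    def test_minus_strand_reads_leftward(self):
        # sense ...CG...: the G at position 3 is a C on the bottom strand
        # whose next base (leftward) is G's complement of C -> CG context
        assert classify_context("ACGTA", 3, "-") == "CG"
        # bottom-strand CHG: sense C-A-G, read on bottom G at pos 3
        assert classify_context("CAGTT", 3, "-") == "CHG"

    def test_non_cytosine_rejected(self):
        with pytest.raises(ValueError, match="not C"):
            classify_context("AAGT", 2)

    def test_contexts_partition_all_cytosines(self):
        for seed in range(10):
            seq = random_sequence(np.random.default_rng(seed), 300)
            n_sites = 0
            for pos, base in enumerate(seq, start=1):
                if base == "C":
                    assert classify_context(seq, pos, "+") in ("CG", "CHG", "CHH")
                    n_sites += 1
                if base == "G":
                    assert classify_context(seq, pos, "-") in ("CG", "CHG", "CHH")
                    n_sites += 1
            assert n_sites == seq.count("C") + seq.count("G")


class TestPromoterHits:
    def test_planted_complement_recovered_at_printed_span(self):
        rng = np.random.default_rng(1)
        phas_dna = to_dna(PROMOTER_PHASIRNA_RNA)
        start, end = PROMOTER_HIT_SPAN
        prom_seq = list(random_sequence(rng, 200))
        prom_seq[start - 1 : end] = list(revcomp(phas_dna))
        promoter = SequenceRecord("PROM", "".join(prom_seq), kind="promoter")
        (hit,) = find_promoter_hits([_phasirna24(phas_dna)], [promoter])
        assert (hit.start, hit.end) == (start, end)
        assert hit.orientation == "complementary"

    def test_no_match_yields_nothing(self):
        rng = np.random.default_rng(2)
        promoter = SequenceRecord("PROM", random_sequence(rng, 200), kind="promoter")
        assert find_promoter_hits(
            [_phasirna24(random_sequence(rng, 24))], [promoter]
        ) == []

    def test_identical_strand_occurrence_flagged(self):
        rng = np.random.default_rng(3)
        phas_dna = random_sequence(rng, 24)
        prom_seq = random_sequence(rng, 100) + phas_dna + random_sequence(rng, 76)
        promoter = SequenceRecord("PROM", prom_seq, kind="promoter")
        (hit,) = find_promoter_hits([_phasirna24(phas_dna)], [promoter])
        assert hit.orientation == "identical"
        assert hit.start == 101

    def test_non_24mers_skipped(self):
        p21 = PhasiRNA("L", 100, 21, 1, "+", "3'", "A" * 21)
        promoter = SequenceRecord("PROM", "T" * 60, kind="promoter")
        assert find_promoter_hits([p21], [promoter]) == []


def _lib(reads):
    return SmallRNALibrary("bis", {s: SmallRNARead(s, c) for s, c in reads.items()})


class TestBisulfiteMapping:
    def test_unconverted_read_counts_all_cytosines_methylated(self):
        rng = np.random.default_rng(4)
        prom = SequenceRecord("P", random_sequence(rng, 120), kind="promoter")
        read = prom.subseq(1, 50)
        counts = map_bisulfite_reads(_lib({read: 1}), [prom])["P"]
        plus = {pos: v for (pos, strand), v in counts.items() if strand == "+"}
        c_positions = [i + 1 for i, b in enumerate(prom.sequence[:50]) if b == "C"]
        assert sorted(plus) == c_positions
        assert all(v == (1, 1) for v in plus.values())

    def test_fully_converted_read_maps_unmethylated(self):
        rng = np.random.default_rng(5)
        prom = SequenceRecord("P", random_sequence(rng, 120), kind="promoter")
        read = prom.subseq(1, 50).replace("C", "T")
        counts = map_bisulfite_reads(_lib({read: 1}), [prom])["P"]
        plus = {pos: v for (pos, strand), v in counts.items() if strand == "+"}
        assert plus and all(v == (0, 1) for v in plus.values())

    def test_reverse_strand_read_counted_at_sense_gs(self):
        rng = np.random.default_rng(6)
        prom = SequenceRecord("P", random_sequence(rng, 120), kind="promoter")
        read = revcomp(prom.subseq(11, 60))  # bottom strand, unconverted
        counts = map_bisulfite_reads(_lib({read: 1}), [prom])["P"]
        minus = {pos: v for (pos, strand), v in counts.items() if strand == "-"}
        g_positions = [
            i + 11 for i, b in enumerate(prom.sequence[10:60]) if b == "G"
        ]
        assert sorted(minus) == g_positions

    def test_multi_promoter_read_discarded(self):
        rng = np.random.default_rng(7)
        shared = random_sequence(rng, 50)
        p1 = SequenceRecord("P1", shared + random_sequence(rng, 50), kind="promoter")
        p2 = SequenceRecord("P2", random_sequence(rng, 50) + shared, kind="promoter")
        counts = map_bisulfite_reads(_lib({shared: 1}), [p1, p2])
        assert counts["P1"] == {} and counts["P2"] == {}

    def test_matches_bruteforce_three_letter_scan(self):
        rng = np.random.default_rng(8)
        prom = SequenceRecord("P", random_sequence(rng, 300), kind="promoter")
        reads = {}
        for _ in range(20):
            start = int(rng.integers(1, 250))
            window = prom.subseq(start, start + 49)
            read = "".join(
                "T" if b == "C" and rng.random() < 0.5 else b for b in window
            )
            reads[read] = reads.get(read, 0) + 1
        counts = map_bisulfite_reads(_lib(reads), [prom])["P"]

        # oracle: test every read at every offset under C->T collapse
        collapsed_ref = prom.sequence.replace("C", "T")
        expected: dict[tuple[int, str], list[int]] = {}
        for read, count in reads.items():
            collapsed = read.replace("C", "T")
            placements = [
                i + 1
                for i in range(len(prom.sequence) - len(read) + 1)
                if collapsed_ref[i : i + len(read)] == collapsed
            ]
            # reverse-strand placements of these forward-derived reads
            rc = revcomp(read).replace("G", "A")
            rc_ref = prom.sequence.replace("G", "A")
            placements_rev = [
                i + 1
                for i in range(len(prom.sequence) - len(read) + 1)
                if rc_ref[i : i + len(read)] == rc
            ]
            if len(placements) + len(placements_rev) != 1:
                continue
            start = placements[0]
            for offset, base in enumerate(
                prom.sequence[start - 1 : start - 1 + len(read)]
            ):
                if base != "C":
                    continue
                cell = expected.setdefault((start + offset, "+"), [0, 0])
                cell[0] += count if read[offset] == "C" else 0
                cell[1] += count
        assert {k: tuple(v) for k, v in expected.items()} == {
            k: v for k, v in counts.items() if k[1] == "+"
        }


class TestMethylationProfile:
    def test_rpm_arithmetic(self):
        prom = SequenceRecord("P", "AACGTT", kind="promoter")
        counts = {(3, "+"): (2, 4)}
        profile = methylation_profile(counts, 4, prom)
        (rec,) = profile.cytosines
        assert rec.context == "CG"
        assert rec.methylated_rpm == pytest.approx(500_000.0)
        assert rec.total_rpm == pytest.approx(1_000_000.0)
        assert rec.fraction == pytest.approx(0.5)

    def test_context_totals_sum_members(self):
        prom = SequenceRecord("P", "ACGACGTACATT", kind="promoter")
        counts = {(2, "+"): (1, 2), (5, "+"): (3, 3), (9, "+"): (0, 2)}
        profile = methylation_profile(counts, 10, prom)
        total = sum(
            profile.context_total(ctx) for ctx in ("CG", "CHG", "CHH")
        )
        assert total == pytest.approx(
            sum(c.methylated_rpm for c in profile.cytosines)
        )

    def test_zero_library_rejected(self):
        prom = SequenceRecord("P", "ACG", kind="promoter")
        with pytest.raises(ValueError, match="positive"):
            methylation_profile({}, 0, prom)

    def test_generator_extremes(self):
        from phasloc.simulate import make_rddm_scenario

        zero = make_rddm_scenario(
            11,
            meth_rates={
                "panicle": {"CG": 0.0, "CHG": 0.0, "CHH": 0.0},
                "root": {"CG": 0.0, "CHG": 0.0, "CHH": 0.0},
            },
        )
        full = make_rddm_scenario(
            11,
            meth_rates={
                "panicle": {"CG": 1.0, "CHG": 1.0, "CHH": 1.0},
                "root": {"CG": 1.0, "CHG": 1.0, "CHH": 1.0},
            },
        )
        for scenario, check in ((zero, "zero"), (full, "full")):
            prom = scenario.promoters[0]
            lib = scenario.bisulfite["panicle"]
            counts = map_bisulfite_reads(lib, scenario.promoters)[prom.id]
            profile = methylation_profile(counts, lib.total_count, prom)
            assert profile.cytosines
            for rec in profile.cytosines:
                if check == "zero":
                    assert rec.methylated_rpm == 0.0
                else:
                    assert rec.methylated_rpm == pytest.approx(rec.total_rpm)


class TestExpression:
    def test_total_rpm_of_matching_reads(self):
        rng = np.random.default_rng(9)
        cdna = SequenceRecord("G", random_sequence(rng, 300))
        reads = {cdna.subseq(i, i + 49): 1 for i in (1, 100, 200)}
        filler = random_sequence(rng, 50)
        reads[filler] = 999_997
        lib = normalize_rpm(
            SmallRNALibrary("r", {s: SmallRNARead(s, c) for s, c in reads.items()})
        )
        assert expression_rpm(lib, cdna) == pytest.approx(3.0)

    def test_no_match_zero(self):
        rng = np.random.default_rng(10)
        cdna = SequenceRecord("G", random_sequence(rng, 200))
        other = random_sequence(rng, 50)
        lib = normalize_rpm(
            SmallRNALibrary("r", {other: SmallRNARead(other, 10)})
        )
        assert expression_rpm(lib, cdna) == 0.0


class TestCompareTissues:
    def _profile(self, chh_rpm, pid="P"):
        from phasloc.rddm import CytosineRecord, MethylationProfile

        rec = CytosineRecord(5, "+", "CHH", 1, 2, chh_rpm, 2 * chh_rpm)
        return MethylationProfile(pid, "lib", [rec])

    def test_consistent_when_meth_up_and_expression_down(self):
        cmp = compare_tissues(self._profile(100.0), self._profile(5.0), 10.0, 80.0)
        assert cmp.consistent

    def test_equal_methylation_not_consistent(self):
        cmp = compare_tissues(self._profile(5.0), self._profile(5.0), 10.0, 80.0)
        assert not cmp.consistent

    def test_higher_expression_breaks_consistency(self):
        cmp = compare_tissues(self._profile(100.0), self._profile(5.0), 90.0, 80.0)
        assert not cmp.consistent

    def test_synthetic_scenario_consistent(self, rddm_scenario):
        s = rddm_scenario
        prom = s.promoters[0]
        profiles, expr = {}, {}
        for tissue in ("panicle", "root"):
            lib = s.bisulfite[tissue]
            counts = map_bisulfite_reads(lib, s.promoters)[prom.id]
            profiles[tissue] = methylation_profile(
                counts, lib.total_count, prom, lib.name
            )
            expr[tissue] = expression_rpm(
                normalize_rpm(s.rnaseq[tissue]), s.cdnas[0]
            )
        cmp = compare_tissues(
            profiles["panicle"], profiles["root"],
            expr["panicle"], expr["root"], "panicle", "root",
        )
        assert cmp.consistent
        assert cmp.chh_expressing > cmp.chh_other
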