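import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from phasloc.phase_model import (
    ReadPlacement,
    classify_phase,
    find_candidate_regions,
    find_occurrences,
    map_reads,
    merged_hull,
)
from phasloc.seq_io import (
    SequenceRecord,
    SmallRNALibrary,
    SmallRNARead,
    normalize_rpm,
    revcomp,
)
from phasloc.simulate import random_sequence


def _transcript(seed=0, length=500, id="T"):
    return SequenceRecord(id, random_sequence(np.random.default_rng(seed), length))


def _library(seqs):
    return normalize_rpm(
        SmallRNALibrary("lib", {s: SmallRNARead(s, 1) for s in seqs})
    )


def _placement(seq, start, strand, tid="T", count=1, rpm=1.0):
    return ReadPlacement(SmallRNARead(seq, count, rpm), tid, start, strand)


class TestMapping:
    def test_plus_strand_coordinates(self):
        t = _transcript(1)
        read = t.subseq(100, 120)
        placements = map_reads(_library([read]), [t])
        plus = [p for p in placements if p.strand == "+"]
        assert len(plus) == 1
        assert plus[0].start == 100
        assert plus[0].five_prime_pos == 100

    def test_minus_strand_five_prime_at_right_end(self):
        t = _transcript(2)
        read = revcomp(t.subseq(100, 120))
        placements = map_reads(_library([read]), [t])
        minus = [p for p in placements if p.strand == "-"]
        assert len(minus) == 1
        assert minus[0].start == 100
        assert minus[0].five_prime_pos == 120

    def test_repeat_transcript_yields_two_placements(self):
        unit = random_sequence(np.random.default_rng(3), 60)
        t = SequenceRecord("T", unit + unit)
        read = unit[10:31]
        placements = map_reads(_library([read]), [t])
        plus = [p for p in placements if p.strand == "+"]
        assert sorted(p.start for p in plus) == [11, 71]

    @given(st.integers(0, 1000))
    @settings(max_examples=25, deadline=None)
    def test_agrees_with_bruteforce_substring_scan(self, seed):
        rng = np.random.default_rng(seed)
        t = SequenceRecord("T", random_sequence(rng, 200))
        start = int(rng.integers(1, 180))
        read = t.subseq(start, start + 20)
        hits = find_occurrences(read, t.sequence)
        brute = [
            i + 1
            for i in range(len(t.sequence) - 20)
            if t.sequence[i : i + 21] == read
        ]
        assert hits == brute


class TestPhaseRule:
    def test_plus_read_in_register(self):
        p = _placement("A" * 21, 143, "+")  # anchor + 2k
        assert classify_phase(p, 101, 21)

    def test_minus_read_at_duplex_bottom_five_prime(self):
        # duplex 1 of an anchor-101 grid: top 101-121, bottom 99-119,
        # bottom-strand 5' end at 119 = anchor + k - 3
        p = ReadPlacement(SmallRNARead("A" * 21, 1), "T", 99, "-")
        assert p.five_prime_pos == 119
        assert classify_phase(p, 101, 21)

    def test_off_register_read(self):
        assert not classify_phase(_placement("A" * 21, 112, "+"), 101, 21)

    def test_invalid_cycle_length(self):
        with pytest.raises(ValueError, match="21, 24"):
            classify_phase(_placement("A" * 21, 101, "+"), 101, 22)

    @given(st.integers(1, 400), st.integers(-5, 5),
           st.sampled_from([21, 24]), st.sampled_from(["+", "-"]))
    @settings(max_examples=100, deadline=None)
    def test_invariant_under_anchor_shift_by_k(self, pos, shift, k, strand):
        p = _placement("A" * k, pos, strand)
        anchor = 50
        assert classify_phase(p, anchor, k) == classify_phase(
            p, anchor + shift * k, k
        )


def _phased_placements(t, anchor, k, registers, strand="+"):
    """In-phase count-1 placements at the given duplex indices (0-based)."""
    out = []
    for i in registers:
        top = anchor + i * k
        if strand == "+":
            out.append(_placement(t.subseq(top, top + k - 1), top, "+", t.id))
        else:
            seq = revcomp(t.subseq(top - 2, top + k - 3))
            out.append(_placement(seq, top - 2, "-", t.id))
    return out


class TestCandidateRegions:
    def test_six_tandem_registers(self):
        t = _transcript(10, 400)
        placements = _phased_placements(t, 101, 21, range(6))
        (region,) = find_candidate_regions(placements, t, 21)
        assert region.anchor == 101
        assert (region.region_start, region.region_end) == (101, 226)
        assert region.n_occupied_tandem == 6

    def test_gap_breaks_the_run(self):
        t = _transcript(11, 400)
        placements = _phased_placements(t, 101, 21, [0, 1, 3, 4, 5])
        assert find_candidate_regions(placements, t, 21) == []

    def test_exactly_five_accepted_four_rejected(self):
        t = _transcript(12, 400)
        five = _phased_placements(t, 101, 21, range(5))
        assert len(find_candidate_regions(five, t, 21)) == 1
        four = _phased_placements(t, 101, 21, range(4))
        assert find_candidate_regions(four, t, 21) == []

    def test_minus_strand_reads_occupy_duplexes(self):
        t = _transcript(13, 400)
        placements = _phased_placements(t, 101, 21, range(5), strand="-")
        (region,) = find_candidate_regions(placements, t, 21)
        assert region.anchor == 101
        assert all(d.minus_rpm > 0 for d in region.duplexes)

    def test_duplex_indices_contiguous(self):
        t = _transcript(14, 500)
        placements = _phased_placements(t, 80, 21, range(7))
        (region,) = find_candidate_regions(placements, t, 21)
        assert [d.index for d in region.duplexes] == list(range(1, 8))
        assert all(
            d.top_start == region.anchor + (d.index - 1) * 21
            for d in region.duplexes
        )

    @given(st.integers(0, 500))
    @settings(max_examples=30, deadline=None)
    def test_agrees_with_bruteforce_run_enumeration(self, seed):
        rng = np.random.default_rng(seed)
        k = 21
        t = SequenceRecord("T", random_sequence(rng, 800))
        anchor = int(rng.integers(30, 60))
        occupied = sorted(
            set(rng.choice(30, size=rng.integers(3, 20), replace=False))
        )
        placements = _phased_placements(t, anchor, k, occupied)

        regions = find_candidate_regions(placements, t, k)

        # oracle: scan the occupied-index set for runs of >= 5
        runs, run = [], []
        for i in occupied + [None]:
            if run and (i is None or i != run[-1] + 1):
                if len(run) >= 5:
                    runs.append((run[0], run[-1]))
                run = []
            if i is not None:
                run.append(i)
        expected = {
            (anchor + a * k, anchor + b * k + k - 1) for a, b in runs
        }
        assert {(r.region_start, r.region_end) for r in regions} == expected

    def test_merged_hull_spans_gapped_runs(self):
        t = _transcript(15, 800)
        placements = _phased_placements(t, 50, 21, list(range(5)) + list(range(7, 13)))
        regions = find_candidate_regions(placements, t, 21)
        assert len(regions) == 2
        (hull,) = merged_hull(regions)
        assert hull.region_start == 50
        assert hull.region_end == 50 + 13 * 21 - 1
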