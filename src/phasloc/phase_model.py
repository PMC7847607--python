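"""Phase-register geometry and candidate PHAS region detection.

A PHAS precursor is diced into head-to-tail k-nt duplexes (k = 21 or 24),
each with a 2-nt 3' overhang.  On sense coordinates, duplex i of a grid
anchored at position ``a`` has its top (sense) strand at
``[a + (i-1)k, a + ik - 1]`` and its bottom (antisense) strand covering
``[a + (i-1)k - 2, a + ik - 3]``; the overhang puts the bottom strand's
5' nucleotide at ``top_end - 2``, hence the minus-strand in-phase rule
``five_prime_pos ≡ anchor + k - 3 (mod k)``.

A candidate phasiRNA production region is a run of at least
``min_duplexes`` (default 5) consecutive occupied duplexes, where a duplex
is occupied when a k-nt read maps in phase on either strand.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable

from .seq_io import SequenceRecord, SmallRNALibrary, SmallRNARead, revcomp

VALID_K = (21, 24)


@dataclass(frozen=True)
class ReadPlacement:
    """An exact match of a read on a transcript.

    ``start`` is the 1-based sense coordinate of the read's leftmost base;
    ``five_prime_pos`` of a minus-strand read is its rightmost base
    (``start + len - 1``) because the read runs 3'->5' along the sense
    strand.
    """

    read: SmallRNARead
    transcript_id: str
    start: int
    strand: str  # '+' or '-'

    @property
    def length(self) -> int:
        return len(self.read)

    @property
    def end(self) -> int:
        return self.start + self.length - 1

    @property
    def five_prime_pos(self) -> int:
        return self.start if self.strand == "+" else self.end


@dataclass(frozen=True)
class PhasedDuplex:
    """One k-nt duplex of a phase grid (index 1 = anchor-proximal)."""

    index: int
    top_start: int
    k: int
    plus_rpm: float = 0.0
    minus_rpm: float = 0.0

    @property
    def top_end(self) -> int:
        return self.top_start + self.k - 1

    @property
    def bottom_span(self) -> tuple[int, int]:
        return (self.top_start - 2, self.top_end - 2)

    @property
    def occupied(self) -> bool:
        return self.plus_rpm + self.minus_rpm > 0


@dataclass
class CandidateRegion:
    """A maximal run of >= min_duplexes consecutive occupied duplexes."""

    transcript_id: str
    k: int
    anchor: int
    region_start: int
    region_end: int
    duplexes: list[PhasedDuplex] = field(default_factory=list)

    @property
    def n_occupied_tandem(self) -> int:
        return len(self.duplexes)


def _check_k(k: int) -> None:
    if k not in VALID_K:
        raise ValueError(f"cycle length k must be one of {VALID_K}, got {k}")


def find_occurrences(needle: str, haystack: str) -> list[int]:
    """All 1-based start positions of exact occurrences (may overlap)."""
    hits = []
    i = haystack.find(needle)
    while i != -1:
        hits.append(i + 1)
        i = haystack.find(needle, i + 1)
    return hits


def map_reads(
    library: SmallRNALibrary, transcripts: Iterable[SequenceRecord]
) -> list[ReadPlacement]:
    """Map every accepted read exactly onto each transcript, both strands.

    Every occurrence is reported; a read may place on several transcripts
    and several positions.
    """
    placements: list[ReadPlacement] = []
    for transcript in transcripts:
        seq = transcript.sequence
        for read in library.accepted_reads():
            for start in find_occurrences(read.sequence, seq):
                placements.append(
                    ReadPlacement(read, transcript.id, start, "+")
                )
            for start in find_occurrences(revcomp(read.sequence), seq):
                placements.append(
                    ReadPlacement(read, transcript.id, start, "-")
                )
    return placements


def classify_phase(placement: ReadPlacement, anchor: int, k: int) -> bool:
    """In-phase test under the 2-nt 3'-overhang duplex geometry.

    Plus-strand reads are in phase when their 5' end sits on the anchor's
    residue class mod k; minus-strand reads when it sits k-3 beyond it
    (the bottom strand's 5' end is 2 nt left of the duplex top end).
    """
    _check_k(k)
    fp = placement.five_prime_pos
    if placement.strand == "+":
        return (fp - anchor) % k == 0
    return (fp - anchor) % k == (k - 3) % k


def duplex_index_of(placement: ReadPlacement, anchor: int, k: int) -> int | None:
    """1-based duplex index of an in-phase placement, or None if off-grid.

    Index 1 is the duplex whose top strand starts at the anchor; indices
    below 1 (upstream of the anchor) return non-positive values.
    """
    if not classify_phase(placement, anchor, k):
        return None
    fp = placement.five_prime_pos
    if placement.strand == "+":
        return (fp - anchor) // k + 1
    # bottom strand 5' end = top_start + k - 3
    return (fp - (anchor + k - 3)) // k + 1


def find_candidate_regions(
    placements: Iterable[ReadPlacement],
    transcript: SequenceRecord,
    k: int,
    min_duplexes: int = 5,
    min_rpm: float = 0.0,
) -> list[CandidateRegion]:
    """Detect candidate phasiRNA production regions on one transcript.

    For every residue class of possible anchors, duplex occupancy is
    tallied from k-nt placements under the phase rule, and maximal runs of
    consecutive occupied duplexes of length >= ``min_duplexes`` are
    reported, deduplicated by (anchor mod k, span).  "Occupied" means
    mapped RPM on either strand strictly above ``min_rpm`` (default 0:
    any detectable read).
    """
    _check_k(k)
    seq_len = len(transcript)
    placements = [
        p
        for p in placements
        if p.transcript_id == transcript.id and p.length == k
    ]
    # occupancy[top_start] accumulates (plus_rpm, minus_rpm)
    plus_rpm: dict[int, float] = {}
    minus_rpm: dict[int, float] = {}
    for p in placements:
        fp = p.five_prime_pos
        if p.strand == "+":
            top_start = fp
            plus_rpm[top_start] = plus_rpm.get(top_start, 0.0) + p.read.rpm
        else:
            top_start = fp - (k - 3)
            if top_start < 1 or top_start + k - 1 > seq_len:
                continue
            minus_rpm[top_start] = minus_rpm.get(top_start, 0.0) + p.read.rpm

    occupied = {
        s
        for s in set(plus_rpm) | set(minus_rpm)
        if plus_rpm.get(s, 0.0) + minus_rpm.get(s, 0.0) > min_rpm
    }

    regions: list[CandidateRegion] = []
    seen: set[tuple[int, int, int]] = set()
    for residue in range(k):
        starts = sorted(s for s in occupied if s % k == residue)
        if not starts:
            continue
        run: list[int] = []
        for s in starts + [None]:  # sentinel flushes the last run
            if run and (s is None or s != run[-1] + k):
                if len(run) >= min_duplexes:
                    anchor = run[0]
                    key = (anchor % k, run[0], run[-1] + k - 1)
                    if key not in seen:
                        seen.add(key)
                        duplexes = [
                            PhasedDuplex(
                                index=i + 1,
                                top_start=ts,
                                k=k,
                                plus_rpm=plus_rpm.get(ts, 0.0),
                                minus_rpm=minus_rpm.get(ts, 0.0),
                            )
                            for i, ts in enumerate(run)
                        ]
                        regions.append(
                            CandidateRegion(
                                transcript_id=transcript.id,
                                k=k,
                                anchor=anchor,
                                region_start=run[0],
                                region_end=run[-1] + k - 1,
                                duplexes=duplexes,
                            )
                        )
                run = []
            if s is not None:
                run.append(s)
    regions.sort(key=lambda r: (r.region_start, r.anchor))
    return regions


def merged_hull(regions: Iterable[CandidateRegion]) -> list[CandidateRegion]:
    """Merge same-phase runs on one transcript into their convex hull.

    Published PHAS tables often print one long region per locus even when
    occupancy has gaps; this reports, per (transcript, k, anchor mod k),
    the span from the first to the last occupied duplex.
    """
    by_phase: dict[tuple[str, int, int], list[CandidateRegion]] = {}
    for r in regions:
        by_phase.setdefault((r.transcript_id, r.k, r.anchor % r.k), []).append(r)
    hulls = []
    for (tid, k, _), group in sorted(by_phase.items()):
        group.sort(key=lambda r: r.region_start)
        first, last = group[0], group[-1]
        duplexes = [d for r in group for d in r.duplexes]
        hulls.append(
            CandidateRegion(
                transcript_id=tid,
                k=k,
                anchor=first.anchor,
                region_start=first.region_start,
                region_end=last.region_end,
                duplexes=duplexes,
            )
        )
    return hulls
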