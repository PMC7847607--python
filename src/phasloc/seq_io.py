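"""Sequence and small-RNA library I/O.

All coordinates throughout the package are 1-based, fully closed intervals
(a 21-nt read starting at 424 covers 424..444).  Matching is always done in
the DNA alphabet: RNA input (U) is normalised to T on the way in, and small
RNAs are rendered back as RNA for display, since that is how the field
prints them.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Iterable

from Bio import SeqIO

DNA_ALPHABET = frozenset("ACGT")

_COMPLEMENT = str.maketrans("ACGT", "TGCA")


class FormatError(ValueError):
    """Malformed input file (bad FASTA record, bad count column, ...)."""


def to_dna(sequence: str) -> str:
    """Uppercase and convert U->T so every comparison runs in one alphabet."""
    return sequence.upper().replace("U", "T")


def to_rna(sequence: str) -> str:
    """Render a DNA-internal sequence as RNA for display."""
    return sequence.upper().replace("T", "U")


def revcomp(sequence: str) -> str:
    """Reverse complement in the DNA alphabet."""
    return to_dna(sequence).translate(_COMPLEMENT)[::-1]


@dataclass(frozen=True)
class SequenceRecord:
    """A named transcript or promoter sequence.

    ``sequence`` is stored DNA-uppercase; ``is_rna`` remembers whether the
    source file used the RNA alphabet so it can be displayed faithfully.
    """

    id: str
    sequence: str
    kind: str = "transcript"  # or "promoter"
    is_rna: bool = False
    metadata: str = ""  # opaque, e.g. a genomic-location string

    def __post_init__(self) -> None:
        if len(self.sequence) == 0:
            raise FormatError(f"record {self.id!r}: empty sequence")
        bad = set(self.sequence) - DNA_ALPHABET
        if bad:
            raise FormatError(
                f"record {self.id!r}: invalid characters {sorted(bad)}"
            )

    def __len__(self) -> int:
        return len(self.sequence)

    def subseq(self, start: int, end: int) -> str:
        """1-based inclusive slice."""
        if start < 1 or end > len(self.sequence) or start > end:
            raise ValueError(
                f"interval {start}-{end} outside record {self.id!r} "
                f"of length {len(self.sequence)}"
            )
        return self.sequence[start - 1 : end]


@dataclass(frozen=True)
class SmallRNARead:
    """A collapsed unique read: one sequence, its count, and its RPM."""

    sequence: str  # DNA-internal
    count: int
    rpm: float = 0.0

    def __post_init__(self) -> None:
        if self.count < 0:
            raise ValueError("negative read count")

    def __len__(self) -> int:
        return len(self.sequence)


MIN_READ_LEN = 15
MAX_READ_LEN = 30


@dataclass
class SmallRNALibrary:
    """A collapsed small-RNA (or degradome-tag) library.

    ``total_count`` is the pre-filter library size: RPM normalisation uses
    it even when individual reads are excluded from analysis by the length
    window, because whole libraries are normalised before any filtering.
    """

    name: str
    reads: dict[str, SmallRNARead] = field(default_factory=dict)
    total_count: int = 0

    def __post_init__(self) -> None:
        if self.total_count == 0 and self.reads:
            self.total_count = sum(r.count for r in self.reads.values())

    def accepted_reads(self) -> list[SmallRNARead]:
        """Reads inside the 15-30 nt analysis window."""
        return [
            r
            for r in self.reads.values()
            if MIN_READ_LEN <= len(r) <= MAX_READ_LEN
        ]

    def reads_of_length(self, k: int) -> list[SmallRNARead]:
        return [r for r in self.accepted_reads() if len(r) == k]

    def __len__(self) -> int:
        return len(self.reads)


# A degradome library is structurally a collapsed read library; the tags
# are 5' fragments of cleaved mRNAs and are only ever mapped sense-strand.
DegradomeLibrary = SmallRNALibrary


def read_fasta(path: str | Path, kind: str = "transcript") -> list[SequenceRecord]:
    """Read a multi-record FASTA into SequenceRecords.

    U is converted to T internally; the original alphabet is remembered on
    the record. Duplicate ids are an error.
    """
    records: list[SequenceRecord] = []
    seen: set[str] = set()
    for entry in SeqIO.parse(str(path), "fasta"):
        raw = str(entry.seq)
        if not raw:
            raise FormatError(f"record {entry.id!r}: empty sequence")
        is_rna = "U" in raw.upper()
        if entry.id in seen:
            raise FormatError(f"duplicate record id {entry.id!r}")
        seen.add(entry.id)
        records.append(
            SequenceRecord(
                id=entry.id,
                sequence=to_dna(raw),
                kind=kind,
                is_rna=is_rna,
                metadata=entry.description[len(entry.id) :].strip(),
            )
        )
    return records


def write_fasta(records: Iterable[SequenceRecord], path: str | Path) -> None:
    with open(path, "w") as fh:
        for rec in records:
            seq = to_rna(rec.sequence) if rec.is_rna else rec.sequence
            header = f">{rec.id}"
            if rec.metadata:
                header += f" {rec.metadata}"
            fh.write(f"{header}\n{seq}\n")


def _parse_collapsed_header(header: str, lineno: int) -> tuple[str, int]:
    base, sep, count_str = header.rpartition("_")
    if not sep or not count_str.isdigit():
        raise FormatError(
            f"line {lineno}: collapsed-FASTA header {header!r} does not "
            f"end in '_<count>'"
        )
    return base, int(count_str)


def read_srna_library(
    path: str | Path, format: str = "tsv", name: str | None = None
) -> SmallRNALibrary:
    """Read a collapsed library from TSV (sequence<TAB>count) or collapsed
    FASTA (headers ``>id_<count>``).

    Reads outside 15-30 nt are kept (they contribute to ``total_count``)
    but flagged out of analysis by :meth:`SmallRNALibrary.accepted_reads`.
    """
    path = Path(path)
    name = name or path.stem
    counts: dict[str, int] = {}

    if format == "tsv":
        with open(path) as fh:
            for lineno, line in enumerate(fh, start=1):
                line = line.rstrip("\n")
                if not line:
                    continue
                fields = line.split("\t")
                if lineno == 1 and fields[0].lower() == "sequence":
                    continue
                if len(fields) < 2:
                    raise FormatError(f"line {lineno}: expected 2 columns")
                seq, count_str = fields[0], fields[1]
                try:
                    count = int(count_str)
                except ValueError:
                    raise FormatError(
                        f"line {lineno}: non-integer count {count_str!r}"
                    ) from None
                counts[to_dna(seq)] = counts.get(to_dna(seq), 0) + count
    elif format == "collapsed_fasta":
        lineno = 0
        for entry in SeqIO.parse(str(path), "fasta"):
            lineno += 1
            _, count = _parse_collapsed_header(entry.id, lineno)
            seq = to_dna(str(entry.seq))
            counts[seq] = counts.get(seq, 0) + count
    else:
        raise ValueError(f"unknown library format {format!r}")

    reads = {s: SmallRNARead(sequence=s, count=c) for s, c in counts.items()}
    return SmallRNALibrary(name=name, reads=reads)


def write_srna_library(library: SmallRNALibrary, path: str | Path) -> None:
    """Write a library as TSV (sequence, count) with a header row."""
    with open(path, "w") as fh:
        fh.write("sequence\tcount\n")
        for seq in sorted(library.reads):
            fh.write(f"{seq}\t{library.reads[seq].count}\n")


def normalize_rpm(library: SmallRNALibrary) -> SmallRNALibrary:
    """Return a copy with rpm = count * 1e6 / total_count on every read.

    The divisor is the library's pre-filter total, so Σ rpm over *all*
    reads is exactly 1e6.
    """
    if library.total_count <= 0:
        raise ValueError(f"empty library {library.name!r}")
    scale = 1e6 / library.total_count
    reads = {
        s: replace(r, rpm=r.count * scale) for s, r in library.reads.items()
    }
    return SmallRNALibrary(
        name=library.name, reads=reads, total_count=library.total_count
    )


def assert_rpm_conserved(library: SmallRNALibrary, rel_tol: float = 1e-6) -> None:
    total = sum(r.rpm for r in library.reads.values())
    if not math.isclose(total, 1e6, rel_tol=rel_tol):
        raise AssertionError(f"Σ rpm = {total}, expected 1e6")
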