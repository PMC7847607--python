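"""24-nt phasiRNA promoter targeting and RdDM methylation analysis.

24-nt phasiRNAs direct DNA methylation (RdDM) at promoters carrying a
perfectly complementary binding site.  This module finds those sites by
exact 24-mer search, profiles bisulfite methylation per cytosine and
context (CG / CHG / CHH, H = A, C or T), computes expression in RPM, and
tests the RdDM expectation: the tissue expressing the phasiRNA shows
higher CHH methylation at the target promoter together with lower target
expression.

Bisulfite reads are matched "three-letter": unmethylated Cs read as T, so
a read maps where it equals the promoter after collapsing C->T on both
(forward strand) or G->A on both (reads from the reverse strand, viewed
in sense coordinates).  Only reads with exactly one placement across all
supplied promoters are used.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Mapping

import pandas as pd

from .phase_model import find_occurrences
from .seq_io import SequenceRecord, SmallRNALibrary, revcomp
from .tasirna import PhasiRNA

CONTEXTS = ("CG", "CHG", "CHH")


@dataclass(frozen=True)
class PromoterHit:
    phasirna_name: str
    phasirna_sequence: str  # DNA-internal
    promoter_id: str
    start: int
    end: int
    orientation: str  # "complementary" (the RdDM-relevant case) or "identical"


@dataclass(frozen=True)
class CytosineRecord:
    position: int  # 1-based sense coordinate (for '-' strand: the G on sense)
    strand: str
    context: str
    methylated_count: int
    total_count: int
    methylated_rpm: float
    total_rpm: float

    @property
    def fraction(self) -> float:
        return self.methylated_count / self.total_count if self.total_count else 0.0


@dataclass
class MethylationProfile:
    promoter_id: str
    library_name: str
    cytosines: list[CytosineRecord] = field(default_factory=list)

    def context_total(self, context: str, column: str = "methylated_rpm") -> float:
        return sum(getattr(c, column) for c in self.cytosines if c.context == context)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            [
                {
                    "position": c.position,
                    "strand": c.strand,
                    "context": c.context,
                    "methylated_rpm": c.methylated_rpm,
                    "total_rpm": c.total_rpm,
                    "fraction": c.fraction,
                }
                for c in self.cytosines
            ],
            columns=[
                "position",
                "strand",
                "context",
                "methylated_rpm",
                "total_rpm",
                "fraction",
            ],
        )


def find_promoter_hits(
    phasirnas: Iterable[PhasiRNA],
    promoters: Iterable[SequenceRecord],
) -> list[PromoterHit]:
    """Every zero-mismatch 24-mer site of each phasiRNA on each promoter.

    The reverse complement of the phasiRNA marks a binding site proper
    ("complementary"); a verbatim occurrence of the phasiRNA's DNA form
    is reported too, flagged "identical".
    """
    promoters = list(promoters)
    hits: list[PromoterHit] = []
    for p in phasirnas:
        if p.k != 24:
            continue
        site = revcomp(p.sequence)
        for prom in promoters:
            for start in find_occurrences(site, prom.sequence):
                hits.append(
                    PromoterHit(
                        p.name, p.sequence, prom.id,
                        start, start + p.k - 1, "complementary",
                    )
                )
            for start in find_occurrences(p.sequence, prom.sequence):
                hits.append(
                    PromoterHit(
                        p.name, p.sequence, prom.id,
                        start, start + p.k - 1, "identical",
                    )
                )
    hits.sort(key=lambda h: (h.promoter_id, h.start, h.orientation))
    return hits


def classify_context(sequence: str, position: int, strand: str = "+") -> str:
    """CG / CHG / CHH context of a cytosine (standard trinucleotide rule).

    ``position`` is 1-based on the sense strand; for strand '-', the sense
    base there is G and the context is read leftward on the complement.
    Truncated triplets at the 3' end default to CHH unless the CG
    dinucleotide is complete.
    """
    seq = sequence.upper()
    if strand == "-":
        rc = revcomp(seq)
        return classify_context(rc, len(seq) - position + 1, "+")
    if seq[position - 1] != "C":
        raise ValueError(
            f"base at position {position} is {seq[position - 1]!r}, not C"
        )
    nxt = seq[position] if position < len(seq) else None
    nxt2 = seq[position + 1] if position + 1 < len(seq) else None
    if nxt == "G":
        return "CG"
    if nxt is None:
        return "CHH"
    if nxt2 == "G":
        return "CHG"
    return "CHH"


def _collapse(seq: str, mode: str) -> str:
    return seq.replace("C", "T") if mode == "CT" else seq.replace("G", "A")


def map_bisulfite_reads(
    library: SmallRNALibrary,
    promoters: Iterable[SequenceRecord],
) -> dict[str, dict[tuple[int, str], tuple[int, int]]]:
    """Unique three-letter mapping of bisulfite reads to promoters.

    Returns, per promoter id, ``{(position, strand): (methylated_count,
    total_count)}`` over the reference cytosines each retained read
    covers.  Forward-strand evidence: read C at a reference C means the
    cytosine was methylated (protected), read T means converted.
    Reverse-strand reads are evaluated in sense coordinates at reference
    Gs via the G->A collapse.  Reads with more than one placement across
    all promoters are discarded.
    """
    promoters = list(promoters)
    fwd_ref = {p.id: _collapse(p.sequence, "CT") for p in promoters}
    rev_ref = {p.id: _collapse(p.sequence, "GA") for p in promoters}

    counts: dict[str, dict[tuple[int, str], list[int]]] = {
        p.id: {} for p in promoters
    }
    for read in library.reads.values():
        placements: list[tuple[str, int, str]] = []  # (promoter, start, strand)
        fwd_query = _collapse(read.sequence, "CT")
        for p in promoters:
            for start in find_occurrences(fwd_query, fwd_ref[p.id]):
                placements.append((p.id, start, "+"))
        rev_query = _collapse(revcomp(read.sequence), "GA")
        for p in promoters:
            for start in find_occurrences(rev_query, rev_ref[p.id]):
                placements.append((p.id, start, "-"))
        if len(placements) != 1:
            continue
        pid, start, strand = placements[0]
        promoter = next(p for p in promoters if p.id == pid)
        read_on_sense = (
            read.sequence if strand == "+" else revcomp(read.sequence)
        )
        for offset, ref_base in enumerate(
            promoter.sequence[start - 1 : start - 1 + len(read)]
        ):
            pos = start + offset
            if strand == "+" and ref_base == "C":
                meth = read_on_sense[offset] == "C"
            elif strand == "-" and ref_base == "G":
                meth = read_on_sense[offset] == "G"
            else:
                continue
            cell = counts[pid].setdefault((pos, strand), [0, 0])
            cell[0] += read.count if meth else 0
            cell[1] += read.count
    return {
        pid: {key: (m, t) for key, (m, t) in cells.items()}
        for pid, cells in counts.items()
    }


def methylation_profile(
    counts: Mapping[tuple[int, str], tuple[int, int]],
    library_total: int,
    promoter: SequenceRecord,
    library_name: str = "",
) -> MethylationProfile:
    """Per-cytosine RPM profile from mapped bisulfite counts.

    ``methylated_rpm`` is methylated-read coverage in RPM of the whole
    bisulfite library; the conventional methylated fraction is carried
    alongside because per-cytosine "coverage in RPM" admits both readings.
    """
    if library_total <= 0:
        raise ValueError("bisulfite library_total must be positive")
    scale = 1e6 / library_total
    records = []
    for (pos, strand), (meth, total) in sorted(counts.items()):
        sense_base = promoter.sequence[pos - 1]
        expected = "C" if strand == "+" else "G"
        if sense_base != expected:
            raise ValueError(
                f"position {pos} strand {strand}: sense base {sense_base!r}"
            )
        records.append(
            CytosineRecord(
                position=pos,
                strand=strand,
                context=classify_context(promoter.sequence, pos, strand),
                methylated_count=meth,
                total_count=total,
                methylated_rpm=meth * scale,
                total_rpm=total * scale,
            )
        )
    return MethylationProfile(
        promoter_id=promoter.id, library_name=library_name, cytosines=records
    )


def expression_rpm(rnaseq: SmallRNALibrary, cdna: SequenceRecord) -> float:
    """Gene expression as total RPM of reads matching the cDNA (sense)."""
    return sum(
        read.rpm
        for read in rnaseq.reads.values()
        if read.sequence in cdna.sequence
    )


@dataclass(frozen=True)
class RdDMComparison:
    promoter_id: str
    expressing_tissue: str
    other_tissue: str
    chh_expressing: float
    chh_other: float
    expression_expressing: float
    expression_other: float
    cg: tuple[float, float] = (0.0, 0.0)
    chg: tuple[float, float] = (0.0, 0.0)
    consistent: bool = False


def compare_tissues(
    profile_expressing: MethylationProfile,
    profile_other: MethylationProfile,
    expression_expressing: float,
    expression_other: float,
    expressing_tissue: str = "expressing",
    other_tissue: str = "other",
) -> RdDMComparison:
    """Test RdDM consistency between the phasiRNA-expressing tissue and
    a reference tissue.

    Consistent iff total CHH methylated RPM is strictly higher in the
    expressing tissue AND target expression is strictly lower there.
    CG/CHG totals are reported but do not enter the call.
    """
    chh_a = profile_expressing.context_total("CHH")
    chh_b = profile_other.context_total("CHH")
    consistent = chh_a > chh_b and expression_expressing < expression_other
    return RdDMComparison(
        promoter_id=profile_expressing.promoter_id,
        expressing_tissue=expressing_tissue,
        other_tissue=other_tissue,
        chh_expressing=chh_a,
        chh_other=chh_b,
        expression_expressing=expression_expressing,
        expression_other=expression_other,
        cg=(profile_expressing.context_total("CG"), profile_other.context_total("CG")),
        chg=(
            profile_expressing.context_total("CHG"),
            profile_other.context_total("CHG"),
        ),
        consistent=consistent,
    )
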