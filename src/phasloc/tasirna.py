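"""phasiRNA enumeration, D-position naming, and target validation.

Mature phasiRNAs are read off the precursor's phase grid.  Counting away
from the trigger-cleavage anchor, duplex i on the 3' fragment ("3'D<i>")
has its sense-strand phasiRNA at ``[anchor + (i-1)k, anchor + ik - 1]``
and its antisense partner (2-nt 3' overhang) as the reverse complement of
``[anchor + (i-1)k - 2, anchor + ik - 3]``.  The 5'-side grid ("5'D<i>")
mirrors this into the upstream fragment, duplex i at
``[anchor - ik, anchor - ik + k - 1]``.

Names follow the field's convention ``Locus(anchor)k 3'D<i>(+)`` and
round-trip through :func:`parse_phasirna_name`.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, replace
from typing import Iterable

import numpy as np

from .degradome import (
    DEFAULT_MIN_DOMINANCE,
    DEFAULT_MIN_RPM,
    DegradomeProfile,
    detect_cleavage,
)
from .seq_io import SequenceRecord, SmallRNALibrary, revcomp, to_rna
from .triggers import MAX_PENALTY, predict_cleavage_site, scan_target

import pandas as pd


@dataclass(frozen=True)
class PhasiRNA:
    locus_id: str
    anchor: int
    k: int
    duplex_index: int
    strand: str  # '+' or '-'
    arm: str  # "3'" (downstream of the anchor) or "5'" (upstream)
    sequence: str  # DNA-internal, length k
    rpm: float = 0.0

    @property
    def name(self) -> str:
        return format_phasirna_name(self)

    @property
    def rna_sequence(self) -> str:
        return to_rna(self.sequence)


@dataclass(frozen=True)
class TargetInteraction:
    phasirna: PhasiRNA
    target_id: str
    miru_start: int
    miru_end: int
    score: float
    validated: bool = False
    validating_libraries: tuple[str, ...] = ()

    @property
    def predicted_cut(self) -> int:
        return predict_cleavage_site(self.miru_start, self.miru_end)


def format_phasirna_name(p: PhasiRNA) -> str:
    return f"{p.locus_id}({p.anchor}){p.k} {p.arm}D{p.duplex_index}({p.strand})"


_NAME_RE = re.compile(
    r"^(?P<locus>\S+?)\((?P<anchor>\d+)\)\s*(?P<k>\d+)\s*"
    r"(?P<arm>5|3)\s*['’′]\s*D\s*(?P<index>\d+)\s*"
    r"\((?P<strand>[+−-])\)$"
)


def parse_phasirna_name(name: str) -> dict:
    """Parse a phasiRNA name back to its fields.

    Tolerates the typographic drift seen in published tables (curly or
    prime apostrophes, stray spaces, minus sign variants).
    """
    m = _NAME_RE.match(name.strip())
    if not m:
        raise ValueError(f"unparseable phasiRNA name {name!r}")
    strand = "-" if m.group("strand") in "-−" else "+"
    return {
        "locus_id": m.group("locus"),
        "anchor": int(m.group("anchor")),
        "k": int(m.group("k")),
        "arm": m.group("arm") + "'",
        "duplex_index": int(m.group("index")),
        "strand": strand,
    }


def duplex_top_span(anchor: int, k: int, index: int, arm: str) -> tuple[int, int]:
    """Sense-strand span of the top strand of duplex ``index`` on ``arm``."""
    if index < 1:
        raise ValueError("duplex index must be >= 1")
    if arm == "3'":
        start = anchor + (index - 1) * k
    elif arm == "5'":
        start = anchor - index * k
    else:
        raise ValueError(f"arm must be \"3'\" or \"5'\", got {arm!r}")
    return start, start + k - 1


def phasirna_sequence(
    transcript: SequenceRecord, anchor: int, k: int, index: int, arm: str, strand: str
) -> str:
    """Mature phasiRNA sequence at one grid slot (DNA alphabet)."""
    start, end = duplex_top_span(anchor, k, index, arm)
    if strand == "+":
        return transcript.subseq(start, end)
    # bottom strand: 2-nt 3' overhang shifts the span 2 nt left
    return revcomp(transcript.subseq(start - 2, end - 2))


def enumerate_phasirnas(
    transcript: SequenceRecord,
    anchor: int,
    k: int,
    library: SmallRNALibrary | None = None,
    arm: str = "3'",
    max_duplexes: int | None = None,
    region_end: int | None = None,
) -> list[PhasiRNA]:
    """Emit both strands of every grid duplex on one arm of the anchor.

    Enumeration runs outward from the anchor until the duplex no longer
    fits the transcript (or the region/count limit).  Each phasiRNA
    carries the RPM of the identical library read, 0 if undetected.
    """
    if not 1 <= anchor <= len(transcript):
        raise ValueError(
            f"anchor {anchor} outside transcript {transcript.id!r}"
        )
    rpm_of = (
        {s: r.rpm for s, r in library.reads.items()} if library is not None else {}
    )
    out: list[PhasiRNA] = []
    index = 0
    while True:
        index += 1
        if max_duplexes is not None and index > max_duplexes:
            break
        start, end = duplex_top_span(anchor, k, index, arm)
        if start - 2 < 1 or end > len(transcript):
            break
        if region_end is not None and arm == "3'" and end > region_end:
            break
        for strand in "+-":
            seq = phasirna_sequence(transcript, anchor, k, index, arm, strand)
            out.append(
                PhasiRNA(
                    locus_id=transcript.id,
                    anchor=anchor,
                    k=k,
                    duplex_index=index,
                    strand=strand,
                    arm=arm,
                    sequence=seq,
                    rpm=rpm_of.get(seq, 0.0),
                )
            )
    return out


def predict_targets(
    phasirna: PhasiRNA,
    transcripts: Iterable[SequenceRecord],
    max_score: float = MAX_PENALTY,
) -> list[TargetInteraction]:
    """miRU-style sweep of a phasiRNA across a transcript set."""
    interactions: list[TargetInteraction] = []
    for transcript in transcripts:
        penalties = scan_target(phasirna.sequence, transcript.sequence)
        for idx in np.flatnonzero(penalties <= max_score):
            start = int(idx) + 1
            interactions.append(
                TargetInteraction(
                    phasirna=phasirna,
                    target_id=transcript.id,
                    miru_start=start,
                    miru_end=start + phasirna.k - 1,
                    score=float(penalties[idx]),
                )
            )
    interactions.sort(key=lambda t: (t.score, t.target_id, t.miru_start))
    return interactions


def validate_interactions(
    interactions: Iterable[TargetInteraction],
    profiles: Iterable[DegradomeProfile],
    min_rpm: float = DEFAULT_MIN_RPM,
    min_dominance: float = DEFAULT_MIN_DOMINANCE,
) -> list[TargetInteraction]:
    """Flag interactions whose predicted cut has degradome support.

    An interaction is validated when at least one library shows a
    dominant signal exactly at the predicted cut site.
    """
    profiles = list(profiles)
    out: list[TargetInteraction] = []
    for inter in interactions:
        cut = inter.predicted_cut
        supporting = []
        for profile in profiles:
            if profile.transcript_id != inter.target_id:
                continue
            if detect_cleavage(profile, (cut, cut), min_rpm, min_dominance):
                supporting.append(profile.library_name)
        out.append(
            replace(
                inter,
                validated=bool(supporting),
                validating_libraries=tuple(supporting),
            )
        )
    return out


def build_network_table(
    interactions: Iterable[TargetInteraction],
) -> pd.DataFrame:
    """Edge table of validated phasiRNA->target interactions.

    One row per unique (phasiRNA, target) pair, ready for network tools;
    node roles are annotated in a separate column.
    """
    rows = []
    seen = set()
    for inter in interactions:
        if not inter.validated:
            continue
        key = (inter.phasirna.name, inter.target_id)
        if key in seen:
            continue
        seen.add(key)
        rows.append(
            {
                "phasirna": inter.phasirna.name,
                "target": inter.target_id,
                "score": inter.score,
                "cut_site": inter.predicted_cut,
                "edge_type": "phasiRNA->target",
            }
        )
    return pd.DataFrame(
        rows, columns=["phasirna", "target", "score", "cut_site", "edge_type"]
    )
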