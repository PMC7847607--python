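"""DCL dependence: wild-type vs dcl-mutant phasiRNA abundance.

In rice, DCL4 produces 21-nt and DCL3 24-nt phasiRNAs, so a genuine PHAS
locus loses its phased reads in the matching dcl mutant.  The call
compares summed in-phase k-nt RPM inside the region between a wild-type
and a mutant library; a locus is dependent when the wild-type carries at
least ``threshold``-fold more (mutant RPM floored at ε to keep the fold
finite).
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable

from .phase_model import CandidateRegion, ReadPlacement, classify_phase, map_reads
from .seq_io import SequenceRecord, SmallRNALibrary, normalize_rpm

DEFAULT_FOLD_THRESHOLD = 2.0
EPSILON_RPM = 0.1


@dataclass(frozen=True)
class DependenceCall:
    locus_id: str
    k: int
    wt_rpm: float
    mutant_rpm: float
    fold: float
    dependent: bool


def region_phased_rpm(
    placements: Iterable[ReadPlacement], region: CandidateRegion
) -> float:
    """Summed RPM of in-phase k-nt reads whose 5' end lies in the region."""
    total = 0.0
    for p in placements:
        if p.transcript_id != region.transcript_id or p.length != region.k:
            continue
        if not region.region_start <= p.five_prime_pos <= region.region_end:
            continue
        if classify_phase(p, region.anchor, region.k):
            total += p.read.rpm
    return total


def call_dependence(
    region: CandidateRegion,
    wt: SmallRNALibrary,
    mutant: SmallRNALibrary,
    transcript: SequenceRecord,
    threshold: float = DEFAULT_FOLD_THRESHOLD,
    epsilon: float = EPSILON_RPM,
) -> DependenceCall:
    """Fold change of in-phase abundance, wild type over mutant.

    Libraries are (re)normalised from their counts, so raw and
    pre-normalised inputs behave identically.
    """
    wt_rpm = region_phased_rpm(map_reads(normalize_rpm(wt), [transcript]), region)
    mutant_rpm = region_phased_rpm(
        map_reads(normalize_rpm(mutant), [transcript]), region
    )
    fold = wt_rpm / max(mutant_rpm, epsilon)
    return DependenceCall(
        locus_id=region.transcript_id,
        k=region.k,
        wt_rpm=wt_rpm,
        mutant_rpm=mutant_rpm,
        fold=fold,
        dependent=fold >= threshold,
    )
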