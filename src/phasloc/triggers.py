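"""Trigger search: the sRNA whose cleavage sets the phase register.

Complementarity is scored with a miRU-style penalty (antiparallel,
ungapped): Watson-Crick pair 0, G:U wobble 0.5, mismatch 1.0, all
penalties doubled at sRNA positions 2-7 (the core).  An alignment is a
candidate trigger when its penalty is at most 3.0 and its predicted
cleavage position — the target base paired to sRNA position 10, i.e.
``binding_end - 9`` — lands at the candidate region's 5' flank or on its
register.  Validation requires a dominant degradome signal at exactly the
predicted position in at least one library.
"""

from __future__ import annotations

from dataclasses import dataclass, replace
from typing import Iterable, Sequence

import numpy as np

from .degradome import (
    DEFAULT_MIN_DOMINANCE,
    DEFAULT_MIN_RPM,
    DegradomeProfile,
    detect_cleavage,
    flank_check,
)
from .phase_model import CandidateRegion
from .seq_io import SequenceRecord, SmallRNALibrary, to_dna, to_rna

MAX_PENALTY = 3.0
CORE_START, CORE_END = 2, 7  # sRNA positions with doubled penalties
TRIGGER_MIN_LEN, TRIGGER_MAX_LEN = 18, 24

_BASE_INDEX = {"A": 0, "C": 1, "G": 2, "T": 3}

# penalty[srna_base, target_base]; both in DNA alphabet, target read as
# mRNA (T == U).  WC pairs 0; G:U wobble (sRNA G : target U, sRNA U :
# target G) 0.5; everything else 1.
_PENALTY = np.ones((4, 4))
for _s, _t in (("A", "T"), ("C", "G"), ("G", "C"), ("T", "A")):
    _PENALTY[_BASE_INDEX[_s], _BASE_INDEX[_t]] = 0.0
_PENALTY[_BASE_INDEX["G"], _BASE_INDEX["T"]] = 0.5
_PENALTY[_BASE_INDEX["T"], _BASE_INDEX["G"]] = 0.5


@dataclass(frozen=True)
class TriggerAlignment:
    srna_id: str
    srna_sequence: str  # RNA display form
    transcript_id: str
    binding_start: int
    binding_end: int
    score: float
    rpm: float = 0.0
    validated: bool = False
    validating_libraries: tuple[str, ...] = ()

    @property
    def predicted_cleavage(self) -> int:
        return predict_cleavage_site(self.binding_start, self.binding_end)


def predict_cleavage_site(binding_start: int, binding_end: int) -> int:
    """Cleavage falls opposite sRNA position 10: ``binding_end - 9``.

    Counting from the sRNA's own 5' end (which pairs with the 3' end of
    the binding site), position 10 faces the target base that becomes the
    5' end of the downstream fragment — for 21- and 22-nt triggers alike.
    """
    if binding_end < binding_start:
        raise ValueError("binding_end before binding_start")
    if binding_end - binding_start + 1 < 10:
        raise ValueError("binding site shorter than 10 nt")
    return binding_end - 9


def _encode(seq: str) -> np.ndarray:
    return np.fromiter((_BASE_INDEX[b] for b in seq), dtype=np.int8, count=len(seq))


def _position_weights(length: int) -> np.ndarray:
    # weights along the *target window* (sense 5'->3'); sRNA position i
    # pairs with window position length - i, so the core sits at the 3'
    # end of the window.
    srna_pos = np.arange(length, 0, -1)  # sRNA position per window column
    return np.where((srna_pos >= CORE_START) & (srna_pos <= CORE_END), 2.0, 1.0)


def score_complementarity(srna: str, target_window: str) -> float:
    """Penalty of an ungapped antiparallel sRNA:target alignment."""
    srna_dna = to_dna(srna)
    target_dna = to_dna(target_window)
    if len(srna_dna) != len(target_dna):
        raise ValueError(
            f"sRNA ({len(srna_dna)} nt) and target window "
            f"({len(target_dna)} nt) must be equal length (ungapped)"
        )
    s = _encode(srna_dna)[::-1]  # sRNA 3'->5' along the sense window
    t = _encode(target_dna)
    return float(np.sum(_PENALTY[s, t] * _position_weights(len(s))))


def scan_target(srna: str, target: str) -> np.ndarray:
    """Penalty at every window start of ``target`` (vectorised sweep)."""
    srna_dna = to_dna(srna)
    target_dna = to_dna(target)
    L = len(srna_dna)
    if len(target_dna) < L:
        return np.empty(0)
    s = _encode(srna_dna)[::-1]
    t = _encode(target_dna)
    windows = np.lib.stride_tricks.sliding_window_view(t, L)
    return (_PENALTY[s[None, :], windows] * _position_weights(L)).sum(axis=1)


def find_trigger(
    candidates: SmallRNALibrary,
    transcript: SequenceRecord,
    region: CandidateRegion,
    known_mirnas: Sequence[SequenceRecord] = (),
    max_score: float = MAX_PENALTY,
    flank_tolerance: int = 2,
) -> list[TriggerAlignment]:
    """All candidate triggers for a region, best first.

    The search space is the union of the supplied known-miRNA set and all
    18-24-nt library reads; alignments must score <= ``max_score`` and
    their predicted cleavage must pass the region flank check.  Sorted by
    (penalty, -RPM).
    """
    pool: list[tuple[str, str, float]] = []
    for rec in known_mirnas:
        pool.append((rec.id, rec.sequence, 0.0))
    for read in candidates.accepted_reads():
        if TRIGGER_MIN_LEN <= len(read) <= TRIGGER_MAX_LEN:
            pool.append((f"sRNA:{to_rna(read.sequence)}", read.sequence, read.rpm))

    alignments: list[TriggerAlignment] = []
    for srna_id, seq, rpm in pool:
        penalties = scan_target(seq, transcript.sequence)
        for idx in np.flatnonzero(penalties <= max_score):
            start = int(idx) + 1
            end = start + len(seq) - 1
            cut = predict_cleavage_site(start, end)
            if not flank_check(cut, region, tolerance=flank_tolerance):
                continue
            alignments.append(
                TriggerAlignment(
                    srna_id=srna_id,
                    srna_sequence=to_rna(seq),
                    transcript_id=transcript.id,
                    binding_start=start,
                    binding_end=end,
                    score=float(penalties[idx]),
                    rpm=rpm,
                )
            )
    alignments.sort(key=lambda a: (a.score, -a.rpm, a.binding_start))
    return alignments


def validate_trigger(
    alignment: TriggerAlignment,
    profiles: Iterable[DegradomeProfile],
    min_rpm: float = DEFAULT_MIN_RPM,
    min_dominance: float = DEFAULT_MIN_DOMINANCE,
    jitter: int = 0,
) -> TriggerAlignment:
    """Confirm the predicted cleavage against degradome profiles.

    Validated when at least one library shows a dominant signal within
    ``jitter`` nt (default 0: exact) of the predicted position.
    """
    cut = alignment.predicted_cleavage
    supporting = []
    for profile in profiles:
        if profile.transcript_id != alignment.transcript_id:
            continue
        hits = detect_cleavage(
            profile, (cut - jitter, cut + jitter), min_rpm, min_dominance
        )
        if hits:
            supporting.append(profile.library_name)
    return replace(
        alignment,
        validated=bool(supporting),
        validating_libraries=tuple(supporting),
    )
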