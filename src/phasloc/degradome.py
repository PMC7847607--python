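"""Degradome (PARE) 5'-tag profiles and cleavage-signal detection.

Degradome tags are the 5' ends of uncapped cleavage fragments, so they are
mapped sense-strand only; a pileup of tag 5' ends at one position marks an
sRNA-guided cleavage site (the data behind a T-plot).
"""

from __future__ import annotations

from dataclasses import dataclass, field

from .phase_model import CandidateRegion, find_occurrences
from .seq_io import DegradomeLibrary, SequenceRecord

DEFAULT_MIN_RPM = 1.0
DEFAULT_MIN_DOMINANCE = 2.0
DOMINANCE_FLANK = 50  # nt of background context on each side
EPSILON_RPM = 0.1  # background floor so dominance is always finite


@dataclass
class DegradomeProfile:
    """Per-position 5'-tag RPM on one transcript for one library."""

    transcript_id: str
    library_name: str
    signal: dict[int, float] = field(default_factory=dict)

    def rpm_at(self, position: int) -> float:
        return self.signal.get(position, 0.0)


@dataclass(frozen=True)
class CleavageSignal:
    position: int
    rpm: float
    library_name: str
    dominance: float


def build_profile(
    degradome: DegradomeLibrary, transcript: SequenceRecord
) -> DegradomeProfile:
    """Sum tag RPM at each sense-strand 5' coordinate of exact matches."""
    signal: dict[int, float] = {}
    for tag in degradome.accepted_reads():
        for start in find_occurrences(tag.sequence, transcript.sequence):
            signal[start] = signal.get(start, 0.0) + tag.rpm
    return DegradomeProfile(
        transcript_id=transcript.id,
        library_name=degradome.name,
        signal=signal,
    )


def dominance_at(profile: DegradomeProfile, position: int) -> float:
    """Signal RPM over the strongest background in the ±50-nt flank."""
    rpm = profile.rpm_at(position)
    background = max(
        (
            v
            for p, v in profile.signal.items()
            if p != position and abs(p - position) <= DOMINANCE_FLANK
        ),
        default=0.0,
    )
    return rpm / max(background, EPSILON_RPM)


def detect_cleavage(
    profile: DegradomeProfile,
    window: tuple[int, int],
    min_rpm: float = DEFAULT_MIN_RPM,
    min_dominance: float = DEFAULT_MIN_DOMINANCE,
) -> list[CleavageSignal]:
    """Dominant cleavage signals inside ``window`` (1-based inclusive).

    A position qualifies when its RPM >= min_rpm and it stands at least
    ``min_dominance``-fold over the strongest other signal within ±50 nt.
    Results are sorted by RPM descending, ties by position ascending.
    """
    lo, hi = window
    signals = []
    for position, rpm in profile.signal.items():
        if position < lo or position > hi or rpm < min_rpm:
            continue
        dom = dominance_at(profile, position)
        if dom >= min_dominance:
            signals.append(
                CleavageSignal(
                    position=position,
                    rpm=rpm,
                    library_name=profile.library_name,
                    dominance=dom,
                )
            )
    signals.sort(key=lambda s: (-s.rpm, s.position))
    return signals


def flank_check(
    signal_position: int, region: CandidateRegion, tolerance: int = 2
) -> bool:
    """Is a cleavage position a plausible phasing initiator for a region?

    True when the position lies within ``tolerance`` nt of the region's 5'
    flank, or when it is register-concordant (congruent to the anchor mod
    k) — the cleavage that set the phase must define a register.
    """
    if abs(signal_position - region.region_start) <= tolerance:
        return True
    return (signal_position - region.anchor) % region.k == 0
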