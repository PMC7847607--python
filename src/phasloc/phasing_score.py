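"""The five-register sliding-window phasing score.

For a window of five consecutive phase registers (5k nt):

    score = (n - 2) * ln(1 + 10 * Σp / (1 + ΣU))

where n is the number of the five registers occupied by at least one
unique in-phase k-nt read, Σp the total read count of all in-phase k-nt
reads in the window, and ΣU the number of unique out-of-phase k-nt reads
in the window.  Note the deliberate asymmetry: p in total reads, U in
unique reads.  A window with n = 2 scores 0, and n < 2 scores negative;
a locus passes the filter only when some window scores strictly above 1.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass
from typing import Iterable

from .phase_model import ReadPlacement, classify_phase

WINDOW_REGISTERS = 5
SCORE_THRESHOLD = 1.0  # pass iff max window score > this (strict)


@dataclass(frozen=True)
class PhasingWindow:
    start_register: int  # 1-based sense position of the window's first register
    k: int
    n: int  # registers (0-5) occupied by >=1 unique in-phase k-nt read
    p_sum: int  # total in-phase read count in the window
    u_sum: int  # unique out-of-phase k-nt reads in the window
    score: float


def window_score(n: int, p_sum: float, u_sum: float) -> float:
    """Closed-form window score (n - 2) * ln(1 + 10*p/(1+u))."""
    if n < 0 or n > WINDOW_REGISTERS:
        raise ValueError(f"n must be in [0, {WINDOW_REGISTERS}], got {n}")
    if p_sum < 0 or u_sum < 0:
        raise ValueError("p_sum and u_sum must be non-negative")
    return (n - 2) * math.log1p(10.0 * p_sum / (1.0 + u_sum))


def score_profile(
    placements: Iterable[ReadPlacement],
    anchor: int,
    k: int,
    span: tuple[int, int],
    include_all_lengths_in_u: bool = False,
) -> list[PhasingWindow]:
    """Per-register window profile over ``span`` (1-based inclusive).

    The window slides register by register (step k nt) starting at every
    register position >= span start whose 5k-nt extent fits inside the
    span.  In/out-of-phase tallies follow the duplex phase rule on both
    strands.  By default only k-nt reads count toward ΣU; the flag admits
    all read lengths.
    """
    start, end = span
    if end - start + 1 < WINDOW_REGISTERS * k:
        warnings.warn(
            f"span {start}-{end} shorter than a {WINDOW_REGISTERS}-register "
            f"window ({WINDOW_REGISTERS * k} nt); empty profile",
            stacklevel=2,
        )
        return []

    placements = list(placements)
    # first register position in span on the anchor's residue class
    first = anchor + math.ceil((start - anchor) / k) * k
    windows: list[PhasingWindow] = []
    reg = first
    while reg + WINDOW_REGISTERS * k - 1 <= end:
        win_lo, win_hi = reg, reg + WINDOW_REGISTERS * k - 1
        occupied: set[int] = set()
        p_sum = 0
        unique_out: set[tuple[str, str, int]] = set()
        for p in placements:
            fp = p.five_prime_pos
            if fp < win_lo or fp > win_hi:
                continue
            if p.length == k and classify_phase(p, anchor, k):
                # register index within window via the top-strand start
                top = fp if p.strand == "+" else fp - (k - 3)
                if win_lo <= top <= win_hi:
                    occupied.add((top - reg) // k)
                    p_sum += p.read.count
            elif p.length == k or include_all_lengths_in_u:
                unique_out.add((p.read.sequence, p.strand, p.start))
        u_sum = len({seq for seq, _, _ in unique_out})
        n = len(occupied)
        windows.append(
            PhasingWindow(
                start_register=reg,
                k=k,
                n=n,
                p_sum=p_sum,
                u_sum=u_sum,
                score=window_score(n, p_sum, u_sum),
            )
        )
        reg += k
    return windows


def region_max_score(profile: list[PhasingWindow]) -> float:
    """Maximum window score of a profile (the locus-level statistic)."""
    if not profile:
        raise ValueError("empty phasing-score profile")
    return max(w.score for w in profile)


def passes_filter(profile: list[PhasingWindow]) -> bool:
    """A candidate locus passes iff its best window scores strictly > 1."""
    return region_max_score(profile) > SCORE_THRESHOLD
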