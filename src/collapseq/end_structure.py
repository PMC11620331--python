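"""Asymmetry statistics distinguishing single- from double-ended breaks.

A single-ended break (fork run-off at a leading-strand nick) leaves all
its sequenced DNA ends on one side of the nick; a double-ended break
(bypass at a lagging-strand nick) leaves ends on both sides.  Counting
reads L in the 3 kb window left of the nick and R in the 3 kb window to
its right, the asymmetry statistic

    asymmetry = 0.5 - R / (L + R)

is 0 for a perfectly symmetric (double-ended) break and +/-0.5 for a
fully one-sided (single-ended) break.  The statistic is signed here —
negative when the dominant end lies right of the nick, as at sites hit by
leftward forks — and classification uses its magnitude.  The nick base
itself belongs to the right window (half-open convention).
"""

from __future__ import annotations

import math

from .tracks_io import NickSite, StrandedTrack

SE_DSB = "seDSB"
DE_DSB = "deDSB"
AMBIGUOUS = "ambiguous"


def peak_asymmetry(track: StrandedTrack, nick: NickSite, window: int = 3000) -> float:
    """Signed break asymmetry 0.5 - R/(L+R) over +/-``window`` bp windows.

    L sums both strand channels over [nick - window, nick), R over
    [nick, nick + window).  Returns NaN when L + R = 0 (no signal; the
    site should then be excluded from downstream correlation).
    """
    pos = nick.position
    left = track.window_sum(nick.chrom, pos - window, pos)
    right = track.window_sum(nick.chrom, pos, pos + window)
    total = left + right
    if total == 0:
        return math.nan
    return 0.5 - right / total


def rpa_asymmetry(track: StrandedTrack, chrom: str, start: int, end: int) -> float:
    """Ratio of plus- to minus-strand reads over [start, end).

    Reports which side(s) of a break carry resected single-stranded DNA.
    Returns +inf when the minus strand is empty (censored observation)
    and NaN when both strands are empty.
    """
    plus = track.window_sum(chrom, start, end, strand="+")
    minus = track.window_sum(chrom, start, end, strand="-")
    if minus == 0:
        return math.inf if plus > 0 else math.nan
    return plus / minus


def classify_end_structure(
    asymmetry: float, se_threshold: float = 0.25, de_threshold: float = 0.10
) -> str:
    """Classify a break from |asymmetry|: seDSB, deDSB, or ambiguous.

    Thresholds default to 0.25 (|a| >= threshold -> single-ended) and
    0.10 (|a| <= threshold -> double-ended), splitting the empirically
    observed ranges of 0.3-0.4 for one-ended and 0-0.1 for two-ended
    breaks.
    """
    if not math.isfinite(asymmetry):
        raise ValueError("asymmetry must be finite for classification")
    magnitude = abs(asymmetry)
    if magnitude >= se_threshold:
        return SE_DSB
    if magnitude <= de_threshold:
        return DE_DSB
    return AMBIGUOUS
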