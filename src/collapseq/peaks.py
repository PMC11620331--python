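"""Threshold-based peak calling and the peak-qualification/intensity rules.

The caller is a deliberately simple, documented replacement for a
broad-peak caller: contiguous runs of combined-strand signal above a
threshold, merged across short gaps, with a Poisson tail probability
against a uniform background rate as the significance surrogate.  The
defaults mirror the downstream filters actually carried by the analysis
(signal > 3, surrogate p < 0.001); the calling machinery itself is not
where the science lives.

Qualification removes multi-nicking artifacts: a peak is kept only if it
contains exactly one target site and that site is farther than a minimum
separation (default 8 kb) from every other target site.  Distance is
measured site-to-site.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, replace
from typing import Iterable, Sequence

import numpy as np
from scipy import stats

from .tracks_io import RAW, NickSite, Peak, StrandedTrack

logger = logging.getLogger(__name__)

DEFAULT_MIN_SIGNAL = 3.0
DEFAULT_MAX_PVALUE = 0.001
DEFAULT_MIN_SEPARATION = 8000


def call_peaks(
    track: StrandedTrack,
    min_signal: float = DEFAULT_MIN_SIGNAL,
    merge_gap: int = 500,
    background_rate: float = 0.1,
) -> list[Peak]:
    """Call peaks as merged runs of combined-strand signal above min_signal.

    Runs separated by <= ``merge_gap`` bp are merged.  Each peak carries
    its summit (argmax), signal (max combined value), and a Poisson upper
    tail probability P(X >= signal) for X ~ Poisson(background_rate) as
    the significance surrogate.  Output is sorted and disjoint.
    """
    if min_signal <= 0:
        raise ValueError("min_signal must be > 0")
    if track.state == RAW:
        raise ValueError("call_peaks requires a normalized (RPM or spike-normalized) track")
    peaks: list[Peak] = []
    for chrom in track.genome.main:
        signal = track.combined(chrom)
        above = signal > min_signal
        if not above.any():
            continue
        idx = np.flatnonzero(above)
        breaks = np.flatnonzero(np.diff(idx) > 1)
        run_starts = np.concatenate(([idx[0]], idx[breaks + 1]))
        run_ends = np.concatenate((idx[breaks] + 1, [idx[-1] + 1]))
        # merge runs separated by <= merge_gap
        merged: list[list[int]] = [[int(run_starts[0]), int(run_ends[0])]]
        for s, e in zip(run_starts[1:], run_ends[1:]):
            if s - merged[-1][1] <= merge_gap:
                merged[-1][1] = int(e)
            else:
                merged.append([int(s), int(e)])
        for s, e in merged:
            window = signal[s:e]
            summit = s + int(np.argmax(window))
            peak_signal = float(window.max())
            pval = float(stats.poisson.sf(math.ceil(peak_signal) - 1, background_rate))
            peaks.append(
                Peak(chrom=chrom, start=s, end=e, summit=summit, signal=peak_signal, qvalue=pval)
            )
    return peaks


@dataclass
class QualificationReport:
    """Book-keeping of the qualification rules applied to a peak set."""

    n_input: int
    n_kept: int
    n_no_site: int
    n_multi_site: int
    n_too_close: int


def _nearest_other_site_distance(site: NickSite, sites: Sequence[NickSite]) -> float:
    dists = [
        abs(other.position - site.position)
        for other in sites
        if other is not site and other.chrom == site.chrom
    ]
    return float(min(dists)) if dists else math.inf


def qualify_peaks(
    peaks: Iterable[Peak],
    target_sites: Sequence[NickSite],
    min_separation: int = DEFAULT_MIN_SEPARATION,
) -> tuple[list[Peak], QualificationReport]:
    """Retain peaks containing exactly one target site, isolated from others.

    The contained site must be more than ``min_separation`` bp (site to
    site) from every other target site.  Retained peaks are annotated with
    the contained site's label and its nearest-other-site distance.
    Idempotent: re-qualifying the output changes nothing.
    """
    kept: list[Peak] = []
    n_input = n_no = n_multi = n_close = 0
    for peak in peaks:
        n_input += 1
        contained = [
            s for s in target_sites if s.chrom == peak.chrom and peak.start <= s.position < peak.end
        ]
        if len(contained) == 0:
            n_no += 1
            continue
        if len(contained) > 1:
            n_multi += 1
            continue
        site = contained[0]
        dist = _nearest_other_site_distance(site, target_sites)
        if dist <= min_separation:
            n_close += 1
            continue
        kept.append(
            replace(
                peak,
                site_labels=(site.label,),
                nearest_site_dist=None if math.isinf(dist) else dist,
            )
        )
    report = QualificationReport(
        n_input=n_input, n_kept=len(kept), n_no_site=n_no, n_multi_site=n_multi, n_too_close=n_close
    )
    return kept, report


def peak_intensity(track: StrandedTrack, nick: NickSite, halfwidth: int = 30000) -> float:
    """Total signal (both strands) within +/- halfwidth of the nick."""
    start = nick.position - halfwidth
    end = nick.position + halfwidth
    if start < 0 or end > track.genome.length(nick.chrom):
        logger.warning(
            "intensity window around %s:%d clamped to chromosome bounds", nick.chrom, nick.position
        )
    return track.window_sum(nick.chrom, start, end)
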