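"""Stranded coverage tracks, nick sites, peaks, and normalization.

This module holds the data model shared by the whole package and the
plain-text readers/writers around it.

Conventions
-----------
* All coordinates are 0-based, half-open (BED convention).  bedGraph I/O
  follows the UCSC dialect (4 columns, 0-based half-open).
* A :class:`GenomeSpec` carries two namespaces: ``main`` (the genome under
  study) and ``spikein`` (an exogenous genome mixed into the sample at a
  known cell fraction, used for cross-sample normalization).
* A :class:`StrandedTrack` stores per-base read-end counts on the plus and
  minus strands.  "Total mapped reads" is carried as metadata rather than
  inferred from the in-track counts, because library-size normalization
  counts reads outside any displayed region.
* Normalization is a one-way state machine: ``raw`` -> ``RPM`` ->
  ``spike_normalized``.  Re-applying a step raises.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Iterable, Mapping, Optional, Sequence

import numpy as np

logger = logging.getLogger(__name__)

# Normalization states
RAW = "raw"
RPM = "RPM"
SPIKE_NORMALIZED = "spike_normalized"

_STATES = (RAW, RPM, SPIKE_NORMALIZED)


class TrackStateError(RuntimeError):
    """Raised on an illegal normalization-state transition."""


class BedGraphParseError(ValueError):
    """Raised on malformed bedGraph/BED input, with the offending line number."""


@dataclass(frozen=True)
class GenomeSpec:
    """Chromosome names and lengths, split into main and spike-in namespaces.

    Parameters
    ----------
    main
        Mapping of chromosome name to length (bp) for the genome under study.
    spikein
        Same, for the exogenous spike-in genome.  May be empty.
    """

    main: Mapping[str, int]
    spikein: Mapping[str, int] = field(default_factory=dict)

    def __post_init__(self) -> None:
        seen: set[str] = set()
        for ns_name, ns in (("main", self.main), ("spikein", self.spikein)):
            for chrom, length in ns.items():
                if length <= 0:
                    raise ValueError(
                        f"chromosome {chrom!r} in namespace {ns_name} has "
                        f"non-positive length {length}"
                    )
                if chrom in seen:
                    raise ValueError(f"chromosome name {chrom!r} is not unique")
                seen.add(chrom)

    def namespace_of(self, chrom: str) -> str:
        if chrom in self.main:
            return "main"
        if chrom in self.spikein:
            return "spikein"
        raise KeyError(f"unknown chromosome {chrom!r}")

    def length(self, chrom: str) -> int:
        if chrom in self.main:
            return self.main[chrom]
        if chrom in self.spikein:
            return self.spikein[chrom]
        raise KeyError(f"unknown chromosome {chrom!r}")

    @property
    def all_chroms(self) -> tuple[str, ...]:
        return tuple(self.main) + tuple(self.spikein)

    @property
    def main_total_length(self) -> int:
        return sum(self.main.values())


@dataclass(frozen=True)
class NickSite:
    """A single-strand break.

    ``position`` is the 0-based offset of the broken phosphodiester bond:
    the nick lies between ``position - 1`` and ``position``.  The target
    strand is the strand carrying the nick: ``+`` (Watson/top) or ``-``
    (Crick/bottom).
    """

    chrom: str
    position: int
    target_strand: str
    label: str = ""

    def __post_init__(self) -> None:
        if self.target_strand not in ("+", "-"):
            raise ValueError(f"target_strand must be '+' or '-', got {self.target_strand!r}")
        if self.position < 0:
            raise ValueError(f"negative nick position {self.position}")

    def validate_against(self, genome: GenomeSpec) -> None:
        if self.position > genome.length(self.chrom):
            raise ValueError(
                f"nick position {self.position} beyond end of {self.chrom} "
                f"({genome.length(self.chrom)} bp)"
            )


@dataclass(frozen=True)
class Peak:
    """A called break interval with signal and qualification metadata.

    ``qvalue`` is the Poisson tail probability used as the significance
    surrogate by the threshold caller.  ``site_labels`` lists target sites
    contained in the peak; ``nearest_site_dist`` is the distance (bp) from
    the contained site to the nearest *other* target site.
    """

    chrom: str
    start: int
    end: int
    summit: int
    signal: float
    qvalue: float = 1.0
    site_labels: tuple[str, ...] = ()
    nearest_site_dist: Optional[float] = None

    def __post_init__(self) -> None:
        if not self.start < self.end:
            raise ValueError(f"peak start {self.start} must be < end {self.end}")
        if not (self.start <= self.summit < self.end):
            raise ValueError(f"summit {self.summit} outside [{self.start}, {self.end})")
        if self.signal < 0:
            raise ValueError("peak signal must be >= 0")


@dataclass(frozen=True)
class SpikeInConfig:
    """Spike-in locus and the cell fraction at which it was mixed in."""

    chrom: str
    start: int
    end: int
    fraction: float = 0.20

    def __post_init__(self) -> None:
        if not 0.0 < self.fraction < 1.0:
            raise ValueError(f"spike-in fraction must be in (0, 1), got {self.fraction}")
        if not self.start < self.end:
            raise ValueError("spike-in locus start must be < end")


@dataclass
class StrandedTrack:
    """Per-base read-end counts on plus and minus strands over a genome.

    Arrays are dense float64, one per chromosome per strand, spanning both
    the main and spike-in namespaces.  ``total_mapped_reads`` counts reads
    mapped to the main genome; ``spikein_reads`` counts reads in the
    spike-in locus.  Both are metadata set by the reader or simulator.
    """

    genome: GenomeSpec
    plus: dict[str, np.ndarray]
    minus: dict[str, np.ndarray]
    total_mapped_reads: float = 0.0
    spikein_reads: float = 0.0
    state: str = RAW

    @classmethod
    def zeros(cls, genome: GenomeSpec) -> "StrandedTrack":
        plus = {c: np.zeros(genome.length(c)) for c in genome.all_chroms}
        minus = {c: np.zeros(genome.length(c)) for c in genome.all_chroms}
        return cls(genome=genome, plus=plus, minus=minus)

    def copy(self) -> "StrandedTrack":
        return StrandedTrack(
            genome=self.genome,
            plus={c: a.copy() for c, a in self.plus.items()},
            minus={c: a.copy() for c, a in self.minus.items()},
            total_mapped_reads=self.total_mapped_reads,
            spikein_reads=self.spikein_reads,
            state=self.state,
        )

    def combined(self, chrom: str) -> np.ndarray:
        """Plus + minus per-base signal for one chromosome."""
        return self.plus[chrom] + self.minus[chrom]

    def window_sum(
        self, chrom: str, start: int, end: int, strand: Optional[str] = None
    ) -> float:
        """Sum of counts over [start, end), clamped to the chromosome."""
        n = self.genome.length(chrom)
        lo, hi = max(0, start), min(n, end)
        if hi <= lo:
            return 0.0
        if strand == "+":
            return float(self.plus[chrom][lo:hi].sum())
        if strand == "-":
            return float(self.minus[chrom][lo:hi].sum())
        return float(self.plus[chrom][lo:hi].sum() + self.minus[chrom][lo:hi].sum())

    def total_signal(self) -> float:
        return float(
            sum(a.sum() for a in self.plus.values())
            + sum(a.sum() for a in self.minus.values())
        )

    def _scaled(self, factor: float, new_state: str) -> "StrandedTrack":
        out = self.copy()
        for c in out.plus:
            out.plus[c] *= factor
            out.minus[c] *= factor
        out.state = new_state
        return out


def compute_rpm(track: StrandedTrack) -> StrandedTrack:
    """Library-size normalization: reads per million mapped reads.

    Every per-base count is multiplied by ``1e6 / total_mapped_reads``.
    Only valid on a raw track with a positive read total.
    """
    if track.state != RAW:
        raise TrackStateError(f"compute_rpm requires a raw track, got state {track.state!r}")
    if track.total_mapped_reads <= 0:
        raise ValueError("total mapped reads must be > 0 for RPM normalization")
    return track._scaled(1e6 / track.total_mapped_reads, RPM)


def spikein_normalize(
    track: StrandedTrack, config: Optional[SpikeInConfig] = None
) -> StrandedTrack:
    """Spike-in normalization of an RPM track.

    The scaling factor is (spike-in locus reads) / (total main-genome
    reads); every RPM value is divided by it.  More spike-in signal
    therefore yields smaller normalized values, which is what makes
    signal comparable across samples sequenced at different depths.
    """
    if track.state != RPM:
        raise TrackStateError(
            f"spikein_normalize requires an RPM track, got state {track.state!r}"
        )
    if track.spikein_reads <= 0:
        raise ValueError("spike-in locus read count must be > 0; normalization impossible")
    factor = track.spikein_reads / track.total_mapped_reads
    return track._scaled(1.0 / factor, SPIKE_NORMALIZED)


# ---------------------------------------------------------------------------
# bedGraph I/O


def _parse_header_metadata(lines: Sequence[str]) -> dict[str, str]:
    meta: dict[str, str] = {}
    for ln in lines:
        if not ln.startswith("#"):
            continue
        for tok in ln[1:].split():
            if "=" in tok:
                k, v = tok.split("=", 1)
                meta[k] = v
    return meta


def _read_bedgraph_into(
    path: str | Path, genome: GenomeSpec, arr: dict[str, np.ndarray]
) -> dict[str, str]:
    header: list[str] = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                header.append(line)
                continue
            if line.startswith("track") or line.startswith("browser"):
                continue
            fields = line.split()
            if len(fields) != 4:
                raise BedGraphParseError(
                    f"{path}:{lineno}: expected 4 columns, got {len(fields)}"
                )
            chrom, s, e, v = fields
            try:
                start, end, value = int(s), int(e), float(v)
            except ValueError as exc:
                raise BedGraphParseError(f"{path}:{lineno}: {exc}") from None
            if chrom not in arr:
                raise BedGraphParseError(f"{path}:{lineno}: unknown chromosome {chrom!r}")
            if start < 0 or end > genome.length(chrom) or start >= end:
                raise BedGraphParseError(
                    f"{path}:{lineno}: bad interval [{start}, {end}) on {chrom}"
                )
            if value < 0:
                raise BedGraphParseError(f"{path}:{lineno}: negative value {value}")
            arr[chrom][start:end] += value
    return _parse_header_metadata(header)


def read_stranded_bedgraph(
    path_plus: str | Path,
    path_minus: str | Path,
    genome: GenomeSpec,
    total_mapped_reads: Optional[float] = None,
    spikein_reads: Optional[float] = None,
) -> StrandedTrack:
    """Read a pair of 4-column bedGraph files (one per strand) into a track.

    Intervals are expanded to per-base counts; overlapping intervals are
    summed.  Header comment lines of the form ``# key=value`` written by
    :func:`write_track_bedgraph` restore the normalization state and read
    totals; explicit arguments override them.  Without either, the total
    defaults to the in-track main-genome sum.
    """
    track = StrandedTrack.zeros(genome)
    meta_p = _read_bedgraph_into(path_plus, genome, track.plus)
    _read_bedgraph_into(path_minus, genome, track.minus)
    state = meta_p.get("state", RAW)
    if state not in _STATES:
        raise BedGraphParseError(f"unknown normalization state {state!r} in {path_plus}")
    track.state = state
    if total_mapped_reads is not None:
        track.total_mapped_reads = total_mapped_reads
    elif "total_mapped_reads" in meta_p:
        track.total_mapped_reads = float(meta_p["total_mapped_reads"])
    else:
        track.total_mapped_reads = float(
            sum(track.plus[c].sum() + track.minus[c].sum() for c in genome.main)
        )
    if spikein_reads is not None:
        track.spikein_reads = spikein_reads
    elif "spikein_reads" in meta_p:
        track.spikein_reads = float(meta_p["spikein_reads"])
    return track


def _runs(values: np.ndarray) -> Iterable[tuple[int, int, float]]:
    """Yield (start, end, value) runs of equal value, skipping zeros."""
    if values.size == 0:
        return
    change = np.flatnonzero(np.diff(values)) + 1
    bounds = np.concatenate(([0], change, [values.size]))
    for s, e in zip(bounds[:-1], bounds[1:]):
        v = values[s]
        if v != 0:
            yield int(s), int(e), float(v)


def write_track_bedgraph(
    track: StrandedTrack, path_plus: str | Path, path_minus: str | Path
) -> None:
    """Write a track as a pair of bedGraph files, run-length encoded.

    A header comment records the normalization state and read totals so
    that a read/write round trip is lossless.
    """
    header = (
        f"# collapseq state={track.state} "
        f"total_mapped_reads={track.total_mapped_reads!r} "
        f"spikein_reads={track.spikein_reads!r}\n"
    )
    for path, arrays in ((path_plus, track.plus), (path_minus, track.minus)):
        with open(path, "w") as fh:
            fh.write(header)
            for chrom in track.genome.all_chroms:
                for s, e, v in _runs(arrays[chrom]):
                    fh.write(f"{chrom}\t{s}\t{e}\t{v!r}\n")


# ---------------------------------------------------------------------------
# BED I/O for nick sites and peaks


def write_nicks_bed(nicks: Iterable[NickSite], path: str | Path) -> None:
    with open(path, "w") as fh:
        fh.write("# collapseq nick sites (BED6; position = start)\n")
        for n in nicks:
            fh.write(f"{n.chrom}\t{n.position}\t{n.position + 1}\t{n.label}\t0\t{n.target_strand}\n")


def read_nicks_bed(path: str | Path) -> list[NickSite]:
    nicks: list[NickSite] = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith(("#", "track", "browser")):
                continue
            f = line.split("\t")
            if len(f) < 6:
                raise BedGraphParseError(f"{path}:{lineno}: BED6 required for nick sites")
            nicks.append(NickSite(chrom=f[0], position=int(f[1]), target_strand=f[5], label=f[3]))
    return nicks


def write_peaks_bed(peaks: Iterable[Peak], path: str | Path) -> None:
    """BED6+4: name, score=signal, strand '.', then summit, qvalue, sites, distance."""
    with open(path, "w") as fh:
        fh.write("# collapseq peaks: chrom start end name signal strand summit qvalue sites nearest_site_dist\n")
        for i, p in enumerate(peaks):
            sites = ",".join(p.site_labels) if p.site_labels else "."
            dist = "." if p.nearest_site_dist is None else repr(p.nearest_site_dist)
            fh.write(
                f"{p.chrom}\t{p.start}\t{p.end}\tpeak_{i}\t{p.signal!r}\t.\t"
                f"{p.summit}\t{p.qvalue!r}\t{sites}\t{dist}\n"
            )


def read_peaks_bed(path: str | Path) -> list[Peak]:
    peaks: list[Peak] = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith(("#", "track", "browser")):
                continue
            f = line.split("\t")
            if len(f) < 10:
                raise BedGraphParseError(f"{path}:{lineno}: expected 10 columns")
            labels = tuple(f[8].split(",")) if f[8] != "." else ()
            dist = None if f[9] == "." else float(f[9])
            peaks.append(
                Peak(
                    chrom=f[0],
                    start=int(f[1]),
                    end=int(f[2]),
                    summit=int(f[6]),
                    signal=float(f[4]),
                    qvalue=float(f[7]),
                    site_labels=labels,
                    nearest_site_dist=dist,
                )
            )
    return peaks
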