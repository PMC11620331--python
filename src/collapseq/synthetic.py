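"""Synthetic data with the statistical structure of nick-induced fork collapse.

A site-specific single-strand break (a nick) collapses the first
replication fork that reaches it.  The outcome depends on which template
strand carries the nick relative to the fork's travel:

* **leading-strand collision** — the replisome runs off the broken
  leading-strand template, leaving a *single-ended* break.  Its one DNA
  end lies on the side the fork came from and, after 5'->3' resection, is
  blunted somewhere within the resection tract, so sequenced break ends
  spread over one side of the nick only.
* **lagging-strand collision** — the helicase bypasses the nick, which is
  converted into a *double-ended* break behind the fork; both sides carry
  an end and the signal is symmetric.

The generator draws, per simulated cell, a fork direction (Bernoulli with
the fork-directionality parameter f = fraction of rightward forks), maps
(direction, nick strand) to a collision orientation, draws per-end
resection lengths, and records one read per DNA end.  A converging fork
can convert an unrepaired single-ended break into a double-ended one by
supplying a second end at a configurable distance.  Uniform Poisson
background, a mouse-like spike-in locus mixed at a known cell fraction,
strand-polarized ssDNA (RPA) coverage, and amplicon reads with
microhomology-biased deletions complete the simulated experiment.

Side/strand convention: a DNA end left of the nick is recorded on the
plus-strand channel, an end to the right on the minus-strand channel.
Real strand-specific protocols display positive- and negative-strand
reads without this identification; downstream asymmetry statistics only
use position (left/right of the nick), so the convention is free and we
fix it once here.

Orientation convention (the generative ground truth mirrored by the
classifier in :mod:`collapseq.rfd`): a Crick (-) strand nick met by a
rightward fork is a lagging-strand collision; a Watson (+) strand nick
met by a rightward fork is leading-strand; both mirror for leftward
forks.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np

from .microhomology import microhomology_length
from .rfd import RFDProfile
from .tracks_io import GenomeSpec, NickSite, SpikeInConfig, StrandedTrack

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class ResectionModel:
    """Distribution of per-end resection tract lengths (bp).

    ``uniform`` draws from (0, l_max]; ``trunc_exp`` draws a truncated
    exponential with the given mean, capped at l_max.  The uniform default
    reflects that per-cell break ends are observed spread across the whole
    tract up to a maximum length, which is the quantity the estimators
    target; the family is configurable for sensitivity checks.
    """

    family: str = "uniform"
    l_max: float = 5000.0
    mean: float = 2000.0

    def __post_init__(self) -> None:
        if self.family not in ("uniform", "trunc_exp"):
            raise ValueError(f"unknown resection family {self.family!r}")
        if self.l_max <= 0:
            raise ValueError("l_max must be > 0")

    def draw(self, rng: np.random.Generator, n: int) -> np.ndarray:
        if self.family == "uniform":
            # ceil maps (0, 1] * l_max onto integers 1..l_max: lengths in (0, l_max]
            u = 1.0 - rng.random(n)
            return np.maximum(1, np.ceil(u * self.l_max)).astype(np.int64)
        u = rng.random(n)
        cap = 1.0 - math.exp(-self.l_max / self.mean)
        x = -self.mean * np.log1p(-u * cap)
        return np.maximum(1, np.ceil(x)).astype(np.int64)


@dataclass(frozen=True)
class CollisionSimParams:
    """Parameters of the fork-collision generator.

    fork_directionality
        Fraction f of forks moving rightward at the nick (RFD = 2f - 1).
    cut_efficiency
        Fraction of cells actually nicked; un-nicked cells emit nothing.
    converging_prob
        Probability that an unrepaired single-ended break gains a second
        end from a converging fork.
    converging_distance
        Distance (bp) beyond the nick at which that second end appears.
    resection
        Per-end resection length distribution.
    background_rate
        Expected background reads per bp (uniform Poisson over the main
        genome), split evenly between strands at random.
    n_events
        Number of cells simulated.
    """

    fork_directionality: float = 0.85
    cut_efficiency: float = 1.0
    converging_prob: float = 0.0
    converging_distance: int = 20000
    resection: ResectionModel = field(default_factory=ResectionModel)
    background_rate: float = 0.0
    n_events: int = 1000
    seed: int = 0

    def __post_init__(self) -> None:
        for name in ("fork_directionality", "cut_efficiency", "converging_prob"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name} must be in [0, 1], got {v}")
        if self.background_rate < 0:
            raise ValueError("background_rate must be >= 0")
        if self.n_events <= 0:
            raise ValueError("n_events must be > 0")
        if self.converging_distance <= 0:
            raise ValueError("converging_distance must be > 0")


@dataclass(frozen=True)
class OutcomeTally:
    """A counted outcome category, e.g. from single-molecule imaging."""

    label: str
    n_event: int
    n_total: int

    def __post_init__(self) -> None:
        if self.n_total <= 0:
            raise ValueError("n_total must be > 0")
        if not 0 <= self.n_event <= self.n_total:
            raise ValueError("need 0 <= n_event <= n_total")


def tally_outcome_proportion(tally: OutcomeTally) -> tuple[float, int]:
    """Percentage of events in a tally, plus a nearest-integer display value."""
    pct = 100.0 * tally.n_event / tally.n_total
    return pct, int(math.floor(pct + 0.5))


def expected_ends_per_event(nick: NickSite, params: CollisionSimParams) -> float:
    """Mean DNA ends emitted per nicked cell under the collision rules."""
    f = params.fork_directionality
    frac_leading = f if nick.target_strand == "+" else 1.0 - f
    frac_lagging = 1.0 - frac_leading
    return frac_leading * (1.0 + params.converging_prob) + frac_lagging * 2.0


def background_rate_for_fraction(
    nick: NickSite, params: CollisionSimParams, genome: GenomeSpec, fraction: float
) -> float:
    """Background rate lambda making background reads a given fraction of signal."""
    total_signal = params.n_events * params.cut_efficiency * expected_ends_per_event(nick, params)
    return fraction * total_signal / genome.main_total_length


def _orientation(rightward: np.ndarray, target_strand: str) -> np.ndarray:
    """True where the collision is leading-strand, per event."""
    if target_strand == "+":
        return rightward
    return ~rightward


def simulate_collision_track(
    nick: NickSite,
    params: CollisionSimParams,
    genome: GenomeSpec,
    rng: Optional[np.random.Generator] = None,
) -> StrandedTrack:
    """Simulate a strand-specific break-end track for one nick.

    Per nicked cell: fork direction ~ Bernoulli(f); leading collisions
    emit one end at nick - r (rightward fork) or nick + r (leftward) on
    the incoming-fork side; lagging collisions emit two ends at nick - r1
    and nick + r2 with independent resection draws; with probability
    ``converging_prob`` a single end gains a partner at the converging
    fork distance on the far side.  Uniform Poisson background is added
    over the main genome.  Fixed seed => byte-identical output.
    """
    nick.validate_against(genome)
    rng = rng if rng is not None else np.random.default_rng(params.seed)
    n = params.n_events
    # fixed draw order for determinism regardless of which draws are used
    nicked = rng.random(n) < params.cut_efficiency
    rightward = rng.random(n) < params.fork_directionality
    r_primary = params.resection.draw(rng, n)
    r_second = params.resection.draw(rng, n)
    converted = rng.random(n) < params.converging_prob

    leading = _orientation(rightward, nick.target_strand)
    pos = nick.position
    left_ends: list[np.ndarray] = []
    right_ends: list[np.ndarray] = []

    # leading-strand collisions: single end on the incoming-fork side
    lead_right = nicked & leading & rightward
    lead_left = nicked & leading & ~rightward
    left_ends.append(pos - r_primary[lead_right])
    right_ends.append(pos + r_primary[lead_left])
    # converging-fork conversion supplies the second end on the far side
    conv_right = lead_right & converted
    conv_left = lead_left & converted
    right_ends.append(np.full(conv_right.sum(), pos + params.converging_distance))
    left_ends.append(np.full(conv_left.sum(), pos - params.converging_distance))

    # lagging-strand collisions: bypass leaves ends on both sides
    lagging = nicked & ~leading
    left_ends.append(pos - r_primary[lagging])
    right_ends.append(pos + r_second[lagging])

    track = StrandedTrack.zeros(genome)
    length = genome.length(nick.chrom)
    n_clamped = 0
    for ends, strand in ((np.concatenate(left_ends), "+"), (np.concatenate(right_ends), "-")):
        clamped = np.clip(ends, 0, length - 1)
        n_clamped += int((clamped != ends).sum())
        arr = track.plus[nick.chrom] if strand == "+" else track.minus[nick.chrom]
        np.add.at(arr, clamped.astype(np.int64), 1.0)
    if n_clamped:
        logger.warning("%d resection draws exceeded chromosome bounds and were clamped", n_clamped)

    n_signal = int(sum(a.size for a in left_ends) + sum(a.size for a in right_ends))
    n_bg = _add_uniform_background(track, genome, params.background_rate, rng)
    track.total_mapped_reads = float(n_signal + n_bg)
    return track


def _add_uniform_background(
    track: StrandedTrack, genome: GenomeSpec, rate: float, rng: np.random.Generator
) -> int:
    """Scatter Poisson background uniformly over the main genome; return count."""
    if rate <= 0:
        return 0
    total_len = genome.main_total_length
    n_bg = int(rng.poisson(rate * total_len))
    if n_bg == 0:
        return 0
    chroms = list(genome.main)
    weights = np.array([genome.main[c] for c in chroms], dtype=float)
    chrom_idx = rng.choice(len(chroms), size=n_bg, p=weights / weights.sum())
    offsets = rng.random(n_bg)
    on_plus = rng.random(n_bg) < 0.5
    for i, c in enumerate(chroms):
        sel = chrom_idx == i
        if not sel.any():
            continue
        positions = (offsets[sel] * genome.main[c]).astype(np.int64)
        for strand_sel, arr in ((on_plus[sel], track.plus[c]), (~on_plus[sel], track.minus[c])):
            np.add.at(arr, positions[strand_sel], 1.0)
    return n_bg


def simulate_rfd_field(
    origin_positions: Sequence[int],
    chrom_length: int,
    bin_size: int,
    smoothing_width: int = 0,
    depth: int = 100,
    chrom: str = "chr1",
) -> RFDProfile:
    """Deterministic fork-directionality field from replication origin positions.

    Each bin takes RFD = +1 if the nearest origin lies to its left
    (rightward fork) and -1 if to its right, with a linear blend of width
    ``smoothing_width`` across the termination midpoint between adjacent
    origins.  Fragment counts per bin are ``depth`` split according to the
    RFD value.
    """
    origins = np.sort(np.asarray(origin_positions, dtype=np.int64))
    if origins.size == 0:
        raise ValueError("at least one origin position is required")
    if (origins < 0).any() or (origins > chrom_length).any():
        raise ValueError("origins must lie within the chromosome")
    n_bins = chrom_length // bin_size
    centers = (np.arange(n_bins) + 0.5) * bin_size
    values = np.empty(n_bins)
    for j, x in enumerate(centers):
        i = int(np.searchsorted(origins, x))
        if i == 0:
            values[j] = -1.0  # everything left of the first origin replicates leftward
        elif i == origins.size:
            values[j] = 1.0
        else:
            mid = (origins[i - 1] + origins[i]) / 2.0
            if smoothing_width > 0:
                values[j] = float(np.clip(2.0 * (mid - x) / smoothing_width, -1.0, 1.0))
            else:
                values[j] = 1.0 if x < mid else -1.0
    crick = np.rint(depth * (1.0 + values) / 2.0)
    watson = depth - crick
    return RFDProfile(chrom=chrom, bin_size=bin_size, crick=crick, watson=watson)


def sample_rfd_counts(
    field: RFDProfile, depth: int, rng: np.random.Generator
) -> RFDProfile:
    """Binomial resampling of an RFD field at a given per-bin fragment depth."""
    p_right = (1.0 + np.nan_to_num(field.rfd)) / 2.0
    crick = rng.binomial(depth, p_right).astype(float)
    return RFDProfile(
        chrom=field.chrom, bin_size=field.bin_size, crick=crick, watson=depth - crick
    )


def simulate_spikein(
    track: StrandedTrack,
    config: SpikeInConfig,
    depth: int,
    rng: np.random.Generator,
) -> StrandedTrack:
    """Add spike-in locus reads for cells mixed in at ``config.fraction``.

    Each of ``depth`` sampled cells is a spike-in cell with probability
    ``fraction``; each spike-in cell contributes one read uniformly placed
    in the spike-in locus (both strands pooled at random).  Sets the
    track's spike-in read-count metadata.
    """
    if track.genome.namespace_of(config.chrom) != "spikein":
        raise ValueError(f"spike-in locus chromosome {config.chrom!r} is not in the spikein namespace")
    out = track.copy()
    n_spike = int(rng.binomial(depth, config.fraction))
    if n_spike:
        positions = rng.integers(config.start, config.end, size=n_spike)
        on_plus = rng.random(n_spike) < 0.5
        np.add.at(out.plus[config.chrom], positions[on_plus], 1.0)
        np.add.at(out.minus[config.chrom], positions[~on_plus], 1.0)
    out.spikein_reads += n_spike
    return out


def simulate_rpa_track(
    nick: NickSite,
    params: CollisionSimParams,
    genome: GenomeSpec,
    invasion_signal: bool = False,
    double_ended: bool = False,
    invasion_fraction: float = 0.25,
    rng: Optional[np.random.Generator] = None,
) -> StrandedTrack:
    """Strand-polarized ssDNA-binding (RPA) coverage around a collapsed fork.

    Resection of the single end left of the nick exposes ssDNA covered on
    the plus channel over [nick - r, nick) per cell.  With
    ``invasion_signal``, a fraction of cells additionally expose ssDNA in
    the migrating displacement loop beyond the nick (minor plus-channel
    signal to the right).  With ``double_ended`` (the no-strand-invasion
    pattern), every cell also carries a resected end right of the nick
    with opposite polarity (minus channel).  Uniform Poisson background
    uses ``params.background_rate``.
    """
    nick.validate_against(genome)
    rng = rng if rng is not None else np.random.default_rng(params.seed)
    n = params.n_events
    r_left = params.resection.draw(rng, n)
    r_right = params.resection.draw(rng, n)
    invaded = rng.random(n) < invasion_fraction

    length = genome.length(nick.chrom)
    pos = nick.position
    track = StrandedTrack.zeros(genome)

    def add_cover(arr: np.ndarray, starts: np.ndarray, ends: np.ndarray) -> None:
        # interval stabbing via a difference array; intervals clamped
        delta = np.zeros(length + 1)
        s = np.clip(starts, 0, length)
        e = np.clip(ends, 0, length)
        np.add.at(delta, s, 1.0)
        np.add.at(delta, e, -1.0)
        arr += np.cumsum(delta[:-1])

    add_cover(track.plus[nick.chrom], pos - r_left, np.full(n, pos))
    if invasion_signal:
        d_loop = (r_right // 2)[invaded]
        add_cover(track.plus[nick.chrom], np.full(d_loop.size, pos), pos + d_loop)
    if double_ended:
        add_cover(track.minus[nick.chrom], np.full(n, pos), pos + r_right)
    n_bg = _add_uniform_background(track, genome, params.background_rate, rng)
    track.total_mapped_reads = float(track.total_signal())
    return track


@dataclass(frozen=True)
class DeletionSpec:
    """Deletion model for simulated amplicon reads.

    Each read deletes a nick-spanning segment with probability ``p_del``.
    With ``mh_bias``, candidate deletions are drawn in batches and the one
    with the longest junctional microhomology wins, emulating repair
    junctions that preferentially use repeated flanks.  ``fixed`` pins a
    single deletion interval for round-trip tests.
    """

    p_del: float = 0.6
    max_len: int = 30
    mh_bias: bool = False
    n_candidates: int = 64
    fixed: Optional[tuple[int, int]] = None

    def __post_init__(self) -> None:
        if not 0.0 <= self.p_del <= 1.0:
            raise ValueError("p_del must be in [0, 1]")
        if self.max_len <= 0 or self.n_candidates <= 0:
            raise ValueError("max_len and n_candidates must be > 0")


def _draw_deletion(
    ref: str, nick_offset: int, model: DeletionSpec, rng: np.random.Generator
) -> tuple[int, int]:
    if model.fixed is not None:
        return model.fixed
    k = model.n_candidates if model.mh_bias else 1
    best: Optional[tuple[int, int]] = None
    best_mh = -1
    for _ in range(k):
        d = int(rng.integers(1, model.max_len + 1))
        lo = max(1, nick_offset - d)
        hi = min(nick_offset, len(ref) - 1 - d)
        if hi < lo:
            continue
        start = int(rng.integers(lo, hi + 1))
        mh = microhomology_length(ref, start, start + d)
        if mh > best_mh:
            best, best_mh = (start, start + d), mh
    if best is None:  # no nick-spanning deletion fits; fall back to 1 bp at nick
        best = (max(1, nick_offset - 1), max(2, nick_offset))
    return best


def simulate_amplicon_reads(
    ref_seq: str,
    nick_offset: int,
    deletion_model: DeletionSpec,
    n_reads: int,
    seed: int,
) -> list[tuple[str, str]]:
    """Simulate amplicon reads as (name, sequence) pairs.

    Each read is the reference, or the reference minus one deletion
    spanning the nick.  Deterministic under a fixed seed.
    """
    if len(ref_seq) < 50:
        raise ValueError("reference must be at least 50 bp")
    if not 0 < nick_offset < len(ref_seq):
        raise ValueError("nick_offset must be interior to the reference")
    rng = np.random.default_rng(seed)
    reads: list[tuple[str, str]] = []
    for i in range(n_reads):
        if rng.random() < deletion_model.p_del:
            a, b = _draw_deletion(ref_seq, nick_offset, deletion_model, rng)
            seq = ref_seq[:a] + ref_seq[b:]
            if not seq:
                raise ValueError("deletion model produced an empty read")
            reads.append((f"read_{i}_del_{a}_{b}", seq))
        else:
            reads.append((f"read_{i}_ref", ref_seq))
    return reads


def write_fasta(records: Sequence[tuple[str, str]], path) -> None:
    from Bio.Seq import Seq
    from Bio.SeqIO import write as seqio_write
    from Bio.SeqRecord import SeqRecord

    seqio_write(
        [SeqRecord(Seq(seq), id=name, description="") for name, seq in records],
        path,
        "fasta",
    )


def random_amplicon_reference(length: int, seed: int) -> str:
    """A random-composition amplicon reference sequence (synthetic stand-in)."""
    rng = np.random.default_rng(seed)
    return "".join(rng.choice(list("ACGT"), size=length))
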