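import numpy as np
import pytest

from collapseq import GenomeSpec, NickSite, StrandedTrack
from collapseq.tracks_io import RAW, RPM


@pytest.fixture
def genome():
    return GenomeSpec(main={"chr1": 200_000}, spikein={"spikeM": 20_000})


@pytest.fixture
def small_genome():
    return GenomeSpec(main={"chr1": 1000, "chr2": 500})


@pytest.fixture
def nick(genome):
    return NickSite(chrom="chr1", position=100_000, target_strand="+", label="sg1")


def track_from_arrays(genome, chrom="chr1", plus=None, minus=None, state=RAW, total=None):
    """Build a track with explicit per-base arrays on one chromosome."""
    track = StrandedTrack.zeros(genome)
    if plus is not None:
        arr = np.asarray(plus, dtype=float)
        track.plus[chrom][: arr.size] = arr
    if minus is not None:
        arr = np.asarray(minus, dtype=float)
        track.minus[chrom][: arr.size] = arr
    track.state = state
    track.total_mapped_reads = (
        total
        if total is not None
        else float(sum(track.plus[c].sum() + track.minus[c].sum() for c in genome.main))
    )
    return track


def random_track(genome, rng, n_reads=500, state=RAW):
    """Scatter point reads uniformly over the main genome."""
    track = StrandedTrack.zeros(genome)
    chroms = list(genome.main)
    chrom_idx = rng.integers(0, len(chroms), size=n_reads)
    for i, c in enumerate(chroms):
        sel = chrom_idx == i
        positions = rng.integers(0, genome.main[c], size=int(sel.sum()))
        on_plus = rng.random(positions.size) < 0.5
        np.add.at(track.plus[c], positions[on_plus], 1.0)
        np.add.at(track.minus[c], positions[~on_plus], 1.0)
    track.state = state
    track.total_mapped_reads = float(n_reads)
    return track
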