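"""Generator behavior: collision rules, spike-in, RFD fields, RPA, amplicons."""

import math

import numpy as np
import pytest

from collapseq import (
    CollisionSimParams,
    DeletionSpec,
    GenomeSpec,
    NickSite,
    OutcomeTally,
    ResectionModel,
    SpikeInConfig,
    StrandedTrack,
    peak_asymmetry,
    rpa_asymmetry,
    simulate_amplicon_reads,
    simulate_collision_track,
    simulate_rfd_field,
    simulate_rpa_track,
    simulate_spikein,
    tally_outcome_proportion,
)
from collapseq.synthetic import expected_ends_per_event, write_fasta


@pytest.fixture
def params():
    return CollisionSimParams(n_events=1000, seed=42)


class TestCollisionTrack:
    def test_fixed_seed_is_byte_identical(self, genome, nick, params):
        a = simulate_collision_track(nick, params, genome)
        b = simulate_collision_track(nick, params, genome)
        for c in genome.all_chroms:
            np.testing.assert_array_equal(a.plus[c], b.plus[c])
            np.testing.assert_array_equal(a.minus[c], b.minus[c])

    def test_pure_leading_is_fully_one_sided(self, genome, nick):
        """f=1 at a Watson nick: every fork runs off; all ends strictly left."""
        p = CollisionSimParams(fork_directionality=1.0, n_events=1000, seed=1)
        track = simulate_collision_track(nick, p, genome)
        combined = track.combined("chr1")
        assert combined[nick.position :].sum() == 0
        assert combined[: nick.position].sum() == 1000
        assert peak_asymmetry(track, nick, window=6000) == 0.5

    def test_pure_lagging_is_symmetric(self, genome):
        """f=1 at a Crick nick: bypass leaves one end on each side; asymmetry ~ 0."""
        nick = NickSite("chr1", 100_000, "-", "sg")
        p = CollisionSimParams(fork_directionality=1.0, n_events=2000, seed=2)
        track = simulate_collision_track(nick, p, genome)
        asym = peak_asymmetry(track, nick, window=6000)
        assert abs(asym) < 3 * 0.5 / math.sqrt(4000)  # binomial sampling error

    def test_read_bookkeeping_is_exact(self, genome, nick):
        """Total reads = events x ends-per-event when background and conversion are off."""
        p = CollisionSimParams(fork_directionality=1.0, n_events=777, seed=3)
        track = simulate_collision_track(nick, p, genome)
        assert track.total_signal() == 777
        assert track.total_mapped_reads == 777
        lagging = NickSite("chr1", 100_000, "-", "sg")
        track2 = simulate_collision_track(lagging, p, genome)
        assert track2.total_signal() == 2 * 777

    def test_converging_fork_adds_far_side_end(self, genome, nick):
        p = CollisionSimParams(
            fork_directionality=1.0, n_events=500, seed=4, converging_prob=1.0,
            converging_distance=20_000,
        )
        track = simulate_collision_track(nick, p, genome)
        assert track.minus["chr1"][nick.position + 20_000] == 500

    def test_outcome_frequencies_converge(self, genome, nick):
        """Leading fraction at n=10,000 matches f within a 4-sigma binomial band."""
        f = 0.85
        p = CollisionSimParams(fork_directionality=f, n_events=10_000, seed=5)
        track = simulate_collision_track(nick, p, genome)
        n_left = track.plus["chr1"].sum()  # leading: 1 left end; lagging: 1 left + 1 right
        n_right = track.minus["chr1"].sum()
        frac_lagging = n_right / 10_000
        se = math.sqrt(f * (1 - f) / 10_000)
        assert abs(frac_lagging - (1 - f)) < 4 * se
        assert n_left == 10_000  # every event leaves exactly one left end here

    def test_cut_efficiency_scales_events(self, genome, nick):
        p = CollisionSimParams(fork_directionality=1.0, n_events=4000, cut_efficiency=0.5, seed=6)
        track = simulate_collision_track(nick, p, genome)
        assert abs(track.total_signal() - 2000) < 4 * math.sqrt(4000 * 0.25)

    def test_resection_draw_clamped_with_warning(self, genome, caplog):
        near_edge = NickSite("chr1", 100, "+", "sg")
        p = CollisionSimParams(
            fork_directionality=1.0, n_events=50, seed=7,
            resection=ResectionModel("uniform", 5000),
        )
        with caplog.at_level("WARNING", logger="collapseq.synthetic"):
            track = simulate_collision_track(near_edge, p, genome)
        assert track.total_signal() == 50  # clamped, not dropped
        assert any("clamped" in r.message for r in caplog.records)

    def test_expected_ends_per_event(self, nick):
        p = CollisionSimParams(fork_directionality=0.85)
        assert expected_ends_per_event(nick, p) == pytest.approx(0.85 + 0.15 * 2)


class TestResectionModel:
    def test_uniform_draws_in_range(self):
        rng = np.random.default_rng(0)
        draws = ResectionModel("uniform", 5000).draw(rng, 10_000)
        assert draws.min() >= 1 and draws.max() <= 5000

    def test_truncated_exponential_respects_cap(self):
        rng = np.random.default_rng(0)
        draws = ResectionModel("trunc_exp", 5000, mean=2000).draw(rng, 10_000)
        assert draws.min() >= 1 and draws.max() <= 5000
        assert draws.mean() < 2000  # truncation pulls the mean below the nominal

    def test_unknown_family_rejected(self):
        with pytest.raises(ValueError, match="family"):
            ResectionModel("normal", 5000)


class TestSpikeIn:
    def test_spikein_read_count_near_expectation(self, genome):
        cfg = SpikeInConfig(chrom="spikeM", start=8000, end=12_000, fraction=0.2)
        track = StrandedTrack.zeros(genome)
        rng = np.random.default_rng(8)
        out = simulate_spikein(track, cfg, depth=10_000, rng=rng)
        se = math.sqrt(10_000 * 0.2 * 0.8)
        assert abs(out.spikein_reads - 2000) < 4 * se
        locus = out.plus["spikeM"][8000:12_000].sum() + out.minus["spikeM"][8000:12_000].sum()
        assert locus == out.spikein_reads

    def test_two_seeds_differ_same_expectation(self, genome):
        cfg = SpikeInConfig(chrom="spikeM", start=8000, end=12_000, fraction=0.2)
        outs = [
            simulate_spikein(StrandedTrack.zeros(genome), cfg, 10_000, np.random.default_rng(s))
            for s in (1, 2)
        ]
        assert outs[0].spikein_reads != outs[1].spikein_reads
        for o in outs:
            assert abs(o.spikein_reads - 2000) < 200

    def test_locus_must_be_in_spikein_namespace(self, genome):
        cfg = SpikeInConfig(chrom="chr1", start=0, end=100, fraction=0.2)
        with pytest.raises(ValueError, match="spikein namespace"):
            simulate_spikein(StrandedTrack.zeros(genome), cfg, 100, np.random.default_rng(0))


class TestRFDField:
    def test_single_origin_splits_directions(self):
        profile = simulate_rfd_field([50_000], 100_000, bin_size=1000)
        rfd = profile.rfd
        assert (rfd[:49] == -1).all()  # left of the origin: leftward forks
        assert (rfd[51:] == 1).all()

    def test_two_origins_terminate_at_midpoint(self):
        profile = simulate_rfd_field([20_000, 80_000], 100_000, bin_size=1000)
        rfd = profile.rfd
        assert rfd[30] == 1.0  # between origin 1 and the midpoint: rightward
        assert rfd[60] == -1.0  # past the midpoint: leftward into the termination zone
        # hard step exactly at the midpoint bin with zero smoothing
        assert set(np.unique(rfd[21:79])) <= {-1.0, 1.0}

    def test_smoothing_blends_linearly(self):
        profile = simulate_rfd_field([20_000, 80_000], 100_000, 1000, smoothing_width=20_000)
        rfd = profile.rfd
        mid = 50
        assert abs(rfd[mid]) < 0.2
        assert rfd[mid - 5] > 0 > rfd[mid + 5]

    def test_zero_origins_error(self):
        with pytest.raises(ValueError, match="origin"):
            simulate_rfd_field([], 100_000, 1000)


class TestRPATrack:
    def test_single_ended_polarity(self, genome, nick):
        p = CollisionSimParams(fork_directionality=1.0, n_events=300, seed=9,
                               background_rate=1e-4)
        track = simulate_rpa_track(nick, p, genome)
        ratio = rpa_asymmetry(track, "chr1", nick.position - 6000, nick.position + 6000)
        assert ratio > 10  # ssDNA almost exclusively on the resected (plus) side

    def test_double_ended_pattern_is_balanced(self, genome, nick):
        p = CollisionSimParams(fork_directionality=1.0, n_events=300, seed=10)
        track = simulate_rpa_track(nick, p, genome, double_ended=True)
        ratio = rpa_asymmetry(track, "chr1", nick.position - 6000, nick.position + 6000)
        assert 0.8 < ratio < 1.25

    def test_invasion_signal_extends_past_nick(self, genome, nick):
        p = CollisionSimParams(fork_directionality=1.0, n_events=300, seed=11)
        with_inv = simulate_rpa_track(nick, p, genome, invasion_signal=True)
        without = simulate_rpa_track(nick, p, genome, invasion_signal=False)
        right = slice(nick.position, nick.position + 3000)
        assert with_inv.plus["chr1"][right].sum() > 0
        assert without.plus["chr1"][right].sum() == 0


class TestAmpliconReads:
    REF = ("ACGTGTCAGGTTACGGATTCCAGAGTTACACGGATCGCAATGCCATTGAG"
           "TCCGGATAACGTTGCAGGTCCTATGCAATGGCCTTAGACCAGGTACGATC")

    def test_no_deletions_returns_reference(self):
        reads = simulate_amplicon_reads(self.REF, 50, DeletionSpec(p_del=0.0), 20, seed=0)
        assert all(seq == self.REF for _, seq in reads)

    def test_fixed_deletion_applied_everywhere(self):
        model = DeletionSpec(p_del=1.0, fixed=(40, 60))
        reads = simulate_amplicon_reads(self.REF, 50, model, 20, seed=0)
        expected = self.REF[:40] + self.REF[60:]
        assert all(seq == expected for _, seq in reads)

    def test_seed_determinism(self):
        model = DeletionSpec(p_del=0.7, max_len=20)
        a = simulate_amplicon_reads(self.REF, 50, model, 50, seed=5)
        b = simulate_amplicon_reads(self.REF, 50, model, 50, seed=5)
        assert a == b

    def test_fasta_output_round_trips(self, tmp_path):
        from Bio import SeqIO

        reads = simulate_amplicon_reads(self.REF, 50, DeletionSpec(p_del=0.5), 10, seed=1)
        write_fasta(reads, tmp_path / "reads.fasta")
        back = [(r.id, str(r.seq)) for r in SeqIO.parse(tmp_path / "reads.fasta", "fasta")]
        assert back == reads

    def test_interior_nick_required(self):
        with pytest.raises(ValueError, match="interior"):
            simulate_amplicon_reads(self.REF, 0, DeletionSpec(), 5, seed=0)
        with pytest.raises(ValueError, match="50 bp"):
            simulate_amplicon_reads("ACGT", 2, DeletionSpec(), 5, seed=0)


class TestOutcomeTally:
    @pytest.mark.parametrize(
        "n_event, n_total, pct, display",
        [(50, 58, 86.2, 86), (57, 59, 96.6, 97), (0, 10, 0.0, 0)],
    )
    def test_proportions(self, n_event, n_total, pct, display):
        value, rounded = tally_outcome_proportion(OutcomeTally("cat", n_event, n_total))
        assert value == pytest.approx(pct, abs=0.05)
        assert rounded == display

    def test_zero_total_rejected(self):
        with pytest.raises(ValueError, match="n_total"):
            OutcomeTally("cat", 0, 0)
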