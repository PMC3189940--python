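import numpy as np
import pytest

from predaseq import simulate as sim
from predaseq._intervals import reciprocal_overlap
from predaseq.composition import (
    call_islands,
    annotate_islands,
    gc_skew,
    predict_ori_ter,
    shuffled_null_track,
    trinuc_chi2_scan,
)
from predaseq.genome_io import Feature, GenomeRecord
from tests._oracles import trinuc_chi2_oracle
from tests.conftest import random_sequence


class TestGcSkew:
    def test_window_values(self):
        g = GenomeRecord(id="x", sequence="GGGCATAT", circular=True)
        prof = gc_skew(g, window_bp=4, step_bp=4)
        assert prof.skew[0] == pytest.approx(0.5)  # GGGC: (3-1)/4
        assert prof.skew[1] == 0.0  # ATAT: zero-GC convention
        assert np.allclose(prof.cumulative, np.cumsum(prof.skew))

    def test_reverse_complement_negates_skew(self):
        rng = np.random.default_rng(1)
        seq = random_sequence(rng, 4000)
        comp = str.maketrans("ACGT", "TGCA")
        rc = seq.translate(comp)[::-1]
        fwd = gc_skew(GenomeRecord(id="f", sequence=seq, circular=False),
                      window_bp=500, step_bp=500)
        rev = gc_skew(GenomeRecord(id="r", sequence=rc, circular=False),
                      window_bp=500, step_bp=500)
        assert np.allclose(rev.skew, -fwd.skew[::-1])

    def test_window_larger_than_genome_errors(self):
        g = GenomeRecord(id="x", sequence="ACGT")
        with pytest.raises(ValueError, match="larger than genome"):
            gc_skew(g, window_bp=10, step_bp=1)


class TestOriTer:
    def test_two_replichore_recovery(self):
        g, truth = sim.make_genome(length=100_000, n_islands=0, n_repeats=0,
                                   with_rrna_operon=False, seed=3)
        pred = predict_ori_ter(gc_skew(g))
        assert pred.confident
        assert min(abs(pred.ori - truth.ori), 100_000 - abs(pred.ori - truth.ori)) <= 2000
        assert abs(pred.ter - truth.ter) <= 2000

    def test_uniform_genome_flagged_low_confidence(self, uniform_genome):
        pred = predict_ori_ter(gc_skew(uniform_genome))
        assert not pred.confident

    def test_rotation_equivariance(self):
        g, _ = sim.make_genome(length=50_000, n_islands=0, n_repeats=0,
                               with_rrna_operon=False, seed=4)
        k = 10_000  # multiple of the step keeps window phase identical
        rotated = GenomeRecord(id="rot", sequence=g.sequence[k:] + g.sequence[:k])
        a = predict_ori_ter(gc_skew(g))
        b = predict_ori_ter(gc_skew(rotated))
        n = len(g)
        assert (a.ori - k) % n == b.ori % n
        assert (a.ter - k) % n == b.ter % n

    def test_flat_profile_errors(self):
        g = GenomeRecord(id="x", sequence="AT" * 3000)
        with pytest.raises(ValueError, match="no transition"):
            predict_ori_ter(gc_skew(g, window_bp=500, step_bp=500))


class TestTrinucChi2:
    def test_zero_when_window_equals_genome(self):
        g = GenomeRecord(id="rep", sequence="ACGTTGCAAC" * 30, circular=True)
        track = trinuc_chi2_scan(g, window_bp=300, step_bp=300)
        assert track.chi2[0] == 0.0

    def test_matches_direct_count_oracle(self):
        rng = np.random.default_rng(9)
        seq = random_sequence(rng, 6000)
        seq = seq[:2000] + "A" * 1000 + seq[3000:]  # poly-A window stands out
        g = GenomeRecord(id="x", sequence=seq, circular=True)
        track = trinuc_chi2_scan(g, window_bp=1000, step_bp=1000)
        for w in (0, 2, 4):
            expected = trinuc_chi2_oracle(seq, int(track.starts[w]) - 1, 1000)
            assert track.chi2[w] == pytest.approx(expected, rel=1e-9)

    def test_single_and_both_strand_conventions_differ(self):
        rng = np.random.default_rng(5)
        # G-rich sequence: strand-asymmetric composition
        codes = rng.choice(4, size=5000, p=[0.15, 0.15, 0.45, 0.25])
        seq = bytes(np.frombuffer(b"ACGT", dtype=np.uint8)[codes]).decode()
        g = GenomeRecord(id="x", sequence=seq, circular=True)
        single = trinuc_chi2_scan(g, window_bp=500, step_bp=500)
        both = trinuc_chi2_scan(g, window_bp=500, step_bp=500, both_strands=True)
        assert not np.allclose(single.chi2, both.chi2)

    def test_scores_nonnegative(self, uniform_genome):
        track = trinuc_chi2_scan(uniform_genome)
        assert np.all(track.chi2 >= 0)

    def test_small_window_rejected(self, uniform_genome):
        with pytest.raises(ValueError, match=">= 100"):
            trinuc_chi2_scan(uniform_genome, window_bp=50, step_bp=50)

    def test_n_windows_scored_on_valid_trinucleotides(self):
        rng = np.random.default_rng(8)
        seq = random_sequence(rng, 3000) + "N" * 200 + random_sequence(rng, 800)
        g = GenomeRecord(id="x", sequence=seq, circular=True)
        track = trinuc_chi2_scan(g, window_bp=500, step_bp=500)
        assert len(track) == 8
        assert np.all(np.isfinite(track.chi2))


class TestIslandCalling:
    def test_homogeneous_genome_yields_no_islands(self):
        rng = np.random.default_rng(17)
        g = GenomeRecord(id="homog", sequence=random_sequence(rng, 200_000))
        track = trinuc_chi2_scan(g, both_strands=True)
        assert call_islands(track, g, seed=17) == []

    def test_planted_islands_recovered(self):
        g, truth = sim.make_genome(length=200_000, n_islands=2,
                                   island_len_range=(14_000, 16_000), seed=21)
        track = trinuc_chi2_scan(g, both_strands=True)
        called = call_islands(track, g, exclusion_features=g.features_of("rRNA"),
                              seed=21)
        truths = truth.island_intervals()
        assert len(called) == 2
        for isl in called:
            assert max(reciprocal_overlap(isl.interval(), t) for t in truths) >= 0.8

    def test_exclusion_semantics(self):
        g, truth = sim.make_genome(length=200_000, n_islands=2,
                                   island_len_range=(14_000, 16_000), seed=21)
        track = trinuc_chi2_scan(g, both_strands=True)
        exclusion = [(truth.islands[0]["start"], truth.islands[0]["end"])]
        called = call_islands(track, g, exclusion_features=exclusion, seed=21)
        excl0 = (truth.islands[0]["start"] - 1, truth.islands[0]["end"])
        assert all(reciprocal_overlap(isl.interval(), excl0) < 0.5 for isl in called)

    def test_idempotent(self):
        g, _ = sim.make_genome(length=150_000, n_islands=1, seed=2)
        track = trinuc_chi2_scan(g, both_strands=True)
        null = shuffled_null_track(g, track.window_bp, track.step_bp, seed=2,
                                   both_strands=True)
        a = call_islands(track, g, null_track=null)
        b = call_islands(track, g, null_track=null)
        assert [i.__dict__ for i in a] == [i.__dict__ for i in b]

    def test_mismatched_null_params_error(self, uniform_genome):
        track = trinuc_chi2_scan(uniform_genome, 2000, 1000)
        null = shuffled_null_track(uniform_genome, 2000, 2000, n_shuffles=1)
        with pytest.raises(ValueError, match="window/step"):
            call_islands(track, uniform_genome, null_track=null)


class TestAnnotateIslands:
    def _island(self, start, end):
        from predaseq.composition import GenomicIsland
        return GenomicIsland(start=start, end=end, size_bp=end - start + 1,
                             mean_chi2=100.0)

    def test_trna_flank_within_distance(self):
        g = GenomeRecord(id="x", sequence="A" * 30_000, features=[
            Feature("t1", "tRNA", 9700, 9775),
        ])
        isl = annotate_islands([self._island(10_000, 20_000)], g, flank_bp=2000)
        assert isl[0].trna_flanked
        far = annotate_islands([self._island(10_000, 20_000)], g, flank_bp=100)
        assert not far[0].trna_flanked

    def test_integrase_keyword_match(self):
        g = GenomeRecord(id="x", sequence="A" * 30_000, features=[
            Feature("i1", "CDS", 12_000, 13_000, "+",
                    "Phage Integrase family protein"),
        ])
        isl = annotate_islands([self._island(10_000, 20_000)], g)
        assert isl[0].has_integrase

    def test_featureless_island_has_no_flags(self):
        g = GenomeRecord(id="x", sequence="A" * 30_000)
        isl = annotate_islands([self._island(10_000, 20_000)], g)
        assert not isl[0].trna_flanked and not isl[0].has_integrase
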