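import numpy as np
import pandas as pd
import pytest

from predaseq import simulate as sim
from predaseq.expression import (
    ClassificationScheme,
    CoverageTrack,
    build_gene_expression,
    classify,
    compare_phases,
    coverage_from_alignments,
    coverage_summaries,
    gene_set_fold_change,
    gei,
    intergenic_background,
    quantify,
)
from predaseq.genome_io import Feature, GenomeRecord


def _track(depth, n=None, condition="x"):
    depth = np.asarray(depth)
    n = n if n is not None else int(depth.sum()) or 1
    return CoverageTrack(condition=condition, depth=depth, n_reads_total=n,
                         n_reads_mapped=n, n_reads_nonrrna=n)


class TestGei:
    def test_default_scale_returns_raw_mean_depth(self):
        track = _track(np.full(1000, 10), n=10**6)
        gene = Feature("g", "CDS", 101, 200)
        assert gei(track, gene) == pytest.approx(10.0)

    def test_zero_coverage(self):
        track = _track(np.zeros(100, dtype=int), n=10)
        assert gei(track, Feature("g", "CDS", 1, 50)) == 0.0

    def test_invariant_under_read_duplication(self):
        depth = np.arange(100)
        gene = Feature("g", "CDS", 10, 60)
        a = gei(_track(depth, n=5000), gene)
        b = gei(_track(depth * 2, n=10000), gene)
        assert a == pytest.approx(b)

    def test_scaling_invariance_exact(self):
        """GEI is bit-identical under uniform read-count scaling."""
        depth = np.array([3, 7, 1, 0, 9, 4] * 50)
        gene = Feature("g", "CDS", 20, 250)
        for k in (2, 8, 64):
            assert gei(_track(depth, n=1024), gene) == gei(
                _track(depth * k, n=1024 * k), gene)

    def test_no_nonrrna_reads_errors(self):
        track = CoverageTrack("x", np.zeros(10, dtype=int), 5, 5, 0)
        with pytest.raises(ValueError, match="non-rRNA"):
            gei(track, Feature("g", "CDS", 1, 5))


class TestClassify:
    @pytest.mark.parametrize(
        "value,expected",
        [
            (0.0, "not_expressed"),
            (0.5, "not_expressed"),
            (0.6999999, "not_expressed"),
            (0.7, "low"),
            (9.999999, "low"),
            (10.0, "medium"),
            (24.999999, "medium"),
            (25.0, "high"),
            (1000.0, "high"),
        ],
    )
    def test_boundaries_lower_inclusive(self, value, expected):
        assert classify(value) == expected

    def test_negative_rejected(self):
        with pytest.raises(ValueError):
            classify(-0.1)

    def test_monotone_step_function(self):
        order = ["not_expressed", "low", "medium", "high"]
        values = np.linspace(0, 30, 301)
        cats = [order.index(classify(v)) for v in values]
        assert cats == sorted(cats)

    def test_invalid_scheme_rejected(self):
        with pytest.raises(ValueError):
            ClassificationScheme(t_off=12, t_low_hi=10, t_med_hi=25)


class TestIntergenicBackground:
    def test_median_of_region_means(self):
        # three intergenic regions with means 0.2, 0.7, 1.4
        depth = np.concatenate([
            np.full(10, 0.2), np.full(10, 5), np.full(10, 0.7),
            np.full(10, 5), np.full(10, 1.4),
        ]).astype(float)
        g = GenomeRecord(id="x", sequence="A" * 50, features=[
            Feature("g1", "CDS", 11, 20), Feature("g2", "CDS", 31, 40),
        ])
        track = CoverageTrack("x", depth, 10**6, 10**6, 10**6)
        assert intergenic_background(track, g) == pytest.approx(0.7)

    def test_all_zero_track(self):
        g = GenomeRecord(id="x", sequence="A" * 50,
                         features=[Feature("g1", "CDS", 11, 20)])
        track = _track(np.zeros(50, dtype=int), n=10)
        assert intergenic_background(track, g) == 0.0

    def test_no_intergenic_errors(self):
        g = GenomeRecord(id="x", sequence="A" * 50,
                         features=[Feature("g1", "CDS", 1, 50)])
        with pytest.raises(ValueError, match="intergenic"):
            intergenic_background(_track(np.ones(50, dtype=int)), g)

    def test_known_background_recovered(self):
        g, truth = sim.make_genome(length=100_000, n_islands=0, n_repeats=0,
                                   seed=6, with_rrna_operon=False)
        truth = sim.design_two_phase(g, truth, seed=7)
        errs = []
        for s in range(5):
            track = sim.make_coverage(g, truth, condition="attachment",
                                      depth_factor=5.0, seed=s)
            est = intergenic_background(track, g,
                                        scale=track.n_reads_nonrrna / 5.0)
            errs.append(abs(est - truth.background_coverage) / 0.7)
        assert np.mean(errs) < 0.10


class TestCoverageFromAlignments:
    def test_sam_round_trip_matches_generator_track(self, tmp_path):
        g, truth = sim.make_genome(length=20_000, n_islands=0, n_repeats=0,
                                   seed=8, with_rrna_operon=False)
        truth = sim.design_two_phase(g, truth, seed=9)
        sam = tmp_path / "att.sam"
        track = sim.make_coverage(g, truth, condition="attachment",
                                  depth_factor=2.0, seed=10, sam_path=sam)
        back = coverage_from_alignments(sam, g, condition="attachment")
        assert np.array_equal(back.depth, track.depth)
        assert back.n_reads_mapped == track.n_reads_nonrrna

    def test_tiling_reads_mean_depth(self, tmp_path):
        g = GenomeRecord(id="tile", sequence="ACGTA" * 100, circular=False)
        sam = tmp_path / "tile.sam"
        lines = ["@HD\tVN:1.6", f"@SQ\tSN:tile\tLN:500"]
        for i in range(10):
            pos = 1 + 50 * i
            lines.append(f"r{i}\t0\ttile\t{pos}\t60\t50M\t*\t0\t0\t"
                         + "A" * 50 + "\t" + "I" * 50)
        sam.write_text("\n".join(lines) + "\n")
        track = coverage_from_alignments(sam, g)
        assert track.depth.mean() == pytest.approx(1.0)
        assert track.n_reads_mapped == 10

    def test_rrna_reads_excluded_from_denominator(self, tmp_path):
        g = GenomeRecord(id="r", sequence="A" * 500, circular=False)
        sam = tmp_path / "r.sam"
        lines = ["@HD\tVN:1.6", "@SQ\tSN:r\tLN:500"]
        for i in range(5):
            lines.append(f"r{i}\t0\tr\t{1 + 10 * i}\t60\t50M\t*\t0\t0\t"
                         + "A" * 50 + "\t" + "I" * 50)
        sam.write_text("\n".join(lines) + "\n")
        track = coverage_from_alignments(sam, g, rrna_intervals=[(1, 200)])
        assert track.n_reads_mapped == 5
        assert track.n_reads_nonrrna == 0

    def test_reference_mismatch_errors(self, tmp_path):
        g = GenomeRecord(id="right", sequence="A" * 100, circular=False)
        sam = tmp_path / "bad.sam"
        sam.write_text("@HD\tVN:1.6\n@SQ\tSN:wrong\tLN:100\n")
        with pytest.raises(ValueError, match="does not match"):
            coverage_from_alignments(sam, g)

    def test_depth_tsv_input(self, tmp_path):
        g = GenomeRecord(id="d", sequence="A" * 100, circular=False)
        tsv = tmp_path / "d.tsv"
        tsv.write_text("".join(f"{i}\t{2}\n" for i in range(1, 101)))
        track = coverage_from_alignments(tsv, g, read_length=50)
        assert track.depth.sum() == 200
        assert track.n_reads_mapped == 4


class TestComparePhases:
    def _expr(self, pairs):
        tables = {}
        for cond, col in (("attachment", 0), ("attack", 1)):
            rows = [(tag, v[col], classify(v[col]), classify(v[col]) != "not_expressed")
                    for tag, v in pairs.items()]
            tables[cond] = pd.DataFrame(
                rows, columns=["locus_tag", "gei", "category", "transcribed"]
            ).set_index("locus_tag")
        return build_gene_expression(tables)

    def test_downregulated_gene_has_fold_below_one(self):
        expr = self._expr({"hemolysin": (30.0, 124.4), "other": (5.0, 5.0)})
        report = compare_phases(expr)
        assert report.table.loc["hemolysin", "fold_change"] < 1

    def test_identical_phases_give_diagonal_transitions(self):
        expr = self._expr({f"g{i}": (v, v) for i, v in enumerate(
            [0.1, 0.8, 12.0, 30.0, 5.0])})
        report = compare_phases(expr)
        off_diag = report.transitions.to_numpy().sum() - np.trace(
            report.transitions.to_numpy())
        assert off_diag == 0

    def test_fraction_transcribed_matches_indicator_mean(self):
        expr = self._expr({f"g{i}": (v, 1.0) for i, v in enumerate(
            [0.1, 0.8, 12.0, 0.2, 30.0])})
        report = compare_phases(expr)
        assert report.frac_transcribed["attachment"] == pytest.approx(3 / 5)
        assert report.frac_transcribed["attack"] == 1.0

    def test_mismatched_gene_sets_error(self):
        tables = {
            "attachment": pd.DataFrame(
                {"gei": [1.0], "category": ["low"], "transcribed": [True]},
                index=pd.Index(["a"], name="locus_tag")),
            "attack": pd.DataFrame(
                {"gei": [1.0], "category": ["low"], "transcribed": [True]},
                index=pd.Index(["b"], name="locus_tag")),
        }
        with pytest.raises(ValueError, match="different gene sets"):
            build_gene_expression(tables)


class TestGeneSetFoldChange:
    def _expr(self):
        expr = []
        from predaseq.expression import GeneExpression
        for tag, att, atk in (("a", 4.0, 1.0), ("b", 16.0, 1.0), ("c", 2.0, 2.0)):
            ge = GeneExpression(locus_tag=tag,
                                gei={"attachment": att, "attack": atk},
                                category={}, transcribed={})
            expr.append(ge)
        return expr

    def test_arithmetic_and_geometric_means(self):
        expr = self._expr()
        arith = gene_set_fold_change(expr, ["a", "b"], pseudocount=0.0)
        geom = gene_set_fold_change(expr, ["a", "b"], pseudocount=0.0,
                                    method="geometric")
        assert arith == pytest.approx(10.0)
        assert geom == pytest.approx(8.0)

    def test_singleton_set(self):
        assert gene_set_fold_change(self._expr(), ["a"], pseudocount=0.0) == 4.0

    def test_empty_set_errors(self):
        with pytest.raises(ValueError, match="empty"):
            gene_set_fold_change(self._expr(), [])


class TestCoverageSummaries:
    def test_uniform_depth_fully_covered(self):
        g = GenomeRecord(id="x", sequence="A" * 100,
                         features=[Feature("g1", "CDS", 1, 50)])
        out = coverage_summaries(_track(np.ones(100, dtype=int)), g)
        assert out["genome_covered_percent"] == 100.0

    def test_no_reads_reports_zero_with_warning(self):
        g = GenomeRecord(id="x", sequence="A" * 100,
                         features=[Feature("g1", "CDS", 1, 50)])
        with pytest.warns(UserWarning, match="no reads"):
            out = coverage_summaries(_track(np.zeros(100, dtype=int), n=1), g)
        assert out["genome_covered_percent"] == 0.0
        assert out["reads_in_orfs_percent"] == 0.0

    def test_midpoint_assignment(self):
        g = GenomeRecord(id="x", sequence="A" * 100,
                         features=[Feature("g1", "CDS", 1, 50)])
        track = CoverageTrack("x", np.ones(100, dtype=int), 4, 4, 4,
                              read_midpoints=np.array([10, 20, 60, 70]))
        out = coverage_summaries(track, g)
        assert out["reads_in_orfs_percent"] == 50.0


def test_quantify_category_recovery_on_simulated_genes():
    """Per-gene GEI estimates recover planted categories at modest depth."""
    g, truth = sim.make_genome(length=60_000, n_islands=0, n_repeats=0,
                               seed=30, with_rrna_operon=False)
    truth = sim.design_two_phase(g, truth, seed=31)
    track = sim.make_coverage(g, truth, condition="attack", depth_factor=2.0,
                              seed=32)
    table = quantify(track, g, scale=track.n_reads_nonrrna / 2.0)
    truth_cat = truth.true_category["attack"]
    agree = (table.loc[truth_cat.index, "category"] == truth_cat).mean()
    assert agree >= 0.95
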