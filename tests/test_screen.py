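"""Expression filter, exon inclusion ratios, and the correlation statistic."""

import math

import numpy as np
import pandas as pd
import pytest

from natscreen.coverage import CoverageTrack
from natscreen.expression import ExpressionMatrix
from natscreen.models import GenomicInterval
from natscreen.pairing import SAPair
from natscreen.screen import (
    correlate_exon_antisense,
    exon_ratio,
    expression_filter,
    multi_isoform_filter,
    run_screen,
)
from tests.test_pairing import make_gene

SAMPLES = pd.DataFrame(
    {
        "tissue": ["wing", "wing", "eye", "eye"],
        "replicate": [1, 2, 1, 2],
    },
    index=pd.Index(["w1", "w2", "e1", "e2"], name="sample_id"),
)


def matrix(rows: dict) -> ExpressionMatrix:
    values = pd.DataFrame(rows, index=SAMPLES.index).T
    return ExpressionMatrix(values=values, samples=SAMPLES)


def pair(lnc="lnc", pc="pc"):
    return SAPair(lnc_id=lnc, pc_id=pc, chrom="c", configuration="internal", overlap_bp=10)


class TestExpressionFilter:
    def test_one_replicate_below_threshold_fails(self):
        expr = matrix({"lnc": [0.6, 0.4, 0.1, 0.1], "pc": [5, 5, 5, 5]})
        assert expression_filter([pair()], expr) == []

    def test_members_may_pass_in_different_tissues(self):
        expr = matrix({"lnc": [0.9, 0.8, 0.1, 0.1], "pc": [0.1, 0.1, 3.0, 2.0]})
        assert expression_filter([pair()], expr) == [pair()]

    def test_zero_threshold_is_vacuous(self):
        expr = matrix({"lnc": [0.01, 0.01, 0.01, 0.01], "pc": [0.01, 0.01, 0.01, 0.01]})
        assert expression_filter([pair()], expr, threshold=0.0) == [pair()]

    def test_missing_feature_counts_as_unexpressed(self):
        expr = matrix({"pc": [5, 5, 5, 5]})
        assert expression_filter([pair()], expr) == []


class TestMultiIsoformFilter:
    def test_single_isoform_host_dropped(self):
        single = make_gene("pc", "protein_coding", "+", [(0, 100)])
        assert multi_isoform_filter([pair()], [single]) == []

    def test_multi_isoform_host_kept_and_empty_input_passes_through(self):
        multi = make_gene("pc", "protein_coding", "+", [(0, 100), (300, 400)])
        multi.transcripts.append(
            type(multi.transcripts[0])(
                "pc-t2", "pc", [GenomicInterval("c", 0, 100, "+")]
            )
        )
        assert multi_isoform_filter([pair()], [multi]) == [pair()]
        assert multi_isoform_filter([], [multi]) == []


def track(rows, chrom="c"):
    starts = np.array([r[0] for r in rows], dtype=np.int64)
    ends = np.array([r[1] for r in rows], dtype=np.int64)
    values = np.array([r[2] for r in rows], dtype=float)
    return CoverageTrack({chrom: (starts, ends, values)})


class TestExonRatio:
    gene = make_gene("g", "protein_coding", "+", [(0, 100), (300, 400)])

    def test_uniform_coverage_gives_ratio_one_in_both_modes(self):
        cov = track([(0, 400, 10.0)])
        exon = self.gene.distinct_exons[0]
        assert exon_ratio(cov, self.gene, exon, "span") == pytest.approx(1.0)
        assert exon_ratio(cov, self.gene, exon, "exon_union") == pytest.approx(1.0)

    def test_ratio_is_mean_exon_over_mean_gene(self):
        # exon mean 5 over [0,100); gene-span mean 10 over [0,400)
        cov = track([(0, 100, 5.0), (100, 400, 35.0 / 3)])
        exon = self.gene.distinct_exons[0]
        assert exon_ratio(cov, self.gene, exon, "span") == pytest.approx(0.5)

    def test_zero_gene_coverage_is_undefined(self):
        cov = track([(5000, 5100, 7.0)])
        assert math.isnan(exon_ratio(cov, self.gene, self.gene.distinct_exons[0]))

    def test_exon_outside_gene_span_raises(self):
        cov = track([(0, 400, 1.0)])
        with pytest.raises(ValueError, match="outside span"):
            exon_ratio(cov, self.gene, GenomicInterval("c", 900, 950, "+"))

    def test_depth_scaling_invariance(self):
        rng = np.random.default_rng(7)
        vals = rng.uniform(1, 9, size=4)
        cov = track([(0, 100, vals[0]), (100, 250, vals[1]), (250, 330, vals[2]), (330, 400, vals[3])])
        for exon in self.gene.distinct_exons:
            for mode in ("span", "exon_union"):
                r1 = exon_ratio(cov, self.gene, exon, mode)
                r2 = exon_ratio(cov.scaled(37.5), self.gene, exon, mode)
                assert r2 == pytest.approx(r1)


class TestPearson:
    def idx(self, values):
        return pd.Series(values, index=["a", "b", "c"], dtype=float)

    def test_perfect_linearity(self):
        r = correlate_exon_antisense(self.idx([0.1, 0.2, 0.3]), self.idx([1, 2, 3]))
        assert r == pytest.approx(1.0)

    def test_hand_computed_value(self):
        # x=(1,2,4), y=(6,5,3): centred y is exactly -1 times centred x,
        # so the product-moment correlation is exactly -1
        r = correlate_exon_antisense(self.idx([1, 2, 4]), self.idx([6, 5, 3]))
        assert r == pytest.approx(-1.0)

    def test_constant_vector_is_undefined(self):
        assert math.isnan(
            correlate_exon_antisense(self.idx([0.5, 0.5, 0.5]), self.idx([1, 2, 3]))
        )

    def test_too_few_valid_samples_is_undefined(self):
        ratios = pd.Series([0.1, np.nan, 0.3], index=["a", "b", "c"])
        assert math.isnan(correlate_exon_antisense(ratios, self.idx([1, 2, 3])))

    def test_mismatched_sample_sets_raise(self):
        other = pd.Series([1.0, 2.0, 3.0], index=["a", "b", "x"])
        with pytest.raises(ValueError, match="different samples"):
            correlate_exon_antisense(self.idx([1, 2, 3]), other)

    def test_affine_invariance_and_sign_antisymmetry(self):
        rng = np.random.default_rng(11)
        x = pd.Series(rng.uniform(0, 1, 6), index=list("abcdef"))
        y = pd.Series(rng.uniform(0, 50, 6), index=list("abcdef"))
        r = correlate_exon_antisense(x, y)
        assert correlate_exon_antisense(0.3 * x + 2, 7 * y + 1) == pytest.approx(r)
        assert correlate_exon_antisense(-x, y) == pytest.approx(-r)
        assert correlate_exon_antisense(x, -y) == pytest.approx(-r)


class TestRunScreen:
    def test_selection_gates_are_strict_and_joint(self, study, study_pairs):
        from natscreen.screen import expression_filter, multi_isoform_filter

        kept = multi_isoform_filter(
            expression_filter(study_pairs, study.expr), study.genes
        )
        cand = run_screen(study.genes, kept, study.expr, study.coverage_by_sample)
        sel = cand[cand.selected]
        assert (sel.sd > 0.1).all() and (sel.r.abs() > 0.7).all()
        unsel = cand[~cand.selected]
        assert (
            (unsel.sd <= 0.1) | (unsel.r.abs() <= 0.7) | unsel.r.isna() | unsel.sd.isna()
        ).all()

    def test_threshold_monotonicity(self, study, study_pairs):
        kept = multi_isoform_filter(
            expression_filter(study_pairs, study.expr), study.genes
        )
        base = run_screen(study.genes, kept, study.expr, study.coverage_by_sample)
        key = ["pc_id", "exon_start"]
        selected = {
            (sd, r): set(
                map(
                    tuple,
                    run_screen(
                        study.genes, kept, study.expr, study.coverage_by_sample,
                        sd_min=sd, abs_r_min=r,
                    ).query("selected")[key].itertuples(index=False),
                )
            )
            for sd in (0.05, 0.1, 0.5)
            for r in (0.5, 0.7, 0.9)
        }
        for sd1, r1 in selected:
            for sd2, r2 in selected:
                if sd2 >= sd1 and r2 >= r1:
                    assert selected[(sd2, r2)] <= selected[(sd1, r1)]
        assert len(base) == sum(
            len(g.distinct_exons)
            for g in study.genes
            if g.gene_id in {p.pc_id for p in kept}
        )

    def test_missing_coverage_track_raises_with_sample_name(self, study, study_pairs):
        cov = dict(study.coverage_by_sample)
        cov.pop("eye_2")
        with pytest.raises(ValueError, match="eye_2"):
            run_screen(study.genes, study_pairs, study.expr, cov)

    def test_output_sorted_by_abs_r_then_sd(self, study, study_pairs):
        kept = multi_isoform_filter(
            expression_filter(study_pairs, study.expr), study.genes
        )
        cand = run_screen(study.genes, kept, study.expr, study.coverage_by_sample)
        abs_r = cand.r.abs()
        defined = abs_r.dropna()
        assert (defined.diff().dropna() <= 1e-12).all()
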