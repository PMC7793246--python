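"""Antisense pair detection, configuration rules, complex resolution."""

import numpy as np
import pytest

from natscreen.models import GeneModel, GenomicInterval, TranscriptModel
from natscreen.oracle import brute_force_pairs
from natscreen.pairing import (
    classify_pair,
    configuration_census,
    find_sa_pairs,
    resolve_complex,
)
from natscreen.simulate import random_genes


def make_gene(gene_id, biotype, strand, exon_coords, chrom="c"):
    """One single-transcript gene from a list of (start, end) exons."""
    exons = [GenomicInterval(chrom, s, e, strand) for s, e in exon_coords]
    return GeneModel(
        gene_id=gene_id,
        biotype=biotype,
        transcripts=[TranscriptModel(f"{gene_id}-t1", gene_id, exons)],
    )


def test_same_strand_overlap_is_not_a_pair():
    a = make_gene("lnc", "lncRNA", "+", [(0, 1000)])
    b = make_gene("pc", "protein_coding", "+", [(500, 1500)])
    assert find_sa_pairs([a, b]) == []


def test_pseudogenes_never_pair():
    a = make_gene("ps", "pseudogene", "-", [(0, 1000)])
    b = make_gene("pc", "protein_coding", "+", [(500, 1500)])
    assert find_sa_pairs([a, b]) == []


def test_internal_containment():
    lnc = make_gene("lnc", "lncRNA", "-", [(1000, 2000)])
    pc = make_gene("pc", "protein_coding", "+", [(0, 400), (9000, 10000)])
    assert classify_pair(lnc, pc) == "internal"


def test_external_containment():
    lnc = make_gene("lnc", "lncRNA", "-", [(0, 500), (9000, 10000)])
    pc = make_gene("pc", "protein_coding", "+", [(1000, 2000)])
    assert classify_pair(lnc, pc) == "external"


def test_head_to_head_first_exon_overlap():
    # pc(+) first exon [1000,1500); lnc(-) 5'-in-transcription exon [1400,1900)
    # overlaps it, and the two 5' ends face each other across the overlap
    pc = make_gene("pc", "protein_coding", "+", [(1000, 1500), (1800, 2200)])
    lnc = make_gene("lnc", "lncRNA", "-", [(200, 500), (1400, 1900)])
    assert classify_pair(lnc, pc) == "head_to_head"


def test_tail_to_tail_last_exon_overlap():
    pc = make_gene("pc", "protein_coding", "+", [(0, 400), (900, 1400)])
    lnc = make_gene("lnc", "lncRNA", "-", [(1300, 1800), (2500, 3000)])
    assert classify_pair(lnc, pc) == "tail_to_tail"


def test_mid_body_overlap_reported_as_other():
    # overlap exists (pc 3' exon inside the lnc span) but neither gene's
    # terminal exons touch any exon of the other -> the unnamed residual class
    pc = make_gene("pc", "protein_coding", "+", [(0, 100), (1400, 1500), (2900, 3000)])
    lnc = make_gene("lnc", "lncRNA", "-", [(1200, 1300), (2000, 2100), (4400, 4500)])
    assert classify_pair(lnc, pc) == "other_overlap"


def test_non_overlapping_genes_raise():
    lnc = make_gene("lnc", "lncRNA", "-", [(5000, 6000)])
    pc = make_gene("pc", "protein_coding", "+", [(0, 1000)])
    with pytest.raises(ValueError, match="do not overlap"):
        classify_pair(lnc, pc)


def test_internal_flips_when_lnc_outgrows_host_by_one_base():
    pc = make_gene("pc", "protein_coding", "+", [(1000, 1200), (4800, 5000)])
    inside = make_gene("lnc", "lncRNA", "-", [(2000, 3000)])
    assert classify_pair(inside, pc) == "internal"
    past_right = make_gene("lnc", "lncRNA", "-", [(2000, 5001)])
    assert classify_pair(past_right, pc) != "internal"
    past_left = make_gene("lnc", "lncRNA", "-", [(999, 3000)])
    assert classify_pair(past_left, pc) != "internal"


def test_two_gene_component_keeps_label_three_gene_component_goes_complex():
    lnc = make_gene("lnc", "lncRNA", "-", [(500, 800), (2600, 3000)])
    pc1 = make_gene("pc1", "protein_coding", "+", [(0, 700), (1000, 1200)])
    pc2 = make_gene("pc2", "protein_coding", "+", [(2500, 2800), (3500, 3800)])

    solo = resolve_complex(find_sa_pairs([lnc, pc1]))
    assert [p.configuration for p in solo] != ["complex"]

    both = resolve_complex(find_sa_pairs([lnc, pc1, pc2]))
    assert len(both) == 2
    assert all(p.configuration == "complex" for p in both)
    assert len({p.component_id for p in both}) == 1


def test_exon_vs_exon_mode_requires_exonic_complementarity():
    # lncRNA fully intronic: pairs under exon_vs_span, not under exon_vs_exon
    pc = make_gene("pc", "protein_coding", "+", [(0, 200), (8000, 8200)])
    lnc = make_gene("lnc", "lncRNA", "-", [(3000, 3500)])
    assert len(find_sa_pairs([lnc, pc], overlap_mode="exon_vs_span")) == 1
    assert find_sa_pairs([lnc, pc], overlap_mode="exon_vs_exon") == []


def test_census_counts_partition_and_percentages(census_genome):
    genes, truth = census_genome
    pairs = resolve_complex(find_sa_pairs(genes), genes)
    census = configuration_census(pairs)
    counts = {k: v["count"] for k, v in census["configurations"].items()}
    assert sum(counts.values()) == census["pairs_total"] == len(pairs)
    expected = truth["expected_configuration"].value_counts().to_dict()
    for label in ("internal", "head_to_head", "tail_to_tail", "external", "complex"):
        assert counts[label] == expected.get(label, 0)
    got = {(p.lnc_id, p.pc_id): p.configuration for p in pairs}
    want = {
        (r.lnc_id, r.pc_id): r.expected_configuration for r in truth.itertuples()
    }
    assert got == want


def test_pair_output_invariant_to_gene_order(census_genome):
    genes, _ = census_genome
    shuffled = list(genes)[::-1]
    assert resolve_complex(find_sa_pairs(genes)) == resolve_complex(
        find_sa_pairs(shuffled)
    )


def test_simulated_antisense_locus_is_internal(study, study_pairs):
    by_key = {(p.lnc_id, p.pc_id): p for p in study_pairs}
    assert by_key[("asRNA_like", "bs_like")].configuration == "internal"
    pc = next(g for g in study.genes if g.gene_id == "bs_like")
    assert len(pc.transcripts) == 3


@pytest.mark.parametrize("mode", ["exon_vs_span", "exon_vs_exon"])
def test_agreement_with_per_base_oracle_on_random_genomes(mode):
    for seed in range(30):
        genes = random_genes(np.random.default_rng(seed))
        mine = {
            (p.lnc_id, p.pc_id): p.configuration
            for p in resolve_complex(find_sa_pairs(genes, overlap_mode=mode))
        }
        assert mine == brute_force_pairs(genes, overlap_mode=mode), f"seed {seed}"
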