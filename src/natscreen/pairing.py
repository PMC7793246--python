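"""Detection and classification of lncRNA/protein-coding antisense pairs.

A sense/antisense (SA) pair is one lncRNA and one protein-coding gene on
opposite strands of the same chromosome whose overlap involves at least one
exonic nucleotide. Each pair is classified into one configuration:

* ``internal``      — the lncRNA span lies fully within the coding gene span
* ``external``      — the coding gene span lies fully within the lncRNA span
* ``head_to_head``  — 5' first-exon overlap, the two 5' ends facing each other
* ``tail_to_tail``  — 3' last-exon overlap, the two 3' ends facing each other
* ``other_overlap`` — mid-body overlap matching none of the above
* ``complex``       — any pair inside an overlap component of more than 2 genes

Classification precedence is internal > external > head_to_head >
tail_to_tail > other_overlap; ``complex`` overrides all of them after the
overlap graph is built. Containment is span-based (an intronic lncRNA is
internal to its host even without exon-exon overlap).
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import networkx as nx
from intervaltree import IntervalTree

from .models import GeneModel, GenomicInterval, merge_intervals

__all__ = [
    "SAPair",
    "find_sa_pairs",
    "classify_pair",
    "resolve_complex",
    "configuration_census",
    "CONFIGURATIONS",
]

CONFIGURATIONS = (
    "internal",
    "head_to_head",
    "tail_to_tail",
    "external",
    "complex",
    "other_overlap",
)

OVERLAP_MODES = ("exon_vs_span", "exon_vs_exon")
TERMINAL_SCOPES = ("union", "longest_transcript")


@dataclass(frozen=True)
class SAPair:
    """One lncRNA <-> protein-coding antisense pair."""

    lnc_id: str
    pc_id: str
    chrom: str
    configuration: str
    overlap_bp: int
    component_id: str | None = None

    def __post_init__(self) -> None:
        if self.overlap_bp < 1:
            raise ValueError("SA pair must overlap by at least 1 exonic base")


def _clip(ivs: list[GenomicInterval], region: GenomicInterval) -> list[GenomicInterval]:
    out = []
    for iv in ivs:
        s, e = max(iv.start, region.start), min(iv.end, region.end)
        if iv.chrom == region.chrom and e > s:
            out.append(GenomicInterval(iv.chrom, s, e, iv.strand))
    return out


def _intersect(a: list[GenomicInterval], b: list[GenomicInterval]) -> list[GenomicInterval]:
    out = []
    for iv in a:
        out.extend(_clip(b, iv))
    return merge_intervals(out) if out else []


def exonic_overlap_bp(a: GeneModel, b: GeneModel, overlap_mode: str) -> int:
    """Number of genomic bases satisfying the exonic-overlap rule.

    ``exon_vs_span``: bases of either gene's exon union inside the other
    gene's span. ``exon_vs_exon``: bases shared between the two exon unions.
    """
    if overlap_mode == "exon_vs_exon":
        shared = _intersect(a.exon_union, b.exon_union)
        return sum(iv.length() for iv in shared)
    if overlap_mode == "exon_vs_span":
        pieces = _clip(a.exon_union, b.span) + _clip(b.exon_union, a.span)
        if not pieces:
            return 0
        return sum(iv.length() for iv in merge_intervals(pieces))
    raise ValueError(f"unknown overlap_mode {overlap_mode!r}")


def _terminal_exons(gene: GeneModel, which: str, scope: str) -> list[GenomicInterval]:
    if scope == "union":
        return gene.first_exons if which == "first" else gene.last_exons
    if scope == "longest_transcript":
        tx = max(gene.transcripts, key=lambda t: (t.span.length(), t.transcript_id))
        return [tx.first_exon if which == "first" else tx.last_exon]
    raise ValueError(f"unknown exon_terminal_scope {scope!r}")


def _any_overlap(a: list[GenomicInterval], b: list[GenomicInterval]) -> bool:
    return any(x.overlaps(y) for x in a for y in b)


def classify_pair(
    lnc: GeneModel,
    pc: GeneModel,
    exon_terminal_scope: str = "union",
) -> str:
    """Pre-complex configuration of one antisense pair.

    The caller guarantees the two genes overlap; raises otherwise.
    """
    if not lnc.span.overlaps(pc.span):
        raise ValueError(
            f"genes {lnc.gene_id} and {pc.gene_id} do not overlap"
        )
    if lnc.strand == pc.strand or "." in (lnc.strand, pc.strand):
        raise ValueError(
            f"genes {lnc.gene_id} and {pc.gene_id} are not antisense"
        )
    if pc.span.contains(lnc.span):
        return "internal"
    if lnc.span.contains(pc.span):
        return "external"

    plus, minus = (lnc, pc) if lnc.strand == "+" else (pc, lnc)
    p1, p2 = plus.span.start, plus.span.end
    m1, m2 = minus.span.start, minus.span.end
    # 5' ends face each other: overlap sits at the + gene's start (its 5')
    # and at the - gene's end (its 5')
    h2h_geometry = m1 <= p1 and m2 <= p2
    # 3' ends face each other: overlap sits at the + gene's end (its 3')
    # and at the - gene's start (its 3')
    t2t_geometry = p1 <= m1 and p2 <= m2

    if h2h_geometry:
        first_a = _terminal_exons(lnc, "first", exon_terminal_scope)
        first_b = _terminal_exons(pc, "first", exon_terminal_scope)
        if _any_overlap(first_a, pc.distinct_exons) or _any_overlap(
            first_b, lnc.distinct_exons
        ):
            return "head_to_head"
    if t2t_geometry:
        last_a = _terminal_exons(lnc, "last", exon_terminal_scope)
        last_b = _terminal_exons(pc, "last", exon_terminal_scope)
        if _any_overlap(last_a, pc.distinct_exons) or _any_overlap(
            last_b, lnc.distinct_exons
        ):
            return "tail_to_tail"
    return "other_overlap"


def find_sa_pairs(
    genes: list[GeneModel],
    overlap_mode: str = "exon_vs_span",
    exon_terminal_scope: str = "union",
) -> list[SAPair]:
    """All lncRNA/protein-coding antisense pairs with >= 1 exonic-base overlap.

    Pairs carry pre-complex configuration labels; run
    :func:`resolve_complex` afterwards to apply the >2-gene rule. Output
    order is deterministic: (chrom, leftmost span start, lnc_id, pc_id).
    Pseudogene/other biotypes never pair.
    """
    if overlap_mode not in OVERLAP_MODES:
        raise ValueError(f"unknown overlap_mode {overlap_mode!r}")
    lncs = [g for g in genes if g.biotype == "lncRNA" and g.strand in "+-"]
    pcs = [g for g in genes if g.biotype == "protein_coding" and g.strand in "+-"]

    trees: dict[str, IntervalTree] = {}
    for pc in pcs:
        trees.setdefault(pc.chrom, IntervalTree()).addi(
            pc.span.start, pc.span.end, pc
        )

    pairs: list[SAPair] = []
    for lnc in lncs:
        tree = trees.get(lnc.chrom)
        if tree is None:
            continue
        for hit in tree.overlap(lnc.span.start, lnc.span.end):
            pc = hit.data
            if pc.strand == lnc.strand:
                continue
            bp = exonic_overlap_bp(lnc, pc, overlap_mode)
            if bp < 1:
                continue
            config = classify_pair(lnc, pc, exon_terminal_scope)
            pairs.append(
                SAPair(
                    lnc_id=lnc.gene_id,
                    pc_id=pc.gene_id,
                    chrom=lnc.chrom,
                    configuration=config,
                    overlap_bp=bp,
                )
            )
    span_start = {g.gene_id: g.span.start for g in genes}
    pairs.sort(
        key=lambda p: (
            p.chrom,
            min(span_start[p.lnc_id], span_start[p.pc_id]),
            p.lnc_id,
            p.pc_id,
        )
    )
    return pairs


def resolve_complex(pairs: list[SAPair], genes: list[GeneModel] | None = None) -> list[SAPair]:
    """Relabel pairs inside >2-gene overlap components as ``complex``.

    Builds the undirected overlap graph whose nodes are genes appearing in
    pairs and whose edges are the pairs themselves; every pair in a
    connected component containing more than 2 genes becomes ``complex``.
    All pairs are assigned a ``component_id``.
    """
    graph = nx.Graph()
    for p in pairs:
        graph.add_edge(p.lnc_id, p.pc_id)
    components = [sorted(c) for c in nx.connected_components(graph)]
    components.sort(key=lambda c: c[0])
    comp_of: dict[str, str] = {}
    comp_size: dict[str, int] = {}
    for i, comp in enumerate(components, start=1):
        cid = f"C{i:04d}"
        for gid in comp:
            comp_of[gid] = cid
            comp_size[gid] = len(comp)
    out = []
    for p in pairs:
        cid = comp_of[p.lnc_id]
        config = "complex" if comp_size[p.lnc_id] > 2 else p.configuration
        out.append(replace(p, configuration=config, component_id=cid))
    return out


def configuration_census(pairs: list[SAPair]) -> dict:
    """Counts and integer percentages per configuration, plus totals.

    Percentages are over the total pair count, rounded to whole percent.
    """
    counts = {label: 0 for label in CONFIGURATIONS}
    for p in pairs:
        counts[p.configuration] += 1
    total = len(pairs)
    return {
        "pairs_total": total,
        "n_lncRNA": len({p.lnc_id for p in pairs}),
        "n_coding": len({p.pc_id for p in pairs}),
        "configurations": {
            label: {
                "count": n,
                "percent": int(round(100.0 * n / total)) if total else 0,
            }
            for label, n in counts.items()
        },
    }
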