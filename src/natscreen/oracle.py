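"""Per-base brute-force reference for pair detection and classification.

This module re-derives antisense pairs by literally marking, for every
genomic base, which genes' exons and spans cover it, and re-implements the
configuration rules on those base masks. It is deliberately slow and
independent of :mod:`natscreen.pairing`; it exists to verify the interval
algebra on small genomes and is used by the test-suite and the acceptance
checks.
"""

from __future__ import annotations

import numpy as np

from .models import GeneModel

__all__ = ["brute_force_pairs"]


def _masks(gene: GeneModel, length: int):
    exon = np.zeros(length, dtype=bool)
    for tx in gene.transcripts:
        for e in tx.exons:
            exon[e.start : e.end] = True
    span = np.zeros(length, dtype=bool)
    span[gene.span.start : gene.span.end] = True
    first = np.zeros(length, dtype=bool)
    last = np.zeros(length, dtype=bool)
    for tx in gene.transcripts:
        fe, le = tx.first_exon, tx.last_exon
        first[fe.start : fe.end] = True
        last[le.start : le.end] = True
    return exon, span, first, last


def brute_force_pairs(
    genes: list[GeneModel], overlap_mode: str = "exon_vs_span"
) -> dict[tuple[str, str], str]:
    """Map (lnc_id, pc_id) -> final configuration, by per-base enumeration."""
    by_chrom: dict[str, list[GeneModel]] = {}
    for g in genes:
        by_chrom.setdefault(g.chrom, []).append(g)

    edges: list[tuple[str, str]] = []
    prelabel: dict[tuple[str, str], str] = {}

    for chrom_genes in by_chrom.values():
        length = max(g.span.end for g in chrom_genes) + 1
        masks = {g.gene_id: _masks(g, length) for g in chrom_genes}
        lncs = [g for g in chrom_genes if g.biotype == "lncRNA" and g.strand in "+-"]
        pcs = [
            g
            for g in chrom_genes
            if g.biotype == "protein_coding" and g.strand in "+-"
        ]
        for lnc in lncs:
            for pc in pcs:
                if lnc.strand == pc.strand:
                    continue
                le, ls, lf, ll = masks[lnc.gene_id]
                pe, ps, pf, pl = masks[pc.gene_id]
                if overlap_mode == "exon_vs_span":
                    hit = (le & ps) | (pe & ls)
                elif overlap_mode == "exon_vs_exon":
                    hit = le & pe
                else:
                    raise ValueError(overlap_mode)
                if not hit.any():
                    continue
                edges.append((lnc.gene_id, pc.gene_id))
                prelabel[(lnc.gene_id, pc.gene_id)] = _classify(
                    lnc, pc, le, ls, lf, ll, pe, ps, pf, pl
                )

    # connected components by hand (BFS over the pair graph)
    adj: dict[str, set[str]] = {}
    for a, b in edges:
        adj.setdefault(a, set()).add(b)
        adj.setdefault(b, set()).add(a)
    comp_size: dict[str, int] = {}
    seen: set[str] = set()
    for node in adj:
        if node in seen:
            continue
        comp = {node}
        queue = [node]
        while queue:
            cur = queue.pop()
            for nxt in adj[cur]:
                if nxt not in comp:
                    comp.add(nxt)
                    queue.append(nxt)
        seen |= comp
        for gid in comp:
            comp_size[gid] = len(comp)

    return {
        key: ("complex" if comp_size[key[0]] > 2 else label)
        for key, label in prelabel.items()
    }


def _classify(lnc, pc, le, ls, lf, ll, pe, ps, pf, pl) -> str:
    if not (ls & ~ps).any():
        return "internal"
    if not (ps & ~ls).any():
        return "external"
    if lnc.strand == "+":
        p_span, m_span = ls, ps
    else:
        p_span, m_span = ps, ls
    p_pos = np.flatnonzero(p_span)
    m_pos = np.flatnonzero(m_span)
    p1, p2 = p_pos[0], p_pos[-1] + 1
    m1, m2 = m_pos[0], m_pos[-1] + 1
    h2h_geometry = m1 <= p1 and m2 <= p2
    t2t_geometry = p1 <= m1 and p2 <= m2
    if h2h_geometry and ((lf & pe).any() or (pf & le).any()):
        return "head_to_head"
    if t2t_geometry and ((ll & pe).any() or (pl & le).any()):
        return "tail_to_tail"
    return "other_overlap"
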