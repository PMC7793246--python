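"""GTF annotation loading with explicit coordinate and biotype semantics.

GTF coordinates are 1-based and closed; internally everything is 0-based,
half-open. The conversion happens only here:
``start_internal = start_gtf - 1``, ``end_internal = end_gtf``.

Biotypes are resolved per transcript from GTF attributes (FlyBase/Ensembl
dialects: ``gene_biotype``, ``gene_type``, ``transcript_biotype``, ...) or,
failing that, from the parent feature type of the transcript (``mRNA``,
``ncRNA``, ``pseudogene`` rows). A gene is ``protein_coding`` if any of its
transcripts is; unknown biotypes are classified ``other``, kept in the model
list but excluded from antisense pairing downstream.
"""

from __future__ import annotations

import json
import logging
import re
from dataclasses import dataclass, field
from pathlib import Path

from .models import GeneModel, GenomicInterval, TranscriptModel

logger = logging.getLogger(__name__)

__all__ = ["BiotypeRules", "load_annotation", "write_gtf", "genes_to_json", "genes_from_json"]

_ATTR_RE = re.compile(r'(\w+)\s+"([^"]*)"')

#: raw annotation labels -> canonical biotypes
DEFAULT_BIOTYPE_MAP = {
    "protein_coding": "protein_coding",
    "mRNA": "protein_coding",
    "ncRNA": "lncRNA",
    "lncRNA": "lncRNA",
    "lincRNA": "lncRNA",
    "antisense": "lncRNA",
    "pseudogene": "pseudogene",
}


@dataclass
class BiotypeRules:
    """How to map annotation attributes/features onto canonical biotypes."""

    mapping: dict[str, str] = field(default_factory=lambda: dict(DEFAULT_BIOTYPE_MAP))
    attribute_keys: tuple[str, ...] = (
        "gene_biotype",
        "gene_type",
        "transcript_biotype",
        "transcript_type",
    )
    #: feature-type column values that carry a transcript-level biotype
    feature_types: tuple[str, ...] = ("mRNA", "ncRNA", "pseudogene", "lncRNA")

    def resolve(self, raw: str | None) -> str | None:
        if raw is None:
            return None
        return self.mapping.get(raw)


def _parse_attributes(attr_field: str) -> dict[str, str]:
    return dict(_ATTR_RE.findall(attr_field))


def load_annotation(
    gtf_path: str | Path,
    biotype_rules: BiotypeRules | None = None,
) -> list[GeneModel]:
    """Read a GTF file into one :class:`GeneModel` per ``gene_id``.

    Only ``exon`` features define structure; transcript-level features
    (mRNA/ncRNA/...) contribute biotype evidence. Genes with zero exon
    features are dropped with a warning. Raises ``ValueError`` naming the
    line number on malformed lines and on exons with ``end < start``.
    """
    rules = biotype_rules or BiotypeRules()
    path = Path(gtf_path)
    # per transcript: list of exons; per gene/transcript: biotype votes
    tx_exons: dict[str, list[GenomicInterval]] = {}
    tx_gene: dict[str, str] = {}
    gene_biotype_votes: dict[str, list[str]] = {}
    gene_order: list[str] = []

    with path.open() as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            fields = line.split("\t")
            if len(fields) != 9:
                raise ValueError(
                    f"{path}:{lineno}: expected 9 tab-separated columns, "
                    f"got {len(fields)}"
                )
            chrom, _source, feature, start_s, end_s, _score, strand, _frame, attrs_s = fields
            attrs = _parse_attributes(attrs_s)
            gene_id = attrs.get("gene_id")

            if feature == "exon":
                try:
                    start_gtf, end_gtf = int(start_s), int(end_s)
                except ValueError as err:
                    raise ValueError(
                        f"{path}:{lineno}: non-integer coordinates "
                        f"{start_s!r}, {end_s!r}"
                    ) from err
                if end_gtf < start_gtf:
                    raise ValueError(
                        f"{path}:{lineno}: exon end {end_gtf} < start {start_gtf}"
                    )
                if gene_id is None or "transcript_id" not in attrs:
                    raise ValueError(
                        f"{path}:{lineno}: exon feature lacks gene_id/transcript_id"
                    )
                tid = attrs["transcript_id"]
                if strand not in ("+", "-", "."):
                    raise ValueError(f"{path}:{lineno}: invalid strand {strand!r}")
                tx_exons.setdefault(tid, []).append(
                    GenomicInterval(chrom, start_gtf - 1, end_gtf, strand)
                )
                if tid not in tx_gene:
                    tx_gene[tid] = gene_id
                if gene_id not in gene_biotype_votes:
                    gene_biotype_votes[gene_id] = []
                    gene_order.append(gene_id)

            # biotype evidence: attributes on any feature, or feature type itself
            if gene_id is not None:
                if gene_id not in gene_biotype_votes:
                    gene_biotype_votes[gene_id] = []
                    gene_order.append(gene_id)
                for key in rules.attribute_keys:
                    canon = rules.resolve(attrs.get(key))
                    if canon is not None:
                        gene_biotype_votes[gene_id].append(canon)
                        break
                else:
                    if feature in rules.feature_types:
                        canon = rules.resolve(feature)
                        if canon is not None:
                            gene_biotype_votes[gene_id].append(canon)

    # assemble genes
    gene_tx: dict[str, list[TranscriptModel]] = {}
    for tid, exons in tx_exons.items():
        gid = tx_gene[tid]
        gene_tx.setdefault(gid, []).append(
            TranscriptModel(transcript_id=tid, gene_id=gid, exons=exons)
        )

    genes: list[GeneModel] = []
    for gid in gene_order:
        txs = gene_tx.get(gid)
        if not txs:
            logger.warning("gene %s has no exon features; dropped", gid)
            continue
        votes = gene_biotype_votes.get(gid, [])
        if "protein_coding" in votes:
            biotype = "protein_coding"
        elif "lncRNA" in votes:
            biotype = "lncRNA"
        elif "pseudogene" in votes:
            biotype = "pseudogene"
        else:
            biotype = "other"
            logger.warning(
                "gene %s has no recognized biotype; classified 'other' and "
                "excluded from pairing", gid,
            )
        txs.sort(key=lambda t: t.transcript_id)
        genes.append(GeneModel(gene_id=gid, biotype=biotype, transcripts=txs))
    return genes


_REVERSE_BIOTYPE = {
    "protein_coding": "protein_coding",
    "lncRNA": "lncRNA",
    "pseudogene": "pseudogene",
    "other": "other",
}


def write_gtf(genes: list[GeneModel], gtf_path: str | Path, source: str = "natscreen") -> None:
    """Write gene models back to GTF (exon features only, 1-based closed)."""
    with Path(gtf_path).open("w") as fh:
        for gene in genes:
            for tx in gene.transcripts:
                for exon in tx.exons:
                    attrs = (
                        f'gene_id "{gene.gene_id}"; '
                        f'transcript_id "{tx.transcript_id}"; '
                        f'gene_biotype "{_REVERSE_BIOTYPE[gene.biotype]}";'
                    )
                    fh.write(
                        f"{exon.chrom}\t{source}\texon\t{exon.start + 1}\t"
                        f"{exon.end}\t.\t{exon.strand}\t.\t{attrs}\n"
                    )


def genes_to_json(genes: list[GeneModel], path: str | Path) -> None:
    """Serialize gene models to a JSON fixture (internal 0-based coords)."""
    payload = [
        {
            "gene_id": g.gene_id,
            "biotype": g.biotype,
            "transcripts": [
                {
                    "transcript_id": t.transcript_id,
                    "exons": [
                        {"chrom": e.chrom, "start": e.start, "end": e.end, "strand": e.strand}
                        for e in t.exons
                    ],
                }
                for t in g.transcripts
            ],
        }
        for g in genes
    ]
    Path(path).write_text(json.dumps(payload, indent=1))


def genes_from_json(path: str | Path) -> list[GeneModel]:
    payload = json.loads(Path(path).read_text())
    genes = []
    for g in payload:
        txs = [
            TranscriptModel(
                transcript_id=t["transcript_id"],
                gene_id=g["gene_id"],
                exons=[
                    GenomicInterval(e["chrom"], e["start"], e["end"], e["strand"])
                    for e in t["exons"]
                ],
            )
            for t in g["transcripts"]
        ]
        genes.append(GeneModel(gene_id=g["gene_id"], biotype=g["biotype"], transcripts=txs))
    return genes
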