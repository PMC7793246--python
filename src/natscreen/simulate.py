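"""Synthetic annotation, expression and coverage with known ground truth.

The default study emulates a stranded RNA-seq design over three larval
imaginal-disc tissues (wing, leg, eye) with two replicates each, centred on
a *blistered*-like locus:

* a protein-coding gene with two TSSs and three isoforms — a short two-exon
  isoform B and two long isoforms A and C that share a constitutive
  MADS-box-like exon and a long-isoform-specific 3' exon downstream of a
  long intron;
* an antisense lncRNA inside that long intron (``internal`` configuration),
  highly expressed in wing, nearly silent in eye;
* a monotone negative coupling between antisense abundance and the
  long-isoform fraction: ``f = clip(f0 + slope * nat_tpm, 0, 1)``, a
  deliberately simple stand-in for polymerase-collision kinetics, which are
  not modelled;
* a null control pair (internal antisense lncRNA, coupling slope 0) and an
  antisense-free multi-isoform control gene.

Coverage is the isoform-TPM-weighted exon indicator scaled by
``read_depth_scale``, with independent multiplicative lognormal noise per
exon per sample. All randomness flows from the single seed.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from pathlib import Path

import numpy as np
import pandas as pd

from .annotation import write_gtf
from .coverage import CoverageTrack
from .expression import ExpressionMatrix
from .models import GeneModel, GenomicInterval, TranscriptModel

__all__ = [
    "SimConfig",
    "SimResult",
    "simulate_study",
    "write_study",
    "plant_census_genome",
    "random_genes",
]


@dataclass(frozen=True)
class SimConfig:
    """Tunable knobs of the synthetic study (defaults are the study design)."""

    seed: int = 0
    tissues: tuple[str, ...] = ("wing", "leg", "eye")
    n_replicates: int = 2
    chrom: str = "chrSim"
    #: mean per-base coverage contributed by 1 TPM of an isoform
    read_depth_scale: float = 10.0
    #: lognormal CV of per-replicate TPM variation
    replicate_cv: float = 0.2
    #: lognormal CV of per-exon per-sample coverage noise
    noise_cv: float = 0.05
    #: change in long-isoform fraction per unit antisense TPM (negative: repression)
    coupling_slope: float = -0.025
    #: long-isoform fraction when the antisense gene is silent
    baseline_long_fraction: float = 0.8
    #: share of long-isoform expression carried by isoform A (rest on C)
    a_share: float = 0.5
    #: antisense TPM level per tissue (wing-high, eye-silent)
    nat_tpm: dict[str, float] = field(
        default_factory=lambda: {"wing": 30.0, "leg": 2.0, "eye": 0.05}
    )
    #: total coding-gene TPM per tissue
    pc_tpm: dict[str, float] = field(
        default_factory=lambda: {"wing": 60.0, "leg": 40.0, "eye": 40.0}
    )
    #: antisense TPM of the null-coupling control pair
    null_nat_tpm: dict[str, float] = field(
        default_factory=lambda: {"wing": 20.0, "leg": 1.0, "eye": 0.05}
    )
    null_pc_tpm: float = 30.0
    free_pc_tpm: float = 20.0
    #: write per-strand coverage tracks (stranded protocol) or one total
    stranded: bool = True

    def __post_init__(self) -> None:
        if self.read_depth_scale <= 0:
            raise ValueError("read_depth_scale must be positive")
        if self.noise_cv < 0 or self.replicate_cv < 0:
            raise ValueError("noise CVs must be non-negative")
        for t in self.tissues:
            if t not in self.nat_tpm or t not in self.pc_tpm:
                raise ValueError(f"missing TPM level for tissue {t!r}")


@dataclass
class SimResult:
    """In-memory synthetic study: models, truth tables, expression, coverage."""

    config: SimConfig
    genes: list[GeneModel]
    truth_pairs: pd.DataFrame  # lnc_id, pc_id, expected_configuration
    truth_exons: pd.DataFrame  # gene_id, exon_start, exon_end, cls, direction, planted_coupled
    expr: ExpressionMatrix
    coverage_by_sample: dict  # sample_id -> CoverageTrack or {"+"/"-": CoverageTrack}
    isoform_tpm: pd.DataFrame  # transcript_id x sample_id


# ---------------------------------------------------------------------------
# locus geometry (offsets relative to a locus origin; + strand coding gene)

_BS = {
    "tss1": (0, 200),  # shared first exon of B and C (TSS1)
    "tss2": (600, 800),  # first exon of A (TSS2)
    "mads": (1000, 1600),  # constitutive MADS-box-like exon
    "long": (8000, 8600),  # long-isoform-specific 3' exon
}
_BS_ISOFORMS = {
    "A": ["tss2", "mads", "long"],
    "B": ["tss1", "mads"],
    "C": ["tss1", "mads", "long"],
}
_BS_NAT_EXONS = [(3000, 3600), (4400, 5000)]  # inside the long intron

_CTRL_EXONS = [(0, 400), (400, 800), (800, 1200)]
_CTRL_NAT_EXONS = [(450, 550), (600, 700)]

_BS_ORIGIN = 1_000
_NULL_ORIGIN = 40_000
_FREE_ORIGIN = 80_000


def _gene(gene_id, biotype, chrom, strand, isoforms: dict[str, list[tuple[int, int]]],
          origin: int = 0) -> GeneModel:
    txs = [
        TranscriptModel(
            transcript_id=tid,
            gene_id=gene_id,
            exons=[
                GenomicInterval(chrom, origin + s, origin + e, strand)
                for s, e in exons
            ],
        )
        for tid, exons in isoforms.items()
    ]
    return GeneModel(gene_id=gene_id, biotype=biotype, transcripts=txs)


def _build_default_genes(cfg: SimConfig) -> tuple[list[GeneModel], pd.DataFrame, pd.DataFrame]:
    chrom = cfg.chrom
    bs = _gene(
        "bs_like", "protein_coding", chrom, "+",
        {f"bs_like-R{t}": [_BS[k] for k in keys] for t, keys in _BS_ISOFORMS.items()},
        origin=_BS_ORIGIN,
    )
    bs_nat = _gene(
        "asRNA_like", "lncRNA", chrom, "-",
        {"asRNA_like-R1": _BS_NAT_EXONS},
        origin=_BS_ORIGIN,
    )
    null_pc = _gene(
        "ctrl_null", "protein_coding", chrom, "+",
        {"ctrl_null-R1": _CTRL_EXONS, "ctrl_null-R2": [_CTRL_EXONS[0], _CTRL_EXONS[2]]},
        origin=_NULL_ORIGIN,
    )
    null_nat = _gene(
        "ctrl_nullAS", "lncRNA", chrom, "-",
        {"ctrl_nullAS-R1": _CTRL_NAT_EXONS},
        origin=_NULL_ORIGIN,
    )
    free_pc = _gene(
        "ctrl_free", "protein_coding", chrom, "+",
        {"ctrl_free-R1": _CTRL_EXONS, "ctrl_free-R2": [_CTRL_EXONS[0], _CTRL_EXONS[2]]},
        origin=_FREE_ORIGIN,
    )
    genes = [bs, bs_nat, null_pc, null_nat, free_pc]

    truth_pairs = pd.DataFrame(
        [
            {"lnc_id": "asRNA_like", "pc_id": "bs_like", "expected_configuration": "internal"},
            {"lnc_id": "ctrl_nullAS", "pc_id": "ctrl_null", "expected_configuration": "internal"},
        ]
    )

    exon_rows = []
    cls_of = {"tss1": "shared_tss1", "tss2": "long_specific", "mads": "constitutive",
              "long": "long_specific"}
    for key, (s, e) in _BS.items():
        cls = cls_of[key]
        exon_rows.append(
            {
                "gene_id": "bs_like",
                "exon_start": _BS_ORIGIN + s,
                "exon_end": _BS_ORIGIN + e,
                "cls": cls,
                "expected_direction": "down" if cls == "long_specific" else "up",
                "planted_coupled": cls == "long_specific",
                "is_control": False,
            }
        )
    for gid, origin in (("ctrl_null", _NULL_ORIGIN), ("ctrl_free", _FREE_ORIGIN)):
        for s, e in _CTRL_EXONS:
            exon_rows.append(
                {
                    "gene_id": gid,
                    "exon_start": origin + s,
                    "exon_end": origin + e,
                    "cls": "control",
                    "expected_direction": "none",
                    "planted_coupled": False,
                    "is_control": True,
                }
            )
    return genes, truth_pairs, pd.DataFrame(exon_rows)


# ---------------------------------------------------------------------------
# expression + coverage


def _ln_noise(rng: np.random.Generator, cv: float, size=None):
    """Multiplicative lognormal noise with unit mean and the given CV."""
    if cv == 0:
        return np.ones(size) if size is not None else 1.0
    sigma = np.sqrt(np.log1p(cv * cv))
    return rng.lognormal(mean=-0.5 * sigma * sigma, sigma=sigma, size=size)


def simulate_study(config: SimConfig | None = None) -> SimResult:
    """Generate the full synthetic study for one seed."""
    cfg = config or SimConfig()
    rng = np.random.default_rng(cfg.seed)
    genes, truth_pairs, truth_exons = _build_default_genes(cfg)
    by_id = {g.gene_id: g for g in genes}

    sample_ids = [f"{t}_{k + 1}" for t in cfg.tissues for k in range(cfg.n_replicates)]
    samples = pd.DataFrame(
        {
            "tissue": [s.rsplit("_", 1)[0] for s in sample_ids],
            "replicate": [int(s.rsplit("_", 1)[1]) for s in sample_ids],
        },
        index=pd.Index(sample_ids, name="sample_id"),
    )

    # isoform TPMs per sample -----------------------------------------------
    iso_tpm = pd.DataFrame(0.0, index=pd.Index([], dtype=object), columns=sample_ids)
    for sid in sample_ids:
        tissue = samples.at[sid, "tissue"]
        nat = cfg.nat_tpm[tissue] * _ln_noise(rng, cfg.replicate_cv)
        total = cfg.pc_tpm[tissue] * _ln_noise(rng, cfg.replicate_cv)
        f = float(np.clip(cfg.baseline_long_fraction + cfg.coupling_slope * nat, 0.0, 1.0))
        iso_tpm.loc["bs_like-RA", sid] = cfg.a_share * f * total
        iso_tpm.loc["bs_like-RC", sid] = (1 - cfg.a_share) * f * total
        iso_tpm.loc["bs_like-RB", sid] = (1 - f) * total
        iso_tpm.loc["asRNA_like-R1", sid] = nat

        null_nat = cfg.null_nat_tpm[tissue] * _ln_noise(rng, cfg.replicate_cv)
        null_total = cfg.null_pc_tpm * _ln_noise(rng, cfg.replicate_cv)
        iso_tpm.loc["ctrl_null-R1", sid] = null_total  # usage fixed: only R1 expressed
        iso_tpm.loc["ctrl_null-R2", sid] = 0.0
        iso_tpm.loc["ctrl_nullAS-R1", sid] = null_nat

        free_total = cfg.free_pc_tpm * _ln_noise(rng, cfg.replicate_cv)
        iso_tpm.loc["ctrl_free-R1", sid] = 0.6 * free_total
        iso_tpm.loc["ctrl_free-R2", sid] = 0.4 * free_total
    iso_tpm = iso_tpm.fillna(0.0)

    # gene TPM = exact sum of isoform TPMs
    tx_gene = {t.transcript_id: g.gene_id for g in genes for t in g.transcripts}
    gene_tpm = iso_tpm.groupby(iso_tpm.index.map(tx_gene)).sum()
    expr = ExpressionMatrix(values=gene_tpm, samples=samples, level="gene")

    # coverage ---------------------------------------------------------------
    coverage_by_sample: dict = {}
    for sid in sample_ids:
        per_strand: dict[str, list[tuple[int, int, float]]] = {"+": [], "-": []}
        for gene in genes:
            for exon in gene.distinct_exons:
                expected = cfg.read_depth_scale * sum(
                    iso_tpm.at[t.transcript_id, sid]
                    for t in gene.transcripts
                    if any(e.start == exon.start and e.end == exon.end for e in t.exons)
                )
                value = expected * float(_ln_noise(rng, cfg.noise_cv))
                per_strand[gene.strand].append((exon.start, exon.end, value))
        tracks = {}
        for strand, rows in per_strand.items():
            rows.sort()
            tracks[strand] = CoverageTrack(
                {
                    cfg.chrom: (
                        np.array([r[0] for r in rows], dtype=np.int64),
                        np.array([r[1] for r in rows], dtype=np.int64),
                        np.array([r[2] for r in rows], dtype=float),
                    )
                }
            )
        if cfg.stranded:
            coverage_by_sample[sid] = tracks
        else:
            starts = np.concatenate([tracks["+"]._data[cfg.chrom][0], tracks["-"]._data[cfg.chrom][0]])
            ends = np.concatenate([tracks["+"]._data[cfg.chrom][1], tracks["-"]._data[cfg.chrom][1]])
            values = np.concatenate([tracks["+"]._data[cfg.chrom][2], tracks["-"]._data[cfg.chrom][2]])
            order = np.argsort(starts, kind="stable")
            coverage_by_sample[sid] = CoverageTrack(
                {cfg.chrom: (starts[order], ends[order], values[order])}
            )

    return SimResult(
        config=cfg,
        genes=genes,
        truth_pairs=truth_pairs,
        truth_exons=truth_exons,
        expr=expr,
        coverage_by_sample=coverage_by_sample,
        isoform_tpm=iso_tpm,
    )


def write_study(result: SimResult, out_dir: str | Path) -> dict[str, Path]:
    """Write the study to disk: GTF, TPM table, samples table, bedGraph
    coverage and truth tables. Returns the paths written."""
    out = Path(out_dir)
    (out / "coverage").mkdir(parents=True, exist_ok=True)
    paths = {
        "annotation": out / "annotation.gtf",
        "expr": out / "expr.tsv",
        "samples": out / "samples.tsv",
        "truth_pairs": out / "truth_pairs.tsv",
        "truth_exons": out / "truth_exons.tsv",
    }
    write_gtf(result.genes, paths["annotation"])
    expr = result.expr
    expr.values.rename_axis("feature_id").to_csv(
        paths["expr"], sep="\t", float_format="%.6g"
    )
    samples = expr.samples.copy()
    cov_cols: dict[str, list[str]] = {}
    for sid in expr.sample_ids:
        entry = result.coverage_by_sample[sid]
        if isinstance(entry, CoverageTrack):
            fname = f"coverage/{sid}.bedGraph"
            entry.to_bedgraph(out / fname)
            cov_cols.setdefault("coverage_file", []).append(fname)
        else:
            for strand, suffix in (("+", "plus"), ("-", "minus")):
                fname = f"coverage/{sid}.{suffix}.bedGraph"
                entry[strand].to_bedgraph(out / fname)
                cov_cols.setdefault(f"coverage_file_{suffix}", []).append(fname)
    for col, vals in cov_cols.items():
        samples[col] = vals
    samples.to_csv(paths["samples"], sep="\t")
    result.truth_pairs.to_csv(paths["truth_pairs"], sep="\t", index=False)
    result.truth_exons.to_csv(paths["truth_exons"], sep="\t", index=False)
    return paths


# ---------------------------------------------------------------------------
# planted-configuration genomes (annotation only)

_PLANTERS = {
    "internal": lambda c, o, i: (
        [
            _gene(f"pc_int{i}", "protein_coding", c, "+",
                  {f"pc_int{i}-R1": [(0, 200), (1000, 1400), (3000, 3400)]}, o),
            _gene(f"lnc_int{i}", "lncRNA", c, "-",
                  {f"lnc_int{i}-R1": [(1500, 1700), (2200, 2500)]}, o),
        ],
        [(f"lnc_int{i}", f"pc_int{i}", "internal")],
    ),
    "external": lambda c, o, i: (
        [
            _gene(f"lnc_ext{i}", "lncRNA", c, "-",
                  {f"lnc_ext{i}-R1": [(0, 300), (4000, 4300)]}, o),
            _gene(f"pc_ext{i}", "protein_coding", c, "+",
                  {f"pc_ext{i}-R1": [(1000, 1300), (2000, 2300)]}, o),
        ],
        [(f"lnc_ext{i}", f"pc_ext{i}", "external")],
    ),
    "head_to_head": lambda c, o, i: (
        [
            _gene(f"pc_h2h{i}", "protein_coding", c, "+",
                  {f"pc_h2h{i}-R1": [(1000, 1500), (2500, 3000)]}, o),
            _gene(f"lnc_h2h{i}", "lncRNA", c, "-",
                  {f"lnc_h2h{i}-R1": [(0, 300), (900, 1400)]}, o),
        ],
        [(f"lnc_h2h{i}", f"pc_h2h{i}", "head_to_head")],
    ),
    "tail_to_tail": lambda c, o, i: (
        [
            _gene(f"pc_t2t{i}", "protein_coding", c, "+",
                  {f"pc_t2t{i}-R1": [(0, 500), (1500, 2000)]}, o),
            _gene(f"lnc_t2t{i}", "lncRNA", c, "-",
                  {f"lnc_t2t{i}-R1": [(1600, 2100), (3000, 3600)]}, o),
        ],
        [(f"lnc_t2t{i}", f"pc_t2t{i}", "tail_to_tail")],
    ),
    "complex": lambda c, o, i: (
        [
            _gene(f"lnc_cpx{i}", "lncRNA", c, "-",
                  {f"lnc_cpx{i}-R1": [(500, 800), (2600, 3000)]}, o),
            _gene(f"pc_cpxA{i}", "protein_coding", c, "+",
                  {f"pc_cpxA{i}-R1": [(0, 700), (1000, 1200)]}, o),
            _gene(f"pc_cpxB{i}", "protein_coding", c, "+",
                  {f"pc_cpxB{i}-R1": [(2500, 2800), (3500, 3800)]}, o),
        ],
        [
            (f"lnc_cpx{i}", f"pc_cpxA{i}", "complex"),
            (f"lnc_cpx{i}", f"pc_cpxB{i}", "complex"),
        ],
    ),
}


def plant_census_genome(
    counts: dict[str, int], chrom: str = "chrP", spacing: int = 10_000
) -> tuple[list[GeneModel], pd.DataFrame]:
    """Build a genome with a chosen number of loci per configuration.

    ``counts`` maps configuration label to the number of loci to plant;
    one ``complex`` locus contributes two complex pairs. Returns the genes
    and a truth table of expected pairs.
    """
    genes: list[GeneModel] = []
    truth_rows = []
    origin = 0
    for label in ("internal", "head_to_head", "tail_to_tail", "external", "complex"):
        for i in range(counts.get(label, 0)):
            locus_genes, expected = _PLANTERS[label](chrom, origin, f"{i:03d}")
            genes.extend(locus_genes)
            truth_rows.extend(
                {"lnc_id": l, "pc_id": p, "expected_configuration": e}
                for l, p, e in expected
            )
            origin += spacing
    return genes, pd.DataFrame(
        truth_rows, columns=["lnc_id", "pc_id", "expected_configuration"]
    )


# ---------------------------------------------------------------------------
# random genomes for oracle verification


def random_genes(
    rng: np.random.Generator,
    n_genes: int = 30,
    chrom: str = "chrR",
    genome_length: int = 20_000,
) -> list[GeneModel]:
    """A random genome of small genes for brute-force cross-checks.

    Genes overlap freely across strands; roughly half are coding and half
    lncRNAs, with an occasional pseudogene (which must never pair).
    """
    genes = []
    for i in range(n_genes):
        biotype = str(
            rng.choice(["protein_coding", "lncRNA", "pseudogene"], p=[0.45, 0.45, 0.1])
        )
        strand = str(rng.choice(["+", "-"]))
        span_len = int(rng.integers(200, 3000))
        origin = int(rng.integers(0, max(1, genome_length - span_len)))
        txs = []
        for t in range(int(rng.integers(1, 4))):
            n_exons = int(rng.integers(1, 5))
            cuts = np.sort(
                rng.choice(np.arange(span_len + 1), size=2 * n_exons, replace=False)
            )
            exons = [
                GenomicInterval(chrom, origin + int(cuts[2 * k]), origin + int(cuts[2 * k + 1]), strand)
                for k in range(n_exons)
                if cuts[2 * k + 1] > cuts[2 * k]
            ]
            if not exons:
                exons = [GenomicInterval(chrom, origin, origin + span_len, strand)]
            txs.append(
                TranscriptModel(transcript_id=f"g{i}-t{t}", gene_id=f"g{i}", exons=exons)
            )
        genes.append(GeneModel(gene_id=f"g{i}", biotype=str(biotype), transcripts=txs))
    return genes
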