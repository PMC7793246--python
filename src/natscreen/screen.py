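"""The candidate screen: expression filter, exon inclusion ratios, and the
correlation/dispersion selection statistic.

For every surviving antisense pair and every distinct exon of its coding
gene, the screen computes the exon inclusion ratio per sample (mean exon
coverage / mean gene coverage), the standard deviation of that ratio across
samples, and the Pearson correlation between the ratio and the antisense
gene's TPM. An exon is selected when sd > 0.1 and |r| > 0.7 (both strict).
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .coverage import CoverageTrack
from .expression import ExpressionMatrix
from .models import GeneModel, GenomicInterval
from .pairing import SAPair

__all__ = [
    "expression_filter",
    "multi_isoform_filter",
    "exon_ratio",
    "correlate_exon_antisense",
    "run_screen",
    "CandidateRecord",
]

CANDIDATE_COLUMNS = [
    "lnc_id",
    "pc_id",
    "configuration",
    "exon_chrom",
    "exon_start",
    "exon_end",
    "n_valid",
    "sd",
    "r",
    "selected",
]


@dataclass(frozen=True)
class CandidateRecord:
    """One (pair, exon) with its correlation/dispersion statistics."""

    pair: SAPair
    exon: GenomicInterval
    n_valid: int
    sd: float  # NaN when < 2 valid ratios
    r: float  # NaN when undefined
    selected: bool


def expression_filter(
    pairs: list[SAPair], expr: ExpressionMatrix, threshold: float = 0.5
) -> list[SAPair]:
    """Keep pairs whose two genes are each expressed at >= threshold TPM in
    all replicates of at least one tissue (not necessarily the same tissue
    for the two genes)."""
    return [
        p
        for p in pairs
        if expr.passes_expression(p.lnc_id, threshold)
        and expr.passes_expression(p.pc_id, threshold)
    ]


def multi_isoform_filter(pairs: list[SAPair], genes: list[GeneModel]) -> list[SAPair]:
    """Keep pairs whose protein-coding gene has >= 2 annotated transcripts."""
    by_id = {g.gene_id: g for g in genes}
    return [p for p in pairs if by_id[p.pc_id].multi_isoform()]


def exon_ratio(
    coverage: CoverageTrack,
    gene: GeneModel,
    exon: GenomicInterval,
    gene_region_mode: str = "span",
) -> float:
    """Exon inclusion ratio for one sample: mean exon coverage over mean
    gene coverage. NaN (undefined) when the gene denominator is 0.

    ``gene_region_mode='span'`` uses the whole genomic span as denominator
    (introns included); ``'exon_union'`` uses exonic bases only.
    """
    if not gene.span.contains(exon):
        raise ValueError(
            f"exon {exon.chrom}:{exon.start}-{exon.end} outside span of {gene.gene_id}"
        )
    if gene_region_mode == "span":
        denom = coverage.mean(gene.span)
    elif gene_region_mode == "exon_union":
        denom = coverage.mean_over(gene.exon_union)
    else:
        raise ValueError(f"unknown gene_region_mode {gene_region_mode!r}")
    if denom == 0:
        return math.nan
    return coverage.mean(exon) / denom


def correlate_exon_antisense(
    ratios: pd.Series, nat_tpm: pd.Series, min_valid: int = 3
) -> float:
    """Pearson r between exon ratios and antisense TPM over shared samples.

    Samples with undefined (NaN) ratio are dropped pairwise. Returns NaN
    when fewer than ``min_valid`` samples remain or either vector is
    constant. Raises on mismatched sample sets.
    """
    if set(ratios.index) != set(nat_tpm.index):
        raise ValueError("exon-ratio and antisense-TPM vectors index different samples")
    nat_tpm = nat_tpm.reindex(ratios.index)
    mask = ratios.notna() & nat_tpm.notna()
    x = ratios[mask].to_numpy(dtype=float)
    y = nat_tpm[mask].to_numpy(dtype=float)
    if len(x) < min_valid:
        return math.nan
    if np.ptp(x) == 0 or np.ptp(y) == 0:
        return math.nan
    with warnings.catch_warnings():
        # exact-constant inputs are handled above; near-constant ones are
        # legitimate (e.g. a clamped isoform fraction) and not an error
        warnings.simplefilter("ignore", stats.NearConstantInputWarning)
        return float(stats.pearsonr(x, y).statistic)


def _strand_track(entry, strand: str) -> CoverageTrack:
    """Resolve a per-sample coverage entry: either one unstranded track or a
    dict keyed by strand; the sense gene then reads its own strand."""
    if isinstance(entry, CoverageTrack):
        return entry
    return entry[strand]


def run_screen(
    genes: list[GeneModel],
    pairs: list[SAPair],
    expr: ExpressionMatrix,
    coverage_by_sample: dict,
    sd_min: float = 0.1,
    abs_r_min: float = 0.7,
    gene_region_mode: str = "span",
    min_valid: int = 3,
    collapse_replicates: bool = False,
    log1p_nat: bool = False,
) -> pd.DataFrame:
    """Rank every (pair, distinct coding-gene exon) by |r| and sd.

    ``pairs`` should already be expression- and multi-isoform-filtered.
    Returns a DataFrame with one row per (pair, exon), sorted by |r|
    descending then sd descending (NaNs last), deterministic tie-break by
    (pc gene, exon start). ``selected`` is True iff sd > sd_min and
    |r| > abs_r_min, both strict.
    """
    by_id = {g.gene_id: g for g in genes}
    missing = [s for s in expr.sample_ids if s not in coverage_by_sample]
    if missing:
        raise ValueError(f"no coverage track for sample(s): {missing}")

    # per-gene per-exon per-sample ratios, computed once and shared by pairs
    ratio_cache: dict[str, pd.DataFrame] = {}

    def gene_ratios(gene: GeneModel) -> pd.DataFrame:
        if gene.gene_id not in ratio_cache:
            rows = {}
            for exon in gene.distinct_exons:
                rows[(exon.start, exon.end)] = {
                    sid: exon_ratio(
                        _strand_track(coverage_by_sample[sid], gene.strand),
                        gene,
                        exon,
                        gene_region_mode,
                    )
                    for sid in expr.sample_ids
                }
            ratio_cache[gene.gene_id] = pd.DataFrame.from_dict(rows, orient="index")
        return ratio_cache[gene.gene_id]

    records = []
    for pair in pairs:
        pc = by_id[pair.pc_id]
        nat = expr.feature_tpm(pair.lnc_id)
        if log1p_nat:
            nat = np.log1p(nat)
        ratios_df = gene_ratios(pc)
        for exon in pc.distinct_exons:
            ratios = ratios_df.loc[(exon.start, exon.end)]
            nat_vec = nat
            if collapse_replicates:
                tissue = expr.samples.loc[ratios.index, "tissue"]
                ratios = ratios.groupby(tissue).mean()
                nat_vec = nat.groupby(tissue).mean()
            valid = ratios.dropna()
            n_valid = int(len(valid))
            sd = float(valid.std(ddof=1)) if n_valid >= 2 else math.nan
            r = correlate_exon_antisense(ratios, nat_vec, min_valid=min_valid)
            selected = (
                not math.isnan(sd)
                and not math.isnan(r)
                and sd > sd_min
                and abs(r) > abs_r_min
            )
            records.append(
                {
                    "lnc_id": pair.lnc_id,
                    "pc_id": pair.pc_id,
                    "configuration": pair.configuration,
                    "exon_chrom": exon.chrom,
                    "exon_start": exon.start,
                    "exon_end": exon.end,
                    "n_valid": n_valid,
                    "sd": sd,
                    "r": r,
                    "selected": selected,
                }
            )
    df = pd.DataFrame.from_records(records, columns=CANDIDATE_COLUMNS)
    if len(df):
        df["_abs_r"] = df["r"].abs()
        df = df.sort_values(
            by=["_abs_r", "sd", "pc_id", "exon_start"],
            ascending=[False, False, True, True],
            na_position="last",
            kind="mergesort",
        ).drop(columns="_abs_r")
        df = df.reset_index(drop=True)
    return df
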