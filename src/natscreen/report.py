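"""End-to-end pipeline: classify -> filter -> screen, with a summary report.

``run_all`` ties the stages together, writes the pair table, the candidate
table, the configuration census and a human-readable report, and records
the resolved configuration (with input hashes) next to the outputs so every
run is reproducible.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
from dataclasses import dataclass
from pathlib import Path

import pandas as pd

from . import __version__
from .annotation import load_annotation
from .coverage import load_coverage
from .expression import ExpressionMatrix
from .pairing import configuration_census, find_sa_pairs, resolve_complex
from .screen import expression_filter, multi_isoform_filter, run_screen

logger = logging.getLogger(__name__)

__all__ = ["RunConfig", "run_all", "load_sample_coverage"]

PAIR_COLUMNS = ["lnc_id", "pc_id", "chrom", "configuration", "overlap_bp", "component_id"]


@dataclass
class RunConfig:
    """All pipeline tunables, frozen at their documented defaults."""

    overlap_mode: str = "exon_vs_span"
    exon_terminal_scope: str = "union"
    gene_region_mode: str = "span"
    tpm_threshold: float = 0.5
    sd_min: float = 0.1
    abs_r_min: float = 0.7
    min_valid: int = 3
    collapse_replicates: bool = False
    log1p_nat: bool = False

    @classmethod
    def from_json(cls, path: str | Path) -> "RunConfig":
        payload = json.loads(Path(path).read_text())
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(payload) - known
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        return cls(**payload)


def _sha256(path: Path) -> str:
    h = hashlib.sha256()
    with path.open("rb") as fh:
        for chunk in iter(lambda: fh.read(1 << 16), b""):
            h.update(chunk)
    return h.hexdigest()


def load_sample_coverage(samples: pd.DataFrame, base_dir: str | Path) -> dict:
    """Build the per-sample coverage mapping from a samples table.

    The table may carry a single ``coverage_file`` column (unstranded
    totals) or ``coverage_file_plus``/``coverage_file_minus`` columns
    (stranded protocol; the sense gene reads its own strand). Paths are
    resolved relative to ``base_dir``.
    """
    base = Path(base_dir)
    out: dict = {}
    stranded = {"coverage_file_plus", "coverage_file_minus"} <= set(samples.columns)
    for sid, row in samples.iterrows():
        if stranded:
            out[sid] = {
                "+": load_coverage(base / row["coverage_file_plus"]),
                "-": load_coverage(base / row["coverage_file_minus"]),
            }
        elif "coverage_file" in samples.columns:
            out[sid] = load_coverage(base / row["coverage_file"])
        else:
            raise ValueError(
                "samples table needs coverage_file or coverage_file_plus/minus columns"
            )
    return out


def pairs_to_frame(pairs) -> pd.DataFrame:
    return pd.DataFrame(
        [
            {
                "lnc_id": p.lnc_id,
                "pc_id": p.pc_id,
                "chrom": p.chrom,
                "configuration": p.configuration,
                "overlap_bp": p.overlap_bp,
                "component_id": p.component_id,
            }
            for p in pairs
        ],
        columns=PAIR_COLUMNS,
    )


def run_all(
    gtf: str | Path,
    out_dir: str | Path,
    expr: str | Path | None = None,
    samples: str | Path | None = None,
    coverage_dir: str | Path | None = None,
    config: RunConfig | None = None,
    top_n: int = 20,
) -> dict:
    """Run classify (and, when expression inputs are given, the screen).

    Writes ``pairs.tsv``, ``census.json``, ``resolved_config.json`` and a
    ``report.txt`` into ``out_dir``; with expression inputs additionally
    ``candidates.tsv``. Returns a summary dict including the filter funnel.
    """
    cfg = config or RunConfig()
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)

    genes = load_annotation(gtf)
    if not genes:
        logger.warning("annotation %s contains no genes; writing empty outputs", gtf)
    pairs = resolve_complex(
        find_sa_pairs(genes, cfg.overlap_mode, cfg.exon_terminal_scope), genes
    )
    census = configuration_census(pairs)
    pairs_to_frame(pairs).to_csv(out / "pairs.tsv", sep="\t", index=False)
    (out / "census.json").write_text(json.dumps(census, indent=1))

    funnel = {"pairs_found": len(pairs)}
    candidates = None
    if expr is not None:
        if samples is None:
            raise ValueError("screening requires a samples table")
        matrix = ExpressionMatrix.from_tsv(expr, samples)
        cov_base = coverage_dir if coverage_dir is not None else Path(samples).parent
        coverage = load_sample_coverage(matrix.samples, cov_base)
        expressed = expression_filter(pairs, matrix, cfg.tpm_threshold)
        funnel["pairs_expressed"] = len(expressed)
        multi = multi_isoform_filter(expressed, genes)
        funnel["pairs_multi_isoform"] = len(multi)
        candidates = run_screen(
            genes,
            multi,
            matrix,
            coverage,
            sd_min=cfg.sd_min,
            abs_r_min=cfg.abs_r_min,
            gene_region_mode=cfg.gene_region_mode,
            min_valid=cfg.min_valid,
            collapse_replicates=cfg.collapse_replicates,
            log1p_nat=cfg.log1p_nat,
        )
        funnel["exons_screened"] = len(candidates)
        funnel["exons_selected"] = int(candidates["selected"].sum())
        candidates.to_csv(out / "candidates.tsv", sep="\t", index=False, float_format="%.6g")

    inputs = {"gtf": gtf, "expr": expr, "samples": samples}
    resolved = {
        "version": __version__,
        "config": dataclasses.asdict(cfg),
        "inputs": {
            name: {"path": str(p), "sha256": _sha256(Path(p))}
            for name, p in inputs.items()
            if p is not None
        },
    }
    (out / "resolved_config.json").write_text(json.dumps(resolved, indent=1))

    report_lines = ["# natscreen run summary", "", "## Filter funnel"]
    report_lines += [f"{k}: {v}" for k, v in funnel.items()]
    report_lines += ["", "## Configuration census"]
    for label, entry in census["configurations"].items():
        report_lines.append(f"{label}: {entry['count']} ({entry['percent']}%)")
    if candidates is not None and len(candidates):
        report_lines += ["", f"## Top candidates (first {top_n})"]
        head = candidates.head(top_n)
        report_lines.append(head.to_string(index=False))
    (out / "report.txt").write_text("\n".join(report_lines) + "\n")

    return {"census": census, "funnel": funnel, "candidates": candidates}
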