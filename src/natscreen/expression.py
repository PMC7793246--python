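"""Gene/transcript abundance matrices (TPM) with sample metadata."""

from __future__ import annotations

import logging
from dataclasses import dataclass
from pathlib import Path

import pandas as pd

logger = logging.getLogger(__name__)

__all__ = ["ExpressionMatrix"]


@dataclass
class ExpressionMatrix:
    """TPM values per (feature, sample) plus sample -> tissue/replicate metadata.

    ``values``: DataFrame indexed by feature_id with one column per
    sample_id. ``samples``: DataFrame indexed by sample_id with at least
    ``tissue`` and ``replicate`` columns. ``level`` records whether the
    features are genes or transcripts.
    """

    values: pd.DataFrame
    samples: pd.DataFrame
    level: str = "gene"

    def __post_init__(self) -> None:
        if (self.values.values < 0).any():
            raise ValueError("TPM values must be non-negative")
        for col in ("tissue", "replicate"):
            if col not in self.samples.columns:
                raise ValueError(f"samples table lacks required column {col!r}")
        missing = set(self.values.columns) - set(self.samples.index)
        if missing:
            raise ValueError(f"samples without metadata: {sorted(missing)}")
        if self.samples["tissue"].isna().any():
            raise ValueError("every sample needs a tissue label")
        # every tissue must have at least one sample among the value columns
        used = self.samples.loc[list(self.values.columns)]
        if used.empty and len(self.values.columns):
            raise ValueError("no usable samples")

    @classmethod
    def from_tsv(
        cls, expr_path: str | Path, samples_path: str | Path, level: str = "gene"
    ) -> "ExpressionMatrix":
        values = pd.read_csv(expr_path, sep="\t", index_col=0)
        samples = pd.read_csv(samples_path, sep="\t", index_col=0)
        return cls(values=values, samples=samples, level=level)

    @property
    def sample_ids(self) -> list[str]:
        return list(self.values.columns)

    def tissues(self) -> dict[str, list[str]]:
        """tissue -> sample_ids, in column order."""
        out: dict[str, list[str]] = {}
        for sid in self.sample_ids:
            out.setdefault(str(self.samples.at[sid, "tissue"]), []).append(sid)
        return out

    def feature_tpm(self, feature_id: str) -> pd.Series:
        """TPM across samples; a missing feature counts as unexpressed (0)."""
        if feature_id not in self.values.index:
            logger.warning("feature %s absent from expression matrix; treated as 0 TPM", feature_id)
            return pd.Series(0.0, index=self.values.columns)
        return self.values.loc[feature_id].astype(float)

    def passes_expression(self, feature_id: str, threshold: float) -> bool:
        """True iff some tissue has ALL of its replicates at TPM >= threshold."""
        tpm = self.feature_tpm(feature_id)
        for _tissue, sids in self.tissues().items():
            if not sids:
                raise ValueError("tissue with zero samples")
            if all(tpm[s] >= threshold for s in sids):
                return True
        return False
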