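"""Per-base coverage tracks from bedGraph or bigWig files.

Tracks are held as sorted, non-overlapping interval arrays per chromosome;
any base not covered by an interval reads as 0. Means over regions are
computed by overlap-weighted sums, so queries do not materialize per-base
arrays.
"""

from __future__ import annotations

from pathlib import Path

import numpy as np

from .models import GenomicInterval

__all__ = ["CoverageTrack", "load_coverage"]


class CoverageTrack:
    """Coverage values over genomic intervals (0-based, half-open)."""

    def __init__(self, data: dict[str, tuple[np.ndarray, np.ndarray, np.ndarray]]):
        # chrom -> (starts, ends, values), sorted by start, non-overlapping
        self._data = data

    @classmethod
    def from_bedgraph(cls, path: str | Path) -> "CoverageTrack":
        raw: dict[str, list[tuple[int, int, float]]] = {}
        with Path(path).open() as fh:
            for lineno, line in enumerate(fh, start=1):
                line = line.strip()
                if not line or line.startswith(("#", "track", "browser")):
                    continue
                fields = line.split("\t")
                if len(fields) < 4:
                    raise ValueError(
                        f"{path}:{lineno}: bedGraph line has fewer than 4 columns"
                    )
                chrom, start, end, value = fields[0], int(fields[1]), int(fields[2]), float(fields[3])
                if end <= start:
                    raise ValueError(f"{path}:{lineno}: empty interval")
                raw.setdefault(chrom, []).append((start, end, value))
        data = {}
        for chrom, rows in raw.items():
            rows.sort()
            starts = np.array([r[0] for r in rows], dtype=np.int64)
            ends = np.array([r[1] for r in rows], dtype=np.int64)
            if (starts[1:] < ends[:-1]).any():
                raise ValueError(f"{path}: overlapping bedGraph intervals on {chrom}")
            values = np.array([r[2] for r in rows], dtype=float)
            data[chrom] = (starts, ends, values)
        return cls(data)

    @classmethod
    def from_bigwig(cls, path: str | Path) -> "CoverageTrack":
        import pyBigWig  # optional dependency

        bw = pyBigWig.open(str(path))
        data = {}
        try:
            for chrom, length in bw.chroms().items():
                ivs = bw.intervals(chrom, 0, length) or []
                starts = np.array([iv[0] for iv in ivs], dtype=np.int64)
                ends = np.array([iv[1] for iv in ivs], dtype=np.int64)
                values = np.array([iv[2] for iv in ivs], dtype=float)
                data[chrom] = (starts, ends, values)
        finally:
            bw.close()
        return cls(data)

    def sum(self, region: GenomicInterval) -> float:
        """Total coverage (sum over bases) within the region."""
        entry = self._data.get(region.chrom)
        if entry is None:
            return 0.0
        starts, ends, values = entry
        ov = np.minimum(ends, region.end) - np.maximum(starts, region.start)
        ov = np.clip(ov, 0, None)
        return float(np.dot(ov, values))

    def mean(self, region: GenomicInterval) -> float:
        """Mean per-base coverage over the region (absent bases read 0)."""
        return self.sum(region) / region.length()

    def mean_over(self, regions: list[GenomicInterval]) -> float:
        """Mean per-base coverage over a set of disjoint regions."""
        total_bases = sum(r.length() for r in regions)
        if total_bases == 0:
            raise ValueError("empty region set")
        return sum(self.sum(r) for r in regions) / total_bases

    def scaled(self, factor: float) -> "CoverageTrack":
        """A new track with every value multiplied by ``factor``."""
        if factor <= 0:
            raise ValueError("scale factor must be positive")
        return CoverageTrack(
            {c: (s, e, v * factor) for c, (s, e, v) in self._data.items()}
        )

    def to_bedgraph(self, path: str | Path) -> None:
        with Path(path).open("w") as fh:
            for chrom in sorted(self._data):
                starts, ends, values = self._data[chrom]
                for s, e, v in zip(starts, ends, values):
                    fh.write(f"{chrom}\t{s}\t{e}\t{v:.6g}\n")


def load_coverage(path: str | Path) -> CoverageTrack:
    """Load a coverage track, dispatching on file extension."""
    p = Path(path)
    if p.suffix.lower() in (".bw", ".bigwig"):
        return CoverageTrack.from_bigwig(p)
    return CoverageTrack.from_bedgraph(p)
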