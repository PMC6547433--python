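"""Genomic position masks (crossmap + CDS edge) excluded from counting and RPKM.

A :class:`MaskSet` is a set of 0-based half-open genomic intervals per
chromosome, kept merged and sorted so membership tests are a single
``searchsorted`` and union is idempotent.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from .annotation import Annotation

__all__ = ["MaskSet", "build_cds_edge_mask"]


def _merge(intervals: np.ndarray) -> np.ndarray:
    """Sort and merge an (n, 2) interval array; drops empty intervals."""
    iv = np.asarray(intervals, dtype=np.int64).reshape(-1, 2)
    iv = iv[iv[:, 1] > iv[:, 0]]
    if len(iv) == 0:
        return iv.reshape(0, 2)
    iv = iv[np.lexsort((iv[:, 1], iv[:, 0]))]
    merged = [list(iv[0])]
    for s, e in iv[1:]:
        if s <= merged[-1][1]:
            merged[-1][1] = max(merged[-1][1], e)
        else:
            merged.append([s, e])
    return np.asarray(merged, dtype=np.int64)


class MaskSet:
    """Non-overlapping masked intervals, keyed by chromosome."""

    def __init__(self, intervals: dict | None = None):
        # intervals: chrom -> iterable of (start, end)
        self._iv = {}
        for chrom, iv in (intervals or {}).items():
            merged = _merge(np.asarray(list(iv), dtype=np.int64).reshape(-1, 2))
            if len(merged):
                self._iv[chrom] = merged

    @property
    def chroms(self):
        return sorted(self._iv)

    def intervals(self, chrom: str) -> np.ndarray:
        return self._iv.get(chrom, np.empty((0, 2), dtype=np.int64))

    def __len__(self):
        return sum(len(v) for v in self._iv.values())

    def __bool__(self):
        return bool(self._iv)

    def total_masked(self) -> int:
        return int(sum((v[:, 1] - v[:, 0]).sum() for v in self._iv.values()))

    def contains(self, chrom: str, positions) -> np.ndarray:
        """Vectorized membership: True where a position lies in a masked interval."""
        pos = np.asarray(positions, dtype=np.int64)
        iv = self._iv.get(chrom)
        if iv is None:
            return np.zeros(pos.shape, dtype=bool)
        idx = np.searchsorted(iv[:, 0], pos, side="right") - 1
        ok = idx >= 0
        out = np.zeros(pos.shape, dtype=bool)
        out[ok] = pos[ok] < iv[idx[ok], 1]
        return out

    def union(self, other: "MaskSet") -> "MaskSet":
        iv = {}
        for chrom in set(self._iv) | set(other._iv):
            iv[chrom] = np.vstack([self.intervals(chrom), other.intervals(chrom)])
        return MaskSet(iv)

    def overlap_length(self, chrom: str, start: int, end: int) -> int:
        """Number of masked positions inside [start, end)."""
        iv = self._iv.get(chrom)
        if iv is None:
            return 0
        lo = np.minimum(np.maximum(iv[:, 0], start), end)
        hi = np.minimum(np.maximum(iv[:, 1], start), end)
        return int((hi - lo).sum())

    # ------------------------------------------------------------------- BED
    def write_bed(self, path, name: str = "mask"):
        rows = [
            (chrom, s, e, name)
            for chrom in self.chroms
            for s, e in self.intervals(chrom)
        ]
        pd.DataFrame(rows, columns=["chrom", "start", "end", "name"]).to_csv(
            path, sep="\t", header=False, index=False
        )

    @classmethod
    def read_bed(cls, path) -> "MaskSet":
        df = pd.read_csv(
            path, sep="\t", header=None, usecols=[0, 1, 2], names=["chrom", "start", "end"]
        )
        iv = {
            chrom: sub[["start", "end"]].to_numpy()
            for chrom, sub in df.groupby("chrom")
        }
        return cls(iv)


def build_cds_edge_mask(
    annotation: Annotation, head_codons: int = 30, tail_codons: int = 5
) -> MaskSet:
    """Mask the first ``head_codons`` and last ``tail_codons`` of every CDS.

    Strand-aware: for a minus-strand gene the head interval sits at the genomic
    3' end of the CDS. Effective length after masking is
    ``cds_length - 3 * (head_codons + tail_codons)``; a CDS too short to retain
    any unmasked codon is an error naming the gene.
    """
    if head_codons < 0 or tail_codons < 0:
        raise ValueError("codon counts must be non-negative")
    head_nt, tail_nt = 3 * head_codons, 3 * tail_codons
    iv: dict = {}
    for g in annotation:
        if g.cds_length <= head_nt + tail_nt:
            raise ValueError(
                f"gene {g.gene_id}: CDS of {g.cds_length // 3} codons has no unmasked "
                f"codons after masking {head_codons}+{tail_codons}"
            )
        if g.strand == "+":
            head = (g.start, g.start + head_nt)
            tail = (g.end - tail_nt, g.end)
        else:
            head = (g.end - head_nt, g.end)
            tail = (g.start, g.start + tail_nt)
        iv.setdefault(g.chrom, []).extend([head, tail])
    return MaskSet(iv)
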