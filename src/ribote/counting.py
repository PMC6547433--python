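"""Masked CDS counting, RPKM, and expression filters.

Every read is reduced to a single genomic position before any mask or CDS
test: the P-site for footprints (5' end + length-dependent offset), the
5'-most aligned base for mRNA reads after strandedness correction. The read
is counted for a gene iff that position falls in the gene's CDS on the
matching strand and is not masked; otherwise it is discarded. The RPKM
denominator is the total of reads assigned to any unmasked CDS in the same
library, which keeps footprint and mRNA RPKM internally consistent.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from .annotation import Annotation
from .masks import MaskSet
from .psite import PsiteOffsets

__all__ = [
    "reduce_to_positions",
    "count_reads",
    "effective_lengths",
    "rpkm",
    "rpkm_vector",
    "build_count_table",
    "filter_genes",
]


def reduce_to_positions(
    alignments: pd.DataFrame,
    mode: str,
    offsets: PsiteOffsets | None = None,
    strandedness: str = "forward",
):
    """Collapse each read to its counting position and effective strand.

    Returns (chrom, position, strand) arrays aligned with the input rows.
    """
    if mode not in ("footprint", "mrna"):
        raise ValueError(f"unknown mode {mode!r}")
    if strandedness not in ("forward", "reverse"):
        raise ValueError(f"unknown strandedness {strandedness!r}")
    chrom = alignments["chrom"].to_numpy()
    start = alignments["start"].to_numpy()
    end = alignments["end"].to_numpy()
    length = alignments["length"].to_numpy()
    strand = alignments["strand"].to_numpy()

    if mode == "footprint":
        if offsets is None:
            raise ValueError("footprint counting requires P-site offsets")
        known = np.array(sorted(offsets.offsets))
        off_by_len = np.array([offsets.offsets[int(k)] for k in known], dtype=np.int64)
        idx = np.searchsorted(known, length)
        if (idx >= len(known)).any() or (known[np.minimum(idx, len(known) - 1)] != length).any():
            bad = sorted(set(length) - set(known.tolist()))
            raise KeyError(f"no P-site offset for footprint length(s) {bad}")
        off = off_by_len[idx]
        pos = np.where(strand == "+", start + off, (end - 1) - off)
        eff_strand = strand
    else:
        if strandedness == "reverse":
            eff_strand = np.where(strand == "+", "-", "+")
        else:
            eff_strand = strand
        pos = np.where(eff_strand == "+", start, end - 1)
    return chrom, pos, eff_strand


def count_reads(
    alignments: pd.DataFrame,
    annotation: Annotation,
    mask: MaskSet,
    mode: str,
    offsets: PsiteOffsets | None = None,
    strandedness: str = "forward",
) -> pd.Series:
    """Per-gene read counts after single-position reduction and masking."""
    chrom, pos, eff_strand = reduce_to_positions(alignments, mode, offsets, strandedness)
    gene_ids = annotation.gene_ids
    gene_index = {gid: i for i, gid in enumerate(gene_ids)}
    counts = np.zeros(len(gene_ids), dtype=np.int64)

    lookup = {}
    for g in annotation.genes:
        lookup.setdefault((g.chrom, g.strand), []).append((g.start, g.end, g.gene_id))
    for key in lookup:
        lookup[key].sort()

    for (c, s), entries in lookup.items():
        sel = (chrom == c) & (eff_strand == s)
        if not sel.any():
            continue
        p = pos[sel]
        starts = np.array([e[0] for e in entries], dtype=np.int64)
        ends = np.array([e[1] for e in entries], dtype=np.int64)
        idx = np.searchsorted(starts, p, side="right") - 1
        inside = (idx >= 0) & (p < ends[np.maximum(idx, 0)])
        if mask:
            inside &= ~mask.contains(c, p)
        if not inside.any():
            continue
        hit_counts = np.bincount(idx[inside], minlength=len(entries))
        for j, (_, _, gid) in enumerate(entries):
            counts[gene_index[gid]] += hit_counts[j]
    return pd.Series(counts, index=pd.Index(gene_ids, name="gene_id"), name=f"{mode}_count")


def effective_lengths(annotation: Annotation, mask: MaskSet) -> pd.Series:
    """CDS length minus masked positions inside the CDS, per gene (nt)."""
    eff = {
        g.gene_id: g.cds_length - mask.overlap_length(g.chrom, g.start, g.end)
        for g in annotation
    }
    return pd.Series(eff, name="eff_len").rename_axis("gene_id")


def rpkm(count: float, effective_length: float, total_assigned_reads: float) -> float:
    """Reads per kilobase of effective region per million assigned reads."""
    if total_assigned_reads <= 0:
        raise ValueError("total assigned reads must be positive")
    if effective_length <= 0:
        if count == 0:
            return 0.0
        raise ValueError("positive count with non-positive effective length")
    return count / (effective_length / 1_000) / (total_assigned_reads / 1_000_000)


def rpkm_vector(counts, eff_len, total=None) -> pd.Series:
    counts = pd.Series(counts).astype(float)
    eff = pd.Series(eff_len).reindex(counts.index).astype(float)
    if total is None:
        total = counts.sum()
    if total <= 0:
        raise ValueError("total assigned reads must be positive")
    if ((eff <= 0) & (counts > 0)).any():
        raise ValueError("positive count with non-positive effective length")
    out = np.zeros(len(counts))
    ok = eff > 0
    out[ok] = counts[ok] / (eff[ok] / 1_000) / (total / 1_000_000)
    return pd.Series(out, index=counts.index)


def build_count_table(
    fp_counts: pd.Series, mrna_counts: pd.Series, eff_len: pd.Series
) -> pd.DataFrame:
    """Assemble the per-gene count table with RPKM for both libraries.

    Columns: fp_count, mrna_count, eff_len, fp_rpkm, mrna_rpkm.
    """
    df = pd.DataFrame(
        {
            "fp_count": fp_counts,
            "mrna_count": mrna_counts.reindex(fp_counts.index),
            "eff_len": eff_len.reindex(fp_counts.index),
        }
    )
    df["fp_rpkm"] = rpkm_vector(df["fp_count"], df["eff_len"])
    df["mrna_rpkm"] = rpkm_vector(df["mrna_count"], df["eff_len"])
    return df


def filter_genes(
    tables,
    min_mrna: int = 128,
    min_footprint: int = 1,
    blacklist=(),
) -> pd.Index:
    """Genes passing expression thresholds in *every* table, minus a blacklist.

    A gene passes iff mRNA count >= ``min_mrna`` and footprint count >=
    ``min_footprint`` in each sample under comparison, and it is not listed
    (e.g. as a dubious ORF) in ``blacklist``.
    """
    tables = list(tables)
    if not tables:
        raise ValueError("no count tables given")
    universe = tables[0].index
    if len(universe) == 0:
        raise ValueError("empty gene universe")
    keep = pd.Series(True, index=universe)
    for t in tables:
        if not t.index.equals(universe):
            raise ValueError("count tables do not share a gene universe")
        keep &= (t["mrna_count"] >= min_mrna) & (t["fp_count"] >= min_footprint)
    keep &= ~universe.isin(list(blacklist))
    return universe[keep]
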