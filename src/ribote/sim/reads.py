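"""Aligned-read simulation for footprint and mRNA libraries.

Reads are allocated multinomially across genes with weights proportional to
abundance x transcript length (mRNA) or footprint density x CDS length
(footprints, whose P-sites are uniform over the CDS apart from a
start-codon pile-up of initiating ribosomes). Footprint 5' ends are placed
so that 5' + offset(length) equals the P-site; mRNA fragments are placed
uniformly along the transcript and emitted antisense (reverse-stranded
chemistry). The LUTI-like gene diverts a configured fraction of its starved
footprints into the uORF of its 5'-extended isoform, outside the CDS.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from ..alignments import make_alignment_table
from ..annotation import Annotation
from .expression import ExpressionState

__all__ = ["simulate_reads"]


def _transcript_bounds(gene, config, starved: bool):
    """Genomic interval of the (possibly extended) transcript."""
    utr = config.utr_length
    start, end = gene.start - utr, gene.end + utr
    if "luti_like" in gene.sets and starved:
        if gene.strand == "+":
            start = gene.start - config.luti_extension_length
        else:
            end = gene.end + config.luti_extension_length
    return start, end


def simulate_reads(
    state: ExpressionState,
    genome: dict,
    annotation: Annotation,
    library_type: str,
    depth: int,
    seed: int,
) -> pd.DataFrame:
    """Emit exactly ``depth`` aligned reads as an alignment table."""
    if library_type not in ("footprint", "mrna"):
        raise ValueError(f"unknown library_type {library_type!r}")
    if depth <= 0:
        raise ValueError("depth must be positive")
    config = state.config
    rng = np.random.default_rng(seed)
    genes = annotation.genes
    starved = state.condition == "starved"

    cds_len = np.array([g.cds_length for g in genes], dtype=float)
    if library_type == "footprint":
        weights = state.footprint_density * cds_len
    else:
        tx_len = np.array(
            [b - a for a, b in (_transcript_bounds(g, config, starved) for g in genes)],
            dtype=float,
        )
        weights = state.mrna * tx_len
    counts = rng.multinomial(depth, weights / weights.sum())

    lengths_avail = np.array(sorted(config.read_length_distribution), dtype=np.int64)
    length_probs = np.array([config.read_length_distribution[int(k)] for k in lengths_avail])
    offsets_by_len = np.array(
        [config.true_psite_offsets[int(k)] for k in lengths_avail], dtype=np.int64
    )

    chroms, starts, lengths, strands, sources = [], [], [], [], []
    for g, n in zip(genes, counts):
        if n == 0:
            continue
        sources.append(np.full(n, g.gene_id))
        if library_type == "footprint":
            li = rng.choice(len(lengths_avail), size=n, p=length_probs)
            rl = lengths_avail[li]
            off = offsets_by_len[li]
            # P-site in transcript coordinates within the CDS
            p_t = rng.integers(0, g.cds_length, size=n)
            peak = rng.random(n) < config.start_peak_fraction
            p_t[peak] = 0  # initiating ribosomes: P-site on the start codon
            if g.strand == "+":
                psite = g.start + p_t
            else:
                psite = (g.end - 1) - p_t
            if "luti_like" in g.sets and starved and config.luti_uorf_fraction > 0:
                in_uorf = rng.random(n) < config.luti_uorf_fraction
                u0, u1 = g.uorf
                psite[in_uorf] = rng.integers(u0, u1, size=int(in_uorf.sum()))
            if g.strand == "+":
                five = psite - off
                start = five
            else:
                five = psite + off
                start = five - (rl - 1)
            read_strand = np.full(n, g.strand)
        else:
            t0, t1 = _transcript_bounds(g, config, starved)
            rl = np.full(n, config.mrna_read_length, dtype=np.int64)
            start = rng.integers(t0, t1 - config.mrna_read_length + 1, size=n)
            # TruSeq-stranded-like chemistry: reads come out antisense
            read_strand = np.full(n, "-" if g.strand == "+" else "+")
        chroms.append(np.full(n, g.chrom))
        starts.append(start)
        lengths.append(rl)
        strands.append(read_strand)

    start = np.concatenate(starts)
    length = np.concatenate(lengths)
    df = make_alignment_table(
        chrom=np.concatenate(chroms),
        start=start,
        length=length,
        strand=np.concatenate(strands),
        name=[f"{library_type}_{i}" for i in range(len(start))],
    )
    df["gene"] = np.concatenate(sources)  # ground-truth source, dropped by BED/SAM writers
    for chrom, size in (annotation.chrom_sizes or {}).items():
        over = (df["chrom"] == chrom) & (df["end"] > size)
        if over.any():
            raise AssertionError("simulated read extends past the chromosome end")
    return df
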