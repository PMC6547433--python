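"""Toy genome and annotation construction.

Single-exon, budding-yeast-like genes laid head-to-tail on one chromosome
with >= ``flank_length`` nt of random intergenic sequence around every CDS.
The gene roster exercises each downstream feature: ribi genes with elevated
Asp/Glu/Lys (DEK) codon usage, one exactly duplicated paralog pair (so the
mappability mask is non-trivial), one GCN4-like gene, one LUTI-like gene
whose starved isoform is 5'-extended with a uORF, and a couple of dubious
ORFs for the blacklist filter.
"""

from __future__ import annotations

import numpy as np

from ..annotation import Annotation, Gene
from .config import SimulationConfig

__all__ = ["build_toy_genome", "MIN_UNMASKED_CDS_NT"]

#: head (30) + tail (5) codon mask leaves nothing of a CDS this short
MIN_UNMASKED_CDS_NT = 3 * (30 + 5)

_STOPS = ("TAA", "TAG", "TGA")
_DEK = ("GAT", "GAC", "GAA", "GAG", "AAA", "AAG")
_BASES = np.array(list("ACGT"))
_ALL_CODONS = ["".join((a, b, c)) for a in "ACGT" for b in "ACGT" for c in "ACGT"]
_NON_DEK_SENSE = [c for c in _ALL_CODONS if c not in _STOPS and c not in _DEK]


def _revcomp(seq: str) -> str:
    return seq.translate(str.maketrans("ACGT", "TGCA"))[::-1]


def _random_seq(rng: np.random.Generator, n: int) -> str:
    return "".join(_BASES[rng.integers(0, 4, size=n)])


def _random_cds(rng: np.random.Generator, n_codons: int, dek_fraction: float) -> str:
    """ATG + internal codons with the requested DEK frequency + one stop."""
    internal = n_codons - 2
    is_dek = rng.random(internal) < dek_fraction
    dek = rng.integers(0, len(_DEK), size=internal)
    other = rng.integers(0, len(_NON_DEK_SENSE), size=internal)
    codons = [_DEK[d] if flag else _NON_DEK_SENSE[o] for flag, d, o in zip(is_dek, dek, other)]
    return "ATG" + "".join(codons) + "TAA"


def build_toy_genome(config: SimulationConfig):
    """Build (genome, annotation) deterministically from ``config.seed``.

    Returns
    -------
    genome : dict
        chromosome name -> sequence string.
    annotation : Annotation
        One CDS per gene with gene-set labels; the LUTI-like gene carries the
        genomic interval of its upstream uORF.
    """
    config.validate()
    lo, hi = config.cds_length_range
    if lo <= MIN_UNMASKED_CDS_NT:
        raise ValueError(
            f"cds_length_range minimum {lo} nt leaves no unmasked codons after the "
            f"30+5 codon edge mask ({MIN_UNMASKED_CDS_NT} nt)"
        )
    rng = np.random.default_rng(config.seed)
    n = config.n_genes

    n_ribi = max(1, round(config.frac_ribi * n))
    roles = np.array(["other"] * n, dtype=object)
    order = rng.permutation(n)
    roles[order[:n_ribi]] = "ribi"
    specials = order[n_ribi:]
    if len(specials) < 4 + config.n_dubious:
        raise ValueError("n_genes too small for the special-gene roster")
    gcn4_i, luti_i, par_a, par_b = (int(x) for x in specials[:4])
    par_a, par_b = sorted((par_a, par_b))  # the copy needs its template built first
    dubious = set(specials[4 : 4 + config.n_dubious].tolist())

    n_codons = rng.integers(lo // 3, hi // 3 + 1, size=n)
    strands = np.where(rng.random(n) < 0.5, "+", "-")

    flank = config.flank_length
    parts, genes = [], []
    cursor = 0
    chrom = "chrI"
    cds_seqs = {}
    for i in range(n):
        dek = config.dek_codon_bias if roles[i] == "ribi" else config.background_dek_frequency
        if i == par_b:
            cds = cds_seqs[f"g{par_a:04d}"]  # exact duplicate of its paralog
        else:
            cds = _random_cds(rng, int(n_codons[i]), dek)
        gene_id = f"g{i:04d}"
        cds_seqs[gene_id] = cds

        parts.append(_random_seq(rng, flank))
        cursor += flank
        start, end = cursor, cursor + len(cds)
        sets = set()
        if roles[i] == "ribi":
            sets.add("ribi")
        if i == gcn4_i:
            sets.add("gcn4_like")
        if i in (par_a, par_b):
            sets.add("paralog")
        if i in dubious:
            sets.add("dubious")
        uorf = None
        if i == luti_i:
            sets.add("luti_like")
            # uORF sits inside the starved-state 5' extension, outside the CDS
            uorf_len = 45
            gap = 30  # uORF stop to CDS start
            if strands[i] == "+":
                uorf = (start - gap - uorf_len, start - gap)
            else:
                uorf = (end + gap, end + gap + uorf_len)
        parts.append(cds if strands[i] == "+" else _revcomp(cds))
        cursor = end
        genes.append(
            Gene(
                gene_id=gene_id,
                chrom=chrom,
                start=start,
                end=end,
                strand=str(strands[i]),
                sets=frozenset(sets),
                uorf=uorf,
            )
        )
    parts.append(_random_seq(rng, flank))
    cursor += flank
    seq = "".join(parts)

    # write a real uORF (ATG + codons + stop) into the LUTI extension
    luti = genes[int(np.flatnonzero([g.uorf is not None for g in genes])[0])]
    us, ue = luti.uorf
    uorf_seq = _random_cds(rng, (ue - us) // 3, config.background_dek_frequency)
    if luti.strand == "-":
        uorf_seq = _revcomp(uorf_seq)
    seq = seq[:us] + uorf_seq + seq[ue:]

    genome = {chrom: seq}
    annotation = Annotation(genes, chrom_sizes={chrom: len(seq)})
    return genome, annotation


def cds_sequence(genome: dict, gene: Gene) -> str:
    """Sense-strand CDS sequence of a gene."""
    s = genome[gene.chrom][gene.start : gene.end]
    return s if gene.strand == "+" else _revcomp(s)
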