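"""P-site offset estimation from start-codon metagene profiles.

Initiating ribosomes pile up with their P-site on the start codon, so for
each footprint length L the histogram of read 5' ends at distance d upstream
of annotated start codons peaks at d = offset(L). Lengths without enough
reads, or without a clear peak, fall back to the depth-weighted mode of the
offsets estimated at the other lengths and are flagged rather than silently
trusted.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .annotation import Annotation

__all__ = ["PsiteOffsets", "estimate_psite_offsets"]


@dataclass
class PsiteOffsets:
    """Read-length -> nt offset from the 5' end to the ribosomal P-site."""

    offsets: dict
    fallback_lengths: frozenset = field(default_factory=frozenset)
    n_reads: dict = field(default_factory=dict)

    def __post_init__(self):
        for length, off in self.offsets.items():
            if not 0 <= off < length:
                raise ValueError(f"offset {off} outside [0, {length}) for length {length}")

    def __getitem__(self, length: int) -> int:
        return self.offsets[length]

    def as_series(self) -> pd.Series:
        return pd.Series(self.offsets, name="offset").sort_index()


def _upstream_distance(five_prime, chrom, strand, anchors):
    """Distance from each 5' end to the start codon of the gene it precedes.

    ``anchors``: (chrom, strand) -> sorted genomic positions of start-codon
    first bases. Returns -1 where no start codon lies within range downstream.
    """
    d = np.full(len(five_prime), -1, dtype=np.int64)
    for (c, s), pos_sorted in anchors.items():
        sel = (chrom == c) & (strand == s)
        if not sel.any():
            continue
        f = five_prime[sel]
        if s == "+":
            idx = np.searchsorted(pos_sorted, f, side="left")
            ok = idx < len(pos_sorted)
            dist = np.where(ok, pos_sorted[np.minimum(idx, len(pos_sorted) - 1)] - f, -1)
        else:
            idx = np.searchsorted(pos_sorted, f, side="right") - 1
            ok = idx >= 0
            dist = np.where(ok, f - pos_sorted[np.maximum(idx, 0)], -1)
        d[sel] = dist
    return d


def estimate_psite_offsets(
    alignments: pd.DataFrame,
    annotation: Annotation,
    min_reads: int = 50,
    peak_to_median: float = 2.0,
    min_peak_fraction: float = 0.15,
) -> PsiteOffsets:
    """Estimate a P-site offset for every footprint length present.

    Parameters
    ----------
    alignments
        Footprint alignment table (sense-strand reads).
    min_reads
        Minimum upstream-window reads a length needs for its own estimate.
    peak_to_median
        A metagene peak below this multiple of the histogram median is
        considered flat and triggers the fallback.
    min_peak_fraction
        The peak must also hold at least this share of the window's reads;
        sparse histograms can beat the median rule by chance while carrying
        no initiation signal.
    """
    if len(annotation) == 0:
        raise ValueError("annotation contains no genes")
    anchors = {}
    for g in annotation:
        key = (g.chrom, g.strand)
        anchor = g.start if g.strand == "+" else g.end - 1
        anchors.setdefault(key, []).append(anchor)
    anchors = {k: np.sort(np.asarray(v, dtype=np.int64)) for k, v in anchors.items()}

    chrom = alignments["chrom"].to_numpy()
    strand = alignments["strand"].to_numpy()
    start = alignments["start"].to_numpy()
    end = alignments["end"].to_numpy()
    length = alignments["length"].to_numpy()
    five_prime = np.where(strand == "+", start, end - 1)
    dist = _upstream_distance(five_prime, chrom, strand, anchors)

    offsets, flagged, n_reads = {}, set(), {}
    for L in sorted(np.unique(length)):
        L = int(L)
        sel = (length == L) & (dist >= 0) & (dist < L)
        hist = np.bincount(dist[sel], minlength=L)
        n = int(hist.sum())
        n_reads[L] = n
        peak = int(hist.max()) if n else 0
        med = float(np.median(hist)) if n else 0.0
        if (
            n < min_reads
            or peak < peak_to_median * max(med, 1e-9)
            or peak < min_peak_fraction * n
        ):
            flagged.add(L)
            offsets[L] = None  # filled below
        else:
            offsets[L] = int(np.argmax(hist))  # argmax -> smallest offset on ties

    good = {L: o for L, o in offsets.items() if o is not None}
    if not good:
        raise ValueError("no footprint length produced a usable start-codon peak")
    if flagged:
        # depth-weighted mode of the successfully estimated offsets
        weights: dict = {}
        for L, o in good.items():
            weights[o] = weights.get(o, 0) + n_reads[L]
        fallback = min(sorted(weights), key=lambda o: (-weights[o], o))
        for L in flagged:
            offsets[L] = min(fallback, L - 1)
    return PsiteOffsets(offsets=offsets, fallback_lengths=frozenset(flagged), n_reads=n_reads)
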