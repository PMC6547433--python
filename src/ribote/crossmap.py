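"""Genome mappability masking.

A genomic position ``p`` is masked when the ``read_length``-mer starting at
``p`` could not be placed uniquely: it matches, within ``max_mismatches``
substitutions, a window at at least one *other* genomic location, on either
strand. Masked positions are excluded from counting and from effective CDS
length downstream.

The search is pigeonhole seed-and-verify: the k-mer is cut into
``max_mismatches + 1`` contiguous parts, so any pair within the mismatch
budget must agree exactly on at least one part; windows are bucketed by each
part, candidate pairs are drawn inside buckets, and Hamming distance is then
verified exactly with numpy. The result is definitionally identical to
all-vs-all enumeration (which the test suite performs independently).
"""

from __future__ import annotations

import numpy as np

from .masks import MaskSet

__all__ = ["compute_crossmap_mask"]

_ENC = np.full(256, 255, dtype=np.uint8)
for i, b in enumerate(b"ACGT"):
    _ENC[b] = i
    _ENC[ord(chr(b).lower())] = i


def _encode(seq: str) -> np.ndarray:
    arr = _ENC[np.frombuffer(seq.encode("ascii"), dtype=np.uint8)]
    if (arr == 255).any():
        raise ValueError("genome sequence contains non-ACGT characters")
    return arr


def _revcomp_codes(arr: np.ndarray) -> np.ndarray:
    return (3 - arr)[..., ::-1]


def compute_crossmap_mask(
    genome: dict, read_length: int = 26, max_mismatches: int = 2
) -> MaskSet:
    """Mask every position whose read cannot be uniquely mapped.

    Parameters
    ----------
    genome
        Mapping of chromosome name to sequence (ACGT string).
    read_length
        Read length used for the uniqueness test (default 26 nt).
    max_mismatches
        Substitution tolerance (default 2; indels are not considered).

    Returns
    -------
    MaskSet
        One-position intervals at every non-unique window start, merged.
    """
    if not genome:
        raise ValueError("empty genome")
    if read_length < 1:
        raise ValueError("read_length must be >= 1")
    if max_mismatches < 0:
        raise ValueError("max_mismatches must be >= 0")

    chrom_names, windows, chrom_idx, pos = [], [], [], []
    for ci, (chrom, seq) in enumerate(sorted(genome.items())):
        chrom_names.append(chrom)
        arr = _encode(str(seq))
        if len(arr) < read_length:
            continue  # too short to start any read; contributes no positions
        w = np.lib.stride_tricks.sliding_window_view(arr, read_length)
        windows.append(w)
        chrom_idx.append(np.full(len(w), ci, dtype=np.int32))
        pos.append(np.arange(len(w), dtype=np.int64))
    if not windows:
        return MaskSet()

    W = np.ascontiguousarray(np.vstack(windows))
    chrom_idx = np.concatenate(chrom_idx)
    pos = np.concatenate(pos)
    n = len(W)
    # rows n..2n-1 are the minus-strand reads of the same genomic intervals
    X = np.vstack([W, _revcomp_codes(W)])

    masked = np.zeros(n, dtype=bool)
    parts = np.array_split(np.arange(read_length), max_mismatches + 1)
    pows = 4 ** np.arange(max(len(p) for p in parts), dtype=np.int64)

    for cols in parts:
        if len(cols) == 0:
            continue
        keys = X[:, cols].astype(np.int64) @ pows[: len(cols)]
        order = np.argsort(keys, kind="stable")
        sorted_keys = keys[order]
        boundaries = np.flatnonzero(np.diff(sorted_keys)) + 1
        starts = np.concatenate([[0], boundaries])
        ends = np.concatenate([boundaries, [len(keys)]])
        pair_i, pair_j = [], []
        for s, e in zip(starts, ends):
            if e - s < 2:
                continue
            grp = order[s:e]
            ii, jj = np.triu_indices(len(grp), k=1)
            pair_i.append(grp[ii])
            pair_j.append(grp[jj])
        if not pair_i:
            continue
        pi = np.concatenate(pair_i)
        pj = np.concatenate(pair_j)
        # same genomic interval (a window and its own reverse complement) is
        # not a second location
        loc_i, loc_j = pi % n, pj % n
        keep = loc_i != loc_j
        # both endpoints already masked -> nothing new to learn
        keep &= ~(masked[loc_i] & masked[loc_j])
        pi, pj, loc_i, loc_j = pi[keep], pj[keep], loc_i[keep], loc_j[keep]
        for lo in range(0, len(pi), 2_000_000):
            hi = lo + 2_000_000
            mism = (X[pi[lo:hi]] != X[pj[lo:hi]]).sum(axis=1)
            hit = mism <= max_mismatches
            masked[loc_i[lo:hi][hit]] = True
            masked[loc_j[lo:hi][hit]] = True

    iv: dict = {}
    for ci, chrom in enumerate(chrom_names):
        p = pos[(chrom_idx == ci) & masked]
        if len(p):
            iv[chrom] = np.column_stack([p, p + 1])
    return MaskSet(iv)
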