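"""Independent brute-force mappability oracle used only by the tests.

Enumerates, for every window start, the Hamming distance to *all* other
windows on both strands by blocked all-vs-all comparison — no seeding, no
bucketing — so it shares no code path with the production implementation.
"""

from __future__ import annotations

import numpy as np

_CODE = {"A": 0, "C": 1, "G": 2, "T": 3}


def _encode(seq: str) -> np.ndarray:
    return np.array([_CODE[b] for b in seq.upper()], dtype=np.uint8)


def crossmap_bruteforce(genome: dict, read_length: int = 26, max_mismatches: int = 2) -> dict:
    """Return {chrom: sorted array of masked window-start positions}."""
    names, rows, chrom_of, pos_of = [], [], [], []
    for chrom, seq in sorted(genome.items()):
        arr = _encode(str(seq))
        if len(arr) < read_length:
            continue
        for p in range(len(arr) - read_length + 1):
            rows.append(arr[p : p + read_length])
            chrom_of.append(chrom)
            pos_of.append(p)
    if not rows:
        return {}
    W = np.array(rows)
    n = len(W)
    X = np.vstack([W, (3 - W)[:, ::-1]])  # plus then reverse-complement windows
    loc = np.concatenate([np.arange(n), np.arange(n)])

    masked = np.zeros(n, dtype=bool)
    chunk = 256
    for lo in range(0, n, chunk):
        hi = min(lo + chunk, n)
        dist = (W[lo:hi, None, :] != X[None, :, :]).sum(axis=2)
        other = loc[None, :] != np.arange(lo, hi)[:, None]
        masked[lo:hi] = ((dist <= max_mismatches) & other).any(axis=1)

    out: dict = {}
    for chrom in sorted(set(chrom_of)):
        sel = [i for i in range(n) if chrom_of[i] == chrom and masked[i]]
        out[chrom] = np.array([pos_of[i] for i in sel], dtype=np.int64)
    return out


def maskset_positions(mask, chroms) -> dict:
    """Flatten a MaskSet into {chrom: sorted masked positions} for comparison."""
    out = {}
    for chrom in chroms:
        iv = mask.intervals(chrom)
        out[chrom] = np.concatenate(
            [np.arange(s, e) for s, e in iv] or [np.empty(0, dtype=np.int64)]
        )
    return out
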