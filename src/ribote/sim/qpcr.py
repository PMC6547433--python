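"""Synthetic qPCR Ct tables from an expression time series.

Ct is linear in -log2(abundance) with amplification efficiency 2:
Ct = c0 - log2(abundance) + N(0, noise_sd), independently per technical
replicate. The reference gene must have constant abundance across states,
matching the housekeeping-reference assumption of the ddCt method.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from .expression import ExpressionState

__all__ = ["simulate_qpcr"]


def simulate_qpcr(
    states,
    target_gene: str,
    reference_gene: str,
    n_technical: int = 3,
    noise_sd: float = 0.2,
    seed: int = 0,
    c0: float = 30.0,
) -> pd.DataFrame:
    """One Ct row per (state, gene, technical replicate)."""
    states = list(states)
    if not states:
        raise ValueError("no expression states given")
    if n_technical < 2:
        raise ValueError("need >= 2 technical replicates (replicate SD undefined)")
    rng = np.random.default_rng(seed)

    ref_levels = []
    for st in states:
        idx = {g: i for i, g in enumerate(st.gene_ids)}
        for gene in (target_gene, reference_gene):
            if gene not in idx:
                raise KeyError(f"gene {gene!r} not in expression state")
        ref_levels.append(st.mrna[idx[reference_gene]])
    if np.ptp(ref_levels) > 1e-9 * max(ref_levels):
        raise ValueError("reference gene abundance varies across states")

    rows = []
    for si, st in enumerate(states):
        idx = {g: i for i, g in enumerate(st.gene_ids)}
        tp = st.timepoint if st.timepoint is not None else si
        for gene in (target_gene, reference_gene):
            level = st.mrna[idx[gene]]
            ct_mean = c0 - np.log2(level)
            noise = rng.normal(0.0, noise_sd, size=n_technical)
            for rep in range(n_technical):
                rows.append(
                    {
                        "sample": f"t{si}",
                        "timepoint": tp,
                        "gene": gene,
                        "replicate": rep,
                        "ct": ct_mean + noise[rep],
                    }
                )
    return pd.DataFrame(rows)
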