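"""Translation-efficiency statistics.

TE is footprint RPKM over mRNA RPKM per gene. Fold changes between samples
are median-normalized (the median fold change over all passing genes is set
to 1) before any comparison; time-course variability is summarized as the
per-gene TE fold-range (max TE / min TE). Gene-set overlap is scored with an
upper-tail hypergeometric probability; grouped +/-CHX count-ratio shifts with
two-sided t-tests. No multiple-testing correction is applied anywhere: the
reported probabilities are raw, per-test values.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats as sps

log = logging.getLogger(__name__)

__all__ = [
    "compute_te",
    "normalize_fold_changes",
    "fold_change_table",
    "te_range",
    "fold_range_table",
    "select_switchers",
    "EnrichmentResult",
    "overlap_enrichment",
    "GroupComparison",
    "group_comparison",
    "DEK_CODONS",
    "codon_frequency",
    "codon_set_comparison",
]

#: codons for aspartate, glutamate and lysine
DEK_CODONS = frozenset({"GAT", "GAC", "GAA", "GAG", "AAA", "AAG"})

TIER_THRESHOLDS = ((1e-25, "****"), (1e-10, "***"), (1e-5, "**"), (1e-2, "*"))


def significance_tier(p: float) -> str:
    for threshold, tier in TIER_THRESHOLDS:
        if p < threshold:
            return tier
    return "NS"


def compute_te(table: pd.DataFrame) -> pd.Series:
    """TE = footprint RPKM / mRNA RPKM, per gene."""
    if (table["mrna_rpkm"] <= 0).any():
        bad = table.index[table["mrna_rpkm"] <= 0].tolist()
        raise ValueError(f"mRNA RPKM is zero for {bad[:5]}; filter before computing TE")
    return (table["fp_rpkm"] / table["mrna_rpkm"]).rename("te")


def normalize_fold_changes(values) -> pd.Series:
    """Divide by the median so the median normalized fold change is 1.

    Median convention: numpy (mean of the middle two for even length).
    Idempotent: renormalizing a normalized vector changes nothing.
    """
    v = pd.Series(values, dtype=float)
    if len(v) == 0:
        raise ValueError("no fold changes to normalize")
    if not np.isfinite(v).all() or (v <= 0).any():
        raise ValueError("fold changes must be finite and positive")
    return v / float(np.median(v))


def fold_change_table(
    numer: pd.DataFrame, denom: pd.DataFrame, genes=None
) -> pd.DataFrame:
    """Median-normalized mRNA and TE fold changes between two samples.

    ``numer``/``denom`` are count tables; the fold change of X is
    X(numer)/X(denom), then each column is normalized to median 1 over the
    supplied gene list.
    """
    if genes is None:
        genes = numer.index
    a, b = numer.loc[genes], denom.loc[genes]
    mrna_fc = a["mrna_rpkm"] / b["mrna_rpkm"]
    te_fc = compute_te(a) / compute_te(b)
    return pd.DataFrame(
        {
            "mrna_fc": normalize_fold_changes(mrna_fc),
            "te_fc": normalize_fold_changes(te_fc),
        }
    )


def te_range(te_series) -> tuple:
    """(min/max ratio, fold-range) of a per-gene TE series over timepoints."""
    v = pd.Series(te_series, dtype=float).dropna()
    if len(v) < 2:
        raise ValueError("need TE at >= 2 passing timepoints")
    if (v <= 0).any():
        raise ValueError("TE must be positive")
    r = float(v.min() / v.max())
    return r, 1.0 / r


def fold_range_table(te_matrix: pd.DataFrame) -> pd.DataFrame:
    """Per-gene TE fold-range across a time course.

    ``te_matrix``: genes x timepoints, NaN where the gene failed filters at
    that timepoint. Genes with fewer than two passing timepoints are omitted
    (complete-case for the summary) with a log entry.
    """
    n_ok = te_matrix.notna().sum(axis=1)
    dropped = te_matrix.index[n_ok < 2]
    if len(dropped):
        log.info("fold_range_table: omitting %d gene(s) with <2 passing timepoints", len(dropped))
    kept = te_matrix.loc[n_ok >= 2]
    lo = kept.min(axis=1)
    hi = kept.max(axis=1)
    ratio = lo / hi
    return pd.DataFrame({"min_over_max": ratio, "fold_range": 1.0 / ratio})


def select_switchers(fold_ranges: pd.Series, threshold: float = 8.0) -> pd.Index:
    """Genes whose TE fold-range is ``threshold``-fold or greater."""
    fr = pd.Series(fold_ranges, dtype=float)
    if not np.isfinite(fr).all():
        raise ValueError("fold-ranges must be finite")
    return fr.index[fr >= threshold]


@dataclass(frozen=True)
class EnrichmentResult:
    label: str
    n_a: int
    n_b: int
    n_intersection: int
    n_universe: int
    n_flagged_universe: int
    n_flagged_intersection: int
    p_value: float


def overlap_enrichment(set_a, set_b, universe, flagged, label: str = "") -> EnrichmentResult:
    """Hypergeometric upper-tail enrichment of a flagged class in A∩B.

    Probability of drawing at least the observed number of flagged genes when
    |A∩B| genes are drawn from the universe containing ``flagged`` genes.
    """
    universe = set(universe)
    if not universe:
        raise ValueError("empty universe")
    a, b = set(set_a) & universe, set(set_b) & universe
    if set(set_a) - universe or set(set_b) - universe:
        raise ValueError("A and B must be subsets of the universe")
    inter = a & b
    flagged = set(flagged) & universe
    k = len(inter & flagged)
    p = float(sps.hypergeom.sf(k - 1, len(universe), len(flagged), len(inter)))
    return EnrichmentResult(
        label=label,
        n_a=len(a),
        n_b=len(b),
        n_intersection=len(inter),
        n_universe=len(universe),
        n_flagged_universe=len(flagged),
        n_flagged_intersection=k,
        p_value=p,
    )


@dataclass(frozen=True)
class GroupComparison:
    label: str
    quantity: str
    condition: str
    test: str  # "one-sample" (ratios vs 0) or "two-sample" (set vs complement)
    n: int
    mean_log2_ratio: float
    t: float
    p: float
    tier: str


def group_comparison(
    table_plus: pd.DataFrame,
    table_minus: pd.DataFrame,
    gene_sets: dict,
    quantity: str,
    condition: str,
    genes=None,
) -> tuple:
    """Compare +CHX/-CHX normalized count ratios between gene sets.

    ``gene_sets`` maps labels to gene-id collections; every gene in ``genes``
    (default: the shared index) not in any set forms the complement set
    "non-<first label>". Ratios are RPKM ratios normalized to median 1 and
    compared on the log2 scale with two-sided t-tests: a one-sample test per
    set (mean ratio vs 0) and a two-sample test of each set against the
    complement. Returns (results, ratios).
    """
    col = {"footprint": "fp_rpkm", "mrna": "mrna_rpkm"}.get(quantity)
    if col is None:
        raise ValueError(f"unknown quantity {quantity!r}")
    if genes is None:
        genes = table_plus.index
    if not table_plus.index.equals(table_minus.index):
        raise ValueError("count tables do not share a gene universe")
    ratio = table_plus.loc[genes, col] / table_minus.loc[genes, col]
    log2_ratio = np.log2(normalize_fold_changes(ratio))

    in_any = set()
    for members in gene_sets.values():
        in_any |= set(members)
    first = next(iter(gene_sets))
    sets = dict(gene_sets)
    sets[f"non-{first}"] = [g for g in genes if g not in in_any]

    results = []
    for label, members in sets.items():
        vals = log2_ratio.loc[log2_ratio.index.intersection(pd.Index(members))]
        if len(vals) < 3:
            raise ValueError(f"gene set {label!r} has fewer than 3 genes after filtering")
        t1, p1 = sps.ttest_1samp(vals, 0.0)
        results.append(
            GroupComparison(
                label, quantity, condition, "one-sample",
                len(vals), float(vals.mean()), float(t1), float(p1), significance_tier(p1),
            )
        )
        if label != f"non-{first}":
            comp = log2_ratio.loc[~log2_ratio.index.isin(pd.Index(members))]
            t2, p2 = sps.ttest_ind(vals, comp, equal_var=False)
            results.append(
                GroupComparison(
                    f"{label} vs rest", quantity, condition, "two-sample",
                    len(vals), float(vals.mean() - comp.mean()), float(t2), float(p2),
                    significance_tier(p2),
                )
            )
    return results, log2_ratio


def codon_frequency(cds_sequences: dict, codon_set=DEK_CODONS) -> pd.Series:
    """Per-gene fraction of codons belonging to ``codon_set``."""
    codon_set = {c.upper() for c in codon_set}
    out = {}
    for gene_id, seq in cds_sequences.items():
        s = str(seq).upper()
        if set(s) - set("ACGT"):
            raise ValueError(f"{gene_id}: CDS contains non-ACGT characters")
        if len(s) % 3:
            raise ValueError(f"{gene_id}: CDS length not a multiple of 3")
        codons = [s[i : i + 3] for i in range(0, len(s), 3)]
        out[gene_id] = sum(c in codon_set for c in codons) / len(codons)
    return pd.Series(out, name="codon_fraction").rename_axis("gene_id")


def codon_set_comparison(
    frequencies: pd.Series, set_genes, footprint_log2_ratio: pd.Series | None = None
) -> dict:
    """Rank-compare codon-set usage between a gene set and the rest.

    Optionally correlates per-gene codon-set fraction with the log2 footprint
    ratio (+CHX / -CHX) across all genes (Spearman).
    """
    in_set = frequencies.index.isin(pd.Index(list(set_genes)))
    a, b = frequencies[in_set], frequencies[~in_set]
    if len(a) < 3 or len(b) < 3:
        raise ValueError("both groups need at least 3 genes")
    u, p = sps.mannwhitneyu(a, b, alternative="two-sided")
    result = {
        "set_median": float(a.median()),
        "background_median": float(b.median()),
        "median_difference": float(a.median() - b.median()),
        "mannwhitney_u": float(u),
        "p_value": float(p),
    }
    if footprint_log2_ratio is not None:
        joint = pd.concat([frequencies, footprint_log2_ratio], axis=1, join="inner")
        rho, p_rho = sps.spearmanr(joint.iloc[:, 0], joint.iloc[:, 1])
        result["spearman_rho"] = float(rho)
        result["spearman_p"] = float(p_rho)
    return result
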