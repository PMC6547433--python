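"""End-to-end orchestration: simulate libraries, count, and tabulate TE.

These helpers wire the generator to the quantification stages exactly the
way the analysis is meant to be run on real alignments: crossmap + CDS-edge
masking, P-site offsets estimated from the footprint library itself,
reverse-stranded mRNA counting, then filtering and TE.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .annotation import Annotation
from .counting import (
    build_count_table,
    count_reads,
    effective_lengths,
    filter_genes,
)
from .crossmap import compute_crossmap_mask
from .masks import MaskSet, build_cds_edge_mask
from .psite import PsiteOffsets, estimate_psite_offsets
from .sim import SimulationConfig, build_toy_genome, simulate_expression_state, simulate_reads
from .stats import compute_te

__all__ = [
    "quantify",
    "ExperimentResult",
    "run_starvation_experiment",
    "TimecourseResult",
    "run_timecourse_experiment",
]


def quantify(
    fp_alignments: pd.DataFrame,
    mrna_alignments: pd.DataFrame,
    annotation: Annotation,
    edge_mask: MaskSet,
    crossmap_mask: MaskSet | None = None,
    offsets: PsiteOffsets | None = None,
    strandedness: str = "reverse",
    crossmap_exempt_genes=(),
) -> pd.DataFrame:
    """Masked counts + RPKM for one footprint/mRNA library pair.

    ``crossmap_exempt_genes`` are quantified with the edge mask only (the
    near-identical-paralog escape hatch); everything else sees the union of
    the edge and crossmap masks. The RPKM denominator is the total of reads
    assigned under each gene's own mask.
    """
    if offsets is None:
        offsets = estimate_psite_offsets(fp_alignments, annotation)
    full_mask = edge_mask.union(crossmap_mask) if crossmap_mask else edge_mask
    fp = count_reads(fp_alignments, annotation, full_mask, "footprint", offsets, "forward")
    mrna = count_reads(mrna_alignments, annotation, full_mask, "mrna", strandedness=strandedness)
    eff = effective_lengths(annotation, full_mask)
    exempt = [g for g in crossmap_exempt_genes if g in annotation]
    if exempt and crossmap_mask:
        fp_e = count_reads(fp_alignments, annotation, edge_mask, "footprint", offsets, "forward")
        mrna_e = count_reads(mrna_alignments, annotation, edge_mask, "mrna", strandedness=strandedness)
        eff_e = effective_lengths(annotation, edge_mask)
        fp.loc[exempt] = fp_e.loc[exempt]
        mrna.loc[exempt] = mrna_e.loc[exempt]
        eff.loc[exempt] = eff_e.loc[exempt]
    return build_count_table(fp, mrna, eff)


def _spawn_seeds(seed: int, n: int) -> list:
    rng = np.random.default_rng(seed)
    return [int(s) for s in rng.integers(0, 2**31 - 1, size=n)]


@dataclass
class ExperimentResult:
    config: SimulationConfig
    genome: dict
    annotation: Annotation
    edge_mask: MaskSet
    crossmap_mask: MaskSet | None
    tables: dict  # (condition, treatment) -> count table
    truths: dict  # (condition, treatment) -> GroundTruth
    offsets: dict  # (condition, treatment) -> PsiteOffsets
    blacklist: list = field(default_factory=list)

    def passing_genes(self, keys=None, min_mrna: int = 128, min_footprint: int = 1):
        keys = list(self.tables) if keys is None else list(keys)
        return filter_genes(
            [self.tables[k] for k in keys],
            min_mrna=min_mrna,
            min_footprint=min_footprint,
            blacklist=self.blacklist,
        )


def run_starvation_experiment(
    config: SimulationConfig,
    depth: int | None = None,
    seed: int | None = None,
    conditions=(("replete", "chx"), ("starved", "chx"), ("replete", "none"), ("starved", "none")),
    use_crossmap: bool = True,
) -> ExperimentResult:
    """Simulate and quantify matched libraries for each (condition, treatment)."""
    depth = depth or config.library_depth
    seed = config.seed if seed is None else seed
    genome, annotation = build_toy_genome(config)
    edge_mask = build_cds_edge_mask(annotation)
    crossmap_mask = compute_crossmap_mask(genome) if use_crossmap else None

    tables, truths, offsets_by_key = {}, {}, {}
    seeds = _spawn_seeds(seed, 2 * len(conditions))
    for i, (condition, treatment) in enumerate(conditions):
        state, truth = simulate_expression_state(config, annotation, condition, treatment)
        fp = simulate_reads(state, genome, annotation, "footprint", depth, seeds[2 * i])
        mrna = simulate_reads(state, genome, annotation, "mrna", depth, seeds[2 * i + 1])
        off = estimate_psite_offsets(fp, annotation)
        tables[(condition, treatment)] = quantify(
            fp, mrna, annotation, edge_mask, crossmap_mask, offsets=off
        )
        truths[(condition, treatment)] = truth
        offsets_by_key[(condition, treatment)] = off
    return ExperimentResult(
        config=config,
        genome=genome,
        annotation=annotation,
        edge_mask=edge_mask,
        crossmap_mask=crossmap_mask,
        tables=tables,
        truths=truths,
        offsets=offsets_by_key,
        blacklist=annotation.in_set("dubious"),
    )


@dataclass
class TimecourseResult:
    config: SimulationConfig
    annotation: Annotation
    tables: dict  # timepoint -> count table
    te_matrix: pd.DataFrame  # genes x timepoints, NaN where filters failed
    blacklist: list


def run_timecourse_experiment(
    config: SimulationConfig,
    depth: int | None = None,
    seed: int | None = None,
    condition: str = "replete",
    treatment: str = "chx",
    min_mrna: int = 128,
    min_footprint: int = 1,
    use_crossmap: bool = True,
    median_center: bool = True,
) -> TimecourseResult:
    """Simulate the oscillating course and assemble the per-gene TE matrix.

    TE is recorded per timepoint only where the gene passes the expression
    filters at that timepoint (complete-case handling happens downstream in
    the fold-range summary). With ``median_center`` each timepoint's TE
    column is divided by its across-gene median: RPKM totals are a property
    of each library's composition, so a synchronized oscillation of one
    regulon shifts every other gene's RPKM in antiphase; dividing by the
    per-sample median removes that common factor, in the same spirit as
    setting the median fold change to 1.
    """
    depth = depth or config.library_depth
    seed = config.seed if seed is None else seed
    genome, annotation = build_toy_genome(config)
    edge_mask = build_cds_edge_mask(annotation)
    crossmap_mask = compute_crossmap_mask(genome) if use_crossmap else None
    blacklist = annotation.in_set("dubious")

    seeds = _spawn_seeds(seed, 2 * config.n_timepoints)
    tables = {}
    te_cols = {}
    for t in range(config.n_timepoints):
        state, _ = simulate_expression_state(config, annotation, condition, treatment, timepoint=t)
        fp = simulate_reads(state, genome, annotation, "footprint", depth, seeds[2 * t])
        mrna = simulate_reads(state, genome, annotation, "mrna", depth, seeds[2 * t + 1])
        table = quantify(fp, mrna, annotation, edge_mask, crossmap_mask)
        tables[t] = table
        passing = filter_genes(
            [table], min_mrna=min_mrna, min_footprint=min_footprint, blacklist=blacklist
        )
        te = pd.Series(np.nan, index=table.index)
        te.loc[passing] = compute_te(table.loc[passing])
        if median_center and len(passing):
            te /= te.loc[passing].median()
        te_cols[t] = te
    te_matrix = pd.DataFrame(te_cols)
    return TimecourseResult(
        config=config,
        annotation=annotation,
        tables=tables,
        te_matrix=te_matrix,
        blacklist=blacklist,
    )
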