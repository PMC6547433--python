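"""Per-gene expression states and the CHX artifact model.

Base mRNA abundance and true TE are drawn log-normally once per genome seed,
so paired conditions differ only through the applied multipliers (and
sampling noise downstream). The artifact model: in starved cells treated
with CHX, TORC1 signaling resumes and new ribi transcripts are made, but
they cannot be translated — measured ribi mRNA rises by
``chx_mrna_multiplier`` while ribi footprint density falls by
``chx_footprint_multiplier``, so the *apparent* TE drops by their ratio even
though no translational regulation occurred. Non-ribi genes are untouched by
treatment. In time-course mode the ribi TE oscillates sinusoidally (shared
phase, peak-to-trough log2 amplitude ``oscillation_amplitude``), emulating a
metabolic-cycle-like synchronized culture.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from ..annotation import Annotation
from .config import SimulationConfig

__all__ = ["ExpressionState", "GroundTruth", "simulate_expression_state"]

CONDITIONS = ("replete", "starved")
TREATMENTS = ("chx", "none")


@dataclass
class GroundTruth:
    """Generating parameters behind one simulated state."""

    gene_ids: list
    base_abundance: np.ndarray
    base_te: np.ndarray
    mrna_multiplier: np.ndarray  # total multiplier applied to measured mRNA
    footprint_multiplier: np.ndarray  # total multiplier applied to footprint density
    true_psite_offsets: dict = field(default_factory=dict)

    def expected_te_ratio_vs(self, other: "GroundTruth") -> np.ndarray:
        """True apparent-TE ratio of this state over another, per gene."""
        te_self = self.footprint_multiplier / self.mrna_multiplier
        te_other = other.footprint_multiplier / other.mrna_multiplier
        return te_self / te_other


@dataclass
class ExpressionState:
    """Measured-scale per-gene mRNA abundance and footprint density."""

    config: SimulationConfig
    gene_ids: list
    mrna: np.ndarray  # arbitrary concentration units
    footprint_density: np.ndarray  # abundance x apparent TE
    condition: str
    treatment: str
    timepoint: int | None = None

    def __post_init__(self):
        if (self.mrna <= 0).any() or (self.footprint_density <= 0).any():
            raise ValueError("abundances and footprint densities must be positive")

    @property
    def apparent_te(self) -> np.ndarray:
        return self.footprint_density / self.mrna


def simulate_expression_state(
    config: SimulationConfig,
    annotation: Annotation,
    condition: str,
    treatment: str,
    timepoint: int | None = None,
):
    """Build the (ExpressionState, GroundTruth) pair for one library pair.

    ``condition`` is replete|starved, ``treatment`` chx|none. With a
    ``timepoint`` (0-based, over ``config.n_timepoints`` spanning one period)
    the ribi TE oscillation is applied on top.
    """
    if condition not in CONDITIONS:
        raise ValueError(f"unknown condition {condition!r}")
    if treatment not in TREATMENTS:
        raise ValueError(f"unknown treatment {treatment!r}")
    if timepoint is not None and not 0 <= timepoint < config.n_timepoints:
        raise ValueError("timepoint outside the configured course")

    rng = np.random.default_rng(config.seed)
    n = len(annotation)
    mu_a, sd_a = config.mean_mrna_abundance
    mu_t, sd_t = config.te_true
    base_abundance = rng.lognormal(mu_a, sd_a, size=n)
    base_te = rng.lognormal(mu_t, sd_t, size=n)

    ids = annotation.gene_ids
    is_ribi = np.array(["ribi" in g.sets for g in annotation])
    is_gcn4 = np.array(["gcn4_like" in g.sets for g in annotation])

    mrna_mult = np.ones(n)
    fp_mult = np.ones(n)  # multiplier on footprint density relative to base
    if condition == "starved":
        mrna_mult[is_ribi] *= config.starvation_ribi_mrna_multiplier
        fp_mult[is_ribi] *= config.starvation_ribi_mrna_multiplier  # footprints track mRNA
        fp_mult[is_gcn4] *= config.gcn4_te_multiplier
        if treatment == "chx":
            # new ribi transcripts are made but cannot be translated
            mrna_mult[is_ribi] *= config.chx_mrna_multiplier
            fp_mult[is_ribi] *= config.chx_footprint_multiplier
    if timepoint is not None:
        phase = 2.0 * np.pi * timepoint / config.n_timepoints
        osc = 2.0 ** (0.5 * config.oscillation_amplitude * np.sin(phase))
        fp_mult[is_ribi] *= osc

    state = ExpressionState(
        config=config,
        gene_ids=ids,
        mrna=base_abundance * mrna_mult,
        footprint_density=base_abundance * base_te * fp_mult,
        condition=condition,
        treatment=treatment,
        timepoint=timepoint,
    )
    truth = GroundTruth(
        gene_ids=ids,
        base_abundance=base_abundance,
        base_te=base_te,
        mrna_multiplier=mrna_mult,
        footprint_multiplier=fp_mult,
        true_psite_offsets=dict(config.true_psite_offsets),
    )
    return state, truth
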