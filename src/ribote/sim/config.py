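"""Simulation configuration.

The defaults encode the study conditions the generator emulates: matched
footprint/RNA-seq libraries for replete/starved yeast-like cultures with and
without cycloheximide (CHX) pretreatment, plus a 16-timepoint oscillating
time course. Ribosome-biogenesis ("ribi") genes receive a CHX-dependent mRNA
increase (new, untranslated transcripts) and footprint decrease; one
GCN4-like gene is translationally activated by starvation; one LUTI-like
gene carries a 5'-extended starved isoform whose uORF sequesters footprints.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, asdict

import yaml

__all__ = ["SimulationConfig"]


def _default_read_lengths() -> dict:
    return {26: 0.02, 27: 0.06, 28: 0.35, 29: 0.20, 30: 0.15, 31: 0.10, 32: 0.07, 33: 0.03, 34: 0.02}


def _default_offsets() -> dict:
    return {26: 12, 27: 12, 28: 13, 29: 13, 30: 14, 31: 14, 32: 15, 33: 15, 34: 16}


@dataclass
class SimulationConfig:
    """Parameters of the synthetic genome, expression states and libraries.

    Log-normal parameters are (location, scale) of the underlying normal.
    Multipliers are fold changes applied to ribi genes (or the GCN4-like
    gene) in the stated state; abundances are arbitrary concentration units.
    """

    n_genes: int = 200
    frac_ribi: float = 0.05
    cds_length_range: tuple = (300, 1500)  # nt, rounded to whole codons
    mean_mrna_abundance: tuple = (3.0, 1.0)
    te_true: tuple = (0.0, 0.5)
    chx_mrna_multiplier: float = 3.0
    chx_footprint_multiplier: float = 0.5
    starvation_ribi_mrna_multiplier: float = 0.5
    gcn4_te_multiplier: float = 4.0
    dek_codon_bias: float = 0.40  # Asp/Glu/Lys codon fraction in ribi CDSs
    background_dek_frequency: float = 0.17
    read_length_distribution: dict = field(default_factory=_default_read_lengths)
    true_psite_offsets: dict = field(default_factory=_default_offsets)
    library_depth: int = 1_000_000
    n_timepoints: int = 16
    oscillation_amplitude: float = math.log2(8.0)  # peak-to-trough, log2-fold
    seed: int = 0
    # ---- generator plumbing beyond the headline biology -------------------
    start_peak_fraction: float = 0.10  # initiating-ribosome pile-up at the start codon
    luti_uorf_fraction: float = 0.70  # starved-state footprints diverted to the uORF
    mrna_read_length: int = 50
    utr_length: int = 60
    luti_extension_length: int = 240
    flank_length: int = 300
    n_dubious: int = 2

    def __post_init__(self):
        self.validate()

    def validate(self) -> None:
        if self.n_genes < 10:
            raise ValueError("n_genes must be >= 10")
        if not 0 < self.frac_ribi < 1:
            raise ValueError("frac_ribi must be in (0, 1)")
        lo, hi = self.cds_length_range
        if lo < 3 or hi < lo:
            raise ValueError("invalid cds_length_range")
        for name in (
            "chx_mrna_multiplier",
            "chx_footprint_multiplier",
            "starvation_ribi_mrna_multiplier",
            "gcn4_te_multiplier",
        ):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be > 0")
        if self.chx_mrna_multiplier < 1:
            raise ValueError("chx_mrna_multiplier must be >= 1")
        if self.chx_footprint_multiplier > 1:
            raise ValueError("chx_footprint_multiplier must be <= 1")
        if set(self.read_length_distribution) - set(range(26, 35)):
            raise ValueError("read lengths must lie in 26..34")
        total = sum(self.read_length_distribution.values())
        if abs(total - 1.0) > 1e-9:
            raise ValueError(f"read_length_distribution sums to {total}, not 1")
        for length, off in self.true_psite_offsets.items():
            if not 0 <= off < length:
                raise ValueError(f"P-site offset {off} outside [0, {length})")
        missing = set(self.read_length_distribution) - set(self.true_psite_offsets)
        if missing:
            raise ValueError(f"no true P-site offset for lengths {sorted(missing)}")
        if not 0 < self.dek_codon_bias < 1 or not 0 < self.background_dek_frequency < 1:
            raise ValueError("codon-bias fractions must be in (0, 1)")
        if not 0 <= self.start_peak_fraction < 1:
            raise ValueError("start_peak_fraction must be in [0, 1)")
        if not 0 <= self.luti_uorf_fraction <= 1:
            raise ValueError("luti_uorf_fraction must be in [0, 1]")
        if self.library_depth <= 0:
            raise ValueError("library_depth must be positive")
        if self.n_timepoints < 2:
            raise ValueError("n_timepoints must be >= 2")
        if self.flank_length < max(100, self.luti_extension_length, self.utr_length + self.mrna_read_length):
            raise ValueError("flank_length must be >= 100 and hold the LUTI extension")

    # ------------------------------------------------------------------ YAML
    def to_yaml(self, path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(asdict(self), fh, sort_keys=False)

    @classmethod
    def from_yaml(cls, path) -> "SimulationConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh)
        for key in ("cds_length_range", "mean_mrna_abundance", "te_true"):
            if key in raw and isinstance(raw[key], list):
                raw[key] = tuple(raw[key])
        for key in ("read_length_distribution", "true_psite_offsets"):
            if key in raw:
                raw[key] = {int(k): v for k, v in raw[key].items()}
        return cls(**raw)
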