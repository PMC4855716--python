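"""Simulation configuration: the study conditions the generator emulates.

The defaults mirror a two-pool XX/XY gonad contrast sequenced as one small-RNA
library per sex: 30 hairpin loci spread unevenly over four chromosomes (one
chromosome deliberately empty), ten miRNAs planted as differentially
expressed at four-fold, 200,000 reads per library with a 0.5% per-base
substitution error, a measured Illumina 3' adapter, and a small mRNA panel
whose 3'UTRs carry seed sites for the planted-DE miRNAs in genes biased
toward the opposite sex.
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict

import yaml

DEFAULT_ADAPTER = "GCCTTGGCACCCGAGAATTCCA"


@dataclass
class SimulationConfig:
    """All knobs of the synthetic-data generator (one seeded RNG throughout)."""

    seed: int = 1
    # genome / planted hairpins
    n_chrom: int = 4
    chrom_lengths: list[int] = field(default_factory=lambda: [50_000] * 4)
    n_premirna: int = 30
    premirna_per_chrom: list[int] = field(default_factory=lambda: [0, 12, 8, 10])
    # expression contrast
    n_de: int = 10
    de_fold: float = 4.0
    library_size_a: int = 200_000
    library_size_b: int = 200_000
    error_rate: float = 0.005
    adapter: str = DEFAULT_ADAPTER
    read_length: int = 36
    ncrna_fraction: float = 0.05
    # known-database divergence (emulated related species)
    divergence: float = 0.05
    mature_divergence: float = 0.0
    # mRNA side
    n_genes: int = 60
    utr_length: int = 500
    planted_target_fraction: float = 1.0
    n_low_genes: int = 6        # FPKM < 0.5 in at least one sex -> excluded
    n_undefined_genes: int = 4  # FPKM > 0.5 in one sex, 0 in the other

    def __post_init__(self) -> None:
        self.validate()

    def validate(self) -> None:
        if len(self.chrom_lengths) != self.n_chrom:
            raise ValueError("chrom_lengths must list n_chrom lengths")
        if len(self.premirna_per_chrom) != self.n_chrom:
            raise ValueError("premirna_per_chrom must list n_chrom counts")
        if sum(self.premirna_per_chrom) != self.n_premirna:
            raise ValueError("sum(premirna_per_chrom) must equal n_premirna")
        if self.n_de > self.n_premirna:
            raise ValueError("n_de cannot exceed n_premirna")
        if self.de_fold < 2:
            raise ValueError("de_fold must be >= 2")
        if not 0 <= self.error_rate < 0.05:
            raise ValueError("error_rate must lie in [0, 0.05)")
        if any(length <= 0 for length in self.chrom_lengths):
            raise ValueError("chromosome lengths must be positive")
        if self.utr_length <= 0 or self.n_genes <= 0 or self.read_length <= 0:
            raise ValueError("lengths and counts must be positive")
        if not 0 <= self.ncrna_fraction < 1:
            raise ValueError("ncrna_fraction must lie in [0, 1)")
        if not 0 <= self.planted_target_fraction <= 1:
            raise ValueError("planted_target_fraction must lie in [0, 1]")
        if not self.adapter:
            raise ValueError("adapter must be non-empty")

    @classmethod
    def from_yaml(cls, path: str) -> "SimulationConfig":
        with open(path) as fh:
            data = yaml.safe_load(fh) or {}
        return cls(**data)

    def to_yaml(self, path: str) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(asdict(self), fh, sort_keys=False)
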