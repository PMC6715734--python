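"""Simulation configuration.

The defaults encode the study conditions of the hybrid cross the pipeline
is built for: a biallelic founder SNP map at ~1 SNP / 170 bp, ~300
homologue-templated DSB repairs per meiosis of which ~10% resolve as
crossovers, exponential conversion tracts with allele-specific means
(30 bp for Cast-controlled, 41 bp for humanised-allele-controlled
hotspots), and sequencing depths of ~10x for founders/F4 and ~20x for
F2/F5 animals.  The genome itself is a scaled-down twin (three autosomes
by default); every *rate* is at study value, only the genome length is a
size knob.
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass, field

import yaml


@dataclass
class SimConfig:
    """Parameters of the synthetic cross.

    Attributes
    ----------
    chrom_lengths : tuple of int
        Autosome lengths in bp.
    snp_spacing_mean : float
        Mean inter-SNP gap in bp (geometric gaps).
    n_hotspots : int
        Number of PRDM9 hotspots genome-wide (placed with >= 2 kb spacing).
    heat_shape : float
        Log-scale sd of the lognormal hotspot heat distribution.  The
        default (1.1) makes the hottest one-sixth of hotspots carry over
        half of the total heat.
    frac_cast_controlled : float
        Fraction of hotspots controlled by the Cast allele of PRDM9 (the
        rest by the humanised allele).
    frac_asymmetric : float
        Fraction of hotspots with strongly homologue-biased PRDM9 binding
        (B6 binding ratio x near 0 or 1); the rest are near-symmetric.
    tract_mean_cast, tract_mean_hum : float
        Mean exponential NCO tract length (bp) at Cast- and
        humanised-controlled hotspots.
    tract_center_sd : float
        SD (bp) of the zero-mean normal displacement of tract centers
        around the hotspot motif center.
    dsb_per_meiosis_mean : float
        Mean number of homologue-templated DSB repairs transmitted per
        meiosis (Poisson).
    co_fraction : float
        Probability a repair resolves as a crossover.
    depth_founder, depth_offspring : float
        Mean sequencing depth for F0/F4 and for F2/F5 samples.
    base_error_rate : float
        Per-read probability of reading the other founder allele.
    false_het_rate, false_hom_rate : float
        Per-site rates of injected artifact genotypes (spurious
        heterozygotes with unbalanced reads; spurious homozygotes at true
        het sites), to exercise the filter cascade.
    motif_disrupted_rate_asym, motif_disrupted_rate_sym : float
        Probability that the PRDM9 motif of an asymmetric / symmetric
        hotspot overlaps a polymorphism.
    chip_alpha, chip_beta : float
        Scale of H3K4me3 and DMC1 ChIP read counts per unit heat.
    dmc1_delay_factor : float
        Fold increase of the DMC1:H3K4me3 ratio as symmetry goes to 0
        (repair delay at asymmetric hotspots); 1 disables it.
    dmc1_shift : float
        Strength of the shift of the DMC1 allele fraction toward the
        less-bound homologue at asymmetric hotspots; 0 disables it.
    sex_heat_multiplier : float
        Multiplier applied to hotspot heats in female meioses (1 = no sex
        difference).
    exact_genotypes : bool
        When True, depths equal the generation mean exactly and
        heterozygous allele depths split evenly: the noise-free mode used
        by recovery tests.
    obligate_co : bool
        Enforce at least one crossover per chromosome per meiosis.
    seed : int
        Base seed recorded alongside outputs.
    """

    chrom_lengths: tuple = (40_000_000, 30_000_000, 20_000_000)
    snp_spacing_mean: float = 170.0
    n_hotspots: int = 1500
    heat_shape: float = 1.1
    frac_cast_controlled: float = 0.5
    frac_asymmetric: float = 0.3
    tract_mean_cast: float = 30.0
    tract_mean_hum: float = 41.0
    tract_center_sd: float = 200.0
    dsb_per_meiosis_mean: float = 300.0
    co_fraction: float = 0.10
    depth_founder: float = 10.0
    depth_offspring: float = 20.0
    base_error_rate: float = 0.001
    false_het_rate: float = 5e-5
    false_hom_rate: float = 5e-5
    motif_disrupted_rate_asym: float = 0.96
    motif_disrupted_rate_sym: float = 0.20
    motif_width: int = 30
    chip_alpha: float = 100.0
    chip_beta: float = 50.0
    dmc1_delay_factor: float = 2.0
    dmc1_shift: float = 0.3
    sex_heat_multiplier: float = 1.0
    exact_genotypes: bool = False
    obligate_co: bool = True
    seed: int = 0

    def __post_init__(self):
        self.chrom_lengths = tuple(int(c) for c in self.chrom_lengths)
        if len(self.chrom_lengths) == 0:
            raise ValueError("chrom_lengths must be nonempty")
        if any(c <= 0 for c in self.chrom_lengths):
            raise ValueError("chromosome lengths must be positive")
        if self.snp_spacing_mean < 1:
            raise ValueError("snp_spacing_mean must be >= 1 bp")
        if self.n_hotspots <= 0:
            raise ValueError("n_hotspots must be positive")
        for name in (
            "frac_cast_controlled",
            "frac_asymmetric",
            "co_fraction",
            "motif_disrupted_rate_asym",
            "motif_disrupted_rate_sym",
        ):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name} must be in [0, 1], got {v}")
        if self.tract_mean_cast < 1 or self.tract_mean_hum < 1:
            raise ValueError("tract means must be >= 1 bp")
        if self.dsb_per_meiosis_mean <= 0:
            raise ValueError("dsb_per_meiosis_mean must be positive")
        if self.depth_founder <= 0 or self.depth_offspring <= 0:
            raise ValueError("depths must be positive")
        for name in ("base_error_rate", "false_het_rate", "false_hom_rate"):
            v = getattr(self, name)
            if v < 0 or v > 1:
                raise ValueError(f"{name} must be in [0, 1], got {v}")
        if self.heat_shape <= 0.0:
            raise ValueError("heat_shape must be positive")

    @property
    def chroms(self):
        return tuple(f"chr{i + 1}" for i in range(len(self.chrom_lengths)))

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        d["chrom_lengths"] = list(self.chrom_lengths)
        return d

    def to_yaml(self, path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(self.to_dict(), fh, sort_keys=False)

    def to_json(self, path) -> None:
        with open(path, "w") as fh:
            json.dump(self.to_dict(), fh, indent=2)

    @classmethod
    def from_dict(cls, d: dict) -> "SimConfig":
        return cls(**d)

    @classmethod
    def from_yaml(cls, path) -> "SimConfig":
        with open(path) as fh:
            return cls.from_dict(yaml.safe_load(fh))
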