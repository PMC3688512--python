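"""Configuration objects for the simulator and the analysis pipeline.

All tunable thresholds live here with their defaults; both configs
round-trip through YAML so a run can be reproduced from its config file
alone.  Every source of randomness flows from the single ``seed``.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field
from pathlib import Path

import yaml


class ConfigError(ValueError):
    """Raised for invalid configuration values (CLI exit code 2)."""


# Per-experiment A-value floors (average log2 intensity below which a spot
# is considered background, as set by array control probes).
DEFAULT_A_CUTOFFS = {
    "total_7min": 10.27,
    "total_45min": 10.61,
    "total_90min": 10.45,
    "poly_90min": 10.44,
}

ARRAY_CONDITIONS = ("total_7min", "total_45min", "total_90min", "poly_90min")


@dataclass
class SimulationConfig:
    """Parameters of the in-silico study.

    Defaults emulate the real study's design: ~1500 genes on two
    biological array replicates per condition, four SILAC evidence
    replicates, log2 effect size 1.5 for regulated genes, per-probe M
    noise sd 0.15 (log2), smooth intensity-dependent dye bias of
    amplitude 0.5, 96% heavy-label incorporation, and 19 planted
    unannotated ORFs of which 13 are transcribed.
    """

    seed: int = 0
    n_genes: int = 1500
    n_operons: int = 150
    operon_size_min: int = 2
    operon_size_max: int = 5
    replicates: int = 2            # two-color arrays, biological replicates
    silac_replicates: int = 4      # evidence sets (2 digestion protocols x 2 biol.)
    array_noise_sd: float = 0.15   # sd of per-probe M (log2-ratio scale)
    dye_bias_amplitude: float = 0.5
    peptide_cv: float = 0.20       # CV of peptide intensity noise
    incorporation: float = 0.96    # heavy-label incorporation probability
    coverage_depth: float = 50.0   # mean reads/nt over expressed loci
    coverage_background: float = 0.2
    effect_size: float = 1.5       # |log2| effect of regulated genes
    # planted class counts (assigned deterministically, not sampled)
    n_rpoe_genes: int = 51         # immediate induction at all time-points
    n_rpoh2_genes: int = 90        # delayed induction (45/90 min only)
    n_pulse_genes: int = 30        # induced at 7 min only
    n_repressed_genes: int = 60    # down-regulated on every layer
    n_translational_only: int = 45
    n_protein_decline: int = 45
    # planted operon polarity
    n_5prime_operons: int = 12
    n_3prime_operons: int = 6
    n_translatome_polar_operons: int = 5
    polarity_offset: float = 0.4   # end-to-end log2 offset is 2x this
    translatome_polarity_offset: float = 0.5  # translatome-only polar operons
    silac_bio_sd: float = 0.1      # per-replicate biological sd (log2)
    # novel ORF planting
    n_novel_orfs: int = 19
    n_expressed_novel_orfs: int = 13
    # array intensity placement
    low_a_fraction: float = 0.12   # fraction of probes below the A floor
    a_floor: float = 10.44
    a_low: float = 8.5
    a_high: float = 14.0
    # protein design
    protein_len_mean: int = 60
    novel_orf_len: int = 40

    def validate(self) -> None:
        if self.n_genes <= 0:
            raise ConfigError("n_genes must be positive")
        if not 0 <= self.incorporation <= 1:
            raise ConfigError("incorporation must be in [0, 1]")
        for name in ("array_noise_sd", "peptide_cv", "coverage_depth",
                     "coverage_background", "dye_bias_amplitude"):
            if getattr(self, name) < 0:
                raise ConfigError(f"{name} must be >= 0")
        if self.operon_size_min < 2 or self.operon_size_max < self.operon_size_min:
            raise ConfigError("operon sizes must satisfy 2 <= min <= max")
        if self.n_operons * self.operon_size_max > self.n_genes:
            raise ConfigError("operon sizes exceed gene count")
        if self.n_expressed_novel_orfs > self.n_novel_orfs:
            raise ConfigError("cannot express more novel ORFs than planted")
        if not 0 <= self.low_a_fraction <= 1:
            raise ConfigError("low_a_fraction must be in [0, 1]")
        n_classed = (self.n_rpoe_genes + self.n_rpoh2_genes + self.n_pulse_genes
                     + self.n_repressed_genes + self.n_translational_only
                     + self.n_protein_decline)
        if n_classed > self.n_genes:
            raise ConfigError("planted class counts exceed n_genes")


@dataclass
class PipelineConfig:
    """Analysis-side thresholds plus the simulation block.

    Defaults are the study's published cutoffs: regulation at |log2| >=
    0.8 with p < 0.05, layer-difference 0.4, per-experiment A floors,
    BH FDR 0.05, >=2 SILAC ratio counts, Lys-C peptides >=6 aa with <=2
    missed cleavages, six-frame ORFs >=7 aa.
    """

    simulation: SimulationConfig = field(default_factory=SimulationConfig)
    reg_threshold: float = 0.8
    p_threshold: float = 0.05
    diff_threshold: float = 0.4
    a_cutoffs: dict = field(default_factory=lambda: dict(DEFAULT_A_CUTOFFS))
    bh_fdr: float = 0.05
    min_ratio_count: int = 2
    min_peptide_len: int = 6
    max_missed_cleavages: int = 2
    min_orf_aa: int = 7
    min_novel_peptides: int = 2
    polarity_epsilon: float = 0.4
    polarity_rho: float = 0.5
    coverage_min_mean: float = 10.0
    coverage_min_frac: float = 0.8
    loess_span: float = 0.3
    loess_iterations: int = 2
    kmeans_k: int = 3
    kmeans_sub_k: int = 3
    kmeans_max_iter: int = 50
    array_var_method: str = "pooled"   # or "per_gene"

    def validate(self) -> None:
        self.simulation.validate()
        if self.array_var_method not in ("pooled", "per_gene"):
            raise ConfigError("array_var_method must be 'pooled' or 'per_gene'")
        for name in ("reg_threshold", "p_threshold", "diff_threshold", "bh_fdr",
                     "polarity_epsilon", "coverage_min_mean", "coverage_min_frac"):
            if getattr(self, name) < 0:
                raise ConfigError(f"{name} must be >= 0")

    # -- YAML round-trip ---------------------------------------------------
    def to_dict(self) -> dict:
        return dataclasses.asdict(self)

    @classmethod
    def from_dict(cls, data: dict) -> "PipelineConfig":
        data = dict(data)
        sim = data.pop("simulation", {})
        known_sim = {f.name for f in dataclasses.fields(SimulationConfig)}
        known = {f.name for f in dataclasses.fields(cls)} - {"simulation"}
        bad = (set(sim) - known_sim) | (set(data) - known)
        if bad:
            raise ConfigError(f"unknown config keys: {sorted(bad)}")
        return cls(simulation=SimulationConfig(**sim), **data)

    def write_yaml(self, path: str | Path) -> None:
        Path(path).write_text(yaml.safe_dump(self.to_dict(), sort_keys=True))

    @classmethod
    def read_yaml(cls, path: str | Path) -> "PipelineConfig":
        return cls.from_dict(yaml.safe_load(Path(path).read_text()))
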