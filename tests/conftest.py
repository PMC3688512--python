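"""Shared fixtures: scaled-down synthetic studies reused across tests."""

import pandas as pd
import pytest

from expressome.config import PipelineConfig
from expressome.genome import generate_genome
from expressome.pipeline import run_full, run_simulate
from expressome.scenario import simulate_true_expression


def small_config(seed: int = 123, **overrides) -> PipelineConfig:
    """A ~300-gene study that keeps every planted structure present."""
    cfg = PipelineConfig()
    s = cfg.simulation
    s.seed = seed
    s.n_genes = 300
    s.n_operons = 40
    s.n_rpoe_genes = 15
    s.n_rpoh2_genes = 40
    s.n_pulse_genes = 8
    s.n_repressed_genes = 15
    s.n_translational_only = 12
    s.n_protein_decline = 12
    s.n_5prime_operons = 4
    s.n_3prime_operons = 2
    s.n_translatome_polar_operons = 2
    for key, value in overrides.items():
        setattr(s, key, value)
    cfg.validate()
    return cfg


def noise_free_config(seed: int = 123, **overrides) -> PipelineConfig:
    """Zero-noise limit of the small study: every estimator should
    recover the planted truth exactly."""
    base = dict(array_noise_sd=0.0, dye_bias_amplitude=0.0,
                peptide_cv=0.0, silac_bio_sd=0.0, low_a_fraction=0.0,
                a_floor=10.7)
    base.update(overrides)
    return small_config(seed=seed, **base)


@pytest.fixture(scope="session")
def small_cfg():
    return small_config()


@pytest.fixture(scope="session")
def small_genome(small_cfg):
    return generate_genome(small_cfg.simulation)


@pytest.fixture(scope="session")
def small_scenario(small_cfg, small_genome):
    return simulate_true_expression(small_genome, small_cfg.simulation)


@pytest.fixture(scope="session")
def small_bundle(small_cfg, tmp_path_factory):
    outdir = tmp_path_factory.mktemp("bundle_small")
    run_simulate(small_cfg, outdir)
    return outdir


@pytest.fixture(scope="session")
def small_results(small_cfg, small_bundle):
    return run_full(small_cfg, small_bundle)


@pytest.fixture(scope="session")
def small_truth(small_bundle):
    return {
        "genes": pd.read_csv(small_bundle / "truth_genes.tsv", sep="\t"),
        "operons": pd.read_csv(small_bundle / "truth_operons.tsv", sep="\t"),
        "novel": pd.read_csv(small_bundle / "truth_novel_orfs.tsv", sep="\t"),
    }
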