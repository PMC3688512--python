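"""Simulators for the three measurement layers.

Two-color arrays: per probe, the reference channel (Cy5) reflects
baseline expression and the stress channel (Cy3) the baseline times
2^(true log2 effect); probe noise is applied on the M (log2-ratio)
scale and an intensity-dependent dye bias d(A) = amplitude*sin(A/2) is
added to M, leaving A untouched — exactly the artifact LOESS
normalization must remove, with a closed-form oracle.

SILAC: every protein is digested in silico with Lys-C; each peptide
carries a heavy intensity proportional to the (fully labeled) standard
and a light intensity proportional to the condition's abundance, with
protein-level replicate factors plus peptide-level measurement noise.
A heavy-only run of the standard supports incorporation estimation.

RNA-seq: strand-specific Poisson per-nucleotide counts over expressed
loci on top of a low background.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from .config import ARRAY_CONDITIONS, SimulationConfig
from .genome import SyntheticGenome
from .proteogenomics import digest_lysC
from .scenario import RegulatoryScenario
from .tracks import CoverageTrack

CONDITION_EFFECT = {
    "total_7min": "t7",
    "total_45min": "t45",
    "total_90min": "t90",
    "poly_90min": "poly90",
}


def dye_bias(a: np.ndarray, amplitude: float) -> np.ndarray:
    """Smooth intensity-dependent dye bias added to M."""
    return amplitude * np.sin(np.asarray(a, float) / 2.0)


def simulate_two_color_arrays(
    scenario: RegulatoryScenario, config: SimulationConfig
) -> pd.DataFrame:
    """Per-probe Cy3/Cy5 intensities for every condition x replicate.

    Columns: probe_id, gene_id, condition, replicate, cy3, cy5.
    """
    rng = np.random.default_rng([3, config.seed])
    genes = scenario.genes
    n = len(genes)
    frames = []
    for condition in ARRAY_CONDITIONS:
        effect = genes[CONDITION_EFFECT[condition]].to_numpy(float)
        a = genes["baseline_a"].to_numpy(float)
        for rep in range(1, config.replicates + 1):
            m = effect + rng.normal(0.0, config.array_noise_sd, n) \
                + dye_bias(a, config.dye_bias_amplitude)
            cy3 = 2.0 ** (a + m / 2.0)
            cy5 = 2.0 ** (a - m / 2.0)
            frames.append(pd.DataFrame({
                "probe_id": [f"P_{g}" for g in genes.index],
                "gene_id": genes.index,
                "condition": condition,
                "replicate": rep,
                "cy3": cy3,
                "cy5": cy5,
            }))
    return pd.concat(frames, ignore_index=True)


def _protein_table(scenario: RegulatoryScenario) -> pd.DataFrame:
    """Annotated proteins plus planted novel ORFs, with SILAC baselines."""
    genes = scenario.genes
    base = pd.DataFrame({
        "protein_id": genes.index,
        "prot_base_log2": genes["prot_base_log2"],
        "standard_log2_offset": genes["standard_log2_offset"],
        "prot90": genes["prot90"],
    }).reset_index(drop=True)
    if len(scenario.novel_orfs):
        nov = pd.DataFrame({
            "protein_id": scenario.novel_orfs["orf_id"],
            "prot_base_log2": scenario.novel_orfs["prot_base_log2"],
            "standard_log2_offset": scenario.novel_orfs["standard_log2_offset"],
            "prot90": 0.0,
        }).reset_index(drop=True)
        base = pd.concat([base, nov], ignore_index=True)
    return base


def simulate_silac_evidence(
    scenario: RegulatoryScenario,
    genome: SyntheticGenome,
    config: SimulationConfig,
    max_peptides_per_protein: int = 6,
) -> pd.DataFrame:
    """Peptide evidence for the reference and stress mixes plus a
    heavy-only incorporation run.

    Columns: peptide, protein_ids, sample, replicate, intensity_H,
    intensity_L.
    """
    rng = np.random.default_rng([4, config.seed])
    sigma_ln = np.sqrt(np.log1p(config.peptide_cv ** 2))

    prot = _protein_table(scenario)
    aa_by_id = {g.gene_id: g.protein for g in genome.genes}
    aa_by_id.update({o.orf_id: o.aa for o in genome.novel_orfs})

    pep_rows = []
    for rec in prot.itertuples(index=False):
        peptides = digest_lysC(aa_by_id[rec.protein_id], max_missed=0,
                               min_len=6)[:max_peptides_per_protein]
        for pep in peptides:
            pep_rows.append((pep, rec.protein_id, rec.prot_base_log2,
                             rec.standard_log2_offset, rec.prot90))
    if not pep_rows:
        return pd.DataFrame(columns=["peptide", "protein_ids", "sample",
                                     "replicate", "intensity_H", "intensity_L"])
    pep = pd.DataFrame(pep_rows, columns=[
        "peptide", "protein_ids", "prot_base_log2", "standard_log2_offset",
        "prot90"])
    n_pep = len(pep)
    pep["q"] = rng.normal(0.0, 1.0, n_pep)  # peptide ionization factor, log2

    heavy_log2 = (pep["prot_base_log2"] + pep["standard_log2_offset"]
                  + pep["q"]).to_numpy()
    n_prot = len(prot)
    prot_index = pep["protein_ids"].map(
        {p: i for i, p in enumerate(prot["protein_id"])}).to_numpy()

    def pair_noise(size: int) -> tuple[np.ndarray, np.ndarray]:
        """Correlated noise for a co-eluting heavy/light peak pair.

        Each intensity carries the configured CV, but most of it is a
        shared feature-level factor (ionization, sampling); only half
        the CV is pair-independent and therefore reaches the ratio —
        the precision SILAC owes to measuring both labels in one peak
        pair.
        """
        if sigma_ln == 0:
            ones = np.ones(size)
            return ones, ones.copy()
        shared = rng.normal(0.0, sigma_ln * np.sqrt(0.75), size)
        ratio = rng.normal(0.0, sigma_ln * 0.5, size)
        return np.exp(shared + ratio / 2.0), np.exp(shared - ratio / 2.0)

    frames = []
    for sample, effect_col in (("reference_mix", None), ("stress_mix", "prot90")):
        for rep in range(1, config.silac_replicates + 1):
            bio = rng.normal(0.0, config.silac_bio_sd, n_prot) \
                if config.silac_bio_sd > 0 else np.zeros(n_prot)
            light_log2 = pep["prot_base_log2"].to_numpy() + pep["q"].to_numpy() \
                + bio[prot_index]
            if effect_col is not None:
                light_log2 = light_log2 + pep[effect_col].to_numpy()
            noise_h, noise_l = pair_noise(n_pep)
            frames.append(pd.DataFrame({
                "peptide": pep["peptide"],
                "protein_ids": pep["protein_ids"],
                "sample": sample,
                "replicate": rep,
                "intensity_H": 2.0 ** heavy_log2 * noise_h,
                "intensity_L": 2.0 ** light_log2 * noise_l,
            }))

    # heavy-only run: the standard measured alone; residual light signal
    # reflects incomplete label incorporation
    total = 2.0 ** heavy_log2
    noise_h, noise_l = pair_noise(n_pep)
    frames.append(pd.DataFrame({
        "peptide": pep["peptide"],
        "protein_ids": pep["protein_ids"],
        "sample": "heavy_only",
        "replicate": 1,
        "intensity_H": total * config.incorporation * noise_h,
        "intensity_L": total * (1.0 - config.incorporation) * noise_l,
    }))
    return pd.concat(frames, ignore_index=True)


def simulate_rnaseq_coverage(
    scenario: RegulatoryScenario,
    genome: SyntheticGenome,
    config: SimulationConfig,
) -> CoverageTrack:
    """Strand-specific per-nucleotide counts; expressed novel ORFs get
    mean depth `coverage_depth`, annotated genes scaled by their
    expression factor, everything else background."""
    rng = np.random.default_rng([5, config.seed])
    n = len(genome.sequence)
    plus = rng.poisson(config.coverage_background, n).astype(float)
    minus = rng.poisson(config.coverage_background, n).astype(float)
    for g in genome.genes:
        rate = config.coverage_depth * float(
            scenario.genes.loc[g.gene_id, "expression_factor"])
        target = plus if g.strand == "+" else minus
        target[g.start:g.end] += rng.poisson(rate, g.end - g.start)
    for o in genome.novel_orfs:
        if not o.expressed or config.coverage_depth == 0:
            continue
        target = plus if o.strand == "+" else minus
        target[o.start:o.end] += rng.poisson(config.coverage_depth,
                                             o.end - o.start)
    if config.coverage_depth == 0:
        plus[:] = 0.0
        minus[:] = 0.0
    return CoverageTrack(replicon=genome.replicon, plus=plus, minus=minus)
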