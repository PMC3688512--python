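"""True regulatory scenario: per-gene, per-layer planted effects.

The scenario turns the genome's design classes into numeric log2 effects
for five measurements — transcriptome at 7/45/90 min, translatome at
90 min, proteome at 90 min — and layers operon polarity offsets on top.
Cross-layer concordance truth labels are derived by applying the
classification rule to the noise-free effects, so in the zero-noise
limit every downstream estimator recovers the truth exactly.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .config import SimulationConfig
from .genome import SyntheticGenome

LAYER_COLUMNS = ("t7", "t45", "t90", "poly90", "prot90")


@dataclass
class RegulatoryScenario:
    """Planted truth: one row per gene plus operon and novel-ORF tables."""

    genes: pd.DataFrame     # indexed by gene_id
    operons: pd.DataFrame   # operon_id, strand, polarity_class, gene order
    novel_orfs: pd.DataFrame


def _class_effects(cls: str, e: float) -> dict[str, float]:
    """Noise-free log2 effects for one design class (before polarity)."""
    table = {
        "rpoe": (e, e, e, e, e),
        "rpoh2": (0.3, e, e, e, e),
        "pulse": (e, 0.3, 0.3, 0.3, 0.3),
        "repressed": (-e, -e, -e, -e, -e),
        "translational_only": (0.0, 0.0, 0.0, e, 0.0),
        "protein_decline": (0.0, 0.0, 0.0, 0.0, -e),
        "flat": (0.0, 0.0, 0.0, 0.0, 0.0),
    }
    return dict(zip(LAYER_COLUMNS, table[cls]))


def concordance_truth(
    a: np.ndarray, b: np.ndarray, reg: float = 0.8, diff: float = 0.4
) -> np.ndarray:
    """Concordance class from two layers' (noise-free) log2 values."""
    a, b = np.asarray(a, float), np.asarray(b, float)
    regulated = (np.abs(a) >= reg) | (np.abs(b) >= reg)
    biased = np.abs(a - b) >= diff
    out = np.where(regulated, np.where(biased, "biased", "unidirectional"),
                   "unchanged")
    return out


def simulate_true_expression(
    genome: SyntheticGenome, config: SimulationConfig
) -> RegulatoryScenario:
    config.validate()
    rng = np.random.default_rng([1, config.seed])
    e = config.effect_size

    rows = []
    for g in genome.genes:
        rec = {"gene_id": g.gene_id, "design_class": g.design_class,
               "regulon": g.regulon, "operon_id": g.operon_id or "",
               "operon_pos": g.operon_pos or 0,
               "strand": g.strand, "start": g.start, "end": g.end}
        rec.update(_class_effects(g.design_class, e))
        rows.append(rec)
    genes = pd.DataFrame(rows).set_index("gene_id")

    # operon polarity offsets, positive at the 5' (first-transcribed) end
    op_rows = []
    for op in genome.operons:
        k = len(op.gene_ids)
        op_rows.append({"operon_id": op.operon_id, "strand": op.strand,
                        "size": k, "polarity_class": op.polarity_class,
                        "gene_ids": ",".join(op.gene_ids)})
        if op.polarity_class == "none":
            continue
        if op.polarity_class == "translatome_5prime":
            d = config.translatome_polarity_offset
            offsets = np.linspace(d, -d, k)
            layers = ("poly90",)
        else:
            d = config.polarity_offset
            sign = 1.0 if op.polarity_class == "5prime" else -1.0
            offsets = sign * np.linspace(d, -d, k)
            layers = LAYER_COLUMNS
        for gene_id, off in zip(op.gene_ids, offsets):
            for layer in layers:
                genes.loc[gene_id, layer] += off
    operons = pd.DataFrame(
        op_rows, columns=["operon_id", "strand", "size", "polarity_class",
                          "gene_ids"])

    genes["polarity_offset"] = 0.0
    for op in genome.operons:
        if op.polarity_class in ("5prime", "3prime"):
            sign = 1.0 if op.polarity_class == "5prime" else -1.0
            offs = sign * np.linspace(config.polarity_offset,
                                      -config.polarity_offset,
                                      len(op.gene_ids))
            genes.loc[list(op.gene_ids), "polarity_offset"] = offs

    # concordance truth per layer pair, from the planted effects
    genes["conc_total_poly"] = concordance_truth(genes["t90"], genes["poly90"])
    genes["conc_prot_total"] = concordance_truth(genes["prot90"], genes["t90"])
    genes["conc_prot_poly"] = concordance_truth(genes["prot90"], genes["poly90"])
    genes["translational_trigger"] = (
        (genes["poly90"] >= 0.8) & (genes["poly90"] - genes["t90"] >= 0.4))
    genes["protein_decline_flag"] = (
        (genes["prot90"] <= -0.8) & (genes["t90"] - genes["prot90"] >= 0.4))

    # array baseline intensities: an exact fraction of probes sits below
    # the A floor (background), the rest spread up to a_high
    n = len(genes)
    n_low = int(round(config.low_a_fraction * n))
    base_a = np.concatenate([
        rng.uniform(config.a_low, config.a_floor, n_low),
        rng.uniform(config.a_floor, config.a_high, n - n_low),
    ])
    rng.shuffle(base_a)
    genes["baseline_a"] = base_a
    genes["expression_factor"] = 2.0 ** rng.normal(0.0, 0.5, n)

    # SILAC baselines: light reference abundance and the heavy-standard
    # offset (the standard pools several growth conditions)
    genes["prot_base_log2"] = rng.uniform(18.0, 24.0, n)
    genes["standard_log2_offset"] = rng.normal(0.0, 0.5, n)

    novel = pd.DataFrame(
        [{"orf_id": o.orf_id, "start": o.start, "end": o.end,
          "strand": o.strand, "aa": o.aa, "expressed": o.expressed,
          "host_gene": o.host_gene or ""} for o in genome.novel_orfs],
        columns=["orf_id", "start", "end", "strand", "aa", "expressed",
                 "host_gene"])
    if len(novel):
        novel = novel.set_index("orf_id", drop=False)
        rng2 = np.random.default_rng([2, config.seed])
        novel["prot_base_log2"] = rng2.uniform(18.0, 24.0, len(novel))
        novel["standard_log2_offset"] = rng2.normal(0.0, 0.5, len(novel))

    return RegulatoryScenario(genes=genes, operons=operons, novel_orfs=novel)
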