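"""Planted truth and the three layer simulators."""

import numpy as np
import pandas as pd
import pytest

from expressome.genome import generate_genome
from expressome.scenario import concordance_truth, simulate_true_expression
from expressome.simulate import (dye_bias, simulate_rnaseq_coverage,
                                 simulate_silac_evidence,
                                 simulate_two_color_arrays)
from expressome.silac import incorporation_rate, quantify_silac

from conftest import noise_free_config, small_config


class TestScenario:
    def test_kinetic_class_effect_shapes(self, small_scenario):
        g = small_scenario.genes
        rpoe = g[g.design_class == "rpoe"]
        assert (rpoe[["t7", "t45", "t90"]] >= 0.8).all().all()
        rpoh2 = g[g.design_class == "rpoh2"]
        assert (rpoh2["t7"] < 0.8).all()
        assert (rpoh2[["t45", "t90"]] >= 0.8).all().all()
        pulse = g[g.design_class == "pulse"]
        assert (pulse["t7"] >= 0.8).all()
        assert (pulse[["t45", "t90"]] < 0.8).all().all()
        flat = g[g.design_class == "flat"]
        assert (flat[["t7", "t45", "t90", "poly90", "prot90"]] == 0).all().all()

    def test_polar_operons_have_monotone_true_effects(self, small_scenario):
        genes = small_scenario.genes
        for op in small_scenario.operons.itertuples(index=False):
            members = op.gene_ids.split(",")
            vals = genes.loc[members, "t90"].to_numpy()
            if op.polarity_class == "5prime":
                assert (np.diff(vals) < 0).all()
            elif op.polarity_class == "3prime":
                assert (np.diff(vals) > 0).all()
            elif op.polarity_class == "translatome_5prime":
                poly = genes.loc[members, "poly90"].to_numpy()
                assert (np.diff(poly) < 0).all()
                assert np.allclose(np.diff(vals), 0)

    def test_concordance_truth_rule(self):
        cls = concordance_truth(np.array([1.0, 1.0, 0.1, 0.9]),
                                np.array([0.9, 0.3, 0.2, 1.4]))
        assert list(cls) == ["unidirectional", "biased", "unchanged", "biased"]

    def test_determinism(self, small_cfg, small_genome, small_scenario):
        again = simulate_true_expression(small_genome, small_cfg.simulation)
        pd.testing.assert_frame_equal(again.genes, small_scenario.genes)


class TestArrays:
    def test_noise_free_m_equals_true_effect(self):
        cfg = noise_free_config()
        genome = generate_genome(cfg.simulation)
        sc = simulate_true_expression(genome, cfg.simulation)
        tab = simulate_two_color_arrays(sc, cfg.simulation)
        m = np.log2(tab["cy3"] / tab["cy5"])
        truth = sc.genes["t7"].reindex(tab[tab.condition == "total_7min"]
                                       ["gene_id"]).to_numpy()
        got = m[tab.condition == "total_7min"].to_numpy()
        assert np.allclose(got, truth, atol=1e-9)

    def test_injected_bias_appears_in_raw_m(self):
        cfg = noise_free_config(dye_bias_amplitude=0.5)
        genome = generate_genome(cfg.simulation)
        sc = simulate_true_expression(genome, cfg.simulation)
        tab = simulate_two_color_arrays(sc, cfg.simulation)
        sub = tab[(tab.condition == "total_90min") & (tab.replicate == 1)]
        truth = sc.genes.loc[sub["gene_id"], "t90"].to_numpy()
        null = truth == 0
        m = np.log2(sub["cy3"] / sub["cy5"]).to_numpy()
        a = 0.5 * np.log2(sub["cy3"] * sub["cy5"]).to_numpy()
        expected = dye_bias(a[null], 0.5)
        assert np.allclose(m[null], expected, atol=1e-9)
        assert np.median(np.abs(m[null])) > 0.05  # bias visibly nonzero

    def test_same_seed_identical_tables(self, small_cfg, small_scenario):
        t1 = simulate_two_color_arrays(small_scenario, small_cfg.simulation)
        t2 = simulate_two_color_arrays(small_scenario, small_cfg.simulation)
        pd.testing.assert_frame_equal(t1, t2)


@pytest.fixture(scope="module")
def noise_free():
    cfg = noise_free_config()
    genome = generate_genome(cfg.simulation)
    sc = simulate_true_expression(genome, cfg.simulation)
    ev = simulate_silac_evidence(sc, genome, cfg.simulation)
    return cfg, sc, ev


class TestSilacSimulator:
    def test_noise_free_direct_ratio_equals_planted_effect(self, noise_free):
        _, sc, ev = noise_free
        quant = quantify_silac(ev).set_index("protein_id")
        shared = quant.index.intersection(sc.genes.index)
        got = quant.loc[shared, "direct_log2"]
        want = sc.genes.loc[shared, "prot90"]
        assert np.allclose(got, want, atol=1e-9)

    def test_unchanged_protein_has_identical_hl_in_both_mixes(self, noise_free):
        _, sc, ev = noise_free
        flat = sc.genes[sc.genes["prot90"] == 0].index[0]
        sub = ev[(ev.protein_ids == flat) & (ev["sample"] != "heavy_only")]
        ratios = (sub["intensity_H"] / sub["intensity_L"])
        by_sample = ratios.groupby([sub["sample"], sub["peptide"]]).mean()
        ref = by_sample["reference_mix"]
        stress = by_sample["stress_mix"]
        assert np.allclose(ref, stress.reindex(ref.index))

    def test_standard_cancellation(self, noise_free):
        cfg, sc, ev = noise_free
        scaled = ev.copy()
        scaled["intensity_H"] *= 37.5  # rescale the standard globally
        q1 = quantify_silac(ev).set_index("protein_id")["direct_log2"]
        q2 = quantify_silac(scaled).set_index("protein_id")["direct_log2"]
        assert np.allclose(q1.dropna(), q2.dropna(), atol=1e-12)

    def test_swap_antisymmetry(self, noise_free):
        _, _, ev = noise_free
        swapped = ev.copy()
        swap = {"reference_mix": "stress_mix", "stress_mix": "reference_mix"}
        swapped["sample"] = swapped["sample"].map(lambda s: swap.get(s, s))
        q1 = quantify_silac(ev).set_index("protein_id")["direct_log2"]
        q2 = quantify_silac(swapped).set_index("protein_id")["direct_log2"]
        assert np.allclose(q1.dropna(), -q2.dropna(), atol=1e-12)

    def test_incorporation_estimate_converges(self):
        cfg = small_config(seed=5, n_genes=500, n_operons=0,
                           n_5prime_operons=0, n_3prime_operons=0,
                           n_translatome_polar_operons=0)
        genome = generate_genome(cfg.simulation)
        sc = simulate_true_expression(genome, cfg.simulation)
        ev = simulate_silac_evidence(sc, genome, cfg.simulation)
        inc = incorporation_rate(ev)
        assert abs(inc["incorporation"].mean() - 0.96) < 0.01


class TestCoverage:
    def test_depth_zero_gives_empty_track(self):
        cfg = small_config(coverage_depth=0.0)
        genome = generate_genome(cfg.simulation)
        sc = simulate_true_expression(genome, cfg.simulation)
        track = simulate_rnaseq_coverage(sc, genome, cfg.simulation)
        assert track.plus.sum() == 0 and track.minus.sum() == 0

    def test_expressed_novel_orf_mean_coverage(self, small_cfg, small_genome,
                                               small_scenario):
        track = simulate_rnaseq_coverage(small_scenario, small_genome,
                                         small_cfg.simulation)
        depth = small_cfg.simulation.coverage_depth
        for orf in small_genome.novel_orfs:
            window = track.strand(orf.strand)[orf.start:orf.end]
            mean = window.mean()
            if orf.expressed:
                # Poisson error on ~100+ positions
                assert abs(mean - depth) < 5 * np.sqrt(depth / len(window)) + 1
            else:
                assert mean < 2.0  # background only

    def test_strands_are_independent(self, small_cfg, small_genome,
                                     small_scenario):
        track = simulate_rnaseq_coverage(small_scenario, small_genome,
                                         small_cfg.simulation)
        bg = small_cfg.simulation.coverage_background
        minus_genes = [g for g in small_genome.genes if g.strand == "-"
                       and not any(o.host_gene == g.gene_id
                                   for o in small_genome.novel_orfs)]
        gene = minus_genes[0]
        plus_window = track.plus[gene.start:gene.end]
        assert plus_window.mean() < bg * 5 + 1
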