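"""M/A computation, LOESS normalization, QC filtering, replicate
combination and regulation calls."""

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from expressome.arrays import (call_regulated, combine_replicates,
                               compute_ma, filter_by_avalue, loess_normalize,
                               normalize_array, quantify_experiment,
                               regulation_summary)
from expressome.genome import generate_genome
from expressome.scenario import simulate_true_expression
from expressome.simulate import dye_bias, simulate_two_color_arrays

from conftest import noise_free_config


@pytest.mark.parametrize("cy3, cy5, m, a", [
    (1024.0, 256.0, 2.0, 9.0),
    (512.0, 512.0, 0.0, 9.0),
    (2048.0, 2048.0, 0.0, 11.0),
])
def test_ma_values_on_powers_of_two(cy3, cy5, m, a):
    out = compute_ma(pd.DataFrame({"cy3": [cy3], "cy5": [cy5]}))
    assert out.loc[0, "M"] == pytest.approx(m)
    assert out.loc[0, "A"] == pytest.approx(a)


def test_nonpositive_intensity_flags_probe():
    out = compute_ma(pd.DataFrame({"cy3": [0.0, 10.0], "cy5": [10.0, 10.0]}))
    assert list(out["flag"]) == ["not_quantified", "ok"]
    assert np.isnan(out.loc[0, "M"])


@pytest.fixture(scope="module")
def biased_null_array():
    """Noise-free all-null probes carrying only the closed-form dye
    bias."""
    cfg = noise_free_config(dye_bias_amplitude=0.5)
    s = cfg.simulation
    s.n_rpoe_genes = s.n_rpoh2_genes = s.n_pulse_genes = 0
    s.n_repressed_genes = 0
    s.n_translational_only = s.n_protein_decline = 0
    s.n_5prime_operons = s.n_3prime_operons = 0
    s.n_translatome_polar_operons = 0
    genome = generate_genome(s)
    sc = simulate_true_expression(genome, s)
    tab = simulate_two_color_arrays(sc, s)
    sub = tab[(tab.condition == "total_90min") & (tab.replicate == 1)]
    m = np.log2(sub["cy3"] / sub["cy5"]).to_numpy()
    a = (0.5 * np.log2(sub["cy3"] * sub["cy5"])).to_numpy()
    return m, a


class TestLoess:
    def test_closed_form_bias_removed(self, biased_null_array):
        m, a = biased_null_array
        resid = loess_normalize(m, a)
        assert np.max(np.abs(resid)) < 0.02

    def test_no_bias_preserves_m_up_to_constant(self):
        """With zero dye-bias amplitude, normalization is close to a
        constant shift on a realistic (signal + noise) array."""
        from expressome.config import PipelineConfig
        from expressome.genome import generate_genome
        from expressome.scenario import simulate_true_expression
        cfg = PipelineConfig()
        cfg.simulation.seed = 2
        cfg.simulation.dye_bias_amplitude = 0.0
        genome = generate_genome(cfg.simulation)
        sc = simulate_true_expression(genome, cfg.simulation)
        tab = simulate_two_color_arrays(sc, cfg.simulation)
        sub = tab[(tab.condition == "total_90min") & (tab.replicate == 1)]
        m = np.log2(sub["cy3"] / sub["cy5"]).to_numpy()
        a = (0.5 * np.log2(sub["cy3"] * sub["cy5"])).to_numpy()
        m_norm = loess_normalize(m, a)
        assert stats.pearsonr(m, m_norm).statistic > 0.999

    def test_constant_m_normalizes_to_zero(self):
        a = np.linspace(8, 14, 200)
        m = np.full(200, 0.7)
        assert np.allclose(loess_normalize(m, a), 0.0, atol=1e-9)

    def test_renormalization_is_nearly_idempotent(self, biased_null_array):
        m, a = biased_null_array
        once = loess_normalize(m, a)
        twice = loess_normalize(once, a)
        removed = np.max(np.abs(m - once))
        assert np.max(np.abs(twice - once)) < 0.02
        assert np.max(np.abs(twice - once)) < removed / 5

    def test_degenerate_constant_a_falls_back_to_median(self):
        m = np.array([1.0, 2.0, 3.0, 4.0, 5.0] * 4)
        a = np.full(20, 10.0)
        assert np.allclose(loess_normalize(m, a), m - 3.0)

    def test_too_few_probes_rejected(self):
        with pytest.raises(ValueError):
            loess_normalize(np.ones(5), np.linspace(8, 14, 5))

    def test_normalization_preserves_probe_count_and_a(self, small_cfg,
                                                       small_scenario):
        tab = simulate_two_color_arrays(small_scenario, small_cfg.simulation)
        arr = tab[(tab.condition == "total_7min") & (tab.replicate == 1)]
        out = normalize_array(arr)
        assert len(out) == len(arr)
        raw = compute_ma(arr)
        assert np.allclose(out["A"], raw["A"], equal_nan=True)


class TestAFilter:
    def test_total_90min_boundary_inclusive(self):
        frame = pd.DataFrame({"A": [10.45, 10.44], "gene_id": ["a", "b"]})
        kept = filter_by_avalue(frame, "total_90min")
        assert list(kept["gene_id"]) == ["a"]

    def test_poly_90min_boundary(self):
        frame = pd.DataFrame({"A": [10.44], "gene_id": ["a"]})
        assert len(filter_by_avalue(frame, "poly_90min")) == 1

    def test_minus_infinity_cutoff_retains_all(self):
        frame = pd.DataFrame({"A": [1.0, 5.0, 20.0]})
        kept = filter_by_avalue(frame, "x", a_cutoffs={"x": -np.inf})
        assert len(kept) == 3

    def test_unknown_experiment_rejected(self):
        with pytest.raises(KeyError):
            filter_by_avalue(pd.DataFrame({"A": [11.0]}), "nope")

    def test_retention_monotone_in_a(self):
        a = np.linspace(9, 12, 100)
        frame = pd.DataFrame({"A": a})
        kept = filter_by_avalue(frame, "total_7min")["A"].to_numpy()
        assert kept.min() >= 10.27
        assert len(kept) == (a >= 10.27).sum()


class TestCombineReplicates:
    @staticmethod
    def _frame(values_by_gene):
        rows = [{"gene_id": g, "replicate": i + 1, "M_norm": v}
                for g, vals in values_by_gene.items()
                for i, v in enumerate(vals)]
        return pd.DataFrame(rows)

    def test_mean_of_identical_replicates(self):
        out = combine_replicates(self._frame({"g": [1.0, 1.0]}))
        assert out.loc[0, "log2_ratio"] == pytest.approx(1.0)

    def test_symmetric_replicates_cancel(self):
        out = combine_replicates(self._frame({"g": [0.9, -0.9]}),
                                 var_method="per_gene")
        assert out.loc[0, "log2_ratio"] == pytest.approx(0.0)
        assert out.loc[0, "p_value"] > 0.5

    def test_four_tight_replicates_are_significant(self):
        vals = [0.8 + j for j in (-0.004, -0.001, 0.002, 0.003)]
        out = combine_replicates(self._frame({"g": vals}),
                                 var_method="per_gene")
        assert out.loc[0, "p_value"] < 0.05

    def test_pooled_variance_shares_information(self):
        genes = {f"g{i}": [0.01 * ((i + j) % 3 - 1) for j in range(2)]
                 for i in range(50)}
        genes["hit"] = [1.5, 1.45]
        out = combine_replicates(self._frame(genes)).set_index("gene_id")
        assert out.loc["hit", "p_value"] < 1e-6

    def test_per_gene_zero_variance_gives_na(self):
        out = combine_replicates(self._frame({"g": [0.5, 0.5]}),
                                 var_method="per_gene")
        assert np.isnan(out.loc[0, "p_value"])


@pytest.mark.parametrize("log2, p, expected", [
    (0.80, 0.049, "up"),
    (0.79, 0.001, "unchanged"),
    (-0.8, 0.04, "down"),
    (1.2, 0.05, "unchanged"),   # p threshold strict
    (0.9, np.nan, "unchanged"),
])
def test_regulation_call_boundaries(log2, p, expected):
    rec = pd.DataFrame({"log2_ratio": [log2], "p_value": [p]})
    assert call_regulated(rec).loc[0, "call"] == expected


class TestRegulationSummary:
    @staticmethod
    def _records(n, up, down):
        calls = ["up"] * up + ["down"] * down + ["unchanged"] * (n - up - down)
        return pd.DataFrame({"call": calls,
                             "log2_ratio": np.zeros(n),
                             "p_value": np.ones(n)})

    def test_zero_up_is_zero_pct(self):
        s = regulation_summary(self._records(100, 0, 0))
        assert s["up_pct"] == 0.0

    def test_counts_partition_quantified(self, small_results):
        df = small_results["experiments"]["total_90min"]
        quantified = (df["call"] != "not_quantified").sum()
        parts = df["call"].value_counts()
        assert parts.get("up", 0) + parts.get("down", 0) \
            + parts.get("unchanged", 0) == quantified

    def test_empty_input_rejected(self):
        with pytest.raises(ValueError):
            regulation_summary(pd.DataFrame(
                {"call": ["not_quantified"], "log2_ratio": [np.nan],
                 "p_value": [np.nan]}))


def test_type_i_error_controlled_on_null_arrays():
    """All-null study: the rate of |log2|>=0.8, p<0.05 calls stays
    within the binomial CI of the (essentially zero) nominal rate."""
    cfg = noise_free_config(seed=42, array_noise_sd=0.15)
    s = cfg.simulation
    s.n_rpoe_genes = s.n_rpoh2_genes = s.n_pulse_genes = 0
    s.n_repressed_genes = s.n_translational_only = s.n_protein_decline = 0
    s.n_5prime_operons = s.n_3prime_operons = 0
    s.n_translatome_polar_operons = 0
    genome = generate_genome(s)
    sc = simulate_true_expression(genome, s)
    tab = simulate_two_color_arrays(sc, s)
    out = quantify_experiment(tab, "total_90min")
    frac = (out["call"] != "unchanged").mean()
    # |mean| >= 0.8 at null is a >7 sigma event under the noise model
    assert frac <= 0.05
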