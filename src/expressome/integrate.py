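"""Cross-layer integration of transcriptome, translatome and proteome.

Layers are compared pairwise by Pearson correlation over shared
quantified genes, and per-gene concordance is classified: a gene
regulated (|log2| >= 0.8) in at least one of the two layers is
"unidirectional" when the layers' log2 ratios differ by < 0.4 and
"biased" otherwise; unregulated genes stay "unchanged".  Directional
detectors flag translationally triggered genes (polysome induction
without a comparable transcriptome increase) and proteins declining
without a matching mRNA change.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from scipy import stats


def correlate_layers(
    values_a: pd.Series, values_b: pd.Series
) -> dict:
    """Pearson correlation over genes quantified in both layers.

    Returns n, r and r_squared (r^2 computed from the unrounded r;
    both are additionally reported at the 2-decimal output precision).
    """
    merged = pd.concat({"a": values_a, "b": values_b}, axis=1).dropna()
    n = len(merged)
    if n < 3:
        raise ValueError(f"need >= 3 shared quantified genes, got {n}")
    r = float(stats.pearsonr(merged["a"], merged["b"]).statistic)
    return {"n": n, "r": r, "r_squared": r * r,
            "r_2dp": round(r, 2), "r_squared_2dp": round(r * r, 2)}


def classify_concordance(
    values_a: pd.Series,
    values_b: pd.Series,
    p_a: pd.Series | None = None,
    p_b: pd.Series | None = None,
    reg_threshold: float = 0.8,
    diff_threshold: float = 0.4,
    alpha: float = 0.05,
) -> pd.DataFrame:
    """Per-gene concordance over a layer pair.

    A gene enters classification when |log2| >= reg_threshold in at
    least one layer (with p < alpha in that layer, when p-values are
    supplied; either-layer gating).  Genes missing either layer are
    flagged ``not_comparable``.
    """
    df = pd.concat({"log2_a": values_a, "log2_b": values_b}, axis=1)
    if p_a is not None:
        df["p_a"] = p_a
    if p_b is not None:
        df["p_b"] = p_b
    a = df["log2_a"].to_numpy(float)
    b = df["log2_b"].to_numpy(float)
    ok = np.isfinite(a) & np.isfinite(b)

    def _regulated(vals: np.ndarray, p: np.ndarray | None) -> np.ndarray:
        reg = np.abs(vals) >= reg_threshold
        if p is not None:
            reg &= np.nan_to_num(p, nan=1.0) < alpha
        return reg

    reg_a = _regulated(a, df["p_a"].to_numpy(float) if p_a is not None else None)
    reg_b = _regulated(b, df["p_b"].to_numpy(float) if p_b is not None else None)
    regulated = (reg_a | reg_b) & ok
    biased = np.abs(a - b) >= diff_threshold
    cls = np.where(regulated, np.where(biased, "biased", "unidirectional"),
                   "unchanged")
    cls = np.where(ok, cls, "not_comparable")
    df["regulated_in"] = np.select(
        [reg_a & reg_b, reg_a, reg_b], ["both", "A", "B"], default="neither")
    df.loc[~ok, "regulated_in"] = "neither"
    df["concordance"] = cls
    return df


def translationally_triggered(
    transcriptome: pd.DataFrame,
    translatome: pd.DataFrame,
    reg_threshold: float = 0.8,
    diff_threshold: float = 0.4,
    alpha: float = 0.05,
) -> pd.Index:
    """Genes induced in polysomes (log2 >= 0.8, p < 0.05) without a
    comparable transcriptome increase (signed difference >= 0.4)."""
    t = transcriptome.set_index("gene_id") if "gene_id" in transcriptome else transcriptome
    p = translatome.set_index("gene_id") if "gene_id" in translatome else translatome
    merged = p[["log2_ratio", "p_value"]].join(
        t[["log2_ratio"]], how="inner", lsuffix="_poly", rsuffix="_total")
    poly = merged["log2_ratio_poly"].to_numpy(float)
    total = merged["log2_ratio_total"].to_numpy(float)
    pv = np.nan_to_num(merged["p_value"].to_numpy(float), nan=1.0)
    mask = (poly >= reg_threshold) & (pv < alpha) \
        & (poly - total >= diff_threshold)
    return merged.index[mask]


def protein_decline_without_rna_change(
    proteome: pd.DataFrame,
    other_layer: pd.DataFrame,
    reg_threshold: float = 0.8,
    diff_threshold: float = 0.4,
    alpha: float = 0.05,
    p_column: str = "p_bh",
) -> pd.Index:
    """Proteins dropping (log2 <= -0.8, adjusted p < 0.05) while the
    RNA layer does not decline to the same extent."""
    pr = proteome.set_index("protein_id") if "protein_id" in proteome else proteome
    ot = other_layer.set_index("gene_id") if "gene_id" in other_layer else other_layer
    merged = pr[["direct_log2", p_column]].join(
        ot[["log2_ratio"]], how="inner")
    prot = merged["direct_log2"].to_numpy(float)
    rna = merged["log2_ratio"].to_numpy(float)
    pv = np.nan_to_num(merged[p_column].to_numpy(float), nan=1.0)
    mask = (prot <= -reg_threshold) & (pv < alpha) \
        & (rna - prot >= diff_threshold)
    return merged.index[mask]


def integrate_expressome(
    transcriptome: dict[str, pd.DataFrame],
    translatome: pd.DataFrame,
    proteome: pd.DataFrame,
    cluster_labels: pd.Series | None = None,
    annotations: pd.DataFrame | None = None,
    reg_threshold: float = 0.8,
    diff_threshold: float = 0.4,
) -> pd.DataFrame:
    """Master table: one row per gene over the union of all layers.

    Transcriptome is the dict of per-time-point tables; genes absent
    from a layer carry NA in that layer's columns.
    """
    pieces = []
    for key, df in transcriptome.items():
        short = key.replace("total_", "")
        if df["gene_id"].duplicated().any():
            raise ValueError(f"duplicate gene_id in layer {key}")
        piece = df.set_index("gene_id")[["log2_ratio", "p_value", "call"]]
        piece.columns = [f"total_{short}_log2", f"total_{short}_p",
                         f"total_{short}_call"]
        pieces.append(piece)
    if translatome["gene_id"].duplicated().any():
        raise ValueError("duplicate gene_id in translatome")
    poly = translatome.set_index("gene_id")[["log2_ratio", "p_value", "call"]]
    poly.columns = ["poly_90min_log2", "poly_90min_p", "poly_90min_call"]
    pieces.append(poly)
    if proteome["protein_id"].duplicated().any():
        raise ValueError("duplicate protein_id in proteome")
    prot = proteome.set_index("protein_id")[
        ["direct_log2", "p_value", "p_bh", "call"]]
    prot.index.name = "gene_id"
    prot.columns = ["silac_90min_log2", "silac_90min_p", "silac_90min_p_bh",
                    "silac_90min_call"]
    pieces.append(prot)

    master = pieces[0].join(pieces[1:], how="outer")

    conc_tp = classify_concordance(
        master["total_90min_log2"], master["poly_90min_log2"],
        reg_threshold=reg_threshold, diff_threshold=diff_threshold)
    master["conc_total_poly"] = conc_tp["concordance"]
    conc_pt = classify_concordance(
        master["silac_90min_log2"], master["total_90min_log2"],
        reg_threshold=reg_threshold, diff_threshold=diff_threshold)
    master["conc_prot_total"] = conc_pt["concordance"]
    conc_pp = classify_concordance(
        master["silac_90min_log2"], master["poly_90min_log2"],
        reg_threshold=reg_threshold, diff_threshold=diff_threshold)
    master["conc_prot_poly"] = conc_pp["concordance"]

    if cluster_labels is not None:
        master["cluster"] = cluster_labels.reindex(master.index)
    if annotations is not None:
        master = master.join(annotations, how="left")
    master.index.name = "gene_id"
    return master
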