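"""Heavy-standard SILAC protein quantification.

Each condition is measured against a common fully heavy-labeled protein
standard; the stress-vs-reference change is the "direct ratio"
(standard/reference) / (standard/stress), in which the standard cancels.
Peptide H/L ratios are aggregated per protein as the median on the log
scale with a minimum of two ratio counts; replicate direct ratios are
tested per protein (one-sample t-test against 0) and adjusted with
Benjamini-Hochberg.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests


def peptide_hl_ratios(evidence: pd.DataFrame) -> pd.DataFrame:
    """Per-row heavy/light ratio; rows with zero light intensity are
    excluded (the ratio is undefined there)."""
    ev = evidence[evidence["intensity_L"] > 0].copy()
    ev["hl_ratio"] = ev["intensity_H"] / ev["intensity_L"]
    return ev


def aggregate_protein(
    ratios: np.ndarray | pd.Series, min_ratio_count: int = 2
) -> tuple[float, int]:
    """Protein-level H/L from peptide ratios: median on the log2 scale
    (geometric for an even count).  Returns (ratio, count); the ratio is
    NaN when fewer than ``min_ratio_count`` peptide ratios exist."""
    arr = np.asarray(ratios, float)
    arr = arr[np.isfinite(arr) & (arr > 0)]
    count = arr.size
    if count < min_ratio_count:
        return (float("nan"), count)
    return (float(2.0 ** np.median(np.log2(arr))), count)


def direct_log2_ratio(hl_reference: float, hl_stress: float) -> float:
    """log2[(H/L reference) / (H/L stress)]; positive = up under stress."""
    if not (np.isfinite(hl_reference) and np.isfinite(hl_stress)):
        return float("nan")
    return float(np.log2(hl_reference) - np.log2(hl_stress))


def protein_hl_table(
    evidence: pd.DataFrame, min_ratio_count: int = 2
) -> pd.DataFrame:
    """Per (protein, sample, replicate) H/L ratios with ratio counts."""
    ev = peptide_hl_ratios(evidence)
    ev = ev[np.isfinite(ev["hl_ratio"]) & (ev["hl_ratio"] > 0)].copy()
    ev["log2_hl"] = np.log2(ev["hl_ratio"])
    agg = ev.groupby(["protein_ids", "sample", "replicate"])["log2_hl"].agg(
        ["median", "count"]).reset_index()
    agg["hl_ratio"] = np.where(agg["count"] >= min_ratio_count,
                               2.0 ** agg["median"], np.nan)
    agg = agg.rename(columns={"protein_ids": "protein_id",
                              "count": "ratio_count"})
    return agg[["protein_id", "sample", "replicate", "hl_ratio",
                "ratio_count"]]


def replicate_direct_ratios(hl_table: pd.DataFrame) -> pd.DataFrame:
    """Direct log2 ratios per protein and replicate (both mixes must be
    quantified in that replicate)."""
    ref = hl_table[hl_table["sample"] == "reference_mix"]
    stress = hl_table[hl_table["sample"] == "stress_mix"]
    merged = ref.merge(stress, on=["protein_id", "replicate"],
                       suffixes=("_ref", "_stress"))
    merged["direct_log2"] = np.log2(merged["hl_ratio_ref"]) \
        - np.log2(merged["hl_ratio_stress"])
    out = merged[["protein_id", "replicate", "direct_log2",
                  "ratio_count_ref", "ratio_count_stress"]].copy()
    return out.dropna(subset=["direct_log2"])


def protein_significance(
    direct: pd.DataFrame,
    fdr: float = 0.05,
    up: float = 0.8,
    down: float = -0.8,
) -> pd.DataFrame:
    """Per-protein t-test on replicate direct ratios, BH adjustment over
    all tested proteins, and regulation calls on the adjusted p.

    Proteins with < 2 replicate ratios get no p-value and stay
    unchanged; zero-variance replicate sets yield p = NA rather than
    spurious certainty.
    """
    rows = []
    for prot, grp in direct.groupby("protein_id"):
        vals = grp["direct_log2"].to_numpy(float)
        rec = {"protein_id": prot, "direct_log2": float(np.mean(vals)),
               "n_replicates": len(vals), "p_value": np.nan}
        if len(vals) >= 2 and np.std(vals) > 0:
            rec["p_value"] = float(stats.ttest_1samp(vals, 0.0).pvalue)
        rows.append(rec)
    table = pd.DataFrame(rows, columns=["protein_id", "direct_log2",
                                        "n_replicates", "p_value"])
    table["p_bh"] = benjamini_hochberg(table["p_value"].to_numpy())
    sig = np.nan_to_num(table["p_bh"].to_numpy(float), nan=1.0) < fdr
    ratio = table["direct_log2"].to_numpy(float)
    table["call"] = np.where((ratio >= up) & sig, "up",
                             np.where((ratio <= down) & sig, "down",
                                      "unchanged"))
    return table


def benjamini_hochberg(p_values: np.ndarray) -> np.ndarray:
    """BH step-up adjusted p-values; NaNs are passed through untested."""
    p = np.asarray(p_values, float)
    adj = np.full(p.shape, np.nan)
    mask = np.isfinite(p)
    if mask.any():
        adj[mask] = multipletests(p[mask], method="fdr_bh")[1]
    return adj


def incorporation_rate(evidence: pd.DataFrame) -> pd.DataFrame:
    """Per-protein label incorporation from the heavy-only run:
    sum(H) / (sum(H) + sum(L)); the global estimate is the mean over
    proteins."""
    heavy = evidence[evidence["sample"] == "heavy_only"]
    if heavy.empty:
        raise ValueError("no heavy_only evidence rows")
    agg = heavy.groupby("protein_ids")[["intensity_H", "intensity_L"]].sum()
    frac = agg["intensity_H"] / (agg["intensity_H"] + agg["intensity_L"])
    return frac.rename("incorporation").reset_index().rename(
        columns={"protein_ids": "protein_id"})


def quantify_silac(
    evidence: pd.DataFrame,
    min_ratio_count: int = 2,
    fdr: float = 0.05,
    up: float = 0.8,
    down: float = -0.8,
) -> pd.DataFrame:
    """Evidence table -> protein quantification with calls.

    Returns protein_id, hl_ref, count_ref, hl_stress, count_stress,
    direct_log2, n_replicates, p_value, p_bh, call (one row per protein
    with any quantified mix).
    """
    hl = protein_hl_table(evidence, min_ratio_count=min_ratio_count)
    direct = replicate_direct_ratios(hl)
    sig = protein_significance(direct, fdr=fdr, up=up, down=down)

    def _geo_mean(x: pd.Series) -> float:
        vals = x.to_numpy(float)
        vals = vals[np.isfinite(vals) & (vals > 0)]
        if vals.size == 0:
            return float("nan")
        return float(2.0 ** np.mean(np.log2(vals)))

    def _mean_hl(sample: str, name: str, cname: str) -> pd.DataFrame:
        sub = hl[hl["sample"] == sample]
        agg = sub.groupby("protein_id").agg(
            **{name: ("hl_ratio", _geo_mean), cname: ("ratio_count", "sum")})
        return agg.reset_index()

    ref = _mean_hl("reference_mix", "hl_ref", "count_ref")
    stress = _mean_hl("stress_mix", "hl_stress", "count_stress")
    out = ref.merge(stress, on="protein_id", how="outer")
    out = out.merge(sig, on="protein_id", how="left")
    out["call"] = out["call"].fillna("unchanged")
    quantified = out["direct_log2"].notna()
    out.loc[~quantified, "call"] = "not_quantified"
    return out
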