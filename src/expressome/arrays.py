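"""Two-color microarray quantification.

Per array: M/A computation, within-array LOESS normalization of M on A,
an A-value background floor per experiment, probe->gene averaging,
replicate combination into per-gene log2 ratios with p-values, and
up/down/unchanged regulation calls at |log2| >= 0.8, p < 0.05.

Replicate combination offers two error models.  The default shares the
residual variance across genes (a common-error, moderated test), which
is what makes a two-replicate design usable; ``per_gene`` performs an
ordinary one-sample t-test per gene and needs more replicates for
power.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from scipy import stats

from .config import DEFAULT_A_CUTOFFS
from .loess import loess_fit

CALLS = ("up", "down", "unchanged", "not_quantified")


def compute_ma(frame: pd.DataFrame) -> pd.DataFrame:
    """Add M = log2(cy3/cy5) and A = 0.5*log2(cy3*cy5) columns.

    Probes with a nonpositive intensity are flagged ``not_quantified``
    and carry NaN M/A; they are excluded downstream.
    """
    out = frame.copy()
    cy3 = out["cy3"].to_numpy(float)
    cy5 = out["cy5"].to_numpy(float)
    ok = (cy3 > 0) & (cy5 > 0)
    m = np.full(len(out), np.nan)
    a = np.full(len(out), np.nan)
    m[ok] = np.log2(cy3[ok] / cy5[ok])
    a[ok] = 0.5 * np.log2(cy3[ok] * cy5[ok])
    out["M"] = m
    out["A"] = a
    out["flag"] = np.where(ok, "ok", "not_quantified")
    return out


def loess_normalize(
    m: np.ndarray,
    a: np.ndarray,
    span: float = 0.3,
    iterations: int = 2,
) -> np.ndarray:
    """Return M' = M - loess_fit(A); A is untouched by construction.

    Falls back to median-centering when A is (numerically) constant,
    where a local regression is degenerate.
    """
    m = np.asarray(m, float)
    a = np.asarray(a, float)
    n = m.size
    if n < max(10, int(np.ceil(span * n))):
        raise ValueError(f"too few probes for LOESS normalization (n={n})")
    if np.ptp(a) < 1e-9:
        return m - np.median(m)
    return m - loess_fit(a, m, span=span, iterations=iterations)


def filter_by_avalue(
    frame: pd.DataFrame,
    experiment: str,
    a_cutoffs: dict[str, float] | None = None,
) -> pd.DataFrame:
    """Retain probes with A >= the experiment's background floor
    (boundary inclusive)."""
    cutoffs = DEFAULT_A_CUTOFFS if a_cutoffs is None else a_cutoffs
    if experiment not in cutoffs:
        raise KeyError(f"unknown experiment {experiment!r}; "
                       f"known: {sorted(cutoffs)}")
    return frame[frame["A"] >= cutoffs[experiment]].copy()


def normalize_array(
    frame: pd.DataFrame,
    span: float = 0.3,
    iterations: int = 2,
) -> pd.DataFrame:
    """MA transform + LOESS normalization for one physical array."""
    ma = compute_ma(frame)
    ok = ma["flag"] == "ok"
    m_norm = np.full(len(ma), np.nan)
    m_norm[ok.to_numpy()] = loess_normalize(
        ma.loc[ok, "M"].to_numpy(), ma.loc[ok, "A"].to_numpy(),
        span=span, iterations=iterations)
    ma["M_norm"] = m_norm
    return ma


def combine_replicates(
    per_replicate: pd.DataFrame,
    var_method: str = "pooled",
) -> pd.DataFrame:
    """Combine replicate gene-level normalized ratios.

    ``per_replicate`` needs columns gene_id, replicate, M_norm (probes
    already averaged per gene).  Returns gene_id, log2_ratio (replicate
    mean), n_reps and a two-sided p-value against zero.  Genes surviving
    in a single replicate keep their ratio but get no p-value (their
    call is later forced to ``unchanged``).
    """
    if var_method not in ("pooled", "per_gene"):
        raise ValueError(f"unknown var_method {var_method!r}")
    grouped = per_replicate.groupby("gene_id")["M_norm"]
    stats_df = grouped.agg(log2_ratio="mean", n_reps="count", sd="std")
    stats_df = stats_df.reset_index()
    n = stats_df["n_reps"].to_numpy(float)
    mean = stats_df["log2_ratio"].to_numpy(float)
    sd = stats_df["sd"].to_numpy(float)

    p = np.full(len(stats_df), np.nan)
    multi = n >= 2
    if var_method == "pooled":
        # common error model: residual variance pooled across genes
        df_resid = float(np.sum(n[multi] - 1))
        if df_resid > 0:
            pooled_var = float(np.sum((sd[multi] ** 2) * (n[multi] - 1))
                               / df_resid)
            if pooled_var > 0:
                t = mean[multi] / np.sqrt(pooled_var / n[multi])
                p[multi] = 2 * stats.t.sf(np.abs(t), df_resid)
            else:
                p[multi] = np.where(mean[multi] == 0, 1.0, 0.0)
    else:
        with np.errstate(divide="ignore", invalid="ignore"):
            t = mean[multi] / (sd[multi] / np.sqrt(n[multi]))
        p_multi = 2 * stats.t.sf(np.abs(t), n[multi] - 1)
        p_multi[sd[multi] == 0] = np.nan  # zero variance: undefined
        p[multi] = p_multi
    stats_df["p_value"] = p
    return stats_df.drop(columns=["sd"])


def call_regulated(
    records: pd.DataFrame,
    up: float = 0.8,
    down: float = -0.8,
    alpha: float = 0.05,
    p_column: str = "p_value",
) -> pd.DataFrame:
    """Assign up/down/unchanged; ratio thresholds inclusive, p strict."""
    out = records.copy()
    ratio = out["log2_ratio"].to_numpy(float)
    p = out[p_column].to_numpy(float)
    sig = np.nan_to_num(p, nan=1.0) < alpha
    call = np.where((ratio >= up) & sig, "up",
                    np.where((ratio <= down) & sig, "down", "unchanged"))
    call = np.where(np.isnan(ratio), "not_quantified", call)
    out["call"] = call
    return out


def regulation_summary(records: pd.DataFrame) -> dict:
    """Counts and percentages of regulated genes among quantified ones.

    Percentages are 100 * count / quantified, rounded to one decimal.
    """
    quantified = records[records["call"] != "not_quantified"]
    n = len(quantified)
    if n == 0:
        raise ValueError("no quantified genes")
    n_up = int((quantified["call"] == "up").sum())
    n_down = int((quantified["call"] == "down").sum())
    return {
        "quantified": n,
        "up": n_up,
        "up_pct": round(100.0 * n_up / n, 1),
        "down": n_down,
        "down_pct": round(100.0 * n_down / n, 1),
    }


def quantify_experiment(
    intensities: pd.DataFrame,
    experiment: str,
    a_cutoffs: dict[str, float] | None = None,
    span: float = 0.3,
    iterations: int = 2,
    var_method: str = "pooled",
    up: float = 0.8,
    down: float = -0.8,
    alpha: float = 0.05,
) -> pd.DataFrame:
    """Full per-experiment pipeline: normalize each replicate array,
    apply the A floor, average probes per gene, combine replicates and
    call regulation.  Genes failing QC everywhere are reported as
    ``not_quantified``."""
    sub = intensities[intensities["condition"] == experiment]
    if sub.empty:
        raise ValueError(f"no probes for experiment {experiment!r}")
    all_genes = pd.Index(sub["gene_id"].unique(), name="gene_id")
    per_rep = []
    for rep, arr in sub.groupby("replicate"):
        norm = normalize_array(arr, span=span, iterations=iterations)
        norm = norm[norm["flag"] == "ok"]
        kept = filter_by_avalue(norm, experiment, a_cutoffs)
        gene_m = kept.groupby("gene_id")["M_norm"].mean().reset_index()
        gene_m["replicate"] = rep
        per_rep.append(gene_m)
    combined = combine_replicates(pd.concat(per_rep, ignore_index=True),
                                  var_method=var_method)
    combined = combined.set_index("gene_id").reindex(all_genes).reset_index()
    combined["n_reps"] = combined["n_reps"].fillna(0).astype(int)
    # single-replicate genes: ratio kept, no p-value, call unchanged
    combined = call_regulated(combined, up=up, down=down, alpha=alpha)
    combined.loc[combined["n_reps"] == 1, "call"] = "unchanged"
    combined["layer"] = "translatome" if experiment.startswith("poly") \
        else "transcriptome"
    combined["experiment"] = experiment
    return combined
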