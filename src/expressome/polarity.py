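"""Operon expression polarity.

Stress-induced operons often show a staircase pattern along gene order:
log2 ratios falling from the first to the last transcribed gene (5'
polarity) or rising (3' polarity).  The call combines a rank trend
(Spearman correlation of value against gene position) with a magnitude
gate on the first-minus-last difference, so that flat-but-noisy operons
are not over-called; for two-gene operons the rank trend is +/-1 by
construction and the magnitude gate alone decides.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from scipy import stats

from .genome import OperonDefinition


def _ordered_values(
    operon: OperonDefinition, values: pd.Series
) -> tuple[list[str], np.ndarray]:
    present = [g for g in operon.gene_ids
               if g in values.index and np.isfinite(values.get(g, np.nan))]
    return present, np.asarray([values[g] for g in present], float)


def call_polarity(
    operon: OperonDefinition,
    values: pd.Series,
    epsilon: float = 0.4,
    rho_threshold: float = 0.5,
) -> dict:
    """Polarity call for one operon on one layer.

    ``values`` maps gene_id -> log2 ratio (or log2 level).  5prime when
    the position-value Spearman trend <= -rho and first-last >= epsilon;
    3prime for the mirrored condition; otherwise none.  Operons with
    fewer than two quantified members get no call.
    """
    genes, vals = _ordered_values(operon, values)
    if len(vals) < 2:
        return {"operon_id": operon.operon_id, "call": "no_call",
                "trend": float("nan"), "strength": float("nan"),
                "n_genes": len(vals), "genes": genes}
    pos = np.arange(1, len(vals) + 1)
    if np.ptp(vals) == 0:
        rho = 0.0
    else:
        rho = float(stats.spearmanr(pos, vals).statistic)
    strength = float(vals[0] - vals[-1])
    call = "none"
    if rho <= -rho_threshold and strength >= epsilon:
        call = "5prime"
    elif rho >= rho_threshold and -strength >= epsilon:
        call = "3prime"
    return {"operon_id": operon.operon_id, "call": call, "trend": rho,
            "strength": strength, "n_genes": len(vals), "genes": genes}


def polarity_strength(operon: OperonDefinition, values: pd.Series) -> float:
    """First-gene minus last-gene value (positive = 5'-polar)."""
    _, vals = _ordered_values(operon, values)
    if len(vals) < 2:
        return float("nan")
    return float(vals[0] - vals[-1])


def compare_prepost_polarity(
    operon: OperonDefinition,
    levels_0min: pd.Series,
    levels_90min: pd.Series,
) -> dict:
    """Polarity strength before vs after stress on log2 expression
    LEVELS (not ratios); positive delta means polarity is induced by
    stress.  Genes missing at either time-point are excluded pairwise.
    """
    shared = [g for g in operon.gene_ids
              if np.isfinite(levels_0min.get(g, np.nan))
              and np.isfinite(levels_90min.get(g, np.nan))]
    if len(shared) < 2:
        return {"operon_id": operon.operon_id, "strength_0": float("nan"),
                "strength_90": float("nan"), "delta": float("nan")}
    v0 = np.asarray([levels_0min[g] for g in shared], float)
    v90 = np.asarray([levels_90min[g] for g in shared], float)
    s0 = float(v0[0] - v0[-1])
    s90 = float(v90[0] - v90[-1])
    return {"operon_id": operon.operon_id, "strength_0": s0,
            "strength_90": s90, "delta": s90 - s0}


def call_polarity_all(
    operons: list[OperonDefinition],
    values: pd.Series,
    layer: str,
    epsilon: float = 0.4,
    rho_threshold: float = 0.5,
) -> pd.DataFrame:
    rows = []
    for op in operons:
        rec = call_polarity(op, values, epsilon=epsilon,
                            rho_threshold=rho_threshold)
        rec["layer"] = layer
        rec.pop("genes")
        rows.append(rec)
    return pd.DataFrame(rows, columns=["operon_id", "layer", "call", "trend",
                                       "strength", "n_genes"])


def polarity_concordance_across_layers(
    calls_by_layer: dict[str, pd.DataFrame],
) -> pd.DataFrame:
    """Agreement of polarity calls between layers, flagging operons
    polar on the translatome but not the transcriptome (post-
    transcriptional polarity)."""
    layers = list(calls_by_layer)
    if len(layers) < 2:
        raise ValueError("need calls from >= 2 layers")
    merged = None
    for layer, df in calls_by_layer.items():
        piece = df.set_index("operon_id")[["call"]].rename(
            columns={"call": f"call_{layer}"})
        merged = piece if merged is None else merged.join(piece, how="outer")
    out = merged.reset_index()
    if {"call_transcriptome", "call_translatome"} <= set(out.columns):
        t = out["call_transcriptome"].fillna("no_call")
        p = out["call_translatome"].fillna("no_call")
        out["agree"] = t == p
        out["translatome_only_polarity"] = (
            p.isin(["5prime", "3prime"]) & (t == "none"))
    return out
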