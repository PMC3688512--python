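"""End-to-end pipeline: simulate -> quantify -> integrate -> evaluate.

`run_simulate` writes a complete fixture bundle (genome, annotation,
truth tables, array intensities, peptide evidence, coverage tracks) to
an output directory; `run_full` runs every analysis stage over such a
bundle (simulated or user-supplied) and writes all result tables;
`evaluate_against_truth` scores the results against the planted truth.
"""

from __future__ import annotations

import hashlib
import json
import logging
import time
from pathlib import Path

import numpy as np
import pandas as pd

from . import arrays, integrate, kinetics, polarity, proteogenomics, silac
from .config import ARRAY_CONDITIONS, PipelineConfig
from .genome import (SyntheticGenome, generate_genome, read_gff3_operons,
                     write_genome_fasta, write_gff3, write_proteome_fasta)
from .scenario import simulate_true_expression
from .simulate import (simulate_rnaseq_coverage, simulate_silac_evidence,
                       simulate_two_color_arrays)
from .tracks import read_track, write_track

log = logging.getLogger("expressome")

BUNDLE_FILES = (
    "genome.fasta", "proteome.fasta", "annotation.gff3",
    "truth_genes.tsv", "truth_operons.tsv", "truth_novel_orfs.tsv",
    "array_intensities.tsv", "peptide_evidence.tsv",
    "coverage_plus.bedgraph", "coverage_minus.bedgraph",
)


def _sha256(path: Path) -> str:
    h = hashlib.sha256()
    h.update(path.read_bytes())
    return h.hexdigest()


def write_manifest(outdir: Path, config: PipelineConfig, files: list[Path]) -> None:
    manifest = {
        "seed": config.simulation.seed,
        "config_sha256": hashlib.sha256(
            json.dumps(config.to_dict(), sort_keys=True).encode()).hexdigest(),
        "checksums": {f.name: _sha256(f) for f in sorted(files)},
    }
    (outdir / "manifest.json").write_text(json.dumps(manifest, indent=2))


def run_simulate(config: PipelineConfig, outdir: str | Path) -> dict:
    """Generate the in-silico study and write the fixture bundle."""
    config.validate()
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    t0 = time.time()

    genome = generate_genome(config.simulation)
    scenario = simulate_true_expression(genome, config.simulation)
    intensities = simulate_two_color_arrays(scenario, config.simulation)
    evidence = simulate_silac_evidence(scenario, genome, config.simulation)
    track = simulate_rnaseq_coverage(scenario, genome, config.simulation)

    write_genome_fasta(genome, outdir / "genome.fasta")
    write_proteome_fasta(genome, outdir / "proteome.fasta")
    write_gff3(genome, outdir / "annotation.gff3")
    scenario.genes.reset_index().to_csv(outdir / "truth_genes.tsv",
                                        sep="\t", index=False)
    scenario.operons.to_csv(outdir / "truth_operons.tsv", sep="\t", index=False)
    scenario.novel_orfs.to_csv(outdir / "truth_novel_orfs.tsv", sep="\t",
                               index=False)
    intensities.to_csv(outdir / "array_intensities.tsv", sep="\t", index=False)
    evidence.to_csv(outdir / "peptide_evidence.tsv", sep="\t", index=False)
    write_track(track, outdir / "coverage")
    write_manifest(outdir, config, [outdir / f for f in BUNDLE_FILES])
    log.info("simulate: wrote bundle to %s in %.1fs", outdir, time.time() - t0)
    return {"genome": genome, "scenario": scenario,
            "intensities": intensities, "evidence": evidence, "track": track}


def _genome_length(fasta: Path) -> tuple[str, int]:
    name, total = "genome", 0
    for line in fasta.read_text().splitlines():
        if line.startswith(">"):
            name = line[1:].split()[0]
        else:
            total += len(line.strip())
    return name, total


def _read_fasta(path: Path) -> dict[str, str]:
    records: dict[str, list[str]] = {}
    current = None
    for line in path.read_text().splitlines():
        if line.startswith(">"):
            current = line[1:].split()[0]
            records[current] = []
        elif current is not None:
            records[current].append(line.strip())
    return {k: "".join(v) for k, v in records.items()}


def run_full(config: PipelineConfig, bundle_dir: str | Path,
             outdir: str | Path | None = None) -> dict:
    """Run every analysis stage over a fixture bundle."""
    config.validate()
    bundle_dir = Path(bundle_dir)
    outdir = Path(outdir) if outdir is not None else bundle_dir / "results"
    outdir.mkdir(parents=True, exist_ok=True)
    results: dict = {}
    t0 = time.time()

    # --- microarray layers -------------------------------------------------
    intensities = pd.read_csv(bundle_dir / "array_intensities.tsv", sep="\t")
    experiments: dict[str, pd.DataFrame] = {}
    for condition in ARRAY_CONDITIONS:
        experiments[condition] = arrays.quantify_experiment(
            intensities, condition, a_cutoffs=config.a_cutoffs,
            span=config.loess_span, iterations=config.loess_iterations,
            var_method=config.array_var_method, up=config.reg_threshold,
            down=-config.reg_threshold, alpha=config.p_threshold)
        log.info("arrays: %s quantified (%.1fs)", condition, time.time() - t0)
    results["experiments"] = experiments
    ratio_rows = []
    for condition, df in experiments.items():
        d = df.copy()
        d["time_min"] = int(condition.split("_")[1].replace("min", ""))
        ratio_rows.append(d[["gene_id", "experiment", "layer", "time_min",
                             "log2_ratio", "p_value", "call"]])
    pd.concat(ratio_rows, ignore_index=True).to_csv(
        outdir / "gene_ratios.tsv", sep="\t", index=False)

    # --- SILAC proteome ----------------------------------------------------
    evidence = pd.read_csv(bundle_dir / "peptide_evidence.tsv", sep="\t")
    proteome = silac.quantify_silac(
        evidence, min_ratio_count=config.min_ratio_count, fdr=config.bh_fdr,
        up=config.reg_threshold, down=-config.reg_threshold)
    proteome.to_csv(outdir / "protein_quant.tsv", sep="\t", index=False)
    incorporation = silac.incorporation_rate(evidence)
    results["proteome"] = proteome
    results["incorporation"] = incorporation
    log.info("silac: %d proteins (%.1fs)", len(proteome), time.time() - t0)

    # --- kinetics clustering ----------------------------------------------
    tc = kinetics.make_timecourses(experiments)
    induced = kinetics.select_induced(tc, threshold=config.reg_threshold,
                                      alpha=config.p_threshold)
    seed = config.simulation.seed
    cluster_labels = pd.Series(dtype=object, name="cluster")
    clusters = None
    complete = induced[list(kinetics.RATIO_COLS)].dropna()
    if len(complete) >= config.kmeans_k:
        clusters = kinetics.kmeans_cluster(
            induced, k=config.kmeans_k, seed=seed,
            max_iter=config.kmeans_max_iter)
        cluster_labels = clusters.assignments.copy()
        largest = cluster_labels.value_counts().index[0]
        members = cluster_labels[cluster_labels == largest]
        if len(members) >= config.kmeans_sub_k:
            sub = kinetics.subdivide_cluster(
                induced, clusters, largest, config.kmeans_sub_k, seed=seed)
            cluster_labels.loc[sub.assignments.index] = sub.assignments
    results["timecourses"] = tc
    results["induced"] = induced
    results["clusters"] = clusters
    results["cluster_labels"] = cluster_labels
    results["core_set"] = kinetics.core_set(tc)
    cluster_labels.rename("cluster").to_frame().reset_index().rename(
        columns={"index": "gene_id"}).to_csv(
        outdir / "cluster_assignments.tsv", sep="\t", index=False)

    # regulon kinetics from GFF3 regulon attributes
    regulon_members = _read_regulons(bundle_dir / "annotation.gff3")
    results["regulon_kinetics"] = {
        name: kinetics.regulon_kinetics(members, tc,
                                        threshold=config.reg_threshold)
        for name, members in regulon_members.items()}
    pd.DataFrame([
        {"regulon": name, "n": prof["n"],
         **{f"mean_log2_{t}": prof["mean_log2"][t] for t in (7, 45, 90)}}
        for name, prof in results["regulon_kinetics"].items()
    ]).to_csv(outdir / "regulon_kinetics.tsv", sep="\t", index=False)

    # --- integration -------------------------------------------------------
    total90 = experiments["total_90min"].set_index("gene_id")
    poly90 = experiments["poly_90min"].set_index("gene_id")
    prot = proteome.set_index("protein_id")
    correlations = []
    for name, a, b in (
        ("total_vs_poly", total90["log2_ratio"], poly90["log2_ratio"]),
        ("prot_vs_total", prot["direct_log2"], total90["log2_ratio"]),
        ("prot_vs_poly", prot["direct_log2"], poly90["log2_ratio"]),
    ):
        corr = integrate.correlate_layers(a, b)
        corr["pair"] = name
        correlations.append(corr)
    correlations = pd.DataFrame(correlations)
    correlations.to_csv(outdir / "layer_correlations.tsv", sep="\t",
                        index=False)
    results["correlations"] = correlations

    master = integrate.integrate_expressome(
        {k: v for k, v in experiments.items() if k.startswith("total")},
        experiments["poly_90min"], proteome,
        cluster_labels=cluster_labels,
        reg_threshold=config.reg_threshold,
        diff_threshold=config.diff_threshold)
    master.reset_index().to_csv(outdir / "expressome_master.tsv", sep="\t",
                                index=False)
    results["master"] = master
    results["triggered"] = integrate.translationally_triggered(
        experiments["total_90min"], experiments["poly_90min"],
        reg_threshold=config.reg_threshold,
        diff_threshold=config.diff_threshold, alpha=config.p_threshold)
    results["protein_decline"] = integrate.protein_decline_without_rna_change(
        proteome, experiments["total_90min"],
        reg_threshold=config.reg_threshold,
        diff_threshold=config.diff_threshold, alpha=config.bh_fdr)

    # Table-1-like regulation summary
    summary_rows = []
    for condition, df in experiments.items():
        s = arrays.regulation_summary(df)
        s["experiment"] = condition
        summary_rows.append(s)
    s = arrays.regulation_summary(
        proteome.rename(columns={"direct_log2": "log2_ratio"}))
    s["experiment"] = "silac_90min"
    summary_rows.append(s)
    summary = pd.DataFrame(summary_rows)[
        ["experiment", "quantified", "up", "up_pct", "down", "down_pct"]]
    summary.to_csv(outdir / "regulation_summary.tsv", sep="\t", index=False)
    results["summary"] = summary
    log.info("integrate: master table %d genes (%.1fs)", len(master),
             time.time() - t0)

    # --- operon polarity ---------------------------------------------------
    operons = read_gff3_operons(bundle_dir / "annotation.gff3")
    calls_by_layer = {
        "transcriptome": polarity.call_polarity_all(
            operons, total90["log2_ratio"], "transcriptome",
            epsilon=config.polarity_epsilon, rho_threshold=config.polarity_rho),
        "translatome": polarity.call_polarity_all(
            operons, poly90["log2_ratio"], "translatome",
            epsilon=config.polarity_epsilon, rho_threshold=config.polarity_rho),
        "proteome": polarity.call_polarity_all(
            operons, prot["direct_log2"], "proteome",
            epsilon=config.polarity_epsilon, rho_threshold=config.polarity_rho),
    }
    pd.concat(calls_by_layer.values(), ignore_index=True).to_csv(
        outdir / "polarity_calls.tsv", sep="\t", index=False)
    results["polarity"] = calls_by_layer
    results["polarity_concordance"] = \
        polarity.polarity_concordance_across_layers(calls_by_layer)

    # pre/post polarity on expression levels (log2 Cy5 at 0 min vs log2
    # Cy3 at 90 min, replicate-averaged)
    t90_int = intensities[intensities["condition"] == "total_90min"]
    levels0 = np.log2(t90_int.groupby("gene_id")["cy5"].mean())
    levels90 = np.log2(t90_int.groupby("gene_id")["cy3"].mean())
    prepost = pd.DataFrame([
        polarity.compare_prepost_polarity(op, levels0, levels90)
        for op in operons])
    prepost.to_csv(outdir / "polarity_prepost.tsv", sep="\t", index=False)
    results["polarity_prepost"] = prepost

    # --- proteogenomics ----------------------------------------------------
    genome_seqs = _read_fasta(bundle_dir / "genome.fasta")
    replicon, sequence = next(iter(genome_seqs.items()))
    orf_db = proteogenomics.six_frame_translate(
        sequence, replicon=replicon, min_aa=config.min_orf_aa)
    annotated = _read_fasta(bundle_dir / "proteome.fasta")
    track = read_track(bundle_dir / "coverage", replicon, len(sequence))
    novel_calls = proteogenomics.call_novel_orfs(
        evidence, annotated, orf_db, track=track,
        min_novel_peptides=config.min_novel_peptides,
        min_mean=config.coverage_min_mean, min_frac=config.coverage_min_frac)
    novel_calls.to_csv(outdir / "novel_orf_calls.tsv", sep="\t", index=False)
    proteogenomics.write_orf_fasta(orf_db, outdir / "orf_database.fasta")
    results["orf_db"] = orf_db
    results["novel_calls"] = novel_calls
    log.info("full pipeline done in %.1fs", time.time() - t0)
    return results


def _read_regulons(gff3: Path) -> dict[str, list[str]]:
    members: dict[str, list[str]] = {"RpoE": [], "RpoH2": []}
    for line in gff3.read_text().splitlines():
        if line.startswith("#") or not line.strip():
            continue
        attrs = dict(kv.split("=", 1)
                     for kv in line.split("\t")[8].split(";") if "=" in kv)
        reg = attrs.get("regulon", "none")
        if reg in members:
            members[reg].append(attrs["ID"])
    return members


def load_results(results_dir: str | Path) -> dict:
    """Reconstruct the evaluation-relevant result frames from a results
    directory written by ``run_full`` (or the stage subcommands)."""
    results_dir = Path(results_dir)
    ratios = pd.read_csv(results_dir / "gene_ratios.tsv", sep="\t")
    experiments = {exp: df.reset_index(drop=True)
                   for exp, df in ratios.groupby("experiment")}
    proteome = pd.read_csv(results_dir / "protein_quant.tsv", sep="\t")
    master = pd.read_csv(results_dir / "expressome_master.tsv",
                         sep="\t").set_index("gene_id")
    pol = pd.read_csv(results_dir / "polarity_calls.tsv", sep="\t")
    polarity_calls = {layer: df.reset_index(drop=True)
                      for layer, df in pol.groupby("layer")}
    novel = pd.read_csv(results_dir / "novel_orf_calls.tsv", sep="\t")
    return {
        "experiments": experiments,
        "proteome": proteome,
        "master": master,
        "polarity": polarity_calls,
        "polarity_concordance":
            polarity.polarity_concordance_across_layers(polarity_calls),
        "novel_calls": novel,
    }


# ---------------------------------------------------------------------------
# Evaluation against planted truth

def _sens_prec(true_pos: pd.Index, called_pos: pd.Index,
               universe: pd.Index) -> dict:
    true_pos = pd.Index(true_pos).intersection(universe)
    called_pos = pd.Index(called_pos).intersection(universe)
    tp = len(true_pos.intersection(called_pos))
    sens = tp / len(true_pos) if len(true_pos) else float("nan")
    prec = tp / len(called_pos) if len(called_pos) else float("nan")
    return {"n_true": len(true_pos), "n_called": len(called_pos),
            "sensitivity": sens, "precision": prec}


def evaluate_against_truth(results: dict, truth_genes: pd.DataFrame,
                           truth_operons: pd.DataFrame,
                           truth_novel: pd.DataFrame,
                           reg_threshold: float = 0.8) -> dict:
    """Sensitivity/precision of every call type against the planted
    truth.  Call recovery is assessed among genes quantified in the
    relevant layer (a probe below the A floor cannot be called)."""
    truth = truth_genes.set_index("gene_id")
    metrics: dict = {}

    layer_specs = [
        ("total_7min", "t7", results["experiments"]["total_7min"]),
        ("total_45min", "t45", results["experiments"]["total_45min"]),
        ("total_90min", "t90", results["experiments"]["total_90min"]),
        ("poly_90min", "poly90", results["experiments"]["poly_90min"]),
    ]
    for name, col, df in layer_specs:
        d = df.set_index("gene_id")
        quantified = d.index[d["call"] != "not_quantified"]
        te = truth[col].reindex(quantified)
        for direction, sign in (("up", 1), ("down", -1)):
            true_set = te.index[sign * te >= reg_threshold]
            called = d.index[d["call"] == direction]
            metrics[f"{name}_{direction}"] = _sens_prec(
                true_set, called, quantified)

    prot = results["proteome"].set_index("protein_id")
    prot = prot[prot.index.isin(truth.index)]
    quantified = prot.index[prot["call"] != "not_quantified"]
    te = truth["prot90"].reindex(quantified)
    for direction, sign in (("up", 1), ("down", -1)):
        true_set = te.index[sign * te >= reg_threshold]
        called = prot.index[prot["call"] == direction]
        metrics[f"silac_90min_{direction}"] = _sens_prec(
            true_set, called, quantified)

    # concordance classes per pair
    master = results["master"]
    for pair, a_col, b_col in (
        ("conc_total_poly", "total_90min_log2", "poly_90min_log2"),
        ("conc_prot_total", "silac_90min_log2", "total_90min_log2"),
        ("conc_prot_poly", "silac_90min_log2", "poly_90min_log2"),
    ):
        both = master.index[master[a_col].notna() & master[b_col].notna()]
        both = both.intersection(truth.index)
        for cls in ("unidirectional", "biased"):
            true_set = truth.index[truth[pair] == cls]
            called = master.index[master[pair] == cls]
            metrics[f"{pair}_{cls}"] = _sens_prec(true_set, called, both)

    # polarity per layer
    t_ops = truth_operons.set_index("operon_id")
    for layer, calls in results["polarity"].items():
        calls = calls.set_index("operon_id")
        if layer == "translatome":
            truth_map = t_ops["polarity_class"].replace(
                {"translatome_5prime": "5prime"})
        else:
            truth_map = t_ops["polarity_class"].replace(
                {"translatome_5prime": "none"})
        called_ops = calls.index[calls["call"] != "no_call"]
        tp = sum(calls.loc[op, "call"] == truth_map.get(op, "none")
                 and truth_map.get(op) in ("5prime", "3prime")
                 for op in called_ops)
        n_true = int(truth_map.reindex(called_ops).isin(
            ["5prime", "3prime"]).sum())
        n_called = int(calls.loc[called_ops, "call"].isin(
            ["5prime", "3prime"]).sum())
        metrics[f"polarity_{layer}"] = {
            "n_true": n_true, "n_called": n_called,
            "sensitivity": tp / n_true if n_true else float("nan"),
            "precision": tp / n_called if n_called else float("nan")}

    # translatome-only polarity flags
    conc = results["polarity_concordance"].set_index("operon_id")
    if "translatome_only_polarity" in conc.columns:
        true_set = t_ops.index[t_ops["polarity_class"] == "translatome_5prime"]
        called = conc.index[conc["translatome_only_polarity"].fillna(False)]
        metrics["translatome_only_polarity"] = _sens_prec(
            true_set, called, pd.Index(t_ops.index))

    # novel ORFs: a call hits a planted ORF when its six-frame span
    # contains the planted span on the same strand
    calls = results["novel_calls"]
    planted = truth_novel
    hits: dict[str, set[str]] = {}
    false_calls = []
    for row in calls.itertuples(index=False):
        matched = planted[(planted["strand"] == row.strand)
                          & (planted["start"] >= row.start)
                          & (planted["end"] <= row.end)]
        if len(matched) == 0:
            false_calls.append(row.orf_id)
        for orf_id in matched["orf_id"]:
            status = getattr(row, "rnaseq_status", None)
            hits.setdefault(orf_id, set()).add(status or "called")
    expressed = planted[planted["expressed"].astype(bool)]
    n_supported = sum("supported" in hits.get(o, set())
                      for o in expressed["orf_id"])
    metrics["novel_orfs"] = {
        "n_planted": int(len(planted)),
        "n_expressed": int(len(expressed)),
        "n_called": int(len(calls)),
        "n_supported_calls": int(
            (calls.get("rnaseq_status") == "supported").sum())
        if "rnaseq_status" in calls else 0,
        "recovered_expressed_as_supported": int(n_supported),
        "sensitivity": n_supported / len(expressed) if len(expressed)
        else float("nan"),
        "false_novel_calls": len(false_calls),
    }
    return metrics
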