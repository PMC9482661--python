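"""End-to-end orchestration over a study directory or in-memory study.

Stitches the stage modules together in the canonical order: replicate
consensus -> temporal classification -> annotation -> expression clustering
-> differential expression -> chromatin states -> differential binding ->
concordance integration -> motif enrichment. All outputs are deterministic
given the config seed.
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import pandas as pd

from cistrack import chromatin, expression, integrate, motifs, temporal
from cistrack.config import AnalysisConfig, STAGES
from cistrack.intervals import PeakSet, consensus_frame, consensus_peaks
from cistrack.io import write_peak_file, write_results_table
from cistrack.simulate import SyntheticStudy
from cistrack.temporal import membership_label


def consensus_all(
    study: SyntheticStudy, cfg: AnalysisConfig
) -> dict[tuple[str, str, str], pd.DataFrame]:
    """Replicate-consensus peaks for every (mark, stage, genotype) present."""
    groups: dict[tuple[str, str, str], list[PeakSet]] = {}
    for (mark, stage, genotype, rep), df in sorted(study.peak_files.items()):
        groups.setdefault((mark, stage, genotype), []).append(
            PeakSet(intervals=df, mark=mark, stage=stage, genotype=genotype, replicate=rep)
        )
    out = {}
    for key in sorted(groups):
        mark, stage, genotype = key
        peaks = consensus_peaks(groups[key], cfg)
        out[key] = consensus_frame(peaks, prefix=f"{mark}_{stage}_{genotype}")
    return out


def run_pipeline(
    study: SyntheticStudy,
    cfg: AnalysisConfig,
    outdir: str | Path | None = None,
) -> dict:
    """Run the full analysis on a study; optionally write every result table."""
    results: dict = {}

    consensus = consensus_all(study, cfg)
    results["consensus"] = consensus

    chd2_wt = {s: consensus[("CHD2", s, "WT")] for s in STAGES}
    classes = temporal.classify_temporal(chd2_wt, cfg)
    results["classes"] = classes

    all_chd2 = pd.concat(chd2_wt.values(), ignore_index=True)
    annotations = temporal.annotate_peaks(all_chd2, study.gene_models, cfg)
    results["annotations"] = annotations

    unique_promoter_genes = {
        s: temporal.stage_unique_promoter_genes(classes, annotations, s) for s in STAGES
    }
    results["unique_promoter_genes"] = unique_promoter_genes

    # expression clustering on WT dynamic genes; k-means runs on log2 relative
    # profiles so multiplicative count noise is homoscedastic across shapes
    rpkm = expression.stage_mean_rpkm(study.rna, genotype="WT")
    dynamic = expression.filter_dynamic_genes(rpkm, cfg)
    profiles = expression.d0_relative(rpkm.loc[sorted(dynamic)], cfg.rpkm_pseudocount)
    model = expression.fit_clusters(np.log2(profiles), cfg)
    results["cluster_model"] = model
    results["rpkm"] = rpkm

    results["cluster_distribution"] = {
        s: integrate.cluster_distribution(unique_promoter_genes[s], model) for s in STAGES
    }

    # differential expression HET vs WT at D35
    meta = study.rna.samples
    wt35 = list(meta.index[(meta["stage"] == "D35") & (meta["genotype"] == "WT")])
    het35 = list(meta.index[(meta["stage"] == "D35") & (meta["genotype"] == "HET")])
    degs = expression.differential_expression(study.rna, wt35, het35, cfg)
    results["degs"] = degs

    # chromatin states over the merged WT CHD2 universe
    universe = chromatin.merge_intervals(list(chd2_wt.values()))
    histone_sets = {
        (m, s): consensus[(m, s, "WT")]
        for m in chromatin.STATE_MARKS
        for s in STAGES
        if (m, s, "WT") in consensus
    }
    states = chromatin.call_states(universe, histone_sets, cfg)
    results["states"] = states
    results["transitions"] = chromatin.tabulate_transitions(states)

    # differential binding on the K27ac union counts (D35, HET vs WT)
    kmeta = study.k27ac_samples
    kwt = list(kmeta.index[kmeta["genotype"] == "WT"])
    khet = list(kmeta.index[kmeta["genotype"] == "HET"])
    dbr_table = chromatin.differential_binding(study.k27ac_counts, kwt, khet, cfg)
    dbr_table = study.k27ac_union.set_index("name").join(dbr_table).reset_index()
    results["dbr_table"] = dbr_table
    dbrs = dbr_table[dbr_table["direction"] != "ns"].reset_index(drop=True)

    records, summary = integrate.concordant_triples(
        dbrs, degs, classes, all_chd2, study.gene_models.tss_table, cfg
    )
    results["concordance"] = records
    results["concordance_summary"] = summary

    # motif enrichment: D35-unique consensus peaks vs GC-matched background
    fg_names = [p for p, m in classes.items() if m == frozenset(["D35"])]
    fg_peaks = all_chd2[all_chd2["name"].isin(fg_names)].reset_index(drop=True)
    if len(fg_peaks):
        fg_seqs = motifs.extract_sequences(fg_peaks, study.genome)
        bg = motifs.make_background(fg_peaks, study.genome, cfg)
        bg_seqs = dict(zip(bg["name"], bg["seq"]))
        results["motif_enrichment"] = motifs.motif_enrichment(
            fg_seqs, bg_seqs, study.pwms, cfg
        )

    if outdir is not None:
        write_pipeline_results(results, outdir)
    return results


def write_pipeline_results(results: dict, outdir: str | Path) -> None:
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    (outdir / "consensus").mkdir(exist_ok=True)
    for (mark, stage, genotype), frame in sorted(results["consensus"].items()):
        write_peak_file(frame, outdir / "consensus" / f"{mark}_{stage}_{genotype}.bed")
    classes_df = pd.DataFrame(
        [{"peak": p, "class": membership_label(m)} for p, m in sorted(results["classes"].items())],
        columns=["peak", "class"],
    )
    write_results_table(classes_df, outdir / "temporal_classes.tsv")
    write_results_table(results["annotations"].reset_index(), outdir / "annotations.tsv")
    model = results["cluster_model"]
    assign = model.assignments.rename("cluster").reset_index()
    assign.columns = ["gene", "cluster"]
    write_results_table(assign, outdir / "clusters.tsv")
    write_results_table(model.centroids.reset_index(names="cluster"), outdir / "centroids.tsv")
    for stage, dist in results["cluster_distribution"].items():
        write_results_table(dist.reset_index(), outdir / f"cluster_distribution_{stage}.tsv")
    write_results_table(results["degs"].reset_index(), outdir / "degs.tsv")
    write_results_table(results["states"], outdir / "states.tsv")
    write_results_table(results["transitions"], outdir / "transitions.tsv")
    write_results_table(results["dbr_table"], outdir / "dbrs.tsv")
    write_results_table(results["concordance"], outdir / "concordance.tsv")
    with open(outdir / "concordance_summary.json", "w") as fh:
        json.dump(results["concordance_summary"], fh, indent=2, sort_keys=True)
    if "motif_enrichment" in results:
        write_results_table(
            results["motif_enrichment"].reset_index(), outdir / "motif_enrichment.tsv"
        )
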