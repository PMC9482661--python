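"""Histone-mark coenrichment states, state transitions, and differential binding.

State calls are set-based: a mark flag is true when the query peak overlaps at
least one consensus peak of that mark at that stage under the standard
reciprocal-overlap predicate. Bivalency is by definition the intersection of
H3K4me3 and H3K27me3.
"""

from __future__ import annotations

import logging

import numpy as np
import pandas as pd

from cistrack.config import AnalysisConfig, STAGES
from cistrack.expression import bh_adjust, nb_wald_test
from cistrack.intervals import ValidationError, _overlap_edges

logger = logging.getLogger(__name__)

LABELS = ("active_promoter", "active", "bivalent", "repressed", "none")
STATE_MARKS = ("H3K4me3", "H3K27ac", "H3K27me3")


def overlaps_any(query: pd.DataFrame, subject: pd.DataFrame, cfg: AnalysisConfig) -> np.ndarray:
    """Boolean per query row: does it overlap >= 1 subject interval?"""
    nq = len(query)
    if nq == 0:
        return np.zeros(0, dtype=bool)
    if len(subject) == 0:
        return np.zeros(nq, dtype=bool)
    chrom = np.concatenate([query["chrom"].to_numpy(), subject["chrom"].to_numpy()])
    start = np.concatenate([query["start"].to_numpy(), subject["start"].to_numpy()])
    end = np.concatenate([query["end"].to_numpy(), subject["end"].to_numpy()])
    ei, ej = _overlap_edges(
        chrom, start, end, cfg.overlap_frac_query, cfg.overlap_frac_subject, cfg.overlap_either
    )
    hit = np.zeros(nq, dtype=bool)
    for i, j in zip(ei, ej):
        if (i < nq) != (j < nq):  # cross query/subject edge
            hit[min(i, j)] = True
    return hit


def derive_label(k4me3: bool, k27ac: bool, k27me3: bool) -> str:
    """Pure label derivation from the three mark flags.

    Precedence: bivalent (k4 & k27me3) > active_promoter (k4 & k27ac) >
    active (k27ac) > k4-only -> active_promoter > repressed (k27me3) > none.
    The untabulated k27ac & k27me3 (no k4) conflict resolves to repressed.
    """
    if k4me3 and k27me3:
        return "bivalent"
    if k4me3 and k27ac:
        return "active_promoter"
    if k27ac and k27me3:
        return "repressed"
    if k27ac:
        return "active"
    if k4me3:
        return "active_promoter"
    if k27me3:
        return "repressed"
    return "none"


def call_states(
    chd2_peaks: pd.DataFrame,
    histone_sets: dict[tuple[str, str], pd.DataFrame],
    cfg: AnalysisConfig,
    stages: tuple[str, ...] = STAGES,
) -> pd.DataFrame:
    """Per-peak, per-stage histone coenrichment flags and derived labels.

    ``histone_sets`` maps (mark, stage) -> consensus peak frame and must cover
    all three marks at every requested stage. Returns a tidy frame with
    columns peak, stage, k4me3, k27ac, k27me3, bivalent, label.
    """
    missing = [
        (m, s) for s in stages for m in STATE_MARKS if (m, s) not in histone_sets
    ]
    if missing:
        raise ValidationError(f"missing histone consensus sets: {missing}")
    records = []
    conflicts = 0
    for stage in stages:
        flags = {
            mark: overlaps_any(chd2_peaks, histone_sets[(mark, stage)], cfg)
            for mark in STATE_MARKS
        }
        for i, peak in enumerate(chd2_peaks["name"]):
            k4, ac, me3 = (
                bool(flags["H3K4me3"][i]),
                bool(flags["H3K27ac"][i]),
                bool(flags["H3K27me3"][i]),
            )
            if ac and me3 and not k4:
                conflicts += 1
            records.append(
                {
                    "peak": peak,
                    "stage": stage,
                    "k4me3": k4,
                    "k27ac": ac,
                    "k27me3": me3,
                    "bivalent": k4 and me3,
                    "label": derive_label(k4, ac, me3),
                }
            )
    if conflicts:
        logger.warning(
            "%d peak-stage calls carry k27ac & k27me3 without k4me3; labelled repressed",
            conflicts,
        )
    return pd.DataFrame(records)


def tabulate_transitions(states: pd.DataFrame) -> pd.DataFrame:
    """Count peaks per ordered (D0, D15, D35) label triple.

    Every peak must have a call at each stage. The returned frame has columns
    D0, D15, D35, count and sums to the number of peaks.
    """
    wide = states.pivot(index="peak", columns="stage", values="label")
    missing_cols = set(STAGES) - set(wide.columns)
    if missing_cols or wide.isna().any().any():
        raise ValidationError("every peak needs a state call at all three stages")
    tab = (
        wide.groupby(list(STAGES), observed=True)
        .size()
        .rename("count")
        .reset_index()
        .sort_values(list(STAGES), kind="mergesort")
        .reset_index(drop=True)
    )
    return tab


def transition_marginals(transitions: pd.DataFrame, stage: str) -> pd.Series:
    """Per-stage label counts recovered by summation over the triple table."""
    return transitions.groupby(stage, observed=True)["count"].sum()


def differential_binding(
    peak_counts: pd.DataFrame,
    group_wt: list[str],
    group_mut: list[str],
    cfg: AnalysisConfig,
) -> pd.DataFrame:
    """NB test of per-peak counts, mutant vs wild type.

    Reuses the expression module's NB Wald machinery with library-size
    normalisation. Direction ``up`` means higher in mutant with
    |log2FC| >= log2(dbr_fold_threshold) and BH q < dbr_fdr; ``down`` is
    symmetric; otherwise ``ns``.
    """
    if len(peak_counts) == 0:
        raise ValidationError("empty union peak set")
    res = nb_wald_test(peak_counts, group_wt, group_mut)
    q = bh_adjust(res["pvalue"].to_numpy())
    lfc = res["log2fc"].to_numpy()
    sig = (q < cfg.dbr_fdr) & (np.abs(lfc) >= np.log2(cfg.dbr_fold_threshold))
    direction = np.where(sig & (lfc > 0), "up", np.where(sig & (lfc < 0), "down", "ns"))
    out = res.copy()
    out["qvalue"] = q
    out["direction"] = direction
    return out


def merge_intervals(frames: list[pd.DataFrame]) -> pd.DataFrame:
    """Coordinate union of peak frames: any-bp-overlapping intervals merge.

    Used to build the union peak set over genotypes before differential
    binding; merged peaks get fresh sequential names.
    """
    allp = pd.concat([f[["chrom", "start", "end"]] for f in frames], ignore_index=True)
    allp = allp.sort_values(["chrom", "start", "end"], kind="mergesort")
    rows = []
    cur = None
    for chrom, start, end in allp.itertuples(index=False):
        if cur is not None and chrom == cur[0] and start < cur[2]:
            cur[2] = max(cur[2], end)
        else:
            if cur is not None:
                rows.append(tuple(cur))
            cur = [chrom, start, end]
    if cur is not None:
        rows.append(tuple(cur))
    out = pd.DataFrame(rows, columns=["chrom", "start", "end"])
    out["name"] = [f"union_{i}" for i in range(len(out))]
    return out
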