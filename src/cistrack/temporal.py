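"""Cross-stage binding classification and peak-to-gene annotation.

Temporal classes are the 7 nonempty subsets of {D0, D15, D35}: singleton
classes are the stage-"unique" peaks, the full set is constitutive binding.
Cross-stage linking reuses the same reciprocal-overlap predicate as replicate
consensus.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from cistrack.config import AnalysisConfig, STAGES
from cistrack.intervals import (
    GenomicInterval,
    ValidationError,
    _UnionFind,
    _overlap_edges,
    nearest_feature,
    nearest_features_bulk,
)

CATEGORIES = ("promoter", "exon", "intron", "TTS", "intergenic")


def membership_label(membership: frozenset[str]) -> str:
    """Canonical string form of a temporal class, e.g. ``D0+D15``."""
    return "+".join(s for s in STAGES if s in membership)


def parse_membership(label: str) -> frozenset[str]:
    parts = label.split("+")
    bad = set(parts) - set(STAGES)
    if bad or not parts:
        raise ValidationError(f"invalid temporal class label {label!r}")
    return frozenset(parts)


@dataclass
class GeneModels:
    """Gene models: per-gene strand/TSS/TTS plus exon blocks.

    ``genes`` columns: gene_id, chrom, start, end, strand (+ derived tss, tts).
    ``exons`` columns: gene_id, chrom, start, end.
    """

    genes: pd.DataFrame
    exons: pd.DataFrame

    def __post_init__(self) -> None:
        g = self.genes
        for col in ("gene_id", "chrom", "start", "end", "strand"):
            if col not in g.columns:
                raise ValidationError(f"gene table lacks column {col!r}")
        if not g["strand"].isin(["+", "-"]).all():
            raise ValidationError("every gene model needs strand + or -")
        g = g.copy()
        g["tss"] = np.where(g["strand"] == "+", g["start"], g["end"] - 1)
        g["tts"] = np.where(g["strand"] == "+", g["end"] - 1, g["start"])
        self.genes = g.reset_index(drop=True)

    @property
    def tss_table(self) -> pd.DataFrame:
        return self.genes[["gene_id", "chrom", "tss", "strand"]]


def classify_temporal(
    peaks_by_stage: dict[str, pd.DataFrame],
    cfg: AnalysisConfig,
) -> dict[str, frozenset[str]]:
    """Assign each consensus peak its cross-stage membership class.

    Peaks from distinct stages are linked under the overlap predicate; each
    connected component's membership is the set of stages contributing at
    least one peak, and every member peak inherits it. Chained overlaps merge
    transitively (a D0–D15 and D15–D35 link yields D0+D15+D35 for all three).

    ``peaks_by_stage`` maps stage -> frame with chrom/start/end/name; returns
    peak name -> membership frozenset.
    """
    bad = set(peaks_by_stage) - set(STAGES)
    if bad:
        raise ValidationError(f"unknown stage keys: {sorted(bad)}")
    frames = []
    for stage, df in peaks_by_stage.items():
        sub = df[["chrom", "start", "end", "name"]].copy()
        sub["stage"] = stage
        frames.append(sub)
    allp = pd.concat(frames, ignore_index=True)
    if allp["name"].duplicated().any():
        raise ValidationError("peak names must be unique across stages")
    n = len(allp)
    if n == 0:
        return {}
    chrom = allp["chrom"].to_numpy()
    start = allp["start"].to_numpy()
    end = allp["end"].to_numpy()
    stage_arr = allp["stage"].to_numpy()

    uf = _UnionFind(n)
    ei, ej = _overlap_edges(
        chrom, start, end, cfg.overlap_frac_query, cfg.overlap_frac_subject, cfg.overlap_either
    )
    for i, j in zip(ei, ej):
        if stage_arr[i] != stage_arr[j]:
            uf.union(int(i), int(j))

    comp_stages: dict[int, set[str]] = {}
    for i in range(n):
        comp_stages.setdefault(uf.find(i), set()).add(stage_arr[i])
    return {
        allp["name"].iloc[i]: frozenset(comp_stages[uf.find(i)]) for i in range(n)
    }


def class_counts(classes: dict[str, frozenset[str]]) -> pd.Series:
    """Count peaks per temporal class over the 7 possible memberships."""
    from itertools import combinations

    labels = []
    for r in (1, 2, 3):
        for combo in combinations(STAGES, r):
            labels.append("+".join(combo))
    counts = pd.Series(0, index=labels, dtype=int)
    for m in classes.values():
        counts[membership_label(m)] += 1
    return counts


def _within_any(mids: np.ndarray, starts: np.ndarray, ends: np.ndarray) -> np.ndarray:
    """For each midpoint, whether it falls inside any [start, end) interval."""
    if len(starts) == 0:
        return np.zeros(len(mids), dtype=bool)
    order = np.argsort(starts, kind="mergesort")
    s = starts[order]
    e = ends[order]
    cummax_e = np.maximum.accumulate(e)
    idx = np.searchsorted(s, mids, side="right")
    out = np.zeros(len(mids), dtype=bool)
    nz = idx > 0
    out[nz] = cummax_e[idx[nz] - 1] > mids[nz]
    # cummax trick is exact only for the containment question: a midpoint is
    # inside some interval iff an interval starting at or before it ends after it
    return out


def annotate_peaks(
    peaks: pd.DataFrame,
    gene_models: GeneModels,
    cfg: AnalysisConfig,
) -> pd.DataFrame:
    """Annotate peaks against gene models with precedence-resolved categories.

    Category precedence: promoter (midpoint within +/- promoter_window_bp of
    any TSS) > exon > intron (inside a gene body) > TTS (within
    +/- tts_window_bp of a transcript end) > intergenic. The nearest gene and
    signed TSS distance come from the nearest-TSS rule; ``promoter_proximal``
    is |distance| <= promoter_window_bp.
    """
    ann = nearest_features_bulk(peaks[["chrom", "start", "end", "name"]], gene_models.tss_table)
    mids = ((peaks["start"].to_numpy() + peaks["end"].to_numpy()) // 2).astype(np.int64)

    promoter = np.zeros(len(peaks), dtype=bool)
    exon = np.zeros(len(peaks), dtype=bool)
    genebody = np.zeros(len(peaks), dtype=bool)
    tts = np.zeros(len(peaks), dtype=bool)
    w = cfg.promoter_window_bp
    wt = cfg.tts_window_bp
    genes = gene_models.genes
    exons = gene_models.exons
    chroms = peaks["chrom"].to_numpy()
    for c in np.unique(chroms):
        mask = chroms == c
        m = mids[mask]
        gsub = genes[genes["chrom"] == c]
        esub = exons[exons["chrom"] == c]
        if len(gsub):
            t = gsub["tss"].to_numpy()
            promoter[mask] = _within_any(m, t - w, t + w + 1)
            genebody[mask] = _within_any(
                m, gsub["start"].to_numpy(), gsub["end"].to_numpy()
            )
            tt = gsub["tts"].to_numpy()
            tts[mask] = _within_any(m, tt - wt, tt + wt + 1)
        if len(esub):
            exon[mask] = _within_any(m, esub["start"].to_numpy(), esub["end"].to_numpy())

    category = np.full(len(peaks), "intergenic", dtype=object)
    category[tts] = "TTS"
    category[genebody] = "intron"
    category[exon] = "exon"
    category[promoter] = "promoter"

    ann["category"] = category
    ann["promoter_proximal"] = np.abs(ann["tss_distance"]) <= w
    return ann.set_index("name")


def annotate_peak(
    peak: GenomicInterval,
    gene_models: GeneModels,
    cfg: AnalysisConfig,
) -> dict:
    """Single-peak annotation; see :func:`annotate_peaks`."""
    df = pd.DataFrame(
        [{"chrom": peak.chrom, "start": peak.start, "end": peak.end, "name": peak.name or "q"}]
    )
    row = annotate_peaks(df, gene_models, cfg).iloc[0]
    return {
        "category": row["category"],
        "gene_id": row["gene_id"],
        "tss_distance": int(row["tss_distance"]),
        "promoter_proximal": bool(row["promoter_proximal"]),
    }


def stage_unique_promoter_genes(
    classes: dict[str, frozenset[str]],
    annotations: pd.DataFrame,
    stage: str,
) -> set[str]:
    """Genes with >= 1 promoter-proximal peak bound uniquely at ``stage``."""
    if stage not in STAGES:
        raise ValidationError(f"unknown stage {stage!r}")
    target = frozenset([stage])
    genes: set[str] = set()
    for peak, membership in classes.items():
        if membership != target or peak not in annotations.index:
            continue
        row = annotations.loc[peak]
        if bool(row["promoter_proximal"]):
            genes.add(str(row["gene_id"]))
    return genes
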