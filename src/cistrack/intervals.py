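"""Genomic-interval set algebra.

Coordinates are BED-style 0-based half-open throughout. The single overlap
predicate used everywhere in the pipeline is :func:`overlaps`, which mirrors
``bedtools intersect -f/-F/-e`` reciprocal-fraction semantics. Replicate
consensus is a connected-component construction over that predicate.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

from cistrack.config import AnalysisConfig, ConfigError

BED_COLUMNS = ["chrom", "start", "end", "name", "score", "strand"]


class ValidationError(ValueError):
    """Raised when inputs violate a pipeline contract."""


@dataclass(frozen=True)
class GenomicInterval:
    """A 0-based half-open genomic region."""

    chrom: str
    start: int
    end: int
    name: str = ""
    strand: str = "."

    def __post_init__(self) -> None:
        if self.start < 0:
            raise ValidationError(f"negative start in {self}")
        if self.start >= self.end:
            raise ValidationError(
                f"start must be < end, got [{self.start}, {self.end}) on {self.chrom}"
            )
        if self.strand not in ("+", "-", "."):
            raise ValidationError(f"invalid strand {self.strand!r}")

    @property
    def length(self) -> int:
        return self.end - self.start

    @property
    def midpoint(self) -> int:
        return (self.start + self.end) // 2


@dataclass
class PeakSet:
    """A collection of peaks from one (mark, stage, genotype, replicate)."""

    intervals: pd.DataFrame
    mark: str = ""
    stage: str = ""
    genotype: str = ""
    replicate: int = 0

    def __post_init__(self) -> None:
        df = self.intervals
        for col in ("chrom", "start", "end"):
            if col not in df.columns:
                raise ValidationError(f"PeakSet frame lacks column {col!r}")
        if len(df) and (df["start"] >= df["end"]).any():
            bad = df.index[df["start"] >= df["end"]][0]
            raise ValidationError(f"interval with start >= end at row {bad}")
        self.intervals = df.sort_values(["chrom", "start", "end"], kind="mergesort").reset_index(
            drop=True
        )

    def __len__(self) -> int:
        return len(self.intervals)


@dataclass(frozen=True)
class ConsensusPeak:
    """A replicate-supported peak spanning the union of its supporters."""

    interval: GenomicInterval
    support: int
    source_ids: tuple[str, ...]


def overlaps(
    a: GenomicInterval,
    b: GenomicInterval,
    frac_a: float = 0.25,
    frac_b: float = 0.25,
    either: bool = True,
) -> bool:
    """Reciprocal-fraction overlap predicate (``bedtools intersect -f -F [-e]``).

    Returns True iff the bp overlap ``o`` is positive and satisfies
    ``o >= frac_a * len(a)`` and/or (per ``either``) ``o >= frac_b * len(b)``.
    Strand is ignored; different chromosomes never overlap.
    """
    for f in (frac_a, frac_b):
        if not 0 < f <= 1:
            raise ConfigError(f"overlap fraction must be in (0, 1], got {f}")
    if a.chrom != b.chrom:
        return False
    o = min(a.end, b.end) - max(a.start, b.start)
    if o <= 0:
        return False
    hit_a = o >= frac_a * a.length
    hit_b = o >= frac_b * b.length
    return (hit_a or hit_b) if either else (hit_a and hit_b)


def _overlap_edges(
    chrom: np.ndarray,
    start: np.ndarray,
    end: np.ndarray,
    frac_a: float,
    frac_b: float,
    either: bool,
) -> tuple[np.ndarray, np.ndarray]:
    """All index pairs (i < j) whose intervals satisfy the overlap predicate.

    Sweep over start-sorted intervals keeping an active window; intended for
    the moderate peak counts of replicate sets (thousands), not genome-scale
    billions.
    """
    n = len(start)
    order = np.lexsort((start, chrom))
    edges_i: list[int] = []
    edges_j: list[int] = []
    active: list[int] = []  # indices into `order` positions
    cur_chrom = None
    for pos in order:
        c, s, e = chrom[pos], start[pos], end[pos]
        if c != cur_chrom:
            active = []
            cur_chrom = c
        active = [k for k in active if end[k] > s]
        for k in active:
            o = min(e, end[k]) - max(s, start[k])
            if o <= 0:
                continue
            la = end[k] - start[k]
            lb = e - s
            hit_a = o >= frac_a * la
            hit_b = o >= frac_b * lb
            if (hit_a or hit_b) if either else (hit_a and hit_b):
                edges_i.append(k)
                edges_j.append(pos)
        active.append(pos)
    return np.asarray(edges_i, dtype=int), np.asarray(edges_j, dtype=int)


class _UnionFind:
    def __init__(self, n: int):
        self.parent = list(range(n))

    def find(self, x: int) -> int:
        while self.parent[x] != x:
            self.parent[x] = self.parent[self.parent[x]]
            x = self.parent[x]
        return x

    def union(self, a: int, b: int) -> None:
        ra, rb = self.find(a), self.find(b)
        if ra != rb:
            self.parent[rb] = ra


def consensus_peaks(
    replicate_sets: Sequence[PeakSet],
    cfg: AnalysisConfig,
) -> list[ConsensusPeak]:
    """Build replicate-consensus peaks from >= 2 replicate peak sets.

    Peaks from distinct replicates are linked when they satisfy the overlap
    predicate under ``cfg``; every connected component spanning at least
    ``cfg.min_replicate_support`` distinct replicates emits one consensus peak
    whose interval is the coordinate union of the component.
    """
    if len(replicate_sets) < 2:
        raise ValidationError("consensus requires >= 2 replicate sets")
    meta = {(ps.mark, ps.stage, ps.genotype) for ps in replicate_sets}
    if len(meta) > 1:
        raise ValidationError(f"replicate sets mix metadata: {sorted(meta)}")

    frames = []
    for ps in replicate_sets:
        df = ps.intervals[["chrom", "start", "end"]].copy()
        df["replicate"] = ps.replicate
        if "name" in ps.intervals.columns:
            df["name"] = ps.intervals["name"].astype(str)
        else:
            df["name"] = [f"rep{ps.replicate}_{i}" for i in range(len(df))]
        frames.append(df)
    allp = pd.concat(frames, ignore_index=True)
    n = len(allp)
    if n == 0:
        return []

    chrom = allp["chrom"].to_numpy()
    start = allp["start"].to_numpy()
    end = allp["end"].to_numpy()
    rep = allp["replicate"].to_numpy()

    uf = _UnionFind(n)
    ei, ej = _overlap_edges(
        chrom, start, end, cfg.overlap_frac_query, cfg.overlap_frac_subject, cfg.overlap_either
    )
    for i, j in zip(ei, ej):
        if rep[i] != rep[j]:
            uf.union(int(i), int(j))

    roots: dict[int, list[int]] = {}
    for i in range(n):
        roots.setdefault(uf.find(i), []).append(i)

    out: list[ConsensusPeak] = []
    for members in roots.values():
        support = len({int(rep[i]) for i in members})
        if support < cfg.min_replicate_support:
            continue
        c = chrom[members[0]]
        s = int(min(start[i] for i in members))
        e = int(max(end[i] for i in members))
        ids = tuple(sorted(allp["name"].iloc[i] for i in members))
        out.append(
            ConsensusPeak(
                interval=GenomicInterval(chrom=c, start=s, end=e),
                support=support,
                source_ids=ids,
            )
        )
    out.sort(key=lambda p: (p.interval.chrom, p.interval.start, p.interval.end))
    return out


def consensus_frame(peaks: Iterable[ConsensusPeak], prefix: str = "peak") -> pd.DataFrame:
    """Flatten consensus peaks into a BED6+2 frame with stable ids."""
    rows = []
    for i, p in enumerate(peaks):
        rows.append(
            {
                "chrom": p.interval.chrom,
                "start": p.interval.start,
                "end": p.interval.end,
                "name": f"{prefix}_{i}",
                "score": p.support,
                "strand": ".",
                "support": p.support,
                "source_ids": ",".join(p.source_ids),
            }
        )
    return pd.DataFrame(
        rows, columns=BED_COLUMNS + ["support", "source_ids"]
    )


def nearest_feature(
    query: GenomicInterval,
    features: pd.DataFrame,
) -> tuple[str, int]:
    """Nearest-TSS lookup for a query interval.

    ``features`` needs columns ``gene_id, chrom, tss, strand`` and is treated
    as an unordered table. Returns ``(gene_id, signed_distance)`` where the
    distance from the query midpoint to the TSS is negative when the midpoint
    lies upstream of the TSS with respect to gene strand. Ties are broken by
    lexicographically smaller gene id.
    """
    if len(features) == 0:
        raise ValidationError("empty feature table")
    sub = features[features["chrom"] == query.chrom]
    if len(sub) == 0:
        raise ValidationError(f"no features on chromosome {query.chrom}")
    mid = query.midpoint
    dist = (sub["tss"].to_numpy() - mid)
    absdist = np.abs(dist)
    best = absdist.min()
    cands = sub.iloc[np.flatnonzero(absdist == best)]
    row = cands.sort_values("gene_id").iloc[0]
    signed = int(mid - row["tss"])
    if row["strand"] == "-":
        signed = -signed
    return str(row["gene_id"]), signed


def nearest_features_bulk(
    queries: pd.DataFrame,
    features: pd.DataFrame,
) -> pd.DataFrame:
    """Vectorised nearest-TSS for a frame of query intervals.

    Same tie rule as :func:`nearest_feature`. Queries on chromosomes absent
    from the feature table get gene_id ``""`` and distance ``NaN``.
    """
    out_gene = np.empty(len(queries), dtype=object)
    out_dist = np.full(len(queries), np.nan)
    mids = ((queries["start"].to_numpy() + queries["end"].to_numpy()) // 2).astype(np.int64)
    for c, sub in features.groupby("chrom"):
        mask = (queries["chrom"] == c).to_numpy()
        if not mask.any():
            continue
        # sort by (tss, gene_id) so equidistant ties resolve to the smaller id;
        # genes sharing a TSS collapse to the lexicographically first one
        sub = sub.sort_values(["tss", "gene_id"], kind="mergesort").drop_duplicates(
            "tss", keep="first"
        )
        tss = sub["tss"].to_numpy(dtype=np.int64)
        gid = sub["gene_id"].to_numpy(dtype=object)
        strand = sub["strand"].to_numpy(dtype=object)
        m = mids[mask]
        idx = np.searchsorted(tss, m)
        left = np.clip(idx - 1, 0, len(tss) - 1)
        right = np.clip(idx, 0, len(tss) - 1)
        dl = np.abs(m - tss[left])
        dr = np.abs(m - tss[right])
        # prefer left on exact distance ties only when its gene id is smaller
        take_left = (dl < dr) | ((dl == dr) & (gid[left] <= gid[right]))
        pick = np.where(take_left, left, right)
        signed = m - tss[pick]
        signed = np.where(strand[pick] == "-", -signed, signed)
        out_gene[mask] = gid[pick]
        out_dist[mask] = signed
    res = queries.copy()
    res["gene_id"] = out_gene
    res["tss_distance"] = out_dist
    return res
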