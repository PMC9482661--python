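"""Expression normalisation, temporal clustering, and differential testing.

RPKM feeds the temporal clustering; CPM feeds the differential-expression
filter — the two normalisations are deliberately kept on those separate
paths. Differential expression is an in-repo negative-binomial Wald test
with pooled method-of-moments dispersion and library-size normalisation,
not a wrapper around an external DE package.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats
from sklearn.cluster import KMeans

from cistrack.config import AnalysisConfig, STAGES
from cistrack.intervals import ValidationError


@dataclass
class CountMatrix:
    """Gene x sample raw counts with sample metadata and gene lengths."""

    counts: pd.DataFrame  # genes x samples, non-negative integers
    samples: pd.DataFrame  # index = sample id; columns stage, genotype, replicate
    gene_lengths: pd.Series | None = None  # bp, for RPKM

    def __post_init__(self) -> None:
        if (self.counts.to_numpy() < 0).any():
            raise ValidationError("negative counts")
        missing = set(self.counts.columns) - set(self.samples.index)
        if missing:
            raise ValidationError(f"samples without metadata: {sorted(missing)}")
        if self.gene_lengths is not None:
            gl = self.gene_lengths.reindex(self.counts.index)
            if gl.isna().any() or (gl <= 0).any():
                raise ValidationError("gene lengths must cover all genes and be > 0")
            self.gene_lengths = gl

    def subset_samples(self, sample_ids) -> "CountMatrix":
        return CountMatrix(
            counts=self.counts[list(sample_ids)],
            samples=self.samples.loc[list(sample_ids)],
            gene_lengths=self.gene_lengths,
        )


def compute_cpm(counts: pd.DataFrame) -> pd.DataFrame:
    """Counts per million; every column of the result sums to 1e6."""
    libsize = counts.sum(axis=0)
    if (libsize <= 0).any():
        bad = libsize.index[libsize <= 0].tolist()
        raise ValidationError(f"zero library size for samples {bad}")
    return counts / libsize * 1e6


def compute_rpkm(counts: pd.DataFrame, gene_lengths: pd.Series) -> pd.DataFrame:
    """Reads per kilobase per million mapped reads."""
    gl = gene_lengths.reindex(counts.index)
    if gl.isna().any() or (gl <= 0).any():
        raise ValidationError("gene lengths must cover all genes and be > 0")
    cpm = compute_cpm(counts)
    return cpm.div(gl / 1e3, axis=0)


def stage_mean_rpkm(cm: CountMatrix, genotype: str = "WT") -> pd.DataFrame:
    """Per-gene mean RPKM at each stage for one genotype (columns D0/D15/D35)."""
    if cm.gene_lengths is None:
        raise ValidationError("gene lengths required for RPKM")
    keep = cm.samples.index[cm.samples["genotype"] == genotype]
    if len(keep) == 0:
        raise ValidationError(f"no samples for genotype {genotype!r}")
    rpkm = compute_rpkm(cm.counts[list(keep)], cm.gene_lengths)
    meta = cm.samples.loc[keep]
    out = {}
    for stage in STAGES:
        ss = meta.index[meta["stage"] == stage]
        if len(ss) == 0:
            raise ValidationError(f"no samples at stage {stage}")
        out[stage] = rpkm[list(ss)].mean(axis=1)
    return pd.DataFrame(out)


def filter_dynamic_genes(rpkm_by_stage: pd.DataFrame, cfg: AnalysisConfig) -> set[str]:
    """Genes whose expression changes > fold threshold on either stage transition.

    Fold change is direction-agnostic (max of ratio and inverse ratio) with a
    strict ``>`` boundary; a pseudo-count guards zero denominators.
    """
    p = cfg.rpkm_pseudocount
    v = rpkm_by_stage[list(STAGES)].to_numpy(dtype=float) + p
    f1 = np.maximum(v[:, 1] / v[:, 0], v[:, 0] / v[:, 1])
    f2 = np.maximum(v[:, 2] / v[:, 1], v[:, 1] / v[:, 2])
    keep = (f1 > cfg.dynamic_fold_threshold) | (f2 > cfg.dynamic_fold_threshold)
    return set(rpkm_by_stage.index[keep])


def d0_relative(rpkm_by_stage: pd.DataFrame, pseudocount: float = 0.1) -> pd.DataFrame:
    """Normalise each gene's stage profile to its D0 value (D0 column == 1)."""
    v = rpkm_by_stage[list(STAGES)].astype(float) + pseudocount
    return v.div(v["D0"], axis=0)


@dataclass
class ClusterModel:
    """Fitted temporal archetypes in D0-relative space."""

    centroids: pd.DataFrame  # K x stages
    assignments: pd.Series  # gene -> cluster id (0..K-1)
    sse_by_k: dict[int, float] = field(default_factory=dict)  # elbow diagnostics

    @property
    def n_clusters(self) -> int:
        return len(self.centroids)

    def members(self, cluster: int) -> list[str]:
        return list(self.assignments.index[self.assignments == cluster])


def fit_clusters(
    profiles: pd.DataFrame,
    cfg: AnalysisConfig,
    k_sweep: range | None = None,
) -> ClusterModel:
    """K-means temporal clustering with multiple restarts and a fixed seed.

    ``profiles`` are genes x stages in D0-relative space. A K sweep of
    within-cluster SSE is recorded for elbow diagnostics, but the final model
    is always fitted at ``cfg.n_clusters``.
    """
    X = profiles[list(STAGES)].to_numpy(dtype=float)
    if len(X) < cfg.n_clusters:
        raise ValidationError(
            f"need >= {cfg.n_clusters} profiles to fit {cfg.n_clusters} clusters, got {len(X)}"
        )
    sse: dict[int, float] = {}
    if k_sweep is not None:
        for k in k_sweep:
            if k > len(X):
                continue
            km = KMeans(n_clusters=k, n_init=10, random_state=cfg.rng_seed).fit(X)
            sse[k] = float(km.inertia_)
    km = KMeans(
        n_clusters=cfg.n_clusters,
        n_init=cfg.kmeans_restarts,
        init="k-means++",
        random_state=cfg.rng_seed,
    ).fit(X)
    sse[cfg.n_clusters] = float(km.inertia_)
    centroids = pd.DataFrame(km.cluster_centers_, columns=list(STAGES))
    assignments = pd.Series(km.labels_, index=profiles.index, name="cluster")
    return ClusterModel(centroids=centroids, assignments=assignments, sse_by_k=sse)


# ---------------------------------------------------------------------------
# negative-binomial testing machinery (shared with differential binding)
# ---------------------------------------------------------------------------


def size_factors(counts: np.ndarray) -> np.ndarray:
    """Median-of-ratios library-size factors; falls back to totals if degenerate."""
    counts = np.asarray(counts, dtype=float)
    with np.errstate(divide="ignore"):
        logc = np.log(counts)
    ref = logc.mean(axis=1)
    finite = np.isfinite(ref)
    if finite.sum() >= 10:
        sf = np.exp(np.median(logc[finite] - ref[finite, None], axis=0))
    else:
        tot = counts.sum(axis=0)
        sf = tot / np.exp(np.mean(np.log(np.maximum(tot, 1.0))))
    return sf / np.exp(np.mean(np.log(sf)))


def _pooled_dispersion(y: np.ndarray, sf: np.ndarray, groups: list[np.ndarray]) -> float:
    """Common NB dispersion via method of moments on normalised counts.

    Residual variance is pooled within groups so real group effects do not
    inflate the estimate.
    """
    z = y / sf
    num = 0.0
    den = 0.0
    inv_s_mean = np.mean(1.0 / sf)
    alphas = []
    for g in range(len(y)):
        resid_var = 0.0
        dof = 0
        mean_all = 0.0
        ntot = 0
        for idx in groups:
            zz = z[g, idx]
            if len(zz) >= 2:
                resid_var += np.var(zz, ddof=1) * (len(zz) - 1)
                dof += len(zz) - 1
            mean_all += zz.sum()
            ntot += len(zz)
        if dof == 0 or ntot == 0:
            continue
        q = mean_all / ntot
        if q <= 0:
            continue
        v = resid_var / dof
        alphas.append((v - q * inv_s_mean) / (q * q))
    if not alphas:
        return 1e-8
    return float(max(1e-8, np.median(alphas)))


def _fit_group_logmean(y: np.ndarray, sf: np.ndarray, alpha: float, n_iter: int = 25):
    """MLE of log group mean (per gene) for NB with fixed dispersion and offsets.

    Returns (t, info): t = log q maximising sum_j [y log mu - (y+1/a)log(1+a mu)]
    with mu_j = s_j e^t; info = Fisher information sum_j mu/(1+a mu).
    """
    y = np.asarray(y, dtype=float)
    stot = sf.sum()
    q0 = np.maximum(y.sum(axis=1), 0.5) / stot
    t = np.log(q0)
    for _ in range(n_iter):
        mu = np.exp(t)[:, None] * sf[None, :]
        grad = (y - mu * (alpha * y + 1.0) / (1.0 + alpha * mu)).sum(axis=1)
        info = (mu / (1.0 + alpha * mu)).sum(axis=1)
        step = np.clip(grad / np.maximum(info, 1e-12), -2.0, 2.0)
        t = t + step
        if np.max(np.abs(step)) < 1e-10:
            break
    mu = np.exp(t)[:, None] * sf[None, :]
    info = (mu / (1.0 + alpha * mu)).sum(axis=1)
    return t, info


def nb_wald_test(
    counts: pd.DataFrame,
    group_a: list[str],
    group_b: list[str],
    alpha: float | None = None,
) -> pd.DataFrame:
    """Per-feature NB Wald test of group B vs group A.

    Library sizes are normalised by median-of-ratios size factors; dispersion
    is pooled across features (method of moments) unless given, with a mild
    small-sample inflation so the Wald statistic (normal reference) stays
    calibrated at few replicates.

    Returns a frame indexed like ``counts`` with columns
    ``log2fc`` (B vs A), ``pvalue``, ``base_mean`` (normalised mean).
    """
    if set(group_a) & set(group_b):
        raise ValidationError("groups overlap")
    if len(group_a) < 2 or len(group_b) < 2:
        raise ValidationError("need >= 2 samples per group")
    samples = list(group_a) + list(group_b)
    y = counts[samples].to_numpy(dtype=float)
    sf = size_factors(y)
    ia = np.arange(len(group_a))
    ib = np.arange(len(group_a), len(samples))
    if alpha is None:
        alpha = _pooled_dispersion(y, sf, [ia, ib])
        # method-of-moments pooling underestimates spread at few replicates;
        # inflate by the chi-square mean bias of the residual dof
        dof = len(samples) - 2
        alpha = alpha * (1.0 + 2.0 / dof)
    ta, info_a = _fit_group_logmean(y[:, ia], sf[ia], alpha)
    tb, info_b = _fit_group_logmean(y[:, ib], sf[ib], alpha)
    delta = tb - ta
    se = np.sqrt(1.0 / np.maximum(info_a, 1e-12) + 1.0 / np.maximum(info_b, 1e-12))
    z = delta / se
    pvalue = 2.0 * stats.norm.sf(np.abs(z))
    # features with zero counts everywhere carry no evidence
    allzero = y.sum(axis=1) == 0
    pvalue[allzero] = 1.0
    delta = np.where(allzero, 0.0, delta)
    return pd.DataFrame(
        {
            "log2fc": delta / np.log(2.0),
            "pvalue": pvalue,
            "base_mean": (y / sf).mean(axis=1),
        },
        index=counts.index,
    )


def bh_adjust(pvalues: np.ndarray) -> np.ndarray:
    """Benjamini–Hochberg step-up adjusted p-values."""
    p = np.asarray(pvalues, dtype=float)
    n = len(p)
    order = np.argsort(p, kind="mergesort")
    ranked = p[order] * n / (np.arange(n) + 1)
    q = np.minimum.accumulate(ranked[::-1])[::-1]
    out = np.empty(n)
    out[order] = np.minimum(q, 1.0)
    return out


def differential_expression(
    cm: CountMatrix,
    group_a: list[str],
    group_b: list[str],
    cfg: AnalysisConfig,
) -> pd.DataFrame:
    """Two-group NB differential expression with the configured thresholds.

    Genes with CPM below ``cfg.de_min_cpm`` in more than half of the compared
    samples are excluded before testing. Direction is ``up``/``down`` only
    when |log2FC| clears ``log2(de_fold_threshold)`` and BH q < ``de_fdr``.

    Returns a frame with columns gene, mean_cpm, log2fc, pvalue, qvalue,
    direction (up/down/ns), restricted to tested genes.
    """
    samples = list(group_a) + list(group_b)
    cpm = compute_cpm(cm.counts[samples])
    n_low = (cpm < cfg.de_min_cpm).sum(axis=1)
    tested = cm.counts.index[n_low <= len(samples) / 2]
    if len(tested) == 0:
        raise ValidationError("no genes pass the CPM filter")
    sub = cm.counts.loc[tested, samples]
    res = nb_wald_test(sub, group_a, group_b)
    q = bh_adjust(res["pvalue"].to_numpy())
    lfc = res["log2fc"].to_numpy()
    sig = (q < cfg.de_fdr) & (np.abs(lfc) >= np.log2(cfg.de_fold_threshold))
    direction = np.where(sig & (lfc > 0), "up", np.where(sig & (lfc < 0), "down", "ns"))
    return pd.DataFrame(
        {
            "gene": tested,
            "mean_cpm": cpm.loc[tested].mean(axis=1).to_numpy(),
            "log2fc": lfc,
            "pvalue": res["pvalue"].to_numpy(),
            "qvalue": q,
            "direction": direction,
        }
    ).set_index("gene")
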