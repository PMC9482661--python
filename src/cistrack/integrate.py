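"""Joins across the binding, chromatin, and expression layers.

Implements cluster-distribution enrichment of gene sets against the fitted
temporal archetypes, curated gene-list overlap reporting, and the
direction-concordant join of differentially bound regions, differentially
expressed genes, and temporal binding classes.
"""

from __future__ import annotations

import logging

import numpy as np
import pandas as pd
from scipy import stats

from cistrack.config import AnalysisConfig, STAGES
from cistrack.expression import ClusterModel, bh_adjust
from cistrack.intervals import ValidationError, _overlap_edges, nearest_features_bulk

logger = logging.getLogger(__name__)

FULL_SET = frozenset(STAGES)
LATER_SETS = (frozenset(["D15", "D35"]), frozenset(["D35"]))


def cluster_distribution(query_genes: set[str], model: ClusterModel) -> pd.DataFrame:
    """Distribution of a gene set across clusters with hypergeometric enrichment.

    The universe is the clustered gene set; the query is intersected with it.
    Per cluster: observed overlap, cluster size, fold enrichment vs uniform,
    upper-tail hypergeometric p, and BH q across the K clusters.
    """
    universe = set(model.assignments.index)
    query = set(query_genes) & universe
    n_universe = len(universe)
    n_query = len(query)
    if n_query == 0:
        logger.warning("query gene set has empty intersection with clustered universe")
    rows = []
    for k in range(model.n_clusters):
        members = set(model.members(k))
        obs = len(query & members)
        size = len(members)
        if n_query and size:
            expected = n_query * size / n_universe
            fold = obs / expected if expected > 0 else np.nan
            p = float(stats.hypergeom.sf(obs - 1, n_universe, size, n_query))
        else:
            fold = 0.0
            p = 1.0
        rows.append(
            {
                "cluster": k,
                "observed": obs,
                "cluster_size": size,
                "fold_enrichment": fold,
                "pvalue": p,
            }
        )
    out = pd.DataFrame(rows).set_index("cluster")
    out["qvalue"] = bh_adjust(out["pvalue"].to_numpy())
    return out


def gene_list_overlap(
    bound_genes_by_stage: dict[str, set[str]],
    risk_list: set[str],
) -> dict:
    """Overlap of stage-wise bound gene sets with a curated gene list.

    Reports the list size, genes bound at any stage (count and percent of the
    list), genes bound at all three stages, and per-stage counts.
    """
    if not risk_list:
        raise ValidationError("empty risk gene list")
    sets = {s: set(g) for s, g in bound_genes_by_stage.items()}
    union = set().union(*sets.values()) if sets else set()
    inter = set.intersection(*sets.values()) if sets else set()
    bound_any = risk_list & union
    bound_all = risk_list & inter
    return {
        "n_risk": len(risk_list),
        "n_bound_any": len(bound_any),
        "pct_bound_any": 100.0 * len(bound_any) / len(risk_list),
        "n_bound_all_stages": len(bound_all),
        "per_stage": {s: len(risk_list & g) for s, g in sets.items()},
    }


def _kinetics(classes_hit: set[frozenset[str]]) -> str:
    """Binding-kinetics label from the D35-containing classes a DBR overlaps."""
    if not classes_hit:
        return "unbound"
    if FULL_SET in classes_hit:
        return "all_stages"
    if any(c in LATER_SETS for c in classes_hit):
        return "later_only"
    return "other"


def concordant_triples(
    dbrs: pd.DataFrame,
    degs: pd.DataFrame,
    chd2_classes: dict[str, frozenset[str]],
    chd2_peaks: pd.DataFrame,
    gene_models_tss: pd.DataFrame,
    cfg: AnalysisConfig,
) -> tuple[pd.DataFrame, dict]:
    """Direction-concordant join of DBRs, nearest-gene DEGs, and binding classes.

    ``dbrs`` needs chrom/start/end/name/direction (up or down only);
    ``degs`` is indexed by gene with a ``direction`` column; ``chd2_peaks``
    provides intervals whose ``name`` keys into ``chd2_classes``.

    Each DBR contributes exactly one record: its nearest gene (TSS of the DBR
    midpoint), the gene's DEG direction (ns when untested), the concordance
    flag, whether the DBR overlaps a CHD2 peak bound at D35
    (``chd2_bound_hcIN``), and a kinetics label (all_stages / later_only /
    other / unbound). The summary tallies concordant counts per direction,
    their CHD2-bound refinements, and the later_only fraction among bound,
    concordant up records.
    """
    if len(dbrs) and not set(dbrs["direction"]) <= {"up", "down"}:
        raise ValidationError("dbrs must carry direction up/down only")

    ann = nearest_features_bulk(dbrs[["chrom", "start", "end", "name"]], gene_models_tss)

    # map each DBR to the temporal classes of overlapping D35-bound CHD2 peaks
    d35_names = [p for p, m in chd2_classes.items() if "D35" in m]
    d35_peaks = chd2_peaks[chd2_peaks["name"].isin(d35_names)].reset_index(drop=True)
    hit_classes: dict[int, set[frozenset[str]]] = {i: set() for i in range(len(dbrs))}
    if len(dbrs) and len(d35_peaks):
        nq = len(dbrs)
        chrom = np.concatenate([dbrs["chrom"].to_numpy(), d35_peaks["chrom"].to_numpy()])
        start = np.concatenate([dbrs["start"].to_numpy(), d35_peaks["start"].to_numpy()])
        end = np.concatenate([dbrs["end"].to_numpy(), d35_peaks["end"].to_numpy()])
        ei, ej = _overlap_edges(
            chrom, start, end,
            cfg.overlap_frac_query, cfg.overlap_frac_subject, cfg.overlap_either,
        )
        for i, j in zip(ei, ej):
            if (i < nq) != (j < nq):
                q, s = (i, j) if i < nq else (j, i)
                hit_classes[int(q)].add(chd2_classes[d35_peaks["name"].iloc[int(s) - nq]])

    deg_dir = degs["direction"].to_dict()
    records = []
    for i in range(len(dbrs)):
        dbr_dir = dbrs["direction"].iloc[i]
        gene = ann["gene_id"].iloc[i]
        gdir = deg_dir.get(gene, "ns")
        kin = _kinetics(hit_classes[i])
        records.append(
            {
                "dbr": dbrs["name"].iloc[i],
                "dbr_direction": dbr_dir,
                "gene_id": gene,
                "deg_direction": gdir,
                "concordant": gdir == dbr_dir,
                "chd2_bound_hcIN": kin != "unbound",
                "kinetics": kin,
            }
        )
    rec = pd.DataFrame(
        records,
        columns=[
            "dbr", "dbr_direction", "gene_id", "deg_direction",
            "concordant", "chd2_bound_hcIN", "kinetics",
        ],
    )

    def _count(mask) -> int:
        return int(mask.sum()) if len(rec) else 0

    conc = rec["concordant"] if len(rec) else pd.Series(dtype=bool)
    summary = {
        "n_dbrs": len(rec),
        "concordant_down": _count(conc & (rec["dbr_direction"] == "down")),
        "concordant_up": _count(conc & (rec["dbr_direction"] == "up")),
        "concordant_down_bound": _count(
            conc & (rec["dbr_direction"] == "down") & rec["chd2_bound_hcIN"]
        ),
        "concordant_up_bound": _count(
            conc & (rec["dbr_direction"] == "up") & rec["chd2_bound_hcIN"]
        ),
        "kinetics_counts": (
            rec["kinetics"].value_counts().to_dict() if len(rec) else {}
        ),
    }
    bound_up = rec[conc & (rec["dbr_direction"] == "up") & rec["chd2_bound_hcIN"]] if len(rec) else rec
    summary["later_only_fraction_bound_up"] = (
        float((bound_up["kinetics"] == "later_only").mean()) if len(bound_up) else float("nan")
    )
    # gene-level dedup as auxiliary info
    if len(rec):
        summary["concordant_down_genes"] = int(
            rec.loc[conc & (rec["dbr_direction"] == "down"), "gene_id"].nunique()
        )
        summary["concordant_up_genes"] = int(
            rec.loc[conc & (rec["dbr_direction"] == "up"), "gene_id"].nunique()
        )
    else:
        summary["concordant_down_genes"] = 0
        summary["concordant_up_genes"] = 0
    return rec, summary
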