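"""Synthetic multi-layer study generator with a machine-readable truth ledger.

Generates a small genome, gene models, replicate peak sets for a TF
(CHD2-like) and three histone marks across three stages and two genotypes,
negative-binomial RNA counts following 12 planted temporal archetypes, a
per-peak acetylation count matrix with planted genotype effects, and
motif-planted peak sequences. Every planted fact is recorded in the
:class:`TruthLedger` so recovery can be scored exactly.
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict
from itertools import combinations
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from cistrack.config import AnalysisConfig, STAGES, GENOTYPES
from cistrack.expression import CountMatrix
from cistrack.intervals import ValidationError
from cistrack.io import (
    write_count_matrix,
    write_fasta,
    write_jaspar,
    write_peak_file,
    write_results_table,
)
from cistrack.motifs import PWM
from cistrack.temporal import GeneModels, membership_label, parse_membership

ALL_CLASSES = tuple(
    frozenset(c) for r in (1, 2, 3) for c in combinations(STAGES, r)
)

# 12 planted temporal archetypes in D0-relative space (D0 == 1 by construction).
# Index 2 is the "cell-cycle-like" late-down shape, index 3 the "neuronal"
# late-up shape, index 4 the D15-peaking progenitor-marker shape.
ARCHETYPES = np.array(
    [
        [1.0, 0.25, 0.25],   # early shut-down
        [1.0, 0.25, 1.0],    # transient dip
        [1.0, 1.0, 0.25],    # cell_cycle module shape (late down)
        [1.0, 1.0, 4.0],     # neuronal module shape (late up)
        [1.0, 2.83, 1.0],    # D15-peaking marker shape
        [1.0, 0.25, 4.0],    # dip then strong induction
        [1.0, 2.83, 4.0],    # early rise, sustained
        [1.0, 8.0, 8.0],     # strong early induction, plateau
        [1.0, 1.0, 11.31],   # late-only induction
        [1.0, 2.83, 0.25],   # transient pulse at D15
        [1.0, 8.0, 2.0],     # strong pulse, partial decay
        [1.0, 8.0, 0.5],     # strong pulse, full decay
    ]
)  # pairwise log2 distance >= 1.5 so profiles stay separable under count noise
CELL_CYCLE_ARCHETYPE = 2
NEURONAL_ARCHETYPE = 3
MARKER_ARCHETYPE = 4

PEAK_WIDTHS = {"CHD2": 400, "H3K4me3": 800, "H3K27ac": 600, "H3K27me3": 1000}


@dataclass
class SimParams:
    """Generator knobs; defaults give the 'default' study size."""

    seed: int = 0
    chrom_lengths: dict = field(
        default_factory=lambda: {"chr1": 1_200_000, "chr2": 1_000_000, "chr3": 800_000}
    )
    n_genes: int = 600
    gene_length_range: tuple[int, int] = (1_500, 4_000)
    gap_range: tuple[int, int] = (1_000, 2_500)
    n_exons_range: tuple[int, int] = (1, 4)
    # peaks
    peaks_per_class: int = 30
    n_module_genes: int = 25
    peak_jitter_sd: float = 10.0
    peak_dropout: float = 0.1
    n_noise_peaks: int = 20
    n_replicates: int = 4
    k27ac_coupling: float = 0.7
    k27ac_background_rate: float = 0.05
    bivalent_fraction: float = 0.2
    transition_fraction: float = 0.3  # D0-active peaks that turn bivalent later
    later_fraction_up: float = 0.4    # neuronal-module peaks bound only late
    later_fraction_down: float = 0.1
    # RNA
    n_rna_replicates: int = 4
    dispersion: float = 0.05
    base_mean: float = 50.0
    base_sigma: float = 1.0
    module_lfc: float = 2.0
    profile_noise_sd: float = 0.05
    # per-peak acetylation counts
    peak_count_mean: float = 100.0
    peak_count_sigma: float = 0.5
    # motifs
    motif_fg_fraction: float = 0.8
    gc_content: float = 0.41

    @classmethod
    def tiny(cls, seed: int = 0) -> "SimParams":
        return cls(
            seed=seed,
            chrom_lengths={"chr1": 200_000, "chr2": 150_000},
            n_genes=70,
            peaks_per_class=6,
            n_module_genes=5,
            n_noise_peaks=4,
        )


def _pyify(obj):
    """Recursively convert numpy scalars/containers into plain Python types."""
    if isinstance(obj, dict):
        return {_pyify(k): _pyify(v) for k, v in obj.items()}
    if isinstance(obj, (list, tuple)):
        return [_pyify(v) for v in obj]
    if isinstance(obj, (np.bool_,)):
        return bool(obj)
    if isinstance(obj, np.integer):
        return int(obj)
    if isinstance(obj, np.floating):
        return float(obj)
    return obj


@dataclass
class TruthLedger:
    """Planted ground truth for every synthetic record."""

    peaks: pd.DataFrame    # name, chrom, start, end, class, gene_id, k27ac_coupled,
    #                        bivalent, transition, module, motif_planted
    genes: pd.DataFrame    # gene_id, archetype, module, planted_lfc
    dbr_direction: dict    # peak name -> up/down/none in the D35 acetylation matrix
    seed: int = 0
    params: dict = field(default_factory=dict)

    def to_yaml(self, path: str | Path) -> None:
        doc = _pyify(
            {
                "seed": int(self.seed),
                "params": self.params,
                "peaks": self.peaks.to_dict(orient="records"),
                "genes": self.genes.to_dict(orient="records"),
                "dbr_direction": dict(self.dbr_direction),
            }
        )
        with open(path, "w") as fh:
            yaml.safe_dump(doc, fh, sort_keys=True)

    @classmethod
    def from_yaml(cls, path: str | Path) -> "TruthLedger":
        with open(path) as fh:
            doc = yaml.safe_load(fh)
        return cls(
            peaks=pd.DataFrame(doc["peaks"]),
            genes=pd.DataFrame(doc["genes"]),
            dbr_direction=doc["dbr_direction"],
            seed=doc["seed"],
            params=doc["params"],
        )


@dataclass
class SyntheticStudy:
    genome: dict[str, str]
    gene_models: GeneModels
    peak_files: dict[tuple[str, str, str, int], pd.DataFrame]  # (mark,stage,genotype,rep)
    rna: CountMatrix
    k27ac_counts: pd.DataFrame
    k27ac_samples: pd.DataFrame
    k27ac_union: pd.DataFrame  # chrom/start/end/name matching k27ac_counts index
    pwms: list[PWM]
    truth: TruthLedger


def _random_genome(rng: np.random.Generator, lengths: dict, gc: float) -> dict[str, str]:
    p = np.array([(1 - gc) / 2, gc / 2, gc / 2, (1 - gc) / 2])
    out = {}
    for chrom in sorted(lengths):
        codes = rng.choice(4, size=lengths[chrom], p=p)
        out[chrom] = codes.astype(np.uint8).tobytes().translate(
            bytes.maketrans(bytes(range(4)), b"ACGT")
        ).decode("ascii")
    return out


def _place_genes(rng: np.random.Generator, params: SimParams) -> GeneModels:
    rows, exon_rows = [], []
    gid = 0
    for chrom in sorted(params.chrom_lengths):
        clen = params.chrom_lengths[chrom]
        cursor = int(rng.integers(*params.gap_range))
        while gid < params.n_genes:
            glen = int(rng.integers(*params.gene_length_range))
            if cursor + glen + params.gap_range[1] > clen:
                break
            strand = "+" if rng.random() < 0.5 else "-"
            gene_id = f"g{gid:04d}"
            start, end = cursor, cursor + glen
            rows.append(
                {"gene_id": gene_id, "chrom": chrom, "start": start, "end": end, "strand": strand}
            )
            n_exons = int(rng.integers(params.n_exons_range[0], params.n_exons_range[1] + 1))
            cuts = np.sort(rng.choice(np.arange(1, glen // 100), size=2 * n_exons, replace=False)) * 100
            for k in range(n_exons):
                exon_rows.append(
                    {
                        "gene_id": gene_id,
                        "chrom": chrom,
                        "start": start + int(cuts[2 * k]) - 100,
                        "end": start + int(cuts[2 * k + 1]),
                    }
                )
            cursor = end + int(rng.integers(*params.gap_range))
            gid += 1
    genes = pd.DataFrame(rows)
    if len(genes) < params.n_genes:
        raise ValidationError(
            f"genome too small: placed {len(genes)} of {params.n_genes} genes"
        )
    return GeneModels(genes=genes, exons=pd.DataFrame(exon_rows))


def _plant_peaks(
    rng: np.random.Generator, params: SimParams, gm: GeneModels, arche: np.ndarray
) -> pd.DataFrame:
    """Plant CHD2 peaks with temporal classes, module links, and mark coupling."""
    genes = gm.genes
    cc_pool = rng.permutation(len(genes)).tolist()  # row positions of unused genes
    cc_genes = [i for i in cc_pool if arche[i] == CELL_CYCLE_ARCHETYPE][: params.n_module_genes]
    nn_genes = [i for i in cc_pool if arche[i] == NEURONAL_ARCHETYPE][: params.n_module_genes]
    used = set(cc_genes) | set(nn_genes)
    free = [i for i in cc_pool if i not in used]

    rows = []
    pid = 0

    def add_peak(gene_row: int | None, membership: frozenset, module: str) -> None:
        nonlocal pid
        if gene_row is not None:
            g = genes.iloc[gene_row]
            center = int(g["tss"]) + int(rng.integers(-150, 151))
            chrom = g["chrom"]
            gene_id = g["gene_id"]
        else:
            raise ValidationError("distal peaks placed separately")
        w = PEAK_WIDTHS["CHD2"]
        start = max(0, center - w // 2)
        rows.append(
            {
                "name": f"peak{pid:04d}",
                "chrom": chrom,
                "start": start,
                "end": start + w,
                "class": membership_label(membership),
                "gene_id": gene_id,
                "module": module,
                "k27ac_coupled": bool(rng.random() < params.k27ac_coupling),
                "bivalent": False,
                "transition": False,
                "motif_planted": False,
            }
        )
        pid += 1

    full = frozenset(STAGES)
    later_classes = [frozenset(["D15", "D35"]), frozenset(["D35"])]
    # deterministic quota per module so the planted later-binding fraction is exact
    n_later_cc = int(round(params.later_fraction_down * len(cc_genes)))
    for k, i in enumerate(cc_genes):
        m = later_classes[k % 2] if k < n_later_cc else full
        add_peak(i, m, "cell_cycle")
    n_later_nn = int(round(params.later_fraction_up * len(nn_genes)))
    for k, i in enumerate(nn_genes):
        m = later_classes[k % 2] if k < n_later_nn else full
        add_peak(i, m, "neuronal")
    for membership in ALL_CLASSES:
        for _ in range(params.peaks_per_class):
            if not free:
                raise ValidationError("not enough genes to host planted peaks")
            add_peak(free.pop(), membership, "none")

    peaks = pd.DataFrame(rows)
    # bivalent / transition flags on a subset (K4me3+K27me3 at later stages)
    biv = rng.random(len(peaks)) < params.bivalent_fraction
    peaks.loc[biv, "bivalent"] = True
    trans = biv & (rng.random(len(peaks)) < params.transition_fraction)
    peaks.loc[trans, "transition"] = True
    # module peaks are always acetylation-coupled so genotype effects propagate
    peaks.loc[peaks["module"] != "none", "k27ac_coupled"] = True
    return peaks


def _assign_archetypes(
    rng: np.random.Generator, genes: pd.DataFrame, params: SimParams
) -> np.ndarray:
    k = len(ARCHETYPES)
    arche = np.tile(np.arange(k), int(np.ceil(len(genes) / k)))[: len(genes)]
    rng.shuffle(arche)
    return arche


def _jittered_replicates(
    rng: np.random.Generator,
    planted: pd.DataFrame,
    present_mask: np.ndarray,
    params: SimParams,
    chrom_lengths: dict,
) -> list[pd.DataFrame]:
    """Per-replicate jittered/dropout copies of the planted rows where present."""
    reps = []
    for rep in range(params.n_replicates):
        keep = present_mask & (rng.random(len(planted)) >= params.peak_dropout)
        sub = planted.loc[keep, ["chrom", "start", "end", "name"]].copy()
        if params.peak_jitter_sd > 0 and len(sub):
            js = rng.normal(0, params.peak_jitter_sd, size=len(sub)).round().astype(int)
            je = rng.normal(0, params.peak_jitter_sd, size=len(sub)).round().astype(int)
            sub["start"] = np.maximum(0, sub["start"].to_numpy() + js)
            sub["end"] = sub["end"].to_numpy() + je
            bad = sub["start"] >= sub["end"]
            sub.loc[bad, "end"] = sub.loc[bad, "start"] + 50
        for chrom, clen in chrom_lengths.items():
            m = sub["chrom"] == chrom
            sub.loc[m, "end"] = np.minimum(sub.loc[m, "end"], clen)
        sub["name"] = [f"{n}_r{rep+1}" for n in sub["name"]]
        reps.append(sub.reset_index(drop=True))
    return reps


def _noise_peaks(
    rng: np.random.Generator,
    params: SimParams,
    planted: pd.DataFrame,
    width: int,
    tag: str,
) -> pd.DataFrame:
    """Private random peaks avoiding all planted intervals (with margin)."""
    occupied: dict[str, list[tuple[int, int]]] = {}
    for chrom, s, e in planted[["chrom", "start", "end"]].itertuples(index=False):
        occupied.setdefault(chrom, []).append((int(s) - width, int(e) + width))
    chroms = sorted(params.chrom_lengths)
    lens = np.array([params.chrom_lengths[c] for c in chroms], dtype=float)
    rows = []
    attempts = 0
    while len(rows) < params.n_noise_peaks and attempts < params.n_noise_peaks * 50:
        attempts += 1
        ci = rng.choice(len(chroms), p=lens / lens.sum())
        c = chroms[ci]
        s = int(rng.integers(0, params.chrom_lengths[c] - width))
        e = s + width
        if any(s < oe and os_ < e for os_, oe in occupied.get(c, ())):
            continue
        rows.append({"chrom": c, "start": s, "end": e, "name": f"noise_{tag}_{len(rows)}"})
    return pd.DataFrame(rows, columns=["chrom", "start", "end", "name"])


def _shift_center(planted: pd.DataFrame, width: int) -> pd.DataFrame:
    """Re-centre planted intervals at a different mark's width."""
    out = planted[["chrom", "start", "end", "name"]].copy()
    center = (out["start"] + out["end"]) // 2
    out["start"] = np.maximum(0, center - width // 2)
    out["end"] = out["start"] + width
    return out


def _nb_draw(rng: np.random.Generator, mu: np.ndarray, phi: float) -> np.ndarray:
    """NB(mean mu, dispersion phi) via gamma-Poisson mixture."""
    mu = np.maximum(np.asarray(mu, dtype=float), 1e-8)
    if phi <= 0:
        return rng.poisson(mu)
    shape = 1.0 / phi
    lam = rng.gamma(shape, mu * phi)
    return rng.poisson(lam)


def simulate_study(params: SimParams | None = None) -> SyntheticStudy:
    """Generate the full synthetic study; deterministic given ``params.seed``."""
    params = params or SimParams()
    if params.n_replicates < 2:
        raise ValidationError("need >= 2 replicates")
    if not 0 <= params.peak_dropout < 1:
        raise ValidationError("dropout must be in [0, 1)")
    if params.peak_jitter_sd < 0:
        raise ValidationError("jitter must be >= 0")
    rng = np.random.default_rng(params.seed)

    genome = _random_genome(rng, params.chrom_lengths, params.gc_content)
    gm = _place_genes(rng, params)
    arche = _assign_archetypes(np.random.default_rng(params.seed + 1), gm.genes, params)
    peaks = _plant_peaks(np.random.default_rng(params.seed + 2), params, gm, arche)

    # --- gene truth table -------------------------------------------------
    module = np.full(len(gm.genes), "none", dtype=object)
    lfc = np.zeros(len(gm.genes))
    gid_to_row = {g: i for i, g in enumerate(gm.genes["gene_id"])}
    for _, p in peaks.iterrows():
        if p["module"] != "none":
            row = gid_to_row[p["gene_id"]]
            module[row] = p["module"]
            lfc[row] = -params.module_lfc if p["module"] == "cell_cycle" else params.module_lfc
    genes_truth = pd.DataFrame(
        {
            "gene_id": gm.genes["gene_id"],
            "archetype": arche,
            "module": module,
            "planted_lfc": lfc,
        }
    )

    # --- replicate peak files --------------------------------------------
    peak_files: dict[tuple[str, str, str, int], pd.DataFrame] = {}
    memberships = [parse_membership(c) for c in peaks["class"]]
    rel_by_stage = {s: ARCHETYPES[arche, i] for i, s in enumerate(STAGES)}

    rng_peaks = np.random.default_rng(params.seed + 3)
    for stage in STAGES:
        chd2_present = np.array([stage in m for m in memberships])
        # histone planted sets for this stage
        k27ac_rows = [peaks[(chd2_present) & peaks["k27ac_coupled"]]]
        bg_ac = peaks[(chd2_present) & ~peaks["k27ac_coupled"]]
        bg_take = rng_peaks.random(len(bg_ac)) < params.k27ac_background_rate
        k27ac_rows.append(bg_ac[bg_take])
        k27ac_planted = _shift_center(pd.concat(k27ac_rows), PEAK_WIDTHS["H3K27ac"])

        # K4me3 at promoters of genes relatively high at this stage, plus
        # bivalent peaks; K27me3 at bivalent/transition peaks per stage.
        hi = rel_by_stage[stage] >= 1.0
        k4_gene_rows = gm.genes[hi]
        w4 = PEAK_WIDTHS["H3K4me3"]
        k4_prom = pd.DataFrame(
            {
                "chrom": k4_gene_rows["chrom"],
                "start": np.maximum(0, k4_gene_rows["tss"] - w4 // 2),
                "name": [f"k4_{g}" for g in k4_gene_rows["gene_id"]],
            }
        )
        k4_prom["end"] = k4_prom["start"] + w4
        biv_now = peaks["bivalent"] & chd2_present
        if stage == "D0":
            k27me3_mask = biv_now & ~peaks["transition"]
            k4_mask = biv_now
        else:
            k27me3_mask = biv_now
            k4_mask = biv_now
        k4_planted = pd.concat(
            [
                k4_prom[["chrom", "start", "end", "name"]],
                _shift_center(peaks[k4_mask], w4),
            ]
        ).reset_index(drop=True)
        k27me3_planted = _shift_center(peaks[k27me3_mask], PEAK_WIDTHS["H3K27me3"])

        for genotype in GENOTYPES:
            planted_by_mark = {
                "CHD2": (peaks[["chrom", "start", "end", "name"]], chd2_present),
                "H3K4me3": (k4_planted, np.ones(len(k4_planted), dtype=bool)),
                "H3K27ac": (k27ac_planted, np.ones(len(k27ac_planted), dtype=bool)),
                "H3K27me3": (k27me3_planted, np.ones(len(k27me3_planted), dtype=bool)),
            }
            for mark, (planted, present) in planted_by_mark.items():
                planted = planted.reset_index(drop=True)
                present = np.asarray(present)[: len(planted)]
                reps = _jittered_replicates(
                    rng_peaks, planted, present, params, params.chrom_lengths
                )
                for r, sub in enumerate(reps):
                    noise = _noise_peaks(
                        rng_peaks, params, peaks, PEAK_WIDTHS[mark],
                        tag=f"{mark}_{stage}_{genotype}_r{r+1}",
                    )
                    df = pd.concat([sub, noise], ignore_index=True)
                    df = df.sort_values(["chrom", "start", "end"], kind="mergesort")
                    peak_files[(mark, stage, genotype, r + 1)] = df.reset_index(drop=True)

    # --- RNA counts -------------------------------------------------------
    rng_rna = np.random.default_rng(params.seed + 4)
    base = np.exp(rng_rna.normal(np.log(params.base_mean), params.base_sigma, len(gm.genes)))
    base[module != "none"] *= 4.0  # keep module genes well-measured
    profiles = ARCHETYPES[arche]  # genes x 3
    gene_noise = np.exp(
        rng_rna.normal(0.0, params.profile_noise_sd, size=profiles.shape)
    )
    shaped = profiles * gene_noise
    counts = {}
    meta_rows = []
    for genotype in GENOTYPES:
        for si, stage in enumerate(STAGES):
            mu = base * shaped[:, si]
            if genotype == "HET" and stage == "D35":
                mu = mu * np.power(2.0, lfc)
            for rep in range(1, params.n_rna_replicates + 1):
                sample = f"RNA_{genotype}_{stage}_r{rep}"
                counts[sample] = _nb_draw(rng_rna, mu, params.dispersion)
                meta_rows.append(
                    {"sample": sample, "stage": stage, "genotype": genotype, "replicate": rep}
                )
    rna_counts = pd.DataFrame(counts, index=gm.genes["gene_id"])
    rna_samples = pd.DataFrame(meta_rows).set_index("sample")
    gene_lengths = pd.Series(
        (gm.genes["end"] - gm.genes["start"]).to_numpy(),
        index=gm.genes["gene_id"],
        name="length",
    )
    rna = CountMatrix(counts=rna_counts, samples=rna_samples, gene_lengths=gene_lengths)

    # --- per-peak K27ac counts at D35 (DBR layer) -------------------------
    rng_dbr = np.random.default_rng(params.seed + 5)
    d35_present = np.array([("D35" in m) for m in memberships])
    union_mask = d35_present & peaks["k27ac_coupled"].to_numpy()
    union = _shift_center(peaks[union_mask], PEAK_WIDTHS["H3K27ac"]).reset_index(drop=True)
    union_modules = peaks.loc[union_mask, "module"].to_numpy()
    mu0 = np.exp(
        rng_dbr.normal(np.log(params.peak_count_mean), params.peak_count_sigma, len(union))
    )
    peak_lfc = np.where(
        union_modules == "cell_cycle", -params.module_lfc,
        np.where(union_modules == "neuronal", params.module_lfc, 0.0),
    )
    k27ac_counts = {}
    k_meta = []
    for genotype in GENOTYPES:
        mu = mu0 * np.power(2.0, peak_lfc) if genotype == "HET" else mu0
        for rep in range(1, params.n_replicates + 1):
            sample = f"K27ac_D35_{genotype}_r{rep}"
            k27ac_counts[sample] = _nb_draw(rng_dbr, mu, params.dispersion)
            k_meta.append(
                {"sample": sample, "stage": "D35", "genotype": genotype, "replicate": rep}
            )
    k27ac_counts = pd.DataFrame(k27ac_counts, index=union["name"])
    k27ac_samples = pd.DataFrame(k_meta).set_index("sample")
    dbr_direction = {
        str(n): ("down" if m == "cell_cycle" else "up" if m == "neuronal" else "none")
        for n, m in zip(union["name"], union_modules)
    }

    # --- motif planting ---------------------------------------------------
    rng_motif = np.random.default_rng(params.seed + 6)
    planted_pwm_counts = np.array(
        [
            [20, 0, 0, 0, 0, 20, 0, 0],
            [0, 20, 0, 0, 20, 0, 0, 0],
            [0, 0, 20, 0, 0, 0, 20, 0],
            [0, 0, 0, 20, 0, 0, 0, 20],
        ],
        dtype=float,
    )  # consensus spells ACGTCAGT
    pwms = [PWM.from_counts("PLANTED", planted_pwm_counts, tf_class="HD")]
    decoy_rng = np.random.default_rng(params.seed + 7)
    for d in range(2):
        counts_d = decoy_rng.integers(0, 20, size=(4, 8)).astype(float) + 1
        pwms.append(PWM.from_counts(f"DECOY{d+1}", counts_d, tf_class="ZF"))
    site = "ACGTCAGT"
    d35_unique = peaks["class"] == "D35"
    plant = d35_unique & (rng_motif.random(len(peaks)) < params.motif_fg_fraction)
    peaks.loc[plant, "motif_planted"] = True
    for _, p in peaks[plant].iterrows():
        chrom = p["chrom"]
        center = (int(p["start"]) + int(p["end"])) // 2
        off = center - len(site) // 2
        seq = genome[chrom]
        genome[chrom] = seq[:off] + site + seq[off + len(site):]

    truth = TruthLedger(
        peaks=peaks,
        genes=genes_truth,
        dbr_direction=dbr_direction,
        seed=params.seed,
        params=_pyify(asdict(params)),
    )
    return SyntheticStudy(
        genome=genome,
        gene_models=gm,
        peak_files=peak_files,
        rna=rna,
        k27ac_counts=k27ac_counts,
        k27ac_samples=k27ac_samples,
        k27ac_union=union,
        pwms=pwms,
        truth=truth,
    )


def write_study(study: SyntheticStudy, outdir: str | Path) -> None:
    """Write every layer of the study in the pipeline's input formats."""
    outdir = Path(outdir)
    (outdir / "peaks").mkdir(parents=True, exist_ok=True)
    write_fasta(study.genome, outdir / "genome.fa")
    write_results_table(
        study.gene_models.genes[["gene_id", "chrom", "start", "end", "strand"]],
        outdir / "genes.tsv",
    )
    write_results_table(study.gene_models.exons, outdir / "exons.tsv")
    sheet_rows = []
    for (mark, stage, genotype, rep), df in sorted(study.peak_files.items()):
        fname = f"peaks/{mark}_{stage}_{genotype}_rep{rep}.bed"
        bed = df.copy()
        bed["score"] = 0
        bed["strand"] = "."
        write_peak_file(bed[["chrom", "start", "end", "name", "score", "strand"]], outdir / fname)
        sheet_rows.append(
            {
                "sample": f"{mark}_{stage}_{genotype}_rep{rep}",
                "mark": mark,
                "stage": stage,
                "genotype": genotype,
                "replicate": rep,
                "path": fname,
            }
        )
    write_results_table(pd.DataFrame(sheet_rows), outdir / "peak_samples.tsv")
    write_count_matrix(study.rna.counts, outdir / "rna_counts.tsv")
    write_results_table(study.rna.samples.reset_index(), outdir / "rna_samples.tsv")
    study.rna.gene_lengths.rename("length").to_csv(outdir / "gene_lengths.tsv", sep="\t")
    write_count_matrix(study.k27ac_counts, outdir / "k27ac_counts.tsv")
    write_results_table(study.k27ac_samples.reset_index(), outdir / "k27ac_samples.tsv")
    ub = study.k27ac_union.copy()
    ub["score"] = 0
    ub["strand"] = "."
    write_peak_file(ub[["chrom", "start", "end", "name", "score", "strand"]], outdir / "k27ac_union.bed")
    write_jaspar([(p.name, p.matrix * 100) for p in study.pwms], outdir / "motifs.jaspar")
    study.truth.to_yaml(outdir / "truth.yaml")


def score_class_recovery(
    truth_peaks: pd.DataFrame,
    consensus_by_stage: dict[str, pd.DataFrame],
    classes: dict[str, frozenset[str]],
) -> float:
    """Fraction of planted peaks whose consensus class matches the planted class.

    A planted peak is recovered when, at every stage of its planted class, a
    consensus peak covering the planted midpoint exists and carries exactly
    the planted membership.
    """
    n_ok = 0
    for _, p in truth_peaks.iterrows():
        planted = parse_membership(p["class"])
        mid = (int(p["start"]) + int(p["end"])) // 2
        ok = True
        for stage in sorted(planted):
            cons = consensus_by_stage[stage]
            m = (
                (cons["chrom"] == p["chrom"])
                & (cons["start"] <= mid)
                & (cons["end"] > mid)
            )
            names = cons.loc[m, "name"]
            if len(names) == 0 or any(classes[n] != planted for n in names):
                ok = False
                break
        n_ok += ok
    return n_ok / len(truth_peaks)


def load_study(indir: str | Path) -> SyntheticStudy:
    """Read a study directory written by :func:`write_study` back into memory."""
    from cistrack.io import (
        read_count_matrix,
        read_fasta,
        read_jaspar,
        read_peak_file,
        read_results_table,
        read_sample_sheet,
    )

    indir = Path(indir)
    genome = read_fasta(indir / "genome.fa")
    genes = read_results_table(indir / "genes.tsv")
    exons = read_results_table(indir / "exons.tsv")
    gm = GeneModels(genes=genes, exons=exons)
    sheet = read_sample_sheet(indir / "peak_samples.tsv")
    peak_files = {}
    for _, row in sheet.iterrows():
        ps = read_peak_file(
            indir / row["path"],
            "bed6",
            mark=row["mark"],
            stage=row["stage"],
            genotype=row["genotype"],
            replicate=int(row["replicate"]),
        )
        peak_files[(row["mark"], row["stage"], row["genotype"], int(row["replicate"]))] = (
            ps.intervals
        )
    rna_counts = read_count_matrix(indir / "rna_counts.tsv")
    rna_samples = read_results_table(indir / "rna_samples.tsv").set_index("sample")
    gene_lengths = pd.read_csv(indir / "gene_lengths.tsv", sep="\t", index_col=0)["length"]
    rna = CountMatrix(counts=rna_counts, samples=rna_samples, gene_lengths=gene_lengths)
    k27ac_counts = read_count_matrix(indir / "k27ac_counts.tsv")
    k27ac_samples = read_results_table(indir / "k27ac_samples.tsv").set_index("sample")
    union = read_peak_file(indir / "k27ac_union.bed", "bed6").intervals
    pwms = [PWM.from_counts(name, mat) for name, mat in read_jaspar(indir / "motifs.jaspar")]
    truth = TruthLedger.from_yaml(indir / "truth.yaml")
    return SyntheticStudy(
        genome=genome,
        gene_models=gm,
        peak_files=peak_files,
        rna=rna,
        k27ac_counts=k27ac_counts,
        k27ac_samples=k27ac_samples,
        k27ac_union=union[["chrom", "start", "end", "name"]],
        pwms=pwms,
        truth=truth,
    )


def export_fixture(size: str = "tiny", outdir: str | Path = "fixture", seed: int = 0) -> Path:
    """Write a packaged fixture directory ('tiny' for unit tests)."""
    if size == "tiny":
        params = SimParams.tiny(seed=seed)
    elif size == "default":
        params = SimParams(seed=seed)
    else:
        raise ValidationError(f"unknown fixture size {size!r}")
    study = simulate_study(params)
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    write_study(study, outdir)
    return outdir
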