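"""PWM scanning and foreground-vs-background motif enrichment.

Scanning is plain log2-odds over both strands; enrichment is a one-sided
Fisher exact test on per-sequence hit presence with BH correction across
motifs. Backgrounds are length-matched, GC-binned random regions sampled
away from the foreground.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from cistrack.config import AnalysisConfig
from cistrack.expression import bh_adjust
from cistrack.intervals import ValidationError, _overlap_edges

BASES = "ACGT"
_BASE_INDEX = {b: i for i, b in enumerate(BASES)}
_COMPLEMENT = str.maketrans("ACGTN", "TGCAN")


@dataclass
class PWM:
    """Position weight matrix with a log-odds hit threshold.

    ``matrix`` is (4, L) per-position base probabilities in A,C,G,T order;
    ``background`` the 4 background base frequencies. ``threshold`` is an
    absolute log2-odds cutoff; when None it is derived from
    ``relative_quantile`` of the maximum achievable score.
    """

    name: str
    matrix: np.ndarray
    background: np.ndarray = field(default_factory=lambda: np.full(4, 0.25))
    threshold: float | None = None
    tf_class: str = ""

    def __post_init__(self) -> None:
        self.matrix = np.asarray(self.matrix, dtype=float)
        self.background = np.asarray(self.background, dtype=float)
        if self.matrix.shape[0] != 4 or self.matrix.shape[1] < 4:
            raise ValidationError(f"PWM {self.name}: matrix must be 4 x L with L >= 4")
        if not np.allclose(self.matrix.sum(axis=0), 1.0, atol=1e-6):
            raise ValidationError(f"PWM {self.name}: columns must sum to 1")
        if not np.isclose(self.background.sum(), 1.0, atol=1e-6):
            raise ValidationError(f"PWM {self.name}: background must sum to 1")

    @classmethod
    def from_counts(
        cls,
        name: str,
        counts: np.ndarray,
        pseudocount: float = 0.5,
        background: np.ndarray | None = None,
        **kwargs,
    ) -> "PWM":
        counts = np.asarray(counts, dtype=float)
        probs = (counts + pseudocount) / (counts + pseudocount).sum(axis=0)
        bg = np.full(4, 0.25) if background is None else np.asarray(background, float)
        return cls(name=name, matrix=probs, background=bg, **kwargs)

    @property
    def length(self) -> int:
        return self.matrix.shape[1]

    @property
    def logodds(self) -> np.ndarray:
        with np.errstate(divide="ignore"):
            return np.log2(self.matrix) - np.log2(self.background[:, None])

    @property
    def max_score(self) -> float:
        return float(self.logodds.max(axis=0).sum())

    def effective_threshold(self, quantile: float = 0.85) -> float:
        if self.threshold is not None:
            return self.threshold
        lo = self.logodds
        finite_min = np.where(np.isfinite(lo), lo, -50.0).min(axis=0).sum()
        return float(finite_min + quantile * (self.max_score - finite_min))

    def reverse_complement(self) -> "PWM":
        return PWM(
            name=self.name + "_rc",
            matrix=self.matrix[::-1, ::-1].copy(),
            background=self.background[::-1].copy(),
            threshold=self.threshold,
            tf_class=self.tf_class,
        )


def _encode(seq: str) -> np.ndarray:
    arr = np.frombuffer(seq.upper().encode("ascii"), dtype=np.uint8)
    out = np.full(len(arr), 4, dtype=np.int8)  # 4 = N / anything else
    for b, i in _BASE_INDEX.items():
        out[arr == ord(b)] = i
    return out


def _scan_strand(codes: np.ndarray, logodds: np.ndarray) -> np.ndarray:
    """Window scores at every forward position (positions with N score -inf)."""
    L = logodds.shape[1]
    n = len(codes) - L + 1
    if n <= 0:
        return np.zeros(0)
    lut = np.vstack([logodds, np.full((1, L), -np.inf)])  # row 4 = N
    scores = np.zeros(n)
    for j in range(L):
        scores += lut[codes[j : j + n], j]
    return scores


def scan_pwm(seq: str, pwm: PWM, quantile: float = 0.85) -> pd.DataFrame:
    """Scan one sequence on both strands.

    Returns a frame of hits with columns position (0-based, forward
    coordinates of the match window start), strand, score; hits are window
    scores >= the PWM's effective threshold. Sequences shorter than the motif
    yield an empty frame.
    """
    thr = pwm.effective_threshold(quantile)
    codes = _encode(seq)
    L = pwm.length
    rows = []
    fwd = _scan_strand(codes, pwm.logodds)
    for pos in np.flatnonzero(fwd >= thr):
        rows.append({"position": int(pos), "strand": "+", "score": float(fwd[pos])})
    rc_codes = _encode(seq.translate(_COMPLEMENT)[::-1])
    rev = _scan_strand(rc_codes, pwm.logodds)
    n = len(seq)
    for pos in np.flatnonzero(rev >= thr):
        rows.append(
            {"position": int(n - L - pos), "strand": "-", "score": float(rev[pos])}
        )
    out = pd.DataFrame(rows, columns=["position", "strand", "score"])
    return out.sort_values(["position", "strand"]).reset_index(drop=True)


def has_site(seq: str, pwm: PWM, quantile: float = 0.85) -> bool:
    return len(scan_pwm(seq, pwm, quantile)) > 0


def motif_enrichment(
    fg: Mapping[str, str],
    bg: Mapping[str, str],
    pwms: Sequence[PWM],
    cfg: AnalysisConfig | None = None,
) -> pd.DataFrame:
    """Per-motif foreground enrichment over background sequences.

    Builds the 2x2 table (has >= 1 site vs not, fg vs bg) per motif, tests
    one-sided Fisher exact for foreground excess, and BH-adjusts across
    motifs. Degenerate tables (no sites anywhere) give odds ratio 1, p 1.
    """
    if not fg or not bg:
        raise ValidationError("foreground and background must both be nonempty")
    shared = set(fg) & set(bg)
    if shared:
        raise ValidationError(f"fg and bg share sequence ids: {sorted(shared)[:5]}")
    quantile = cfg.motif_logodds_quantile if cfg is not None else 0.85
    rows = []
    for pwm in pwms:
        fg_hits = sum(has_site(s, pwm, quantile) for s in fg.values())
        bg_hits = sum(has_site(s, pwm, quantile) for s in bg.values())
        table = [
            [fg_hits, len(fg) - fg_hits],
            [bg_hits, len(bg) - bg_hits],
        ]
        if fg_hits + bg_hits == 0:
            odds, p = 1.0, 1.0
        else:
            odds, p = stats.fisher_exact(table, alternative="greater")
        rows.append(
            {
                "motif": pwm.name,
                "tf_class": pwm.tf_class,
                "fg_with_site": fg_hits,
                "bg_with_site": bg_hits,
                "fg_size": len(fg),
                "bg_size": len(bg),
                "pct_fg_with_site": 100.0 * fg_hits / len(fg),
                "pct_bg_with_site": 100.0 * bg_hits / len(bg),
                "odds_ratio": float(odds) if np.isfinite(odds) else np.inf,
                "pvalue": float(p),
            }
        )
    out = pd.DataFrame(rows)
    out["qvalue"] = bh_adjust(out["pvalue"].to_numpy())
    return out.set_index("motif")


def gc_content(seq: str) -> float:
    if not seq:
        return 0.0
    s = seq.upper()
    return (s.count("G") + s.count("C")) / len(s)


def make_background(
    fg_peaks: pd.DataFrame,
    genome: Mapping[str, str],
    cfg: AnalysisConfig,
    oversample: int = 2,
    n_gc_bins: int = 5,
    rng: np.random.Generator | None = None,
    max_tries: int = 200,
) -> pd.DataFrame:
    """Sample length-matched, GC-binned background regions avoiding the foreground.

    For every foreground peak, ``oversample`` regions of identical length are
    drawn uniformly from the same genome, rejected when they overlap any
    foreground peak (under the configured predicate) or fall in a different
    GC bin (``n_gc_bins`` equal-width bins). Returns a frame with
    chrom/start/end/name/seq columns.
    """
    if rng is None:
        rng = np.random.default_rng(cfg.rng_seed)
    missing = set(fg_peaks["chrom"]) - set(genome)
    if missing:
        raise ValidationError(f"genome lacks chromosomes {sorted(missing)}")
    chrom_names = sorted(genome)
    chrom_lens = np.array([len(genome[c]) for c in chrom_names], dtype=float)
    chrom_p = chrom_lens / chrom_lens.sum()

    fg_by_chrom: dict[str, list[tuple[int, int]]] = {}
    for chrom, s, e in fg_peaks[["chrom", "start", "end"]].itertuples(index=False):
        fg_by_chrom.setdefault(chrom, []).append((int(s), int(e)))

    def _overlaps_fg(chrom: str, s: int, e: int) -> bool:
        for fs, fe in fg_by_chrom.get(chrom, ()):
            o = min(e, fe) - max(s, fs)
            if o <= 0:
                continue
            fa = cfg.overlap_frac_query * (fe - fs)
            fb = cfg.overlap_frac_subject * (e - s)
            hit = (o >= fa) or (o >= fb) if cfg.overlap_either else (o >= fa and o >= fb)
            if hit:
                return True
        return False

    rows = []
    for idx, (chrom, s, e, name) in enumerate(
        fg_peaks[["chrom", "start", "end", "name"]].itertuples(index=False)
    ):
        length = int(e) - int(s)
        fg_gc_bin = min(int(gc_content(genome[chrom][s:e]) * n_gc_bins), n_gc_bins - 1)
        for copy in range(oversample):
            placed = False
            for _ in range(max_tries):
                ci = rng.choice(len(chrom_names), p=chrom_p)
                c = chrom_names[ci]
                if len(genome[c]) <= length:
                    continue
                bs = int(rng.integers(0, len(genome[c]) - length))
                be = bs + length
                if _overlaps_fg(c, bs, be):
                    continue
                seq = genome[c][bs:be]
                b = min(int(gc_content(seq) * n_gc_bins), n_gc_bins - 1)
                if b != fg_gc_bin:
                    continue
                rows.append(
                    {"chrom": c, "start": bs, "end": be, "name": f"bg_{name}_{copy}", "seq": seq}
                )
                placed = True
                break
            if not placed:
                raise ValidationError(
                    f"could not place background for {name} (length {length}, GC bin {fg_gc_bin})"
                )
    return pd.DataFrame(rows, columns=["chrom", "start", "end", "name", "seq"])


def extract_sequences(peaks: pd.DataFrame, genome: Mapping[str, str]) -> dict[str, str]:
    """Pull peak sequences from a genome mapping, keyed by peak name."""
    out = {}
    for chrom, s, e, name in peaks[["chrom", "start", "end", "name"]].itertuples(index=False):
        if chrom not in genome:
            raise ValidationError(f"genome lacks chromosome {chrom}")
        out[str(name)] = genome[chrom][int(s) : int(e)]
    return out
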