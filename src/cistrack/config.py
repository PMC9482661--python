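"""Central analysis configuration.

All numeric thresholds used anywhere in the pipeline live on
:class:`AnalysisConfig`; modules never hard-code them. The defaults are the
standard settings of this analysis (reciprocal 25% overlap in either-mode,
2-of-4 replicate support, a +/-2 kb promoter window, a 1.5-fold dynamic-gene
filter, K=12 temporal clusters, and 2-fold / 1 CPM / FDR 0.05 differential
cutoffs).
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field
from pathlib import Path

import yaml

STAGES = ("D0", "D15", "D35")
GENOTYPES = ("WT", "HET")
MARKS = ("CHD2", "H3K4me3", "H3K27ac", "H3K27me3")


class ConfigError(ValueError):
    """Raised when a configuration value violates its contract."""


@dataclass
class AnalysisConfig:
    # reciprocal-fraction overlap predicate (bedtools -f/-F/-e semantics)
    overlap_frac_query: float = 0.25
    overlap_frac_subject: float = 0.25
    overlap_either: bool = True
    # replicate-consensus rule
    min_replicate_support: int = 2
    n_replicates: int = 4
    # annotation
    promoter_window_bp: int = 2000
    tts_window_bp: int = 1000
    # temporal expression clustering
    dynamic_fold_threshold: float = 1.5
    n_clusters: int = 12
    rpkm_pseudocount: float = 0.1
    kmeans_restarts: int = 50
    # differential expression
    de_fold_threshold: float = 2.0
    de_min_cpm: float = 1.0
    de_fdr: float = 0.05
    # differential binding
    dbr_fold_threshold: float = 2.0
    dbr_fdr: float = 0.05
    # motif scanning
    motif_logodds_quantile: float = 0.85
    # seeded randomness for every stochastic stage
    rng_seed: int = 0

    def __post_init__(self) -> None:
        for name in ("overlap_frac_query", "overlap_frac_subject"):
            v = getattr(self, name)
            if not 0 < v <= 1:
                raise ConfigError(f"{name} must be in (0, 1], got {v}")
        for name in ("min_replicate_support", "n_replicates", "promoter_window_bp",
                     "tts_window_bp", "n_clusters"):
            v = getattr(self, name)
            if not (isinstance(v, int) and v > 0):
                raise ConfigError(f"{name} must be a positive integer, got {v!r}")
        for name in ("dynamic_fold_threshold", "de_fold_threshold", "de_min_cpm",
                     "dbr_fold_threshold", "rpkm_pseudocount"):
            if getattr(self, name) <= 0:
                raise ConfigError(f"{name} must be positive")
        for name in ("de_fdr", "dbr_fdr", "motif_logodds_quantile"):
            v = getattr(self, name)
            if not 0 < v < 1:
                raise ConfigError(f"{name} must be in (0, 1), got {v}")

    def to_dict(self) -> dict:
        return dataclasses.asdict(self)

    @classmethod
    def from_dict(cls, d: dict) -> "AnalysisConfig":
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(d) - known
        if unknown:
            raise ConfigError(f"unknown config keys: {sorted(unknown)}")
        return cls(**d)

    def save(self, path: str | Path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(self.to_dict(), fh, sort_keys=True)

    @classmethod
    def load(cls, path: str | Path) -> "AnalysisConfig":
        with open(path) as fh:
            d = yaml.safe_load(fh)
        if not isinstance(d, dict):
            raise ConfigError(f"config file {path} does not hold a mapping")
        return cls.from_dict(d)

    def replace(self, **kwargs) -> "AnalysisConfig":
        return dataclasses.replace(self, **kwargs)
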