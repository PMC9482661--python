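"""Readers and writers for the plain-text formats the pipeline speaks.

Peaks travel as BED6 / ENCODE narrowPeak, tables as TSV with a header row,
sequences as FASTA, and motifs as JASPAR-style count matrices. Every
reader/writer pair round-trips valid files.
"""

from __future__ import annotations

from pathlib import Path
from typing import Iterable, Mapping

import numpy as np
import pandas as pd

from cistrack.config import ConfigError
from cistrack.intervals import BED_COLUMNS, PeakSet, ValidationError

NARROWPEAK_COLUMNS = BED_COLUMNS + ["signalValue", "pValue", "qValue", "summit_offset"]


class PeakParseError(ValueError):
    """Malformed peak line; message carries the 1-based line number."""


def read_peak_file(
    path: str | Path,
    dialect: str = "bed6",
    *,
    mark: str = "",
    stage: str = "",
    genotype: str = "",
    replicate: int = 0,
) -> PeakSet:
    """Parse a BED6 or 10-column narrowPeak file into a :class:`PeakSet`.

    Coordinates are taken as 0-based half-open per the BED standard. For
    narrowPeak input an absolute ``summit`` column (start + summit offset) is
    added; a ``-1`` offset (summit unknown) yields ``summit = -1``.
    """
    if dialect not in ("bed6", "narrowPeak"):
        raise ConfigError(f"unknown peak dialect {dialect!r}")
    rows = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith(("#", "track", "browser")):
                continue
            parts = line.split("\t")
            if len(parts) < 3:
                raise PeakParseError(f"{path}:{lineno}: fewer than 3 columns")
            try:
                start = int(parts[1])
                end = int(parts[2])
            except ValueError as exc:
                raise PeakParseError(f"{path}:{lineno}: non-integer coordinate") from exc
            if start >= end:
                raise PeakParseError(f"{path}:{lineno}: start >= end ({start} >= {end})")
            if start < 0:
                raise PeakParseError(f"{path}:{lineno}: negative start {start}")
            row = {
                "chrom": parts[0],
                "start": start,
                "end": end,
                "name": parts[3] if len(parts) > 3 else f"peak_{lineno}",
                "score": float(parts[4]) if len(parts) > 4 and parts[4] != "." else 0.0,
                "strand": parts[5] if len(parts) > 5 else ".",
            }
            if dialect == "narrowPeak":
                if len(parts) < 10:
                    raise PeakParseError(f"{path}:{lineno}: narrowPeak needs 10 columns")
                row["signalValue"] = float(parts[6])
                row["pValue"] = float(parts[7])
                row["qValue"] = float(parts[8])
                offset = int(parts[9])
                row["summit"] = start + offset if offset >= 0 else -1
            rows.append(row)
    cols = BED_COLUMNS + (["signalValue", "pValue", "qValue", "summit"] if dialect == "narrowPeak" else [])
    df = pd.DataFrame(rows, columns=cols)
    return PeakSet(intervals=df, mark=mark, stage=stage, genotype=genotype, replicate=replicate)


def write_peak_file(frame: pd.DataFrame, path: str | Path) -> None:
    """Write a peak frame as headerless tab-separated BED-like text.

    All columns present in the frame are written in order (BED6 first when
    present), so consensus extras like ``support`` survive the round trip for
    readers that take extra columns.
    """
    cols = [c for c in BED_COLUMNS if c in frame.columns]
    cols += [c for c in frame.columns if c not in cols]
    frame[cols].to_csv(path, sep="\t", header=False, index=False)


def write_results_table(records: pd.DataFrame | Iterable[Mapping], path: str | Path) -> None:
    """Write result records as TSV with a header row (exact round trip)."""
    df = records if isinstance(records, pd.DataFrame) else pd.DataFrame(list(records))
    df.to_csv(path, sep="\t", index=False)


def read_results_table(path: str | Path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t")


def read_sample_sheet(path: str | Path) -> pd.DataFrame:
    """Sample metadata TSV: columns sample, mark, stage, genotype, replicate[, path]."""
    df = pd.read_csv(path, sep="\t", dtype={"sample": str})
    required = {"sample", "stage", "genotype", "replicate"}
    missing = required - set(df.columns)
    if missing:
        raise ValidationError(f"sample sheet lacks columns {sorted(missing)}")
    return df


def read_count_matrix(path: str | Path) -> pd.DataFrame:
    """Gene x sample counts, first column = gene/peak id (index)."""
    df = pd.read_csv(path, sep="\t", index_col=0)
    if (df.to_numpy() < 0).any():
        raise ValidationError(f"negative counts in {path}")
    return df


def write_count_matrix(df: pd.DataFrame, path: str | Path) -> None:
    df.to_csv(path, sep="\t")


def read_fasta(path: str | Path) -> dict[str, str]:
    """FASTA file to an ordered {name: sequence} mapping (uppercased)."""
    seqs: dict[str, str] = {}
    name = None
    chunks: list[str] = []
    with open(path) as fh:
        for line in fh:
            line = line.rstrip()
            if line.startswith(">"):
                if name is not None:
                    seqs[name] = "".join(chunks).upper()
                name = line[1:].split()[0]
                chunks = []
            elif line:
                chunks.append(line)
    if name is not None:
        seqs[name] = "".join(chunks).upper()
    return seqs


def write_fasta(seqs: Mapping[str, str], path: str | Path, width: int = 80) -> None:
    with open(path, "w") as fh:
        for name, seq in seqs.items():
            fh.write(f">{name}\n")
            for i in range(0, len(seq), width):
                fh.write(seq[i : i + width] + "\n")


def read_jaspar(path: str | Path) -> list[tuple[str, np.ndarray]]:
    """Parse JASPAR-style plain-text count matrices.

    Expected block format::

        >MA0001.1 NAME
        A [ 4 19 0 ... ]
        C [16  0 20 ...]
        G [ 0  1  0 ...]
        T [ 0  0  0 ...]

    Returns ``[(name, counts)]`` with counts shaped (4, L) in A,C,G,T order.
    """
    motifs: list[tuple[str, np.ndarray]] = []
    name = None
    rows: dict[str, list[float]] = {}
    order = "ACGT"

    def flush() -> None:
        if name is None:
            return
        missing = [b for b in order if b not in rows]
        if missing:
            raise ValidationError(f"motif {name}: missing rows {missing}")
        mat = np.array([rows[b] for b in order], dtype=float)
        if mat.shape[1] < 1 or len({len(rows[b]) for b in order}) != 1:
            raise ValidationError(f"motif {name}: ragged matrix")
        motifs.append((name, mat))

    with open(path) as fh:
        for line in fh:
            line = line.strip()
            if not line:
                continue
            if line.startswith(">"):
                flush()
                fields = line[1:].split()
                name = fields[-1] if len(fields) > 1 else fields[0]
                rows = {}
            else:
                base = line[0].upper()
                body = line[1:].replace("[", " ").replace("]", " ")
                rows[base] = [float(x) for x in body.split()]
    flush()
    return motifs


def write_jaspar(motifs: Iterable[tuple[str, np.ndarray]], path: str | Path) -> None:
    with open(path, "w") as fh:
        for name, mat in motifs:
            fh.write(f">{name}\n")
            for base, row in zip("ACGT", np.asarray(mat)):
                vals = " ".join(f"{v:g}" for v in row)
                fh.write(f"{base} [ {vals} ]\n")
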