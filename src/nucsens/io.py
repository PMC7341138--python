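"""Readers and writers for the standard formats the pipeline touches.

BED3 fragment intervals, BED6 TSS annotation, ENCODE narrowPeak, two-column
expression TSV, and TSV promoter matrices with an ``NA`` sentinel. All
coordinates are 0-based half-open on disk and in memory.
"""

from __future__ import annotations

import os
from pathlib import Path

import numpy as np
import pandas as pd

from .containers import (
    NARROWPEAK_COLUMNS,
    ExpressionTable,
    FragmentSet,
    PeakSet,
    PromoterMatrix,
    TssAnnotation,
)


class ParseError(ValueError):
    """A malformed record; the message names the offending line."""


def _read_table(path: str | os.PathLike, n_cols: int, what: str) -> pd.DataFrame:
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(f"{what} file not found: {path}")
    try:
        df = pd.read_csv(
            path, sep=r"\s+", header=None, comment="#", dtype=str, engine="python"
        )
    except pd.errors.EmptyDataError:
        return pd.DataFrame(columns=range(n_cols))
    if df.shape[1] < n_cols:
        raise ParseError(
            f"{path}: expected at least {n_cols} columns, found {df.shape[1]}"
        )
    return df


def _int_column(df: pd.DataFrame, col: int, path: Path | str, what: str) -> np.ndarray:
    raw = df[col]
    converted = pd.to_numeric(raw, errors="coerce")
    bad = converted.isna() | (converted != converted.round())
    if bad.any():
        line = int(np.flatnonzero(bad.to_numpy())[0]) + 1
        raise ParseError(f"{path}: line {line}: non-integer {what} {raw[bad].iloc[0]!r}")
    return converted.to_numpy(dtype=np.int64)


def read_fragments_bed(path: str | os.PathLike, label: str = "") -> FragmentSet:
    """Read BED3+ fragment intervals, one fragment per line."""
    df = _read_table(path, 3, "fragment BED")
    if df.empty:
        return FragmentSet([], [], [], label=label)
    starts = _int_column(df, 1, path, "start")
    ends = _int_column(df, 2, path, "end")
    bad = (ends <= starts) | (starts < 0)
    if bad.any():
        line = int(np.flatnonzero(bad)[0]) + 1
        raise ParseError(
            f"{path}: line {line}: invalid interval "
            f"[{starts[line - 1]}, {ends[line - 1]})"
        )
    return FragmentSet(df[0].to_numpy(dtype=object), starts, ends, label=label)


def write_fragments_bed(fragments: FragmentSet, path: str | os.PathLike) -> None:
    pd.DataFrame(
        {"chrom": fragments.chroms, "start": fragments.starts, "end": fragments.ends}
    ).to_csv(path, sep="\t", header=False, index=False)


def read_tss_annotation(path: str | os.PathLike, flank: int = 1000) -> TssAnnotation:
    """Read a BED6-like TSS annotation.

    The TSS is the start coordinate of +-strand records and end-1 of
    --strand records (standard RefSeq-derived convention).
    """
    df = _read_table(path, 6, "TSS annotation")
    if df.empty:
        raise ParseError(f"{path}: empty annotation")
    starts = _int_column(df, 1, path, "start")
    ends = _int_column(df, 2, path, "end")
    strands = df[5].to_numpy(dtype=object)
    bad = ~np.isin(strands, ["+", "-"])
    if bad.any():
        line = int(np.flatnonzero(bad)[0]) + 1
        raise ParseError(f"{path}: line {line}: strand must be + or -")
    tss = np.where(strands == "+", starts, ends - 1)
    records = pd.DataFrame(
        {"gene_id": df[3], "chrom": df[0], "tss": tss, "strand": strands}
    )
    return TssAnnotation(records, flank=flank)


def write_tss_annotation(annotation: TssAnnotation, path: str | os.PathLike) -> None:
    """Write BED6 with 1-bp intervals so the TSS convention round-trips."""
    r = annotation.records
    starts = np.where(r["strand"] == "+", r["tss"], r["tss"])
    out = pd.DataFrame(
        {
            "chrom": r["chrom"],
            "start": starts,
            "end": starts + 1,
            "name": r["gene_id"],
            "score": 0,
            "strand": r["strand"],
        }
    )
    out.to_csv(path, sep="\t", header=False, index=False)


def read_narrowpeak(path: str | os.PathLike, factor: str = "") -> PeakSet:
    """Read an ENCODE narrowPeak (BED6+4) file."""
    df = _read_table(path, 10, "narrowPeak")
    if df.empty:
        records = pd.DataFrame(
            {c: pd.Series(dtype=float if c in ("score", "signalValue", "pValue",
                                               "qValue") else
                          (np.int64 if c in ("start", "end", "summit") else object))
             for c in NARROWPEAK_COLUMNS}
        )
        return PeakSet(records, factor)
    records = pd.DataFrame(
        {
            "chrom": df[0],
            "start": _int_column(df, 1, path, "start"),
            "end": _int_column(df, 2, path, "end"),
            "name": df[3],
            "score": pd.to_numeric(df[4]),
            "strand": df[5],
            "signalValue": pd.to_numeric(df[6]).astype(float),
            "pValue": pd.to_numeric(df[7]).astype(float),
            "qValue": pd.to_numeric(df[8]).astype(float),
            "summit": _int_column(df, 9, path, "summit"),
        }
    )
    return PeakSet(records, factor=factor)


def write_narrowpeak(peaks: PeakSet, path: str | os.PathLike) -> None:
    peaks.records[NARROWPEAK_COLUMNS].to_csv(path, sep="\t", header=False, index=False)


def read_expression_table(path: str | os.PathLike) -> ExpressionTable:
    """Read a two-column TSV (gene_id, value)."""
    df = _read_table(path, 2, "expression")
    if df.empty:
        return ExpressionTable(pd.Series(dtype=float))
    values = pd.to_numeric(df[1], errors="coerce")
    if values.isna().any():
        line = int(np.flatnonzero(values.isna().to_numpy())[0]) + 1
        raise ParseError(f"{path}: line {line}: non-numeric expression value")
    return ExpressionTable(pd.Series(values.to_numpy(), index=df[0].tolist()))


def write_expression_table(expr: ExpressionTable, path: str | os.PathLike) -> None:
    expr.values.to_csv(path, sep="\t", header=False)


def write_matrix(matrix: PromoterMatrix, path: str | os.PathLike) -> None:
    """Write a promoter matrix as TSV: header of window-center offsets,
    first column gene_id, missing cells as ``NA``. Full float precision so a
    round-trip read reproduces the values exactly."""
    if matrix.values.size == 0:
        raise ValueError("refusing to write an empty matrix")
    out = matrix.values.copy()
    out.index.name = "gene_id"
    out.to_csv(path, sep="\t", na_rep="NA", float_format="%.17g")


def read_matrix(path: str | os.PathLike, metadata: dict | None = None) -> PromoterMatrix:
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(f"matrix file not found: {path}")
    df = pd.read_csv(path, sep="\t", index_col=0, na_values=["NA"])
    df.columns = [int(c) if float(c) == int(float(c)) else float(c) for c in df.columns]
    return PromoterMatrix(df, metadata or {})


def bam_to_fragments(path: str | os.PathLike, label: str = "",
                     min_mapq: int = 1) -> FragmentSet:
    """Convert properly-paired, uniquely aligned BAM records to outer-span
    fragment intervals. Optional; BED is the canonical input."""
    import pysam  # deferred: optional dependency

    chroms, starts, ends = [], [], []
    with pysam.AlignmentFile(str(path)) as bam:
        for read in bam:
            if (
                not read.is_proper_pair
                or read.is_secondary
                or read.is_supplementary
                or read.is_read2
                or read.mapping_quality < min_mapq
                or read.template_length <= 0
            ):
                continue
            chroms.append(read.reference_name)
            starts.append(read.reference_start)
            ends.append(read.reference_start + read.template_length)
    return FragmentSet(chroms, starts, ends, label=label)
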