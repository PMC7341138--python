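"""Shared in-memory containers for TSS-anchored MNase-seq analysis.

Coordinates are 0-based half-open (BED convention) everywhere. Promoter
matrices are strand-oriented: positive offsets are downstream of
transcription, so a minus-strand gene's row reads left-to-right in the
direction of transcription.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterator, Mapping, Sequence

import numpy as np
import pandas as pd

VALID_STRANDS = ("+", "-", ".")


@dataclass(frozen=True)
class GenomicInterval:
    """A 0-based half-open genomic interval."""

    chrom: str
    start: int
    end: int
    strand: str = "."

    def __post_init__(self) -> None:
        if self.start < 0:
            raise ValueError(f"start must be >= 0, got {self.start}")
        if self.end <= self.start:
            raise ValueError(
                f"end must be > start, got [{self.start}, {self.end})"
            )
        if self.strand not in VALID_STRANDS:
            raise ValueError(f"strand must be one of {VALID_STRANDS}")

    @property
    def length(self) -> int:
        return self.end - self.start


class FragmentSet:
    """Aligned paired-end fragment intervals for one digest level/condition.

    Stored columnar (numpy arrays) for speed; fragments are strand-less,
    each pair represented by its merged outer span.
    """

    def __init__(
        self,
        chroms: Sequence[str] | np.ndarray,
        starts: Sequence[int] | np.ndarray,
        ends: Sequence[int] | np.ndarray,
        label: str = "",
    ) -> None:
        self.chroms = np.asarray(chroms, dtype=object)
        self.starts = np.asarray(starts, dtype=np.int64)
        self.ends = np.asarray(ends, dtype=np.int64)
        if not (len(self.chroms) == len(self.starts) == len(self.ends)):
            raise ValueError("chroms, starts and ends must have equal length")
        if np.any(self.starts < 0):
            raise ValueError("fragment starts must be >= 0")
        if np.any(self.ends <= self.starts):
            bad = int(np.argmax(self.ends <= self.starts))
            raise ValueError(
                f"fragment {bad}: end ({self.ends[bad]}) must be > start "
                f"({self.starts[bad]})"
            )
        self.label = label

    @classmethod
    def from_intervals(
        cls, intervals: Sequence[GenomicInterval], label: str = ""
    ) -> "FragmentSet":
        return cls(
            [iv.chrom for iv in intervals],
            [iv.start for iv in intervals],
            [iv.end for iv in intervals],
            label=label,
        )

    @property
    def total_count(self) -> int:
        return len(self.starts)

    @property
    def lengths(self) -> np.ndarray:
        return self.ends - self.starts

    def midpoints(self) -> np.ndarray:
        """Fragment midpoints, floor((start + end) / 2)."""
        return (self.starts + self.ends) // 2

    def intervals(self) -> Iterator[GenomicInterval]:
        for c, s, e in zip(self.chroms, self.starts, self.ends):
            yield GenomicInterval(str(c), int(s), int(e), ".")

    def subset(self, mask: np.ndarray, label: str | None = None) -> "FragmentSet":
        return FragmentSet(
            self.chroms[mask],
            self.starts[mask],
            self.ends[mask],
            label=self.label if label is None else label,
        )

    def __len__(self) -> int:
        return self.total_count

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, FragmentSet):
            return NotImplemented
        return (
            np.array_equal(self.chroms, other.chroms)
            and np.array_equal(self.starts, other.starts)
            and np.array_equal(self.ends, other.ends)
        )

    def __repr__(self) -> str:
        return f"FragmentSet(n={self.total_count}, label={self.label!r})"


class TssAnnotation:
    """Gene id, chromosome, TSS coordinate and strand, plus the flank size.

    The promoter window of a gene is [tss - flank, tss + flank).
    """

    def __init__(self, records: pd.DataFrame, flank: int = 1000) -> None:
        required = {"gene_id", "chrom", "tss", "strand"}
        if not required.issubset(records.columns):
            raise ValueError(f"annotation needs columns {sorted(required)}")
        if records["gene_id"].duplicated().any():
            dup = records.loc[records["gene_id"].duplicated(), "gene_id"].iloc[0]
            raise ValueError(f"duplicate gene_id: {dup!r}")
        bad = ~records["strand"].isin(["+", "-"])
        if bad.any():
            raise ValueError(
                f"gene {records.loc[bad, 'gene_id'].iloc[0]!r}: strand must be + or -"
            )
        if flank <= 0:
            raise ValueError("flank must be positive")
        self.records = records.reset_index(drop=True)
        self.flank = int(flank)

    @property
    def gene_ids(self) -> list[str]:
        return self.records["gene_id"].tolist()

    @property
    def n_genes(self) -> int:
        return len(self.records)

    def windows(self) -> pd.DataFrame:
        """Promoter windows [tss - flank, tss + flank) per gene."""
        w = self.records.copy()
        w["start"] = w["tss"] - self.flank
        w["end"] = w["tss"] + self.flank
        return w

    def __len__(self) -> int:
        return self.n_genes


class ExpressionTable:
    """Per-gene expression values (non-negative, arbitrary units)."""

    def __init__(self, values: Mapping[str, float] | pd.Series) -> None:
        s = pd.Series(values, dtype=float)
        if s.index.duplicated().any():
            raise ValueError("duplicate gene_id in expression table")
        if (s < 0).any():
            raise ValueError("expression values must be >= 0")
        s.index.name = "gene_id"
        self.values = s

    def __getitem__(self, gene_id: str) -> float:
        return float(self.values[gene_id])

    def __len__(self) -> int:
        return len(self.values)


NARROWPEAK_COLUMNS = [
    "chrom", "start", "end", "name", "score", "strand",
    "signalValue", "pValue", "qValue", "summit",
]


class PeakSet:
    """ENCODE narrowPeak records for one regulatory factor."""

    def __init__(self, records: pd.DataFrame, factor: str = "") -> None:
        missing = set(NARROWPEAK_COLUMNS) - set(records.columns)
        if missing:
            raise ValueError(f"narrowPeak records missing columns {sorted(missing)}")
        if (records["signalValue"] < 0).any():
            raise ValueError("signalValue must be >= 0")
        lengths = records["end"] - records["start"]
        bad = (records["summit"] >= lengths) & (records["summit"] != -1)
        if bad.any():
            raise ValueError("summit offset must be < peak length or -1")
        self.records = records.reset_index(drop=True)
        self.factor = factor

    def __len__(self) -> int:
        return len(self.records)


@dataclass
class PromoterMatrix:
    """Gene x position signal matrix anchored and oriented at the TSS.

    ``values`` is indexed by gene_id with integer window-center offsets as
    columns (strictly increasing, positive = downstream of transcription).
    """

    values: pd.DataFrame
    metadata: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        cols = np.asarray(self.values.columns)
        if len(cols) > 1 and not np.all(np.diff(cols.astype(float)) > 0):
            raise ValueError("window centers must be strictly increasing")

    @property
    def gene_ids(self) -> list[str]:
        return list(self.values.index)

    @property
    def window_centers(self) -> np.ndarray:
        return np.asarray(self.values.columns)

    @property
    def shape(self) -> tuple[int, int]:
        return self.values.shape

    def row(self, gene_id: str) -> pd.Series:
        return self.values.loc[gene_id]

    def copy_with(self, values: pd.DataFrame, **meta) -> "PromoterMatrix":
        md = dict(self.metadata)
        md.update(meta)
        return PromoterMatrix(values, md)


@dataclass
class SensitivityMatrix(PromoterMatrix):
    """log2(light/heavy) promoter matrix; positive = MNase-sensitive (MSF),
    negative = MNase-resistant (MRF)."""

    pseudocount: float = 1.0
    light_label: str = ""
    heavy_label: str = ""
    condition: str = ""


@dataclass
class CoverageTrack:
    """Per-bp fragments-per-million coverage over each TSS +/- flank window.

    ``values`` rows are genes, columns strand-oriented bp offsets
    (-flank .. flank-1 relative to the TSS).
    """

    values: pd.DataFrame
    flank: int
    metadata: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.values.shape[1] != 2 * self.flank:
            raise ValueError("coverage arrays must span exactly 2*flank bp")
        if (self.values.to_numpy() < 0).any():
            raise ValueError("coverage values must be >= 0")
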