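"""Sorting, quartiling, clustering and group-averaging of promoter matrices.

These are the heatmap-style operations: rank promoters by maximum signal,
cut gene lists into quartiles, k-means promoter profiles into sets with
similar features, and average profiles within a cluster or quartile.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping

import numpy as np
import pandas as pd
from sklearn.cluster import KMeans

from .containers import PeakSet, PromoterMatrix, TssAnnotation
from .occupancy import window_centers

QUARTILES = ("Q1", "Q2", "Q3", "Q4")


@dataclass
class SortOrder:
    """A permutation of a matrix's genes with the key that produced it."""

    gene_ids: list[str]
    key_name: str
    key_values: pd.Series

    def __len__(self) -> int:
        return len(self.gene_ids)


@dataclass
class ClusterAssignment:
    labels: pd.Series          # gene_id -> cluster label in 1..k
    k: int
    seed: int
    sizes: dict[int, int] = field(default_factory=dict)
    mean_profiles: pd.DataFrame | None = None
    imputed_genes: list[str] = field(default_factory=list)
    inertia: float = float("nan")


def sort_by_max_signal(matrix: PromoterMatrix) -> SortOrder:
    """Per-gene maximum over all windows, descending; ties broken by
    gene_id lexicographic order."""
    if matrix.values.size == 0:
        raise ValueError("empty matrix")
    key = matrix.values.max(axis=1, skipna=True)
    order = (
        pd.DataFrame({"key": key, "gene_id": key.index})
        .sort_values(["key", "gene_id"], ascending=[False, True], kind="mergesort")
        .index.tolist()
    )
    return SortOrder(order, "max_signal", key)


def quartiles_by_key(
    genes: list[str], key: Mapping[str, float] | pd.Series
) -> dict[str, str]:
    """Rank genes by key descending and cut into 4 contiguous groups; the
    earlier quartiles absorb the remainder. Q1 holds the highest keys."""
    if len(genes) < 4:
        raise ValueError("need at least 4 genes for quartiles")
    key = pd.Series(key).reindex(genes)
    ranked = (
        pd.DataFrame({"key": key, "gene_id": genes}, index=genes)
        .sort_values(["key", "gene_id"], ascending=[False, True], kind="mergesort")
        .index.tolist()
    )
    n = len(genes)
    base, rem = divmod(n, 4)
    sizes = [base + (1 if i < rem else 0) for i in range(4)]
    out: dict[str, str] = {}
    pos = 0
    for q, size in zip(QUARTILES, sizes):
        for g in ranked[pos:pos + size]:
            out[g] = q
        pos += size
    return out


def kmeans_profiles(
    matrix: PromoterMatrix,
    k: int,
    seed: int = 0,
    n_init: int = 10,
    standardize: bool = False,
) -> ClusterAssignment:
    """Lloyd's k-means on promoter rows (Euclidean distance), best of
    ``n_init`` restarts by within-cluster sum of squares.

    Rows containing NA are mean-imputed per column for the clustering
    only and flagged in the result. ``standardize`` z-scores columns
    first (the raw rows are the default feature space).
    """
    if k < 2:
        raise ValueError("k must be >= 2")
    n = matrix.shape[0]
    if k > n:
        raise ValueError(f"k ({k}) exceeds the number of genes ({n})")
    X = matrix.values.to_numpy(dtype=float).copy()
    imputed = matrix.values.index[np.isnan(X).any(axis=1)].tolist()
    if imputed:
        col_means = np.nanmean(X, axis=0)
        col_means = np.where(np.isnan(col_means), 0.0, col_means)
        nan_r, nan_c = np.nonzero(np.isnan(X))
        X[nan_r, nan_c] = col_means[nan_c]
    if standardize:
        sd = X.std(axis=0)
        sd[sd == 0] = 1.0
        X = (X - X.mean(axis=0)) / sd
    km = KMeans(
        n_clusters=k, n_init=n_init, random_state=seed, algorithm="lloyd"
    ).fit(X)
    labels = pd.Series(km.labels_ + 1, index=matrix.values.index, name="cluster")
    sizes = labels.value_counts().to_dict()
    means = matrix.values.groupby(labels).mean()
    means.index.name = "cluster"
    return ClusterAssignment(
        labels=labels, k=k, seed=seed, sizes=sizes,
        mean_profiles=means, imputed_genes=imputed, inertia=float(km.inertia_),
    )


def dominant_sensitive_cluster(
    assignment: ClusterAssignment, band: tuple[int, int] = (-200, 0)
) -> int:
    """The cluster whose mean profile peaks inside the band immediately
    upstream of the TSS — the 'dominant -1 sensitive nucleosome' set."""
    means = assignment.mean_profiles
    if means is None or means.empty:
        raise ValueError("assignment carries no mean profiles")
    centers = np.asarray(means.columns, dtype=float)
    best_label, best_val = None, -np.inf
    for label, row in means.iterrows():
        r = row.to_numpy(dtype=float)
        peak = centers[np.nanargmax(r)]
        if band[0] <= peak <= band[1] and np.nanmax(r) > best_val:
            best_label, best_val = int(label), float(np.nanmax(r))
    if best_label is None:
        raise ValueError(f"no cluster peaks within band {band}")
    return best_label


def cluster_average_profiles(
    matrix: PromoterMatrix,
    groups: ClusterAssignment | Mapping[str, object],
) -> tuple[pd.DataFrame, dict]:
    """Per-group, per-window arithmetic mean (NA-ignoring) plus group sizes."""
    if isinstance(groups, ClusterAssignment):
        mapping = groups.labels
    else:
        mapping = pd.Series(dict(groups))
    missing = set(matrix.values.index) - set(mapping.index)
    if missing:
        raise ValueError(f"genes without a group: {sorted(missing)[:5]}")
    mapping = mapping.reindex(matrix.values.index)
    sizes = mapping.value_counts().to_dict()
    if any(v == 0 for v in sizes.values()):
        raise ValueError("empty group")
    means = matrix.values.groupby(mapping).mean()
    return means, sizes


def apply_sort(matrix: PromoterMatrix, order: SortOrder | list[str]) -> PromoterMatrix:
    """Row-reorder a matrix by a sort order computed on it — or on any other
    matrix sharing the same genes, enabling cross-dataset overlays."""
    gene_ids = order.gene_ids if isinstance(order, SortOrder) else list(order)
    if sorted(gene_ids) != sorted(matrix.values.index):
        raise ValueError("sort order is not a permutation of the matrix's genes")
    return matrix.copy_with(matrix.values.reindex(gene_ids))


def peak_matrix(
    peaks: PeakSet,
    annotation: TssAnnotation,
    window: int = 60,
    step: int = 10,
    mode: str = "signal",
) -> PromoterMatrix:
    """Regulatory-factor binding on the promoter window grid.

    Cell value = summed signalValue of peaks overlapping the window
    (``mode="binary"``: 1 if any peak overlaps). Orientation rules match
    midpoint_matrix.
    """
    if mode not in ("signal", "binary"):
        raise ValueError("mode must be 'signal' or 'binary'")
    if window <= 0 or step <= 0:
        raise ValueError("window and step must be positive")
    if window % 2:
        raise ValueError("window must be even")
    if window > 2 * annotation.flank:
        raise ValueError("window exceeds the promoter span (2*flank)")
    centers = window_centers(annotation.flank, window, step)
    half = window // 2
    rows = np.zeros((annotation.n_genes, len(centers)))
    recs = peaks.records
    for chrom, grp in annotation.windows().groupby("chrom", sort=False):
        p = recs[recs["chrom"] == chrom]
        ps = p["start"].to_numpy()
        pe = p["end"].to_numpy()
        sig = p["signalValue"].to_numpy(dtype=float)
        for row_i, tss, strand in zip(
            grp.index, grp["tss"].to_numpy(), grp["strand"].to_numpy()
        ):
            lo = tss + centers - half
            hi = lo + window
            row = np.zeros(len(centers))
            for s, e, v in zip(ps, pe, sig):
                overlap = (s < hi) & (e > lo)
                if mode == "signal":
                    row[overlap] += v
                else:
                    row[overlap] = 1.0
            if strand == "-":
                row = row[::-1]
            rows[row_i] = row
    df = pd.DataFrame(rows, index=annotation.gene_ids, columns=centers)
    return PromoterMatrix(
        df,
        {
            "label": f"peaks:{peaks.factor}",
            "normalization": mode,
            "window": window,
            "step": step,
            "flank": annotation.flank,
        },
    )
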