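"""Fragment sets -> per-bp coverage and TSS-anchored midpoint matrices.

Nucleosome occupancy is summarized two ways, mirroring the assay's
processing: per-bp fragments-per-million coverage over each promoter
window, and fragment-midpoint counts in sliding windows (default 60 bp
windows at a 10 bp step) across the 2 kb surrounding each TSS.

Normalization: "fragments per million" uses as denominator the number of
fragments whose midpoint falls inside the captured region set (the union
of TSS +/- flank windows), not the genome-wide total.
"""

from __future__ import annotations

import logging

import numpy as np
import pandas as pd

from .containers import CoverageTrack, FragmentSet, PromoterMatrix, TssAnnotation

logger = logging.getLogger(__name__)

SCALE = 1_000_000


def filter_mononucleosome(
    fragments: FragmentSet, min_len: int = 140, max_len: int = 160
) -> FragmentSet:
    """Retain fragments with min_len <= length <= max_len (the ~150 bp
    mononucleosome band)."""
    if min_len >= max_len:
        raise ValueError(f"min_len ({min_len}) must be < max_len ({max_len})")
    mask = (fragments.lengths >= min_len) & (fragments.lengths <= max_len)
    kept = fragments.subset(mask)
    logger.info(
        "mononucleosome filter [%d, %d] on %s: retained %d, discarded %d",
        min_len, max_len, fragments.label or "<unlabelled>",
        kept.total_count, fragments.total_count - kept.total_count,
    )
    return kept


def _region_fragment_count(
    fragments: FragmentSet, annotation: TssAnnotation
) -> np.ndarray:
    """Boolean mask of fragments whose midpoint lies in some promoter window."""
    mids = fragments.midpoints()
    mask = np.zeros(len(mids), dtype=bool)
    windows = annotation.windows()
    for chrom, grp in windows.groupby("chrom", sort=False):
        on_chrom = fragments.chroms == chrom
        m = mids[on_chrom]
        order = np.argsort(grp["start"].to_numpy(), kind="stable")
        starts = grp["start"].to_numpy()[order]
        ends = grp["end"].to_numpy()[order]
        if len(starts) > 1 and np.any(starts[1:] < ends[:-1]):
            # overlapping windows: per-window scan
            hit = np.zeros(len(m), dtype=bool)
            for start, end in zip(starts, ends):
                hit |= (m >= start) & (m < end)
        else:
            idx = np.searchsorted(starts, m, side="right") - 1
            valid = idx >= 0
            hit = np.zeros(len(m), dtype=bool)
            hit[valid] = m[valid] < ends[idx[valid]]
        mask[on_chrom] = hit
    return mask


def coverage_fpm(
    fragments: FragmentSet,
    annotation: TssAnnotation,
    normalize: bool = True,
) -> CoverageTrack:
    """Per-bp coverage over each TSS +/- flank window, in fragments per
    million mapped to the region set.

    The value at base b is (number of fragments whose interval contains b)
    / denominator x 1e6; rows of minus-strand genes are reversed so the
    track reads in the direction of transcription.
    """
    if fragments.total_count == 0:
        raise ValueError("empty fragment set")
    in_region = _region_fragment_count(fragments, annotation)
    denom = int(in_region.sum())
    if normalize and denom == 0:
        raise ValueError("no fragments map within the promoter region set")
    logger.info("coverage_fpm: %d/%d fragments in region set",
                denom, fragments.total_count)

    flank = annotation.flank
    rows = np.zeros((annotation.n_genes, 2 * flank))
    windows = annotation.windows()
    order = np.argsort(fragments.starts, kind="stable")
    starts = fragments.starts[order]
    ends = fragments.ends[order]
    chroms = fragments.chroms[order]
    max_len = int(fragments.lengths.max())

    for chrom, grp in windows.groupby("chrom", sort=False):
        sel = chroms == chrom
        cs, ce = starts[sel], ends[sel]
        for row_i, wstart, wend, strand in zip(
            grp.index, grp["start"].to_numpy(), grp["end"].to_numpy(),
            grp["strand"].to_numpy(),
        ):
            lo = np.searchsorted(cs, wstart - max_len, side="left")
            hi = np.searchsorted(cs, wend, side="left")
            fs, fe = cs[lo:hi], ce[lo:hi]
            keep = fe > wstart
            fs, fe = np.clip(fs[keep], wstart, wend), np.clip(fe[keep], wstart, wend)
            diff = np.zeros(2 * flank + 1)
            np.add.at(diff, fs - wstart, 1)
            np.add.at(diff, fe - wstart, -1)
            track = np.cumsum(diff[:-1])
            if strand == "-":
                track = track[::-1]
            rows[row_i] = track

    if normalize:
        rows = rows * (SCALE / denom)
        tag = "fpm"
    else:
        tag = "raw"
    offsets = np.arange(-flank, flank)
    df = pd.DataFrame(rows, index=annotation.gene_ids, columns=offsets)
    return CoverageTrack(
        df, flank=flank,
        metadata={"label": fragments.label, "normalization": tag,
                  "region_fragments": denom},
    )


def window_centers(flank: int, window: int, step: int) -> np.ndarray:
    """Window-center offsets: TSS-flank+window/2 .. TSS+flank-window/2."""
    return np.arange(-flank + window // 2, flank - window // 2 + 1, step,
                     dtype=np.int64)


def midpoint_matrix(
    fragments: FragmentSet,
    annotation: TssAnnotation,
    window: int = 60,
    step: int = 10,
    normalize: bool = True,
) -> PromoterMatrix:
    """Fragment-midpoint density in sliding windows across each promoter.

    Cell value = count of fragment midpoints in [center - window/2,
    center + window/2), scaled to fragments per million mapped in the
    region set (or left raw with ``normalize=False``). Midpoint of a
    fragment [s, e) is floor((s + e) / 2). Minus-strand rows are reversed
    so positive offsets are downstream of transcription.
    """
    if window <= 0 or step <= 0:
        raise ValueError("window and step must be positive")
    if window % 2:
        raise ValueError("window must be even so the center grid is integral")
    if window > 2 * annotation.flank:
        raise ValueError("window exceeds the promoter span (2*flank)")

    centers = window_centers(annotation.flank, window, step)
    half = window // 2
    mids_all = fragments.midpoints()
    in_region = _region_fragment_count(fragments, annotation)
    denom = int(in_region.sum())
    if normalize and denom == 0:
        raise ValueError("no fragments map within the promoter region set")

    rows = np.zeros((annotation.n_genes, len(centers)))
    for chrom, grp in annotation.windows().groupby("chrom", sort=False):
        mids = np.sort(mids_all[fragments.chroms == chrom], kind="stable")
        for row_i, tss, strand in zip(
            grp.index, grp["tss"].to_numpy(), grp["strand"].to_numpy()
        ):
            lo_edges = tss + centers - half
            hi_edges = lo_edges + window
            counts = (
                np.searchsorted(mids, hi_edges, side="left")
                - np.searchsorted(mids, lo_edges, side="left")
            )
            row = counts.astype(float)
            if strand == "-":
                row = row[::-1]
            rows[row_i] = row

    tag = "raw"
    if normalize:
        rows = rows * (SCALE / denom)
        tag = "fpm"
    logger.info(
        "midpoint_matrix %s: %d genes x %d windows (window=%d, step=%d, %s; "
        "%d/%d fragments in region set)",
        fragments.label or "<unlabelled>", annotation.n_genes, len(centers),
        window, step, tag, denom, fragments.total_count,
    )
    df = pd.DataFrame(rows, index=annotation.gene_ids, columns=centers)
    return PromoterMatrix(
        df,
        metadata={
            "label": fragments.label,
            "normalization": tag,
            "window": window,
            "step": step,
            "flank": annotation.flank,
            "region_fragments": denom,
        },
    )
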