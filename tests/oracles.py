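"""Independent brute-force reference implementations.

Deliberately naive double/triple loops over (gene, position, fragment)
following only the documented conventions: 0-based half-open intervals,
midpoint = floor((start+end)/2), half-open window membership, FPM
denominator = fragments with midpoint inside some TSS +/- flank window,
minus-strand rows reversed. They share no code with the package paths
they check.
"""

from __future__ import annotations

import numpy as np

SCALE = 1_000_000


def _fragment_records(fragments):
    return list(zip(fragments.chroms, fragments.starts, fragments.ends))


def _gene_records(annotation):
    r = annotation.records
    return list(zip(r["gene_id"], r["chrom"], r["tss"], r["strand"]))


def _in_region_count(fragments, annotation) -> int:
    flank = annotation.flank
    n = 0
    for chrom, s, e in _fragment_records(fragments):
        mid = (s + e) // 2
        for _, gchrom, tss, _ in _gene_records(annotation):
            if chrom == gchrom and tss - flank <= mid < tss + flank:
                n += 1
                break
    return n


def brute_coverage(fragments, annotation, normalize=True) -> np.ndarray:
    """Per-gene, per-bp containment counts (x 1e6 / denominator)."""
    flank = annotation.flank
    genes = _gene_records(annotation)
    out = np.zeros((len(genes), 2 * flank))
    for gi, (_, gchrom, tss, strand) in enumerate(genes):
        for offset in range(-flank, flank):
            base = tss + offset
            count = sum(
                1
                for chrom, s, e in _fragment_records(fragments)
                if chrom == gchrom and s <= base < e
            )
            col = offset + flank
            if strand == "-":
                col = 2 * flank - 1 - col
            out[gi, col] = count
    if normalize:
        out = out * (SCALE / _in_region_count(fragments, annotation))
    return out


def brute_midpoint_matrix(
    fragments, annotation, window=60, step=10, normalize=True
) -> np.ndarray:
    flank = annotation.flank
    half = window // 2
    centers = list(range(-flank + half, flank - half + 1, step))
    genes = _gene_records(annotation)
    out = np.zeros((len(genes), len(centers)))
    for gi, (_, gchrom, tss, strand) in enumerate(genes):
        row = []
        for c in centers:
            lo = tss + c - half
            hi = lo + window
            count = sum(
                1
                for chrom, s, e in _fragment_records(fragments)
                if chrom == gchrom and lo <= (s + e) // 2 < hi
            )
            row.append(count)
        if strand == "-":
            row = row[::-1]
        out[gi] = row
    if normalize:
        out = out * (SCALE / _in_region_count(fragments, annotation))
    return out


def brute_peak_matrix(peaks, annotation, window=60, step=10) -> np.ndarray:
    """Summed signalValue of peaks overlapping each genomic window."""
    flank = annotation.flank
    half = window // 2
    centers = list(range(-flank + half, flank - half + 1, step))
    genes = _gene_records(annotation)
    out = np.zeros((len(genes), len(centers)))
    recs = peaks.records
    for gi, (_, gchrom, tss, strand) in enumerate(genes):
        row = []
        for c in centers:
            lo = tss + c - half
            hi = lo + window
            total = 0.0
            for _, peak in recs.iterrows():
                if peak["chrom"] == gchrom and peak["start"] < hi and peak["end"] > lo:
                    total += peak["signalValue"]
            row.append(total)
        if strand == "-":
            row = row[::-1]
        out[gi] = row
    return out


def student_t_two_sided_p_df2(t: float) -> float:
    """Closed-form two-sided Student-t tail for 2 degrees of freedom:
    F(t) = 1/2 + t / (2 * sqrt(2 + t^2))."""
    cdf = 0.5 + t / (2.0 * np.sqrt(2.0 + t * t))
    return 2.0 * (1.0 - cdf)
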