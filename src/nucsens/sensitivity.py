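"""MNase-sensitivity statistic: log2(light/heavy) and MSF/MRF calls.

Comparing fragments released by a light (low-concentration) MNase digest
against those surviving a heavy digest distinguishes MNase-sensitive
fragments (MSFs, preferentially released when digestion is light,
positive log2 ratio) from MNase-resistant fragments (MRFs, recovered
even under heavy digestion, negative log2 ratio).
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from .containers import PromoterMatrix, SensitivityMatrix


def _check_grids(a: PromoterMatrix, b: PromoterMatrix) -> None:
    if list(a.values.index) != list(b.values.index):
        raise ValueError("matrices have mismatched gene order")
    if list(a.values.columns) != list(b.values.columns):
        raise ValueError("matrices have mismatched window grids")


def sensitivity_matrix(
    light: PromoterMatrix,
    heavy: PromoterMatrix,
    pseudocount: float = 1.0,
) -> SensitivityMatrix:
    """Cell-wise log2((light + pseudocount) / (heavy + pseudocount)).

    The pseudocount (default 1.0, in the matrices' FPM units) keeps every
    value finite and maps empty cells to exactly 0.
    """
    _check_grids(light, heavy)
    if pseudocount <= 0:
        raise ValueError("pseudocount must be > 0")
    na = light.metadata.get("normalization")
    nb = heavy.metadata.get("normalization")
    if na != nb:
        raise ValueError(f"normalization mismatch: {na!r} vs {nb!r}")
    vals = np.log2(
        (light.values.to_numpy() + pseudocount)
        / (heavy.values.to_numpy() + pseudocount)
    )
    df = pd.DataFrame(vals, index=light.values.index, columns=light.values.columns)
    meta = {
        "normalization": na,
        "window": light.metadata.get("window"),
        "step": light.metadata.get("step"),
        "flank": light.metadata.get("flank"),
        "statistic": "log2(light/heavy)",
        "pseudocount": pseudocount,
    }
    return SensitivityMatrix(
        df,
        meta,
        pseudocount=pseudocount,
        light_label=light.metadata.get("label", ""),
        heavy_label=heavy.metadata.get("label", ""),
    )


def classify_msf_mrf(sens: SensitivityMatrix, threshold: float = 0.0) -> pd.DataFrame:
    """Label each cell MSF (value > threshold), MRF (< -threshold) or
    neutral. Threshold 0 is the plain sign rule."""
    if threshold < 0:
        raise ValueError("threshold must be >= 0")
    v = sens.values.to_numpy()
    labels = np.full(v.shape, "neutral", dtype=object)
    labels[v > threshold] = "MSF"
    labels[v < -threshold] = "MRF"
    return pd.DataFrame(labels, index=sens.values.index, columns=sens.values.columns)


def differential_occupancy(a: PromoterMatrix, b: PromoterMatrix) -> PromoterMatrix:
    """Cell-wise difference b - a on matched grids and normalization."""
    _check_grids(a, b)
    if a.metadata.get("normalization") != b.metadata.get("normalization"):
        raise ValueError("normalization mismatch")
    df = b.values - a.values
    return PromoterMatrix(
        df,
        {
            "normalization": a.metadata.get("normalization"),
            "window": a.metadata.get("window"),
            "step": a.metadata.get("step"),
            "flank": a.metadata.get("flank"),
            "statistic": "difference",
            "minuend": b.metadata.get("label", ""),
            "subtrahend": a.metadata.get("label", ""),
        },
    )
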