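"""Synthetic mTSS-seq digestion simulator.

Generates promoters with positioned nucleosomes at canonical offsets
around a nucleosome-free region (NFR), then draws mononucleosome-sized
fragments under light or heavy MNase digestion. Sensitivity is modelled
as a digest-dependent release probability per nucleosome: a nucleosome
preferentially released by the light digest yields positive
log2(light/heavy) signal (an MNase-sensitive fragment, MSF).

At baseline the light and heavy release probabilities are equal, so the
expected light and heavy midpoint densities are proportional and the
sensitivity log-ratio is zero in expectation. The treated condition
multiplies the light release probability of the -1 nucleosome (offset
-100) in top-expression-tier genes by ``effect_size``, planting the
localized sensitivity gain the analysis is meant to recover.

Randomness is counter-based: every stream is ``default_rng(SeedSequence(
seed, spawn_key=(purpose, gene_index)))``, so any gene subset and any
digest/condition is reproducible in isolation.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml
from numpy.random import SeedSequence, default_rng
from scipy.special import ndtr, ndtri

from .containers import (
    ExpressionTable,
    FragmentSet,
    PeakSet,
    TssAnnotation,
)
from . import io as gio

DIGESTS = ("light", "heavy")

# spawn_key purposes (first element); second element is the gene index
# (or 0 for global streams)
_STREAM_TIERS = 0
_STREAM_EXPRESSION = 1
_STREAM_STRAND = 2
_STREAM_PEAKS = 3
_STREAM_GENE = 10         # per-gene occupancy / release draws
_STREAM_FRAGMENTS = 100   # + digest/condition offset, per-gene fragment draws

DEFAULT_DYADS = (-350, -200, -100, 50, 200, 350)
MINUS_ONE_DYAD = -100
NFR = (-50, 40)


@dataclass
class SimulationConfig:
    """Conditions of the synthetic study.

    Defaults emulate the assay's stated geometry: 2 kb promoter windows,
    a ~150 bp mononucleosome band from a 50-200 bp size-selected library,
    and a x2 light-release gain at the -1 nucleosome of top-tier genes in
    the treated condition.
    """

    n_genes: int = 100
    flank: int = 1000
    frag_len_mean: float = 150.0
    frag_len_sd: float = 20.0
    frag_len_min: int = 50
    frag_len_max: int = 200
    jitter_sd: float = 20.0
    depth: int = 2000
    seed: int = 0
    effect_size: float = 2.0
    background_frac: float = 0.10
    conditions: tuple[str, ...] = ("untreated", "20min")
    treated_condition: str = "20min"
    dyads: tuple[int, ...] = DEFAULT_DYADS
    randomize_strand: bool = False
    chrom: str = "chrS"
    tf_factor: str = "synthTF"

    def validate(self) -> None:
        if self.n_genes < 4:
            raise ValueError("n_genes must be >= 4 so quartiles are non-empty")
        if self.depth <= 0:
            raise ValueError("depth must be positive")
        if not (0 < self.frag_len_min < self.frag_len_max):
            raise ValueError("need 0 < frag_len_min < frag_len_max")
        if not (0.0 <= self.background_frac <= 1.0):
            raise ValueError("background_frac must be in [0, 1]")
        if self.flank <= 0:
            raise ValueError("flank must be positive")
        if self.effect_size < 0:
            raise ValueError("effect_size must be >= 0")
        if self.jitter_sd < 0 or self.frag_len_sd < 0:
            raise ValueError("standard deviations must be >= 0")
        if self.treated_condition not in self.conditions:
            raise ValueError(
                f"treated_condition {self.treated_condition!r} not in conditions"
            )
        if any(abs(d) >= self.flank for d in self.dyads):
            raise ValueError("dyad offsets must lie within +/- flank")
        if MINUS_ONE_DYAD not in self.dyads:
            raise ValueError(f"dyads must include the -1 position ({MINUS_ONE_DYAD})")

    @classmethod
    def from_yaml(cls, path: str | Path) -> "SimulationConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        for key in ("conditions", "dyads"):
            if key in raw:
                raw[key] = tuple(raw[key])
        cfg = cls(**raw)
        cfg.validate()
        return cfg

    def to_yaml(self, path: str | Path) -> None:
        d = dataclasses.asdict(self)
        d["conditions"] = list(self.conditions)
        d["dyads"] = list(self.dyads)
        with open(path, "w") as fh:
            yaml.safe_dump(d, fh, sort_keys=False)


@dataclass
class PromoterTruth:
    """Ground truth for one synthetic promoter."""

    gene_id: str
    tss: int
    strand: str
    dyads: np.ndarray                 # offsets relative to TSS, oriented
    occupancy: np.ndarray             # per-dyad weights, >= 0
    release_light: np.ndarray         # baseline per-dyad release prob, [0,1]
    release_heavy: np.ndarray
    expression_tier: str              # Q1 (highest) .. Q4
    has_tf_peak: bool
    condition_effects: dict[str, np.ndarray] = field(default_factory=dict)
    # per-condition multipliers on release_light

    def effective_release(self, digest: str, condition: str) -> np.ndarray:
        if digest not in DIGESTS:
            raise ValueError(f"unknown digest {digest!r}")
        if condition not in self.condition_effects:
            raise ValueError(f"unknown condition {condition!r}")
        if digest == "light":
            return np.clip(self.release_light * self.condition_effects[condition], 0, 1)
        return self.release_heavy


def _rng(seed: int, purpose: int, index: int = 0):
    return default_rng(SeedSequence(seed, spawn_key=(purpose, index)))


def _tier_sizes(n: int) -> list[int]:
    base, rem = divmod(n, 4)
    return [base + (1 if i < rem else 0) for i in range(4)]


_TIER_RANGES = {"Q1": (100.0, 1000.0), "Q2": (10.0, 100.0),
                "Q3": (1.0, 10.0), "Q4": (0.0, 1.0)}


def simulate_truth(
    config: SimulationConfig,
) -> tuple[list[PromoterTruth], TssAnnotation, ExpressionTable, PeakSet]:
    """Lay out promoters on one synthetic chromosome and draw ground truth.

    Genes are tiled at fixed spacing so 2*flank promoter windows never
    overlap; expression is drawn from disjoint per-tier ranges so tiers
    are strictly ordered; TF peaks are centered in the NFR of every other
    top-tier gene.
    """
    config.validate()
    n = config.n_genes
    seed = config.seed
    spacing = 2 * config.flank + 1000
    width = len(str(n - 1))
    gene_ids = [f"g{str(i).zfill(width)}" for i in range(n)]
    tss = np.array([config.flank + 500 + i * spacing for i in range(n)])

    if config.randomize_strand:
        strands = np.where(_rng(seed, _STREAM_STRAND).random(n) < 0.5, "+", "-")
    else:
        strands = np.full(n, "+", dtype=object)

    # assign expression tiers: random permutation, earlier tiers larger
    perm = _rng(seed, _STREAM_TIERS).permutation(n)
    tiers = np.empty(n, dtype=object)
    pos = 0
    for tier, size in zip(("Q1", "Q2", "Q3", "Q4"), _tier_sizes(n)):
        tiers[perm[pos:pos + size]] = tier
        pos += size

    expr_rng = _rng(seed, _STREAM_EXPRESSION)
    expression = np.empty(n)
    for i in range(n):
        lo, hi = _TIER_RANGES[tiers[i]]
        expression[i] = expr_rng.uniform(lo, hi)

    dyads = np.asarray(config.dyads, dtype=np.int64)
    minus_one = int(np.flatnonzero(dyads == MINUS_ONE_DYAD)[0])
    multiplier = config.effect_size if config.effect_size > 0 else 1.0

    # designated top-tier subset for TF peaks: every other Q1 gene
    q1_indices = [i for i in range(n) if tiers[i] == "Q1"]
    tf_genes = set(q1_indices[::2])

    truths: list[PromoterTruth] = []
    for i in range(n):
        g = _rng(seed, _STREAM_GENE, i)
        occ = g.uniform(0.8, 1.2, size=len(dyads))
        release = g.uniform(0.30, 0.50, size=len(dyads))
        effects = {c: np.ones(len(dyads)) for c in config.conditions}
        if tiers[i] == "Q1":
            eff = np.ones(len(dyads))
            eff[minus_one] = multiplier
            effects[config.treated_condition] = eff
        truths.append(
            PromoterTruth(
                gene_id=gene_ids[i],
                tss=int(tss[i]),
                strand=str(strands[i]),
                dyads=dyads,
                occupancy=occ,
                release_light=release,
                release_heavy=release.copy(),
                expression_tier=str(tiers[i]),
                has_tf_peak=i in tf_genes,
                condition_effects=effects,
            )
        )

    annotation = TssAnnotation(
        pd.DataFrame(
            {"gene_id": gene_ids, "chrom": config.chrom, "tss": tss,
             "strand": strands}
        ),
        flank=config.flank,
    )
    expr_table = ExpressionTable(pd.Series(expression, index=gene_ids))

    peak_rng = _rng(seed, _STREAM_PEAKS)
    rows = []
    nfr_center = (NFR[0] + NFR[1]) // 2
    for i in sorted(tf_genes):
        sign = 1 if strands[i] == "+" else -1
        center = int(tss[i]) + sign * nfr_center
        rows.append(
            {
                "chrom": config.chrom,
                "start": center - 45,
                "end": center + 45,
                "name": f"{config.tf_factor}_{gene_ids[i]}",
                "score": 0,
                "strand": ".",
                "signalValue": float(peak_rng.uniform(5.0, 15.0)),
                "pValue": -1.0,
                "qValue": -1.0,
                "summit": 45,
            }
        )
    peaks = PeakSet(
        pd.DataFrame(rows, columns=[
            "chrom", "start", "end", "name", "score", "strand",
            "signalValue", "pValue", "qValue", "summit",
        ]),
        factor=config.tf_factor,
    )
    return truths, annotation, expr_table, peaks


def _truncnorm(rng, mean: float, sd: float, lo: float, hi: float, n: int) -> np.ndarray:
    """Truncated normal via inverse-CDF on a uniform draw (exact, cheap)."""
    if sd == 0:
        return np.full(n, mean)
    a, b = ndtr((lo - mean) / sd), ndtr((hi - mean) / sd)
    u = rng.uniform(a, b, size=n)
    return mean + sd * ndtri(u)


def simulate_digest(
    truths: list[PromoterTruth],
    digest: str,
    condition: str,
    config: SimulationConfig,
) -> FragmentSet:
    """Draw ``depth`` fragments per gene for one digest level and condition.

    Per gene: a background fraction lands uniformly in the promoter
    window; the rest pick a dyad proportional to occupancy x effective
    release probability, get a Gaussian-jittered midpoint, and a length
    from the truncated size-selection distribution.
    """
    config.validate()
    if digest not in DIGESTS:
        raise ValueError(f"unknown digest {digest!r}; expected one of {DIGESTS}")
    if condition not in config.conditions:
        raise ValueError(
            f"unknown condition {condition!r}; expected one of {config.conditions}"
        )
    stream = (
        _STREAM_FRAGMENTS
        + DIGESTS.index(digest) * len(config.conditions)
        + config.conditions.index(condition)
    )
    n_bg = int(round(config.background_frac * config.depth))
    n_nuc = config.depth - n_bg

    all_mids = []
    all_lens = []
    for i, truth in enumerate(truths):
        rng = _rng(config.seed, stream, i)
        sign = 1 if truth.strand == "+" else -1
        weights = truth.occupancy * truth.effective_release(digest, condition)
        total = weights.sum()
        if total > 0 and n_nuc > 0:
            counts = rng.multinomial(n_nuc, weights / total)
            extra_bg = 0
        else:
            counts = np.zeros(len(truth.dyads), dtype=int)
            extra_bg = n_nuc
        mids = np.empty(config.depth, dtype=np.int64)
        pos = 0
        for d, c in zip(truth.dyads, counts):
            if c == 0:
                continue
            center = truth.tss + sign * int(d)
            jitter = np.rint(rng.normal(0.0, config.jitter_sd, size=c)).astype(np.int64)
            mids[pos:pos + c] = center + jitter
            pos += c
        n_uniform = n_bg + extra_bg
        if n_uniform:
            mids[pos:pos + n_uniform] = rng.integers(
                truth.tss - config.flank, truth.tss + config.flank, size=n_uniform
            )
            pos += n_uniform
        lens = np.rint(
            _truncnorm(
                rng, config.frag_len_mean, config.frag_len_sd,
                config.frag_len_min, config.frag_len_max, config.depth,
            )
        ).astype(np.int64)
        np.clip(lens, config.frag_len_min, config.frag_len_max, out=lens)
        all_mids.append(mids)
        all_lens.append(lens)

    mids = np.concatenate(all_mids) if all_mids else np.empty(0, dtype=np.int64)
    lens = np.concatenate(all_lens) if all_lens else np.empty(0, dtype=np.int64)
    starts = mids - lens // 2
    ends = starts + lens
    chroms = np.full(len(mids), config.chrom, dtype=object)
    return FragmentSet(chroms, starts, ends, label=f"{digest}:{condition}")


def truth_table(truths: list[PromoterTruth]) -> pd.DataFrame:
    """Flatten ground truth to a TSV-friendly table."""
    rows = []
    for t in truths:
        rows.append(
            {
                "gene_id": t.gene_id,
                "tss": t.tss,
                "strand": t.strand,
                "expression_tier": t.expression_tier,
                "has_tf_peak": t.has_tf_peak,
                "dyads": ",".join(map(str, t.dyads)),
                "occupancy": ",".join(f"{x:.6g}" for x in t.occupancy),
                "release_light": ",".join(f"{x:.6g}" for x in t.release_light),
                "release_heavy": ",".join(f"{x:.6g}" for x in t.release_heavy),
            }
        )
    return pd.DataFrame(rows)


def write_dataset(config: SimulationConfig, outdir: str | Path) -> dict[str, Path]:
    """Simulate and write a full dataset: per digest/condition fragment BEDs,
    TSS annotation BED6, expression TSV, narrowPeak file, truth TSV, and the
    YAML config. Returns the paths written."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    truths, annotation, expr, peaks = simulate_truth(config)
    paths: dict[str, Path] = {}
    for condition in config.conditions:
        for digest in DIGESTS:
            frags = simulate_digest(truths, digest, condition, config)
            p = outdir / f"fragments_{condition}_{digest}.bed"
            gio.write_fragments_bed(frags, p)
            paths[f"fragments:{condition}:{digest}"] = p
    gio.write_tss_annotation(annotation, outdir / "tss.bed")
    gio.write_expression_table(expr, outdir / "expression.tsv")
    gio.write_narrowpeak(peaks, outdir / f"peaks_{config.tf_factor}.narrowPeak")
    truth_table(truths).to_csv(outdir / "truth.tsv", sep="\t", index=False)
    config.to_yaml(outdir / "sim_config.yaml")
    paths.update(
        {
            "tss": outdir / "tss.bed",
            "expression": outdir / "expression.tsv",
            "peaks": outdir / f"peaks_{config.tf_factor}.narrowPeak",
            "truth": outdir / "truth.tsv",
            "config": outdir / "sim_config.yaml",
        }
    )
    return paths
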