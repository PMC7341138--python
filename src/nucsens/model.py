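"""Promoter nucleosome model: fit the full occupancy/sensitivity analysis.

``PromoterNucleosomeModel`` is built from per-condition light/heavy
fragment sets plus a TSS annotation (and optionally an expression table
and regulatory-factor peak files); ``fit()`` runs the whole analysis —
mononucleosome filtering, TSS-anchored midpoint matrices, log2
light/heavy sensitivity, max-signal and quartile sorts, the -1-band
paired t-tests against the baseline condition, k-means promoter sets,
cluster averages and peak overlays — and returns a
``PromoterNucleosomeResults`` carrying the estimates, the tests and a
``summary()`` table. Identical inputs and parameters reproduce identical
outputs.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import io as gio
from .config import DIGESTS, PipelineConfig
from .containers import (
    ExpressionTable,
    FragmentSet,
    PeakSet,
    PromoterMatrix,
    SensitivityMatrix,
    TssAnnotation,
)
from .matrix_ops import (
    ClusterAssignment,
    SortOrder,
    apply_sort,
    cluster_average_profiles,
    kmeans_profiles,
    peak_matrix,
    quartiles_by_key,
    sort_by_max_signal,
)
from .occupancy import filter_mononucleosome, midpoint_matrix
from .sensitivity import classify_msf_mrf, sensitivity_matrix
from .stats import PairedTestResult, paired_t_test, region_summary

logger = logging.getLogger(__name__)

QUARTILES = ("Q1", "Q2", "Q3", "Q4")


@dataclass
class PromoterNucleosomeResults:
    """Fitted matrices, sorts, clusters and tests; see ``summary()``."""

    occupancy: dict[tuple[str, str], PromoterMatrix]
    sensitivity: dict[str, SensitivityMatrix]
    max_signal_order: SortOrder
    expression_quartiles: dict[str, str] | None
    sensitivity_quartiles: dict[str, dict[str, str]]
    max_sensitivity_orders: dict[str, SortOrder]
    paired_tests: list[PairedTestResult]
    clusters: dict[str, ClusterAssignment]
    cluster_means: dict[str, pd.DataFrame]
    peak_matrices: dict[str, PromoterMatrix]
    band: tuple[int, int]
    baseline: str
    sort_condition: str
    run_log: list[str] = field(default_factory=list)

    @property
    def conditions(self) -> list[str]:
        return list(self.sensitivity)

    def summary(self) -> str:
        lines = ["Promoter nucleosome occupancy / MNase-sensitivity analysis",
                 "=" * 60]
        any_cond = next(iter(self.sensitivity.values()))
        n_genes, n_win = any_cond.shape
        lines.append(f"genes: {n_genes}   windows: {n_win}   "
                     f"conditions: {', '.join(self.conditions)}")
        lines.append(f"baseline: {self.baseline}   "
                     f"-1 band: {self.band[0]}..{self.band[1]} bp")
        lines.append("")
        lines.append(f"Paired t-tests vs {self.baseline} "
                     f"(band mean log2 light/heavy per gene):")
        for r in self.paired_tests:
            lines.append("  " + str(r))
        for condition, assignment in self.clusters.items():
            sizes = ", ".join(
                f"{lab}:{assignment.sizes[lab]}" for lab in sorted(assignment.sizes)
            )
            lines.append(f"k-means ({condition}, k={assignment.k}): {sizes}")
        return "\n".join(lines)

    def save(self, outdir: str | Path) -> None:
        """Write all matrices, sorts, assignments, tests and the run log."""
        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        for (condition, digest), mat in self.occupancy.items():
            gio.write_matrix(mat, outdir / f"occupancy_{condition}_{digest}.tsv")
        for condition, sens in self.sensitivity.items():
            gio.write_matrix(sens, outdir / f"sensitivity_{condition}.tsv")
            labels = classify_msf_mrf(sens)
            labels.index.name = "gene_id"
            labels.to_csv(outdir / f"msf_mrf_{condition}.tsv", sep="\t")
        pd.Series(
            self.max_signal_order.key_values.reindex(self.max_signal_order.gene_ids),
            name="max_signal",
        ).to_csv(outdir / "sort_max_signal.tsv", sep="\t", header=True)
        if self.expression_quartiles is not None:
            pd.Series(self.expression_quartiles, name="quartile").rename_axis(
                "gene_id"
            ).to_csv(outdir / "expression_quartiles.tsv", sep="\t")
        for condition, qmap in self.sensitivity_quartiles.items():
            pd.Series(qmap, name="quartile").rename_axis("gene_id").to_csv(
                outdir / f"max_sensitivity_quartiles_{condition}.tsv", sep="\t"
            )
        rows = [
            {
                "condition_vs_baseline": r.gene_set,
                "band_lo": r.band[0], "band_hi": r.band[1],
                "n": r.n, "mean_diff": r.mean_diff, "t": r.t, "df": r.df,
                "p": r.p, "dropped": r.n_dropped, "flag": r.flag,
            }
            for r in self.paired_tests
        ]
        pd.DataFrame(rows).to_csv(outdir / "paired_tests.tsv", sep="\t", index=False)
        for condition, assignment in self.clusters.items():
            assignment.labels.rename_axis("gene_id").to_csv(
                outdir / f"kmeans_{condition}.tsv", sep="\t"
            )
            means = self.cluster_means[condition]
            means.index.name = "cluster"
            means.to_csv(outdir / f"cluster_means_{condition}.tsv", sep="\t",
                         float_format="%.17g")
        order = self.max_sensitivity_orders[self.sort_condition]
        for factor, mat in self.peak_matrices.items():
            gio.write_matrix(
                apply_sort(mat, order),
                outdir / f"peaks_{factor}_sorted_{self.sort_condition}.tsv",
            )
        (outdir / "summary.txt").write_text(self.summary() + "\n")
        (outdir / "run_log.txt").write_text("\n".join(self.run_log) + "\n")

    def plot_heatmap(self, condition: str, path: str | Path, **kwargs) -> None:
        from .plotting import sensitivity_heatmap

        sensitivity_heatmap(self.sensitivity[condition], path, **kwargs)


class PromoterNucleosomeModel:
    """The analysis model over one set of promoters.

    Parameters
    ----------
    fragments : mapping (condition, digest) -> FragmentSet
        Aligned paired-end mononucleosome fragment intervals; ``digest``
        is ``"light"`` or ``"heavy"``. Every condition needs both.
    annotation : TssAnnotation
    expression : ExpressionTable, optional
        Enables expression-quartile sorting and per-quartile tests.
    peaks : mapping factor -> PeakSet, optional
    """

    def __init__(
        self,
        fragments: dict[tuple[str, str], FragmentSet],
        annotation: TssAnnotation,
        expression: ExpressionTable | None = None,
        peaks: dict[str, PeakSet] | None = None,
        *,
        baseline: str = "untreated",
        window: int = 60,
        step: int = 10,
        mono_bounds: tuple[int, int] = (140, 160),
        pseudocount: float = 1.0,
        normalize: bool = True,
    ) -> None:
        self.conditions = sorted({c for c, _ in fragments}, key=str)
        for condition in self.conditions:
            for digest in DIGESTS:
                if (condition, digest) not in fragments:
                    raise ValueError(
                        f"condition {condition!r}: missing {digest} digest"
                    )
        if baseline not in self.conditions:
            raise ValueError(f"baseline condition {baseline!r} not provided")
        # keep baseline first, then the treated time points in given order
        self.conditions.sort(key=lambda c: (c != baseline, c))
        self.fragments = fragments
        self.annotation = annotation
        self.expression = expression
        self.peaks = peaks or {}
        self.baseline = baseline
        self.window = window
        self.step = step
        self.mono_bounds = mono_bounds
        self.pseudocount = pseudocount
        self.normalize = normalize

    @classmethod
    def from_config(cls, cfg: PipelineConfig) -> "PromoterNucleosomeModel":
        cfg.validate()
        annotation = gio.read_tss_annotation(cfg.tss, flank=cfg.flank)
        fragments: dict[tuple[str, str], FragmentSet] = {}
        for condition, digests in cfg.fragments.items():
            for digest, paths in digests.items():
                parts = [
                    gio.read_fragments_bed(p, label=f"{digest}:{condition}")
                    for p in paths
                ]
                if len(parts) == 1:
                    pooled = parts[0]
                else:
                    pooled = FragmentSet(
                        np.concatenate([p.chroms for p in parts]),
                        np.concatenate([p.starts for p in parts]),
                        np.concatenate([p.ends for p in parts]),
                        label=f"{digest}:{condition} (pooled x{len(parts)})",
                    )
                    logger.info(
                        "pooled %d replicate files for %s %s",
                        len(parts), condition, digest,
                    )
                fragments[(condition, digest)] = pooled
        expression = (
            gio.read_expression_table(cfg.expression) if cfg.expression else None
        )
        peaks = {
            factor: gio.read_narrowpeak(path, factor=factor)
            for factor, path in cfg.peaks.items()
        }
        return cls(
            fragments, annotation, expression, peaks,
            baseline=cfg.baseline, window=cfg.window, step=cfg.step,
            mono_bounds=(cfg.mono_min, cfg.mono_max),
            pseudocount=cfg.pseudocount,
        )

    def fit(
        self,
        k: int = 6,
        kmeans_seed: int = 0,
        n_init: int = 10,
        band: tuple[int, int] = (-200, 0),
        sort_condition: str | None = None,
    ) -> PromoterNucleosomeResults:
        log: list[str] = []

        def note(msg: str) -> None:
            log.append(msg)
            logger.info(msg)

        note(f"conditions: {', '.join(self.conditions)} (baseline {self.baseline})")
        note(f"mononucleosome bounds: {self.mono_bounds[0]}-{self.mono_bounds[1]} bp")
        note(f"window {self.window} bp, step {self.step} bp, "
             f"flank {self.annotation.flank} bp")
        note("normalization: fragments per million mapped in the TSS+/-flank "
             "region set (midpoint rule)" if self.normalize else
             "normalization: raw midpoint counts")
        note(f"sensitivity pseudocount: {self.pseudocount} (symmetric)")

        occupancy: dict[tuple[str, str], PromoterMatrix] = {}
        for condition in self.conditions:
            for digest in DIGESTS:
                try:
                    frags = self.fragments[(condition, digest)]
                    kept = filter_mononucleosome(frags, *self.mono_bounds)
                    note(
                        f"{condition}/{digest}: {kept.total_count}/"
                        f"{frags.total_count} mononucleosome fragments retained"
                    )
                    occupancy[(condition, digest)] = midpoint_matrix(
                        kept, self.annotation, self.window, self.step,
                        normalize=self.normalize,
                    )
                except Exception as exc:
                    raise RuntimeError(
                        f"stage occupancy failed for condition {condition!r} "
                        f"({digest} digest): {exc}"
                    ) from exc

        sens: dict[str, SensitivityMatrix] = {}
        for condition in self.conditions:
            try:
                sens[condition] = sensitivity_matrix(
                    occupancy[(condition, "light")],
                    occupancy[(condition, "heavy")],
                    pseudocount=self.pseudocount,
                )
                sens[condition].metadata["label"] = f"sensitivity:{condition}"
            except Exception as exc:
                raise RuntimeError(
                    f"stage sensitivity failed for condition {condition!r}: {exc}"
                ) from exc

        # heatmap sorts: total-occupancy max signal on the baseline light digest
        max_order = sort_by_max_signal(occupancy[(self.baseline, "light")])
        note(f"max-signal sort computed on {self.baseline}/light occupancy")

        expr_quartiles = None
        if self.expression is not None:
            expr_quartiles = quartiles_by_key(
                self.annotation.gene_ids,
                self.expression.values.reindex(self.annotation.gene_ids),
            )
            note("expression quartiles: Q1 = highest expression; earlier "
                 "quartiles take the remainder")

        sens_quartiles: dict[str, dict[str, str]] = {}
        max_sens_orders: dict[str, SortOrder] = {}
        for condition, s in sens.items():
            order = sort_by_max_signal(s)
            order.key_name = "max_sensitivity"
            max_sens_orders[condition] = order
            sens_quartiles[condition] = quartiles_by_key(
                self.annotation.gene_ids, order.key_values
            )
        note("max-sensitivity quartiles computed per condition")

        # paired t-tests: each treated condition vs baseline on the -1 band
        tests: list[PairedTestResult] = []
        base_summary = region_summary(sens[self.baseline], band)
        for condition in self.conditions:
            if condition == self.baseline:
                continue
            cond_summary = region_summary(sens[condition], band)
            if expr_quartiles is not None:
                for q in QUARTILES:
                    genes = [g for g, qq in expr_quartiles.items() if qq == q]
                    tests.append(
                        paired_t_test(
                            base_summary, cond_summary, genes,
                            gene_set=f"{condition} vs {self.baseline}, "
                                     f"expression {q}",
                        )
                    )
            tests.append(
                paired_t_test(
                    base_summary, cond_summary,
                    gene_set=f"{condition} vs {self.baseline}, all genes",
                )
            )

        clusters: dict[str, ClusterAssignment] = {}
        cluster_means: dict[str, pd.DataFrame] = {}
        for condition, s in sens.items():
            assignment = kmeans_profiles(s, k=k, seed=kmeans_seed, n_init=n_init)
            clusters[condition] = assignment
            cluster_means[condition], _ = cluster_average_profiles(s, assignment)
            if assignment.imputed_genes:
                note(f"kmeans {condition}: {len(assignment.imputed_genes)} rows "
                     "mean-imputed per column")
        note(f"kmeans on raw sensitivity rows, k={k}, n_init={n_init}, "
             f"seed={kmeans_seed}")

        peak_mats = {
            factor: peak_matrix(ps, self.annotation, self.window, self.step)
            for factor, ps in self.peaks.items()
        }

        if sort_condition is None:
            non_base = [c for c in self.conditions if c != self.baseline]
            sort_condition = non_base[0] if non_base else self.baseline
        note(f"peak overlays sorted by max sensitivity of {sort_condition!r}")

        return PromoterNucleosomeResults(
            occupancy=occupancy,
            sensitivity=sens,
            max_signal_order=max_order,
            expression_quartiles=expr_quartiles,
            sensitivity_quartiles=sens_quartiles,
            max_sensitivity_orders=max_sens_orders,
            paired_tests=tests,
            clusters=clusters,
            cluster_means=cluster_means,
            peak_matrices=peak_mats,
            band=band,
            baseline=self.baseline,
            sort_condition=sort_condition,
            run_log=log,
        )


def run_full_analysis(cfg: PipelineConfig) -> PromoterNucleosomeResults:
    """Config-driven end-to-end run; writes every declared output to
    ``cfg.outdir`` and returns the results object."""
    model = PromoterNucleosomeModel.from_config(cfg)
    results = model.fit(
        k=cfg.k, kmeans_seed=cfg.kmeans_seed, n_init=cfg.n_init,
        band=cfg.band, sort_condition=cfg.sort_condition,
    )
    results.save(cfg.outdir)
    return results
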