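"""YAML-driven pipeline configuration.

A single manifest names the fragment BED files per condition and digest
level (a list of paths per digest is pooled on load), the TSS
annotation, optional expression table and narrowPeak files, plus the
analysis parameters. Every path is validated up front so a bad manifest
fails before any compute.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import yaml

DIGESTS = ("light", "heavy")


@dataclass
class PipelineConfig:
    fragments: dict[str, dict[str, list[str]]]   # condition -> digest -> paths
    tss: str
    expression: str | None = None
    peaks: dict[str, str] = field(default_factory=dict)  # factor -> path
    baseline: str = "untreated"
    flank: int = 1000
    window: int = 60
    step: int = 10
    mono_min: int = 140
    mono_max: int = 160
    pseudocount: float = 1.0
    k: int = 6
    kmeans_seed: int = 0
    n_init: int = 10
    band: tuple[int, int] = (-200, 0)
    sort_condition: str | None = None   # default: first non-baseline condition
    outdir: str = "nucsens_out"

    def validate(self) -> None:
        if not self.fragments:
            raise ValueError("manifest lists no conditions")
        for condition, digests in self.fragments.items():
            for digest in DIGESTS:
                if digest not in digests or not digests[digest]:
                    raise ValueError(
                        f"condition {condition!r}: missing {digest} digest"
                    )
                for p in digests[digest]:
                    if not Path(p).exists():
                        raise FileNotFoundError(
                            f"condition {condition!r} {digest}: {p} not found"
                        )
        if self.baseline not in self.fragments:
            raise ValueError(
                f"baseline condition {self.baseline!r} not in manifest"
            )
        if not Path(self.tss).exists():
            raise FileNotFoundError(f"TSS annotation {self.tss} not found")
        if self.expression and not Path(self.expression).exists():
            raise FileNotFoundError(f"expression table {self.expression} not found")
        for factor, p in self.peaks.items():
            if not Path(p).exists():
                raise FileNotFoundError(f"peaks[{factor}]: {p} not found")
        if self.mono_min >= self.mono_max:
            raise ValueError("mono_min must be < mono_max")
        if self.window <= 0 or self.step <= 0 or self.window % 2:
            raise ValueError("window must be positive and even, step positive")
        if self.window > 2 * self.flank:
            raise ValueError("window exceeds 2*flank")
        if self.pseudocount <= 0:
            raise ValueError("pseudocount must be > 0")
        if self.k < 2:
            raise ValueError("k must be >= 2")
        if self.band[0] > self.band[1]:
            raise ValueError("band must be (lo, hi) with lo <= hi")
        if self.sort_condition is not None and self.sort_condition not in self.fragments:
            raise ValueError(f"sort_condition {self.sort_condition!r} not in manifest")

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        fragments = {}
        for condition, digests in (raw.pop("fragments", {}) or {}).items():
            fragments[condition] = {
                digest: [paths] if isinstance(paths, str) else list(paths)
                for digest, paths in digests.items()
            }
        raw["fragments"] = fragments
        if "band" in raw:
            raw["band"] = tuple(raw["band"])
        cfg = cls(**raw)
        cfg.validate()
        return cfg
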