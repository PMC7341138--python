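import sys
from pathlib import Path

import numpy as np
import pandas as pd
import pytest

sys.path.insert(0, str(Path(__file__).parent))  # make oracles importable

from nucsens import (
    FragmentSet,
    PromoterMatrix,
    SimulationConfig,
    TssAnnotation,
    simulate_truth,
)
from nucsens.simulate import write_dataset


@pytest.fixture(scope="session")
def small_cfg() -> SimulationConfig:
    return SimulationConfig(n_genes=12, depth=300, seed=5)


@pytest.fixture(scope="session")
def small_truth(small_cfg):
    return simulate_truth(small_cfg)


@pytest.fixture(scope="session")
def dataset_dir(tmp_path_factory, small_cfg) -> Path:
    out = tmp_path_factory.mktemp("synth")
    write_dataset(small_cfg, out)
    return out


@pytest.fixture
def rng() -> np.random.Generator:
    return np.random.default_rng(1234)


@pytest.fixture
def tiny_annotation() -> TssAnnotation:
    """Three genes, mixed strands, flank 500, on two chromosomes."""
    return TssAnnotation(
        pd.DataFrame(
            {
                "gene_id": ["gA", "gB", "gC"],
                "chrom": ["chr1", "chr1", "chr2"],
                "tss": [1000, 4000, 2000],
                "strand": ["+", "-", "+"],
            }
        ),
        flank=500,
    )


def random_fragments(
    rng: np.random.Generator,
    n: int,
    annotation: TssAnnotation,
    label: str = "",
) -> FragmentSet:
    """Fragments scattered in and around the annotation's windows."""
    recs = annotation.records
    idx = rng.integers(0, len(recs), size=n)
    tss = recs["tss"].to_numpy()[idx]
    chroms = recs["chrom"].to_numpy(dtype=object)[idx]
    mids = tss + rng.integers(-annotation.flank - 200, annotation.flank + 200, size=n)
    lengths = rng.integers(80, 200, size=n)
    starts = np.maximum(mids - lengths // 2, 0)
    return FragmentSet(chroms, starts, starts + lengths, label=label)


def matrix_from_array(values: np.ndarray, centers=None, genes=None, **meta) -> PromoterMatrix:
    n, m = values.shape
    if centers is None:
        centers = np.arange(m) * 10 - (m // 2) * 10
    if genes is None:
        genes = [f"g{i:03d}" for i in range(n)]
    md = {"normalization": "fpm"}
    md.update(meta)
    return PromoterMatrix(pd.DataFrame(values, index=genes, columns=centers), md)
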