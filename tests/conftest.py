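import numpy as np
import pandas as pd
import pytest

from megs import (
    GenotypeMatrix,
    SimulationConfig,
    simulate_dataset,
)
from megs.evaluation import PredictionData


@pytest.fixture(scope="session")
def small_ds():
    """One modest simulated dataset with planted SNP and ASV signal."""
    cfg = SimulationConfig(
        n_genotypes=60, n_snps=300, n_asvs=60, n_groups=10, n_classes=4,
        ld_block_size=5, n_causal_asvs=8, n_mediators=4,
        h2_snp=0.4, var_share_asv=0.2, asv_h2=0.4, seed=7,
    )
    return simulate_dataset(cfg)


@pytest.fixture(scope="session")
def small_data(small_ds):
    return PredictionData.from_simulated(small_ds)


@pytest.fixture
def tiny_geno():
    """Handcrafted 4x3 genotype matrix: marker m2 half-missing, m3 monomorphic."""
    return GenotypeMatrix(
        individual_ids=["i1", "i2", "i3", "i4"],
        marker_ids=["m1", "m2", "m3"],
        chrom=np.array(["1", "1", "1"]),
        pos_bp=np.array([100, 200, 300]),
        dosages=np.array([
            [0.0, np.nan, 2.0],
            [1.0, np.nan, 2.0],
            [2.0, 1.0, 2.0],
            [1.0, 0.0, 2.0],
        ]),
    )


def random_genotypes(n, m, rng, maf_low=0.1, maf_high=0.5, spacing=50, chrom="1"):
    """Unstructured HWE genotypes on an evenly spaced coordinate grid."""
    p = rng.uniform(maf_low, maf_high, size=m)
    dos = (rng.random((n, m)) < p).astype(float) + (rng.random((n, m)) < p)
    return GenotypeMatrix(
        individual_ids=[f"i{k}" for k in range(n)],
        marker_ids=[f"m{j}" for j in range(m)],
        chrom=np.array([chrom] * m),
        pos_bp=np.arange(1, m + 1) * spacing,
        dosages=dos,
    )


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture
def balanced_design():
    """Fully observed 2-treatment x 2-block design for 6 genotypes."""
    rows = []
    for trt in ("HN", "LN"):
        for blk in ("B1", "B2"):
            for g in range(6):
                rows.append((f"G{g}", trt, blk, f"SP{g % 4 + 1}", f"SPB{g % 3 + 1}",
                             f"{blk}:SP{g % 4 + 1}"))
    df = pd.DataFrame(rows, columns=["genotype", "treatment", "block", "splitplot",
                                     "splitplot_block", "quadrant"])
    df.index = pd.Index([f"p{i}" for i in range(len(df))], name="plot_id")
    return df
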