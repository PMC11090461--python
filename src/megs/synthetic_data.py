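"""Synthetic hologenome generator: genotypes -> rhizosphere microbiome -> phenotype.

Emulates a split-plot field trial on a diversity panel: ~230 genotypes grown
under two nitrogen treatments (HN/LN) in two blocks, plots nested in split
plots and split-plot blocks, with ~14% of plots lost to missingness (the
scale at which 230 x 2 x 2 = 920 potential plots yield ~795 observations).
ASV log abundances receive microenvironment (design) effects plus, for
heritable ASVs, a sparse host-genetic component scaled to a target
genotype-attributable variance fraction. The phenotype combines polygenic SNP
effects, sparse ASV effects (optionally active only under the LN-like
treatment) and noise, with components rescaled so realized variance shares
match the configured ones. Every planted parameter is returned in a
TruthBundle for recovery tests.
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict

import numpy as np
import pandas as pd

from .genotypes import GenotypeMatrix
from .microbiome import MicrobiomeTable

__all__ = [
    "DesignSpec",
    "SimulationConfig",
    "TruthBundle",
    "SimulatedDataset",
    "simulate_genotypes",
    "simulate_design",
    "simulate_microbiome",
    "simulate_phenotype",
    "simulate_dataset",
]

TREATMENTS = ("HN", "LN")


@dataclass(frozen=True)
class DesignSpec:
    """Split-plot layout cardinalities and plot dropout rate."""

    n_treatments: int = 2
    n_blocks: int = 2
    n_splitplots: int = 4
    n_splitplotblocks: int = 3
    plot_missing_rate: float = 125.0 / 920.0  # 920 potential plots -> ~795 retained

    def __post_init__(self) -> None:
        if not 0.0 <= self.plot_missing_rate < 1.0:
            raise ValueError("plot_missing_rate must be in [0, 1)")
        if self.n_treatments != len(TREATMENTS):
            raise ValueError("only the two-treatment (HN/LN) layout is supported")


@dataclass(frozen=True)
class SimulationConfig:
    n_genotypes: int = 230
    n_snps: int = 50_000
    n_asvs: int = 3_626
    n_groups: int = 154
    n_classes: int = 19
    maf_range: tuple[float, float] = (0.05, 0.5)
    ld_block_size: int = 10
    n_chromosomes: int = 10
    design_spec: DesignSpec = field(default_factory=DesignSpec)
    h2_snp: float = 0.5
    var_share_asv: float = 0.2
    n_causal_asvs: int = 20
    n_mediators: int = 10
    n_heritable_noncausal: int | None = None
    snps_per_asv: int = 5
    asv_h2: float = 0.4
    treatment_specific: bool = False
    seed: int = 0

    def __post_init__(self) -> None:
        lo, hi = self.maf_range
        if not (0.0 < lo <= hi <= 0.5):
            raise ValueError(f"maf_range must satisfy 0 < low <= high <= 0.5, got {self.maf_range}")
        if not (self.h2_snp >= 0 and self.var_share_asv >= 0
                and self.h2_snp + self.var_share_asv < 1):
            raise ValueError("h2_snp + var_share_asv must be < 1 with both nonnegative")
        if not self.n_mediators <= self.n_causal_asvs <= self.n_asvs:
            raise ValueError("require n_mediators <= n_causal_asvs <= n_asvs")
        if not 0.0 <= self.asv_h2 < 1.0:
            raise ValueError("asv_h2 must be in [0, 1)")
        if self.n_genotypes < 2 or self.n_snps < 1:
            raise ValueError("need n_genotypes >= 2 and n_snps >= 1")
        if not self.n_classes <= self.n_groups <= self.n_asvs:
            raise ValueError("require n_classes <= n_groups <= n_asvs")

    @property
    def n_heritable_extra(self) -> int:
        if self.n_heritable_noncausal is not None:
            return self.n_heritable_noncausal
        return self.n_causal_asvs - self.n_mediators


@dataclass
class TruthBundle:
    """Generative ground truth of one simulated dataset."""

    true_alpha: np.ndarray
    true_B: dict[str, tuple[np.ndarray, np.ndarray]]  # asv_id -> (snp col idx, effects)
    true_gamma: pd.Series
    mediator_ids: list[str]
    heritable_ids: list[str]
    causal_ids: list[str]
    variance_components: dict[str, float]
    gamma_treatment_mask: dict[str, float]

    def to_jsonable(self) -> dict:
        return {
            "true_alpha": self.true_alpha.tolist(),
            "true_B": {k: [v[0].tolist(), v[1].tolist()] for k, v in self.true_B.items()},
            "true_gamma": self.true_gamma.to_dict(),
            "mediator_ids": self.mediator_ids,
            "heritable_ids": self.heritable_ids,
            "causal_ids": self.causal_ids,
            "variance_components": self.variance_components,
            "gamma_treatment_mask": self.gamma_treatment_mask,
        }


@dataclass
class SimulatedDataset:
    config: SimulationConfig
    genotypes: GenotypeMatrix
    design: pd.DataFrame
    microbiome: MicrobiomeTable
    phenotype: pd.Series
    truth: TruthBundle


def _rng_for(config: SimulationConfig, stage: int) -> np.random.Generator:
    # independent streams per stage so each operation is deterministic in isolation
    return np.random.default_rng(np.random.SeedSequence([int(config.seed) % (2**31), stage]))


def simulate_genotypes(config: SimulationConfig) -> GenotypeMatrix:
    """Dosage matrix with block-structured LD on a synthetic coordinate grid.

    Each haplotype allele is a thresholded Gaussian: markers within an LD
    block share a latent factor (equicorrelation rho=0.9), blocks are
    independent, so adjacent within-block markers are correlated and
    cross-block markers independent in expectation. Dosage = sum of two
    independent haplotypes, giving Hardy-Weinberg genotype frequencies at the
    drawn MAF.
    """
    rng = _rng_for(config, 0)
    n, m = config.n_genotypes, config.n_snps
    lo, hi = config.maf_range
    p = rng.uniform(lo, hi, size=m)
    bs = max(1, config.ld_block_size)
    n_blocks = -(-m // bs)
    rho = 0.9 if bs > 1 else 0.0
    thresh = _norm_ppf(p)
    dos = np.zeros((n, m), dtype=float)
    for _hap in range(2):
        shared = rng.standard_normal((n, n_blocks))
        eps = rng.standard_normal((n, m))
        block_of = np.arange(m) // bs
        z = np.sqrt(rho) * shared[:, block_of] + np.sqrt(1.0 - rho) * eps
        dos += (z < thresh[None, :]).astype(float)
    # coordinate grid: chromosomes split on block boundaries, 100 bp spacing
    n_chrom = max(1, min(config.n_chromosomes, n_blocks))
    blocks_per_chrom = -(-n_blocks // n_chrom)
    chrom = np.array([f"chr{(b // blocks_per_chrom) + 1}" for b in np.arange(m) // bs])
    pos = np.empty(m, dtype=np.int64)
    for c in np.unique(chrom):
        idx = np.nonzero(chrom == c)[0]
        pos[idx] = 1 + 100 * np.arange(len(idx))
    return GenotypeMatrix(
        individual_ids=[f"G{i + 1:04d}" for i in range(n)],
        marker_ids=[f"snp{j + 1:06d}" for j in range(m)],
        chrom=chrom,
        pos_bp=pos,
        dosages=dos,
    )


def _norm_ppf(q: np.ndarray) -> np.ndarray:
    from scipy.stats import norm

    return norm.ppf(q)


def simulate_design(config: SimulationConfig) -> pd.DataFrame:
    """Plot-level design table for the split-plot HN/LN layout.

    Each genotype appears once per (treatment x block) before dropout. Within
    each treatment-block replicate genotypes are laid out in a random field
    order, cut into contiguous split plots, each cut into contiguous
    split-plot blocks. The quadrant label is the (block, split plot) cell.
    Plots are then dropped i.i.d. at ``plot_missing_rate``.
    """
    spec = config.design_spec
    rng = _rng_for(config, 1)
    geno_ids = [f"G{i + 1:04d}" for i in range(config.n_genotypes)]
    rows = []
    for trt in TREATMENTS:
        for blk in range(1, spec.n_blocks + 1):
            order = rng.permutation(config.n_genotypes)
            n_per_sp = -(-config.n_genotypes // spec.n_splitplots)
            for fpos, gi in enumerate(order):
                sp = min(fpos // n_per_sp, spec.n_splitplots - 1) + 1
                within = fpos % n_per_sp
                n_per_spb = -(-n_per_sp // spec.n_splitplotblocks)
                spb = min(within // n_per_spb, spec.n_splitplotblocks - 1) + 1
                rows.append((geno_ids[gi], trt, f"B{blk}", f"SP{sp}", f"SPB{spb}",
                             f"B{blk}:SP{sp}"))
    df = pd.DataFrame(rows, columns=["genotype", "treatment", "block", "splitplot",
                                     "splitplot_block", "quadrant"])
    keep = rng.random(len(df)) >= spec.plot_missing_rate
    df = df.loc[keep].reset_index(drop=True)
    df.index = pd.Index([f"plot{i + 1:05d}" for i in range(len(df))], name="plot_id")
    return df


def _expand_to_plots(geno: GenotypeMatrix, design: pd.DataFrame) -> np.ndarray:
    """Plot-level centered dosage matrix (rows follow the design table)."""
    pos = {g: i for i, g in enumerate(geno.individual_ids)}
    missing = [g for g in design["genotype"].unique() if g not in pos]
    if missing:
        raise ValueError(f"design references genotypes absent from panel: {missing[:5]}")
    Zc = geno.centered()
    return Zc[[pos[g] for g in design["genotype"]], :]


def _design_effect_vector(design: pd.DataFrame, rng: np.random.Generator,
                          sd_treatment: float, sd_other: float) -> np.ndarray:
    """A fixed microenvironment contribution from the design factors."""
    eff = np.zeros(len(design))
    for colname, sd in [("treatment", sd_treatment), ("block", sd_other),
                        ("splitplot", sd_other), ("splitplot_block", sd_other)]:
        levels = pd.unique(design[colname])
        vals = dict(zip(levels, rng.normal(0.0, sd, size=len(levels))))
        eff += design[colname].map(vals).to_numpy(dtype=float)
    return eff


def simulate_microbiome(
    geno: GenotypeMatrix,
    design: pd.DataFrame,
    config: SimulationConfig,
) -> tuple[MicrobiomeTable, dict]:
    """ASV log abundances: intercept + microenvironment + genetic part + noise.

    Heritable ASVs (planted mediators plus heritable-but-phenotype-neutral
    extras) receive a sparse SNP-driven component rescaled so the
    genotype-attributable variance fraction equals ``asv_h2``. Abundances are
    generated directly on the log relative abundance scale. Returns the table
    plus the partial truth (sparse B coefficients, heritable/mediator ids,
    taxonomy is assigned round-robin so groups nest within classes).
    """
    rng = _rng_for(config, 2)
    n_plots = len(design)
    m = config.n_asvs
    asv_ids = [f"asv{j + 1:05d}" for j in range(m)]

    causal = rng.choice(m, size=config.n_causal_asvs, replace=False)
    mediators = causal[: config.n_mediators]
    noncausal = np.setdiff1d(np.arange(m), causal)
    n_extra = min(config.n_heritable_extra, len(noncausal))
    extra = rng.choice(noncausal, size=n_extra, replace=False) if n_extra else np.array([], int)
    heritable = np.concatenate([mediators, extra]).astype(int)

    Zplots = _expand_to_plots(geno, design)
    intercepts = rng.normal(-8.0, 1.0, size=m)
    vals = np.empty((n_plots, m))
    true_B: dict[str, tuple[np.ndarray, np.ndarray]] = {}
    heritable_set = set(int(j) for j in heritable)
    for j in range(m):
        env = _design_effect_vector(design, rng, sd_treatment=0.3, sd_other=0.1)
        noise = rng.normal(0.0, 1.0, size=n_plots)
        genetic = np.zeros(n_plots)
        if j in heritable_set and config.asv_h2 > 0:
            idx = rng.choice(config.n_snps, size=min(config.snps_per_asv, config.n_snps),
                             replace=False)
            b = rng.normal(0.0, 1.0, size=len(idx))
            raw = Zplots[:, idx] @ b
            vg, ve = raw.var(), (env + noise).var()
            if vg > 0:
                scale = np.sqrt(config.asv_h2 / (1.0 - config.asv_h2) * ve / vg)
                b = b * scale
                genetic = raw * scale
                true_B[asv_ids[j]] = (idx, b)
        vals[:, j] = intercepts[j] + env + genetic + noise

    taxonomy = pd.DataFrame(
        {
            "group": [f"group{(j % config.n_groups) + 1:03d}" for j in range(m)],
            "class_": [f"class{((j % config.n_groups) % config.n_classes) + 1:02d}"
                       for j in range(m)],
        },
        index=pd.Index(asv_ids, name="asv_id"),
    )
    table = MicrobiomeTable(
        values=pd.DataFrame(vals, index=design.index, columns=asv_ids),
        taxonomy=taxonomy,
    )
    partial = {
        "true_B": true_B,
        "mediator_ids": [asv_ids[int(j)] for j in mediators],
        "heritable_ids": [asv_ids[int(j)] for j in heritable],
        "causal_ids": [asv_ids[int(j)] for j in causal],
    }
    return table, partial


def simulate_phenotype(
    geno: GenotypeMatrix,
    microbiome: MicrobiomeTable,
    design: pd.DataFrame,
    config: SimulationConfig,
    partial_truth: dict,
) -> tuple[pd.Series, TruthBundle]:
    """Phenotype = mean + design fixed effects + SNP part + ASV part + noise.

    The polygenic SNP component, the sparse ASV component and the residual are
    empirically rescaled so realized variance shares equal ``h2_snp``,
    ``var_share_asv`` and their complement. With ``treatment_specific`` the
    ASV effects act only in the LN treatment (scaling still targets the
    whole-sample share).
    """
    if not microbiome.observation_ids.equals(design.index):
        raise ValueError("microbiome rows are not aligned with the design table "
                         f"(first mismatch near {_first_mismatch(microbiome, design)})")
    rng = _rng_for(config, 3)
    n = len(design)
    Zplots = _expand_to_plots(geno, design)

    alpha = rng.normal(0.0, 1.0, size=config.n_snps)
    u = Zplots @ alpha
    gamma = pd.Series(0.0, index=microbiome.asv_ids)
    causal = partial_truth["causal_ids"]
    # planted effects are bounded away from zero: random sign, comparable size,
    # so every causal ASV genuinely carries the configured variance share
    gamma.loc[causal] = (rng.choice([-1.0, 1.0], size=len(causal))
                         * rng.uniform(0.8, 1.2, size=len(causal)))
    Mc = microbiome.matrix - microbiome.matrix.mean(axis=0)
    v = Mc @ gamma.to_numpy()
    mask = np.ones(n)
    if config.treatment_specific:
        mask = (design["treatment"] == "LN").to_numpy(dtype=float)
    v = v * mask
    eps = rng.normal(0.0, 1.0, size=n)

    def _rescale(x: np.ndarray, target_var: float) -> tuple[np.ndarray, float]:
        s = x.std()
        if target_var == 0.0 or s == 0.0:
            return np.zeros_like(x), 0.0
        f = np.sqrt(target_var) / s
        return x * f, f

    resid_share = 1.0 - config.h2_snp - config.var_share_asv
    u, f_u = _rescale(u, config.h2_snp)
    v, f_v = _rescale(v, config.var_share_asv)
    eps, _ = _rescale(eps, resid_share)
    alpha = alpha * f_u
    gamma = gamma * f_v

    fixed = 10.0 + _design_effect_vector(design, rng, sd_treatment=0.5, sd_other=0.1)
    y = pd.Series(fixed + u + v + eps, index=design.index, name="phenotype")

    truth = TruthBundle(
        true_alpha=alpha,
        true_B={k: (i, b * 1.0) for k, (i, b) in partial_truth["true_B"].items()},
        true_gamma=gamma,
        mediator_ids=partial_truth["mediator_ids"],
        heritable_ids=partial_truth["heritable_ids"],
        causal_ids=partial_truth["causal_ids"],
        variance_components={
            "var_snp": float(np.var(u)),
            "var_asv": float(np.var(v)),
            "var_residual": float(np.var(eps)),
            "h2_snp": config.h2_snp,
            "var_share_asv": config.var_share_asv,
        },
        gamma_treatment_mask={"HN": 0.0 if config.treatment_specific else 1.0, "LN": 1.0},
    )
    return y, truth


def _first_mismatch(microbiome: MicrobiomeTable, design: pd.DataFrame) -> str:
    a, b = microbiome.observation_ids, design.index
    if len(a) != len(b):
        return f"length {len(a)} vs {len(b)}"
    bad = np.nonzero((a != b).to_numpy())[0]
    return f"row {bad[0]}: {a[bad[0]]!r} vs {b[bad[0]]!r}" if len(bad) else "unknown"


def simulate_dataset(config: SimulationConfig) -> SimulatedDataset:
    """Run the full generator chain and assemble the dataset bundle."""
    geno = simulate_genotypes(config)
    design = simulate_design(config)
    micro, partial = simulate_microbiome(geno, design, config)
    y, truth = simulate_phenotype(geno, micro, design, config, partial)
    return SimulatedDataset(config=config, genotypes=geno, design=design,
                            microbiome=micro, phenotype=y, truth=truth)


def config_dict(config: SimulationConfig) -> dict:
    return asdict(config)
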