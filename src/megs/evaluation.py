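"""Cross-validation engine and accuracy statistics for the prediction models.

Folds are genotype-disjoint: genotypes are partitioned into k near-equal
folds and every plot inherits its genotype's fold, so no genotype is seen in
both training and test. Three model arms are supported — SNP-only RR-BLUP,
the joint SNP+ASV model with plug-in variances, and the shuffled-microbiome
control (same fold seeds, ASV rows permuted within treatment) — and accuracy
is the Pearson correlation of predicted versus observed phenotype over the
held-out plots.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from .genotypes import GenotypeMatrix, genotype_pcs
from .microbiome import MicrobiomeTable, aggregate_taxa, shuffle_microbiome
from .mixed_models import (
    FixedCoder,
    estimate_asv_variance,
    fit_two_component,
    predict,
    reml_single_component,
)
from .synthetic_data import SimulatedDataset

logger = logging.getLogger(__name__)

__all__ = [
    "PredictionData",
    "CVResult",
    "make_folds",
    "cross_validate",
    "relative_improvement",
    "compare_models",
    "significance_stars",
    "run_megs_experiment",
]

ARMS = ("snp", "snp+asv", "snp+shuffled")


@dataclass
class PredictionData:
    """Row-aligned bundle consumed by the CV engine."""

    design: pd.DataFrame
    y: pd.Series
    Z: np.ndarray
    snp_ids: list
    M: np.ndarray
    asv_ids: list
    pcs: pd.DataFrame  # genotype-level PC scores
    microbiome: MicrobiomeTable | None = None

    @classmethod
    def from_simulated(cls, ds: SimulatedDataset, level: str = "asv",
                       n_pcs: int = 3) -> "PredictionData":
        table = aggregate_taxa(ds.microbiome, level=level)
        return cls.from_components(ds.genotypes, ds.design, table, ds.phenotype,
                                   n_pcs=n_pcs)

    @classmethod
    def from_components(cls, geno: GenotypeMatrix, design: pd.DataFrame,
                        microbiome: MicrobiomeTable, y: pd.Series,
                        n_pcs: int = 3) -> "PredictionData":
        if not microbiome.observation_ids.equals(design.index):
            raise ValueError("microbiome rows not aligned with design")
        y = y.loc[design.index]
        pos = {g: i for i, g in enumerate(geno.individual_ids)}
        rows = [pos[g] for g in design["genotype"]]
        Z = geno.centered()[rows, :]
        Mraw = microbiome.matrix
        M = Mraw - Mraw.mean(axis=0)
        pcs = genotype_pcs(geno, k=min(n_pcs, geno.n_individuals - 1, geno.n_markers))
        return cls(design=design, y=y, Z=Z, snp_ids=list(geno.marker_ids),
                   M=M, asv_ids=list(microbiome.asv_ids), pcs=pcs,
                   microbiome=microbiome)

    def subset_treatment(self, treatment: str) -> "PredictionData":
        mask = (self.design["treatment"] == treatment).to_numpy()
        design = self.design.loc[mask]
        micro = None
        if self.microbiome is not None:
            micro = MicrobiomeTable(values=self.microbiome.values.loc[design.index],
                                    taxonomy=self.microbiome.taxonomy,
                                    annotations=self.microbiome.annotations)
        return PredictionData(design=design, y=self.y.loc[design.index],
                              Z=self.Z[mask], snp_ids=self.snp_ids,
                              M=self.M[mask], asv_ids=self.asv_ids,
                              pcs=self.pcs, microbiome=micro)


@dataclass
class CVResult:
    """Per-(arm, repeat, fold) accuracies with the scheme that produced them."""

    accuracies: pd.DataFrame  # columns: arm, repeat, fold, accuracy
    k: int
    n_repeats: int
    grouping: str
    seed: int
    meta: dict = field(default_factory=dict)

    def arm(self, arm: str) -> pd.DataFrame:
        return self.accuracies[self.accuracies["arm"] == arm].reset_index(drop=True)

    def mean_accuracy(self, arm: str) -> float:
        return float(self.arm(arm)["accuracy"].mean())

    def repeat_means(self, arm: str) -> pd.Series:
        return self.arm(arm).groupby("repeat")["accuracy"].mean()


def make_folds(design: pd.DataFrame, k: int = 5, grouping: str = "genotype",
               seed: int = 0) -> pd.Series:
    """Genotype-disjoint fold assignment: every plot inherits its genotype's fold."""
    groups = np.sort(pd.unique(design[grouping]))
    if k > len(groups):
        raise ValueError(f"k={k} exceeds {len(groups)} distinct {grouping} values")
    rng = np.random.default_rng(seed)
    order = rng.permutation(len(groups))
    fold_of = {}
    for f, chunk in enumerate(np.array_split(order, k)):
        for gi in chunk:
            fold_of[groups[gi]] = f
    return design[grouping].map(fold_of).rename("fold")


def _pearson(a: np.ndarray, b: np.ndarray) -> float:
    if len(a) < 2 or np.std(a) == 0 or np.std(b) == 0:
        return np.nan
    return float(np.corrcoef(a, b)[0, 1])


def _fit_arms_on_fold(data: PredictionData, M_arm: dict[str, np.ndarray],
                      train: np.ndarray, test: np.ndarray) -> dict[str, float]:
    """Fit all requested arms on one training fold, score on the held-out fold."""
    design_tr = data.design.loc[train]
    design_te = data.design.loc[test]
    y_tr = data.y.loc[train].to_numpy()
    y_te = data.y.loc[test].to_numpy()
    tr_mask = data.design.index.isin(train)
    te_mask = data.design.index.isin(test)
    Z_tr, Z_te = data.Z[tr_mask], data.Z[te_mask]

    factors = tuple(f for f in ("treatment", "block", "splitplot", "splitplot_block")
                    if design_tr[f].nunique() > 1)
    coder = FixedCoder(factors=factors)
    X_tr = coder.fit(design_tr)
    X_te = coder.transform(design_te)

    s_a, s_e, fit_snp = reml_single_component(
        y_tr, X_tr, Z_random=Z_tr, fixed_names=coder.columns_, effect_name="snp",
        effect_ids=data.snp_ids,
    )
    keep = [coder.columns_.index(c) for c in fit_snp.fixed_effects.index]
    out: dict[str, float] = {}
    pred = predict(fit_snp, X_te[:, keep], snp=Z_te)
    out["snp"] = _pearson(pred, y_te)

    for arm, M in M_arm.items():
        if arm == "snp":
            continue
        M_tr, M_te = M[tr_mask], M[te_mask]
        s_g, _, _ = estimate_asv_variance(y_tr, design_tr, data.pcs, M_tr,
                                          factors=factors)
        if s_a <= 0 and s_g <= 0:
            out[arm] = out["snp"]
            continue
        fit = fit_two_component(
            y_tr, X_tr, Z_tr, M_tr,
            sigma2_snp=max(s_a, 1e-12), sigma2_asv=max(s_g, 1e-12), sigma2_e=s_e,
            fixed_names=coder.columns_, snp_ids=data.snp_ids, asv_ids=data.asv_ids,
            solver="kernel",
        )
        keep2 = [coder.columns_.index(c) for c in fit.fixed_effects.index]
        pred = predict(fit, X_te[:, keep2], snp=Z_te, asv=M_te)
        out[arm] = _pearson(pred, y_te)
    return out


def cross_validate(
    data: PredictionData,
    arms: tuple[str, ...] = ("snp", "snp+asv"),
    k: int = 5,
    n_repeats: int = 20,
    seed: int = 0,
    shuffle_strategy: str = "within_treatment",
) -> CVResult:
    """Repeated genotype-disjoint k-fold CV over the requested model arms.

    Repeats differ only in the fold-assignment seed; the shuffled-microbiome
    arm reuses the true-ASV arm's folds (paired design) with the ASV rows
    permuted within treatment once per repeat.
    """
    unknown = set(arms) - set(ARMS)
    if unknown:
        raise ValueError(f"unknown arms: {sorted(unknown)}")
    records = []
    for rep in range(n_repeats):
        ss = np.random.SeedSequence([seed % (2**31), rep])
        fold_seed, shuf_seed = (int(s) for s in ss.generate_state(2) // 2)
        folds = make_folds(data.design, k=k, seed=fold_seed)
        M_arm: dict[str, np.ndarray] = {}
        if "snp+asv" in arms:
            M_arm["snp+asv"] = data.M
        if "snp+shuffled" in arms:
            if data.microbiome is None:
                raise ValueError("shuffled arm requires the microbiome table")
            shuf = shuffle_microbiome(data.microbiome, data.design,
                                      strategy=shuffle_strategy, seed=shuf_seed)
            Ms = shuf.matrix
            M_arm["snp+shuffled"] = Ms - Ms.mean(axis=0)
        for f in range(k):
            test = data.design.index[(folds == f).to_numpy()]
            train = data.design.index[(folds != f).to_numpy()]
            accs = _fit_arms_on_fold(data, M_arm, train, test)
            for arm in arms:
                acc = accs[arm]
                if np.isnan(acc):
                    logger.warning("undefined accuracy (constant fold) arm=%s rep=%d fold=%d",
                                   arm, rep, f)
                records.append({"arm": arm, "repeat": rep, "fold": f, "accuracy": acc})
    return CVResult(accuracies=pd.DataFrame(records), k=k, n_repeats=n_repeats,
                    grouping="genotype", seed=seed)


def relative_improvement(r_full: float, r_base: float) -> float:
    """(r_full - r_base) / r_base; undefined (NaN) for a zero baseline."""
    if r_base == 0 or np.isnan(r_base):
        return np.nan
    return (r_full - r_base) / r_base


def significance_stars(p: float) -> str:
    if np.isnan(p):
        return "ns"
    if p <= 1e-4:
        return "****"
    if p <= 1e-3:
        return "***"
    if p <= 1e-2:
        return "**"
    if p <= 0.05:
        return "*"
    return "ns"


def compare_models(cv_a: CVResult, cv_b: CVResult | None = None,
                   arm_a: str = "snp+asv", arm_b: str = "snp",
                   test: str = "t") -> tuple[float, float, str]:
    """Paired two-sided test on fold-level accuracy differences.

    Pairs by (repeat, fold); the two results must come from the same CV
    scheme. ``test`` is ``"t"`` (paired t) or ``"wilcoxon"`` (signed-rank).
    Returns (statistic, p_value, star label).
    """
    if cv_b is None:
        cv_b = cv_a
    if (cv_a.k, cv_a.n_repeats, cv_a.seed) != (cv_b.k, cv_b.n_repeats, cv_b.seed):
        raise ValueError("CV schemes differ; comparisons must be paired")
    a = cv_a.arm(arm_a).set_index(["repeat", "fold"])["accuracy"]
    b = cv_b.arm(arm_b).set_index(["repeat", "fold"])["accuracy"]
    joined = pd.concat([a, b], axis=1, keys=["a", "b"]).dropna()
    d = joined["a"] - joined["b"]
    if np.allclose(d, 0.0):
        return 0.0, 1.0, "ns"
    if test == "t":
        res = stats.ttest_rel(joined["a"], joined["b"])
    elif test == "wilcoxon":
        res = stats.wilcoxon(joined["a"], joined["b"])
    else:
        raise ValueError(f"unknown test {test!r}")
    stat, p = float(res.statistic), float(res.pvalue)
    return stat, p, significance_stars(p)


def run_megs_experiment(
    ds: SimulatedDataset,
    arms: tuple[str, ...] = ("snp", "snp+asv", "snp+shuffled"),
    resolutions: tuple[str, ...] = ("asv",),
    treatments: tuple[str, ...] = ("all",),
    k: int = 5,
    n_repeats: int = 5,
    seed: int = 0,
) -> pd.DataFrame:
    """Full factorial of model arm x taxonomic resolution x treatment scope.

    Returns a tidy summary (one row per resolution x treatment x comparison)
    with mean accuracies, the relative improvement over the SNP-only arm and
    the paired-test significance, mirroring the resolution-grid and HN/LN
    experiment layout.
    """
    rows = []
    for level in resolutions:
        full = PredictionData.from_simulated(ds, level=level)
        for scope in treatments:
            data = full if scope == "all" else full.subset_treatment(scope)
            cv = cross_validate(data, arms=arms, k=k, n_repeats=n_repeats, seed=seed)
            r_base = cv.mean_accuracy("snp")
            for arm in arms:
                if arm == "snp":
                    continue
                stat, p, star = compare_models(cv, arm_a=arm, arm_b="snp")
                rows.append({
                    "resolution": level, "treatment": scope, "arm": arm,
                    "accuracy": cv.mean_accuracy(arm), "accuracy_snp": r_base,
                    "relative_improvement": relative_improvement(cv.mean_accuracy(arm), r_base),
                    "statistic": stat, "p_value": p, "stars": star,
                })
    return pd.DataFrame(rows)
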