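"""Post-fit effect-size analyses.

Given per-feature effect estimates from a fitted prediction model (SNP or ASV
BLUP coefficients), these operations rank features by effect magnitude,
test whether large effects concentrate in particular taxonomic groups
(Kruskal–Wallis), compare input annotations such as ASV heritability or
selection scores between the top fraction and the rest (Wilcoxon rank-sum),
and correlate single-ASV abundance with the phenotype within a treatment
scope (Spearman).
"""

from __future__ import annotations

import logging

import numpy as np
import pandas as pd
from scipy import stats

logger = logging.getLogger(__name__)

__all__ = [
    "EffectTable",
    "top_fraction",
    "effect_group_test",
    "annotation_compare",
    "abundance_phenotype_correlation",
    "consistent_top_features",
]


class EffectTable:
    """Per-feature effect estimates with optional taxonomy and context labels.

    ``effects`` is a Series indexed by feature id. ``taxonomy`` (optional) is
    indexed by feature id with a ``group`` column. ``context`` carries labels
    such as trait, date and treatment scope.
    """

    def __init__(self, effects: pd.Series, taxonomy: pd.DataFrame | None = None,
                 context: dict | None = None):
        if effects.empty:
            raise ValueError("empty effect table")
        if not np.isfinite(effects.to_numpy(dtype=float)).all():
            raise ValueError("non-finite effect values")
        if effects.index.duplicated().any():
            raise ValueError("duplicated feature ids")
        self.effects = effects.astype(float)
        self.taxonomy = taxonomy
        self.context = dict(context or {})

    def __len__(self) -> int:
        return len(self.effects)


def top_fraction(effects: EffectTable | pd.Series, fraction: float = 0.01) -> list:
    """Feature ids of the ceil(fraction * count) largest absolute effects.

    Boundary ties are broken deterministically by feature id (ascending), so
    the selection size is exact.
    """
    if not 0.0 < fraction <= 1.0:
        raise ValueError(f"fraction must be in (0, 1], got {fraction}")
    eff = effects.effects if isinstance(effects, EffectTable) else effects.astype(float)
    n_top = int(np.ceil(fraction * len(eff)))
    ranked = (
        pd.DataFrame({"mag": eff.abs(), "fid": eff.index.astype(str)}, index=eff.index)
        .sort_values(["mag", "fid"], ascending=[False, True], kind="mergesort")
    )
    return ranked.index[:n_top].tolist()


def effect_group_test(effects: EffectTable | pd.Series,
                      taxonomy: pd.DataFrame | None = None,
                      signed: bool = False) -> tuple[float, float]:
    """Kruskal–Wallis H test of effect size across taxonomic groups.

    By default the test is on absolute effects (the ranking scale); pass
    ``signed=True`` to test the signed values. Tie correction is applied; if
    every value is identical the statistic is 0 with p = 1.
    """
    if isinstance(effects, EffectTable):
        eff, tax = effects.effects, taxonomy if taxonomy is not None else effects.taxonomy
    else:
        eff, tax = effects.astype(float), taxonomy
    if tax is None:
        raise ValueError("taxonomy required")
    groups = tax.loc[eff.index, "group"]
    vals = eff if signed else eff.abs()
    samples = [vals[groups == g].to_numpy() for g in pd.unique(groups)]
    samples = [s for s in samples if len(s) > 0]
    if len(samples) < 2:
        raise ValueError("need at least two taxonomic groups")
    pooled = np.concatenate(samples)
    if np.all(pooled == pooled[0]):
        return 0.0, 1.0
    h, p = stats.kruskal(*samples)
    return float(h), float(p)


def annotation_compare(
    top_ids: list,
    rest_ids: list,
    annotations: pd.Series,
    alternative: str = "two-sided",
) -> tuple[float, float]:
    """Wilcoxon rank-sum (Mann–Whitney U) on an annotation between feature sets.

    ``annotations`` maps feature id to a score (e.g. ASV heritability or
    selection score supplied with the input data). Features with missing
    annotations are dropped with a logged count. Returns (U statistic, p).
    """
    if not top_ids or not rest_ids:
        raise ValueError("both feature sets must be non-empty")
    a = annotations.reindex(top_ids).dropna()
    b = annotations.reindex(rest_ids).dropna()
    n_dropped = (len(top_ids) - len(a)) + (len(rest_ids) - len(b))
    if n_dropped:
        logger.info("annotation_compare dropped %d features without annotation", n_dropped)
    if a.empty or b.empty:
        raise ValueError("a feature set has no annotated members")
    res = stats.mannwhitneyu(a, b, alternative=alternative)
    return float(res.statistic), float(res.pvalue)


def abundance_phenotype_correlation(
    asv_values: pd.Series,
    phenotype: pd.Series,
    design: pd.DataFrame | None = None,
    treatment: str | None = None,
) -> tuple[float, float]:
    """Spearman correlation of one ASV's abundance with the phenotype.

    When ``treatment`` is given, rows are restricted to that treatment scope
    via the design table. Requires at least three paired observations;
    constant input yields (NaN, NaN) with a warning.
    """
    idx = asv_values.index.intersection(phenotype.index)
    if treatment is not None:
        if design is None:
            raise ValueError("design required to scope by treatment")
        idx = idx.intersection(design.index[design["treatment"] == treatment])
    x = asv_values.loc[idx].to_numpy(dtype=float)
    y = phenotype.loc[idx].to_numpy(dtype=float)
    if len(idx) < 3:
        raise ValueError(f"need >=3 paired observations in scope, got {len(idx)}")
    if np.std(x) == 0 or np.std(y) == 0:
        logger.warning("constant input; Spearman correlation undefined")
        return np.nan, np.nan
    rho, p = stats.spearmanr(x, y)
    return float(rho), float(p)


def consistent_top_features(per_context_effects: dict[str, pd.Series],
                            fraction: float = 0.01) -> set:
    """Features in the top fraction in every context (e.g. every date)."""
    sets = [set(top_fraction(eff, fraction)) for eff in per_context_effects.values()]
    return set.intersection(*sets) if sets else set()
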