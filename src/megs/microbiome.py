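"""ASV table preparation: log relative abundance, taxonomic aggregation,
repeatability (heritability-like) scoring, and the shuffled-microbiome null.

Abundances are carried as natural-log relative abundances, the scale on which
the prediction models consume them. Taxonomy maps every ASV to exactly one
group and one class, groups nesting within classes, which supports the three
analysis resolutions (ASV / group / class).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

__all__ = [
    "MicrobiomeTable",
    "log_relative_abundance",
    "aggregate_taxa",
    "asv_repeatability",
    "shuffle_microbiome",
]


@dataclass
class MicrobiomeTable:
    """Observations x ASVs log relative abundances plus taxonomy.

    ``values`` is a DataFrame indexed by observation (plot) id with one column
    per ASV. ``taxonomy`` is indexed by asv_id with columns ``group`` and
    ``class_``; ``annotations`` optionally carries per-ASV heritability and
    selection scores supplied as inputs.
    """

    values: pd.DataFrame
    taxonomy: pd.DataFrame | None = None
    annotations: pd.DataFrame | None = None

    def __post_init__(self) -> None:
        if self.taxonomy is not None:
            missing = set(self.values.columns) - set(self.taxonomy.index)
            if missing:
                raise ValueError(f"ASVs without taxonomy: {sorted(missing)[:5]} ...")
            nest = self.taxonomy.groupby("group")["class_"].nunique()
            if (nest > 1).any():
                bad = nest[nest > 1].index.tolist()
                raise ValueError(f"groups spanning multiple classes: {bad[:5]}")

    @property
    def observation_ids(self) -> pd.Index:
        return self.values.index

    @property
    def asv_ids(self) -> pd.Index:
        return self.values.columns

    @property
    def matrix(self) -> np.ndarray:
        return self.values.to_numpy(dtype=float)


def log_relative_abundance(
    counts: pd.DataFrame,
    pseudocount: float | str = "half-min",
) -> MicrobiomeTable:
    """Natural-log relative abundance from a nonnegative count table.

    Each row is divided by its total; zeros are then replaced according to the
    pseudocount policy before taking logs, so the output is finite everywhere.

    ``pseudocount="half-min"`` replaces zero relative abundances with half the
    smallest nonzero relative abundance in the table, guaranteeing zeros map
    strictly below every observed nonzero value. A float value is used as-is
    as the replacement relative abundance.
    """
    X = counts.to_numpy(dtype=float)
    if (X < 0).any():
        raise ValueError("negative counts")
    totals = X.sum(axis=1)
    zero_rows = counts.index[totals == 0].tolist()
    if zero_rows:
        raise ValueError(f"all-zero observation rows: {zero_rows[:5]}")
    rel = X / totals[:, None]
    if pseudocount == "half-min":
        nz = rel[rel > 0]
        eps = nz.min() / 2.0
    else:
        eps = float(pseudocount)
        if eps <= 0 and (rel == 0).any():
            raise ValueError("zero counts present but pseudocount <= 0")
    rel = np.where(rel == 0, eps, rel)
    vals = pd.DataFrame(np.log(rel), index=counts.index, columns=counts.columns)
    return MicrobiomeTable(values=vals)


def aggregate_taxa(table: MicrobiomeTable, level: str = "asv") -> MicrobiomeTable:
    """Collapse ASV columns to a coarser taxonomic resolution.

    ``level`` is one of ``asv`` (identity), ``group`` or ``class``. ASVs
    sharing a label are combined by summing relative abundances (exp of the
    stored log values) before re-applying the log, so per-observation total
    relative abundance is conserved across resolutions.
    """
    if level == "asv":
        return table
    if table.taxonomy is None:
        raise ValueError("taxonomy required for aggregation")
    col = {"group": "group", "class": "class_"}.get(level)
    if col is None:
        raise ValueError(f"unknown level {level!r}")
    labels = table.taxonomy.loc[table.asv_ids, col]
    if labels.isna().any():
        raise ValueError(f"ASVs missing taxonomy at level {level!r}")
    rel = np.exp(table.matrix)
    out = {}
    for lab in pd.unique(labels):
        cols = np.nonzero((labels == lab).to_numpy())[0]
        out[lab] = np.log(rel[:, cols].sum(axis=1))
    vals = pd.DataFrame(out, index=table.observation_ids)
    tax = None
    if level == "group":
        g2c = table.taxonomy.drop_duplicates("group").set_index("group")["class_"]
        tax = pd.DataFrame({"group": vals.columns, "class_": g2c.loc[vals.columns].to_numpy()},
                           index=vals.columns)
    return MicrobiomeTable(values=vals, taxonomy=tax)


def asv_repeatability(table: MicrobiomeTable, design: pd.DataFrame) -> pd.DataFrame:
    """Per-ASV, per-treatment repeatability of log abundance across replicates.

    Fits a one-way genotype-random model per ASV within each treatment and
    reports the variance ratio sigma2_genotype / (sigma2_genotype +
    sigma2_residual) from the ANOVA method-of-moments estimator, clipped to
    [0, 1]. Treatments without genotype replication yield NaN.
    """
    out = {}
    for trt, sub in design.groupby("treatment", sort=True, observed=True):
        rows = table.values.loc[sub.index]
        g = sub["genotype"].to_numpy()
        groups = pd.unique(g)
        counts = pd.Series(g).value_counts()
        if (counts < 2).all():
            out[trt] = pd.Series(np.nan, index=table.asv_ids)
            logger.warning("treatment %r has no genotype replication", trt)
            continue
        X = rows.to_numpy(dtype=float)
        n, _ = X.shape
        k = len(groups)
        idx = {gg: np.nonzero(g == gg)[0] for gg in groups}
        gm = X.mean(axis=0)
        ssb = np.zeros(X.shape[1])
        ssw = np.zeros(X.shape[1])
        for gg in groups:
            xi = X[idx[gg]]
            mi = xi.mean(axis=0)
            ssb += len(idx[gg]) * (mi - gm) ** 2
            ssw += ((xi - mi) ** 2).sum(axis=0)
        msb = ssb / (k - 1)
        msw = ssw / max(n - k, 1)
        # unbalanced one-way ANOVA effective replicate number
        ni = np.array([len(idx[gg]) for gg in groups], dtype=float)
        n0 = (n - (ni**2).sum() / n) / (k - 1)
        sg = (msb - msw) / n0
        with np.errstate(divide="ignore", invalid="ignore"):
            rep = sg / (sg + msw)
        out[trt] = pd.Series(np.clip(np.nan_to_num(rep, nan=0.0), 0.0, 1.0),
                             index=table.asv_ids)
    return pd.DataFrame(out)


def shuffle_microbiome(
    table: MicrobiomeTable,
    design: pd.DataFrame,
    strategy: str = "within_treatment",
    seed: int = 0,
) -> MicrobiomeTable:
    """Permute ASV rows within design groups, leaving phenotype/design intact.

    ``strategy`` is ``within_treatment`` or ``within_treatment_quadrant``; the
    corresponding design columns define the grouping, and rows are permuted
    uniformly at random (without replacement) within each group, so each
    group's row multiset is exactly preserved. Singleton groups stay fixed.
    """
    keys = {"within_treatment": ["treatment"],
            "within_treatment_quadrant": ["treatment", "quadrant"]}.get(strategy)
    if keys is None:
        raise ValueError(f"unknown strategy {strategy!r}")
    for kcol in keys:
        if kcol not in design.columns:
            raise ValueError(f"design lacks grouping column {kcol!r}")
    rng = np.random.default_rng(seed)
    vals = table.values.loc[design.index].to_numpy(dtype=float).copy()
    pos = {obs: i for i, obs in enumerate(design.index)}
    for _, sub in design.groupby(keys, sort=True, observed=True):
        rows = np.array([pos[o] for o in sub.index])
        if len(rows) == 1:
            logger.info("singleton shuffle group left fixed")
            continue
        vals[rows] = vals[rng.permutation(rows)]
    out = pd.DataFrame(vals, index=design.index, columns=table.asv_ids)
    return MicrobiomeTable(values=out, taxonomy=table.taxonomy,
                           annotations=table.annotations)
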