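"""Mixed-model estimation core for microbiome-enabled genomic selection.

Three model families are provided:

* single-variance-component ridge/BLUP models (RR-BLUP on markers or ASVs,
  G-BLUP through an additive relationship kernel), with REML estimation of
  the variance ratio by spectral decomposition (EMMA-style one-dimensional
  search);
* the joint SNP+ASV predictor: two independent random components whose
  per-column variances are plugged in from the two single-component fits,
  solved through the equivalent n x n kernel system (or Henderson's
  column-side mixed-model equations when columns are few);
* genotype-level G-BLUP with covariance A * sigma2_g, optionally augmented
  with an identity-covariance random component over taxonomic-group
  abundances.

All models take a dense fixed-effect design built by :class:`FixedCoder`
(treatment contrasts, first level as reference, intercept always present).
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import linalg, optimize

from .genotypes import Grm

logger = logging.getLogger(__name__)

__all__ = [
    "FixedCoder",
    "ModelFit",
    "reml_single_component",
    "estimate_asv_variance",
    "fit_two_component",
    "fit_gblup_genotype",
    "predict",
]

DESIGN_FACTORS = ("treatment", "block", "splitplot", "splitplot_block")


class FixedCoder:
    """Dummy-codes design factors (first level = reference) plus covariates.

    Factor levels are frozen at fit time; transforming rows with an unseen
    level maps them to the reference level with a warning.
    """

    def __init__(self, factors: tuple[str, ...] = DESIGN_FACTORS,
                 covariates: tuple[str, ...] = ()):
        self.factors = tuple(factors)
        self.covariates = tuple(covariates)
        self.levels_: dict[str, list] = {}
        self.columns_: list[str] | None = None

    def fit(self, design: pd.DataFrame, extra: pd.DataFrame | None = None) -> np.ndarray:
        self.levels_ = {f: sorted(pd.unique(design[f]).tolist()) for f in self.factors}
        X, cols = self._build(design, extra)
        self.columns_ = cols
        return X

    def transform(self, design: pd.DataFrame, extra: pd.DataFrame | None = None) -> np.ndarray:
        if self.columns_ is None:
            raise RuntimeError("FixedCoder not fitted")
        X, _ = self._build(design, extra)
        return X

    def _build(self, design: pd.DataFrame, extra: pd.DataFrame | None):
        n = len(design)
        cols: list[str] = ["intercept"]
        parts = [np.ones((n, 1))]
        for f in self.factors:
            levels = self.levels_[f]
            vals = design[f]
            unseen = set(pd.unique(vals)) - set(levels)
            if unseen:
                warnings.warn(f"unseen levels {sorted(unseen)} in factor {f!r}; "
                              "mapped to reference")
            for lev in levels[1:]:
                parts.append((vals == lev).to_numpy(dtype=float)[:, None])
                cols.append(f"{f}[{lev}]")
        if extra is not None:
            arr = extra.loc[design.index] if extra.index.size else extra
            parts.append(np.asarray(arr, dtype=float))
            cols.extend(str(c) for c in extra.columns)
        for c in self.covariates:
            parts.append(design[c].to_numpy(dtype=float)[:, None])
            cols.append(c)
        return np.hstack(parts), cols


@dataclass
class ModelFit:
    """Fitted mixed model: fixed coefficients, BLUPs, variance components."""

    fixed_effects: pd.Series
    random_effects: dict[str, pd.Series]
    variance_components: dict[str, float]
    meta: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        for name, val in self.variance_components.items():
            if val < 0 and not np.isclose(val, 0.0):
                raise ValueError(f"negative variance component {name}={val}")


def _full_rank_basis(X: np.ndarray, cols: list[str]) -> tuple[np.ndarray, list[str]]:
    """Drop aliased columns so X has full column rank (pivoted QR)."""
    if X.shape[1] == 0:
        return X, cols
    _, R, piv = linalg.qr(X, mode="economic", pivoting=True)
    diag = np.abs(np.diag(R))
    tol = diag.max() * max(X.shape) * np.finfo(float).eps if diag.size else 0.0
    rank = int((diag > tol).sum())
    keep = np.sort(piv[:rank])
    if rank < X.shape[1]:
        dropped = [cols[i] for i in np.sort(piv[rank:])]
        logger.info("aliased fixed-effect columns dropped: %s", dropped)
    return X[:, keep], [cols[i] for i in keep]


def _reml_profile(y: np.ndarray, X: np.ndarray, G: np.ndarray):
    """Spectral pieces for the 1-D restricted likelihood in the variance ratio."""
    n = len(y)
    # orthonormal basis of the complement of col(X)
    if X.shape[1]:
        U, s, _ = linalg.svd(X, full_matrices=True)
        rank = int((s > (s.max() * max(X.shape) * np.finfo(float).eps)).sum()) if s.size else 0
        Uc = U[:, rank:]
    else:
        Uc, rank = np.eye(n), 0
    T = Uc.T @ G @ Uc
    xi, V = linalg.eigh((T + T.T) / 2.0)
    xi = np.clip(xi, 0.0, None)
    eta = V.T @ (Uc.T @ y)
    return xi, eta, n - rank


def _neg_restricted_ll(log10_ratio: float, xi: np.ndarray, eta2: np.ndarray, df: int) -> float:
    lam = 10.0 ** log10_ratio
    w = xi * lam + 1.0
    s = float(np.sum(eta2 / w))
    return df * np.log(s) + float(np.sum(np.log(w)))


def reml_single_component(
    y: np.ndarray | pd.Series,
    X_fixed: np.ndarray,
    Z_random: np.ndarray | None = None,
    K: Grm | np.ndarray | None = None,
    *,
    G: np.ndarray | None = None,
    fixed_names: list[str] | None = None,
    effect_name: str = "u",
    effect_ids: list | None = None,
    bounds: tuple[float, float] = (-10.0, 10.0),
    tol: float = 1e-8,
) -> tuple[float, float, ModelFit]:
    """REML fit of y = X b + Z u + e with u ~ N(0, K sigma2_u), e ~ N(0, sigma2_e I).

    The variance ratio lambda = sigma2_u / sigma2_e is profiled on a spectral
    decomposition of the random-effect covariance restricted to the fixed-
    effect complement, and optimized on log10(lambda) over ``bounds``.
    Returns (sigma2_u, sigma2_e, fit); the fit carries GLS fixed effects and
    the BLUP of u at the optimum. ``K=None`` means identity (RR-BLUP); a
    precomputed covariance ``G = Z K Z'`` may be passed directly.
    """
    y = np.asarray(y, dtype=float).ravel()
    if not np.isfinite(y).all():
        raise ValueError("non-finite phenotype values")
    n = len(y)
    X = np.asarray(X_fixed, dtype=float)
    names = fixed_names if fixed_names is not None else [f"x{i}" for i in range(X.shape[1])]
    X, names = _full_rank_basis(X, list(names))
    if n <= X.shape[1]:
        raise ValueError("need n > rank(X_fixed)")

    Kmat = K.matrix if isinstance(K, Grm) else K
    if G is None:
        if Z_random is None:
            raise ValueError("provide Z_random or G")
        Z = np.asarray(Z_random, dtype=float)
        G = Z @ (Kmat @ Z.T) if Kmat is not None else Z @ Z.T
    G = np.asarray(G, dtype=float)

    xi, eta, df = _reml_profile(y, X, G)
    eta2 = eta**2
    res = optimize.minimize_scalar(
        _neg_restricted_ll, bounds=bounds, args=(xi, eta2, df),
        method="bounded", options={"xatol": tol},
    )
    log10_lam = float(res.x)
    # prefer the boundary when the criterion is flat down to it (null component)
    lo_val = _neg_restricted_ll(bounds[0], xi, eta2, df)
    if lo_val <= res.fun + 1e-10:
        log10_lam = bounds[0]
    lam = 10.0 ** log10_lam
    w = xi * lam + 1.0
    sigma2_e = float(np.sum(eta2 / w) / df)
    sigma2_u = lam * sigma2_e
    at_lower = log10_lam <= bounds[0] + 1e-6
    if at_lower:
        sigma2_u = 0.0

    C = lam * G + np.eye(n)
    cf = linalg.cho_factor(C, lower=True)
    Ci_y = linalg.cho_solve(cf, y)
    Ci_X = linalg.cho_solve(cf, X)
    XtCiX = X.T @ Ci_X
    beta = linalg.solve(XtCiX, X.T @ Ci_y, assume_a="pos")
    resid = y - X @ beta
    Ci_r = linalg.cho_solve(cf, resid)

    random_effects: dict[str, pd.Series] = {}
    if Z_random is not None:
        Z = np.asarray(Z_random, dtype=float)
        u = lam * (Kmat @ (Z.T @ Ci_r)) if Kmat is not None else lam * (Z.T @ Ci_r)
        ids = effect_ids if effect_ids is not None else list(range(Z.shape[1]))
        random_effects[effect_name] = pd.Series(u, index=ids)

    fit = ModelFit(
        fixed_effects=pd.Series(beta, index=names),
        random_effects=random_effects,
        variance_components={"sigma2_u": sigma2_u, "sigma2_e": sigma2_e},
        meta={
            "method": "reml-spectral",
            "n": n,
            "rank_X": X.shape[1],
            "log10_ratio": log10_lam,
            "at_boundary": bool(at_lower),
            "reml_neg2ll_profile": float(res.fun),
        },
    )
    return sigma2_u, sigma2_e, fit


def estimate_asv_variance(
    y: np.ndarray | pd.Series,
    design: pd.DataFrame,
    pcs: pd.DataFrame,
    M: np.ndarray,
    factors: tuple[str, ...] = DESIGN_FACTORS,
) -> tuple[float, float, ModelFit]:
    """Per-ASV effect variance: ASVs random, design factors + genotype PCs fixed.

    The PC covariates control the genomic background so that sigma2_gamma
    reflects microbiome signal rather than population structure. Returns
    (sigma2_gamma, sigma2_e, fit).
    """
    pcs_plot = pcs.loc[design["genotype"]].set_axis(design.index)
    coder = FixedCoder(factors=factors)
    X = coder.fit(design, extra=pcs_plot)
    s_g, s_e, fit = reml_single_component(
        y, X, Z_random=M, fixed_names=coder.columns_, effect_name="asv",
    )
    fit.meta["coder"] = coder
    return s_g, s_e, fit


def _solve_kernel_system(y, X, names, comps):
    """GLS + BLUPs through the n x n system V = sum_c v_c G_c + v_e I."""
    n = len(y)
    V = np.eye(n) * comps["_sigma2_e"]
    for name, (G, _backmap, _ids, var) in comps["components"].items():
        V += var * G
    try:
        cf = linalg.cho_factor(V, lower=True)
    except linalg.LinAlgError as err:
        raise ValueError(f"singular covariance (cond={np.linalg.cond(V):.3g})") from err
    Ci_X = linalg.cho_solve(cf, X)
    beta = linalg.solve(X.T @ Ci_X, X.T @ linalg.cho_solve(cf, y), assume_a="pos")
    r = y - X @ beta
    Ci_r = linalg.cho_solve(cf, r)
    randoms = {
        name: pd.Series(var * backmap(Ci_r), index=ids)
        for name, (G, backmap, ids, var) in comps["components"].items()
    }
    return pd.Series(beta, index=names), randoms


def fit_two_component(
    y: np.ndarray | pd.Series,
    X_fixed: np.ndarray,
    Z_snp: np.ndarray,
    M_asv: np.ndarray,
    sigma2_snp: float,
    sigma2_asv: float,
    sigma2_e: float,
    *,
    fixed_names: list[str] | None = None,
    snp_ids: list | None = None,
    asv_ids: list | None = None,
    solver: str = "auto",
) -> ModelFit:
    """Joint SNP+ASV BLUP with plugged-in per-column variances.

    Solves Henderson's equations for two independent random components; with
    many more columns than rows this is done through the equivalent n x n
    kernel system, otherwise through the column-side normal equations. The
    solution equals generalized ridge regression with per-block penalties
    sigma2_e / sigma2_snp and sigma2_e / sigma2_asv.
    """
    y = np.asarray(y, dtype=float).ravel()
    X = np.asarray(X_fixed, dtype=float)
    names = fixed_names if fixed_names is not None else [f"x{i}" for i in range(X.shape[1])]
    X, names = _full_rank_basis(X, list(names))
    Z = np.asarray(Z_snp, dtype=float)
    M = np.asarray(M_asv, dtype=float)
    if sigma2_e <= 0:
        raise ValueError("residual variance must be strictly positive")
    n, q = Z.shape
    p_asv = M.shape[1]
    if solver == "auto":
        solver = "kernel" if q + p_asv > n else "columns"
    sid = snp_ids if snp_ids is not None else list(range(q))
    aid = asv_ids if asv_ids is not None else list(range(p_asv))

    if solver == "kernel":
        comps = {
            "_sigma2_e": sigma2_e,
            "components": {
                "snp": (Z @ Z.T, lambda v: Z.T @ v, sid, sigma2_snp),
                "asv": (M @ M.T, lambda v: M.T @ v, aid, sigma2_asv),
            },
        }
        beta, randoms = _solve_kernel_system(y, X, names, comps)
    elif solver == "columns":
        W = np.hstack([Z, M])
        lam = np.concatenate([
            np.full(q, sigma2_e / sigma2_snp if sigma2_snp > 0 else np.inf),
            np.full(p_asv, sigma2_e / sigma2_asv if sigma2_asv > 0 else np.inf),
        ])
        if np.isinf(lam).any():
            raise ValueError("zero plug-in variance collapses a component; drop it instead")
        p = X.shape[1]
        A = np.empty((p + q + p_asv, p + q + p_asv))
        A[:p, :p] = X.T @ X
        A[:p, p:] = X.T @ W
        A[p:, :p] = W.T @ X
        A[p:, p:] = W.T @ W + np.diag(lam)
        rhs = np.concatenate([X.T @ y, W.T @ y])
        try:
            sol = linalg.solve(A, rhs, assume_a="sym")
        except linalg.LinAlgError as err:
            raise ValueError(f"singular MME (cond={np.linalg.cond(A):.3g})") from err
        beta = pd.Series(sol[:p], index=names)
        randoms = {
            "snp": pd.Series(sol[p:p + q], index=sid),
            "asv": pd.Series(sol[p + q:], index=aid),
        }
    else:
        raise ValueError(f"unknown solver {solver!r}")

    return ModelFit(
        fixed_effects=beta,
        random_effects=randoms,
        variance_components={
            "sigma2_snp": sigma2_snp, "sigma2_asv": sigma2_asv, "sigma2_e": sigma2_e,
        },
        meta={"method": f"two-component-{solver}", "n": n,
              "n_snp_cols": q, "n_asv_cols": p_asv},
    )


def fit_gblup_genotype(
    y: np.ndarray | pd.Series,
    design: pd.DataFrame,
    grm: Grm,
    asv_groups: pd.DataFrame | None = None,
    factors: tuple[str, ...] = ("block", "splitplot", "splitplot_block"),
) -> ModelFit:
    """Genotype-level G-BLUP: g ~ N(0, A sigma2_g), design factors fixed.

    When ``asv_groups`` (observations x taxonomic-group log abundances) is
    supplied, a second identity-covariance random component over the group
    abundances is added, with its variance plugged in from a single-component
    fit (groups random, design factors fixed). Returns per-genotype BLUPs.
    """
    y = np.asarray(y, dtype=float).ravel()
    genos = list(grm.individual_ids)
    pos = {g: i for i, g in enumerate(genos)}
    absent = sorted(set(design["genotype"]) - set(genos))
    if absent:
        raise ValueError(f"genotypes absent from GRM: {absent[:10]}")
    n = len(design)
    W = np.zeros((n, len(genos)))
    W[np.arange(n), [pos[g] for g in design["genotype"]]] = 1.0
    use = [f for f in factors if design[f].nunique() > 1]
    coder = FixedCoder(factors=tuple(use))
    X = coder.fit(design)
    G_geno = W @ grm.matrix @ W.T

    s_g, s_e, base = reml_single_component(
        y, X, Z_random=W, K=grm, G=G_geno,
        fixed_names=coder.columns_, effect_name="genotype", effect_ids=genos,
    )
    if asv_groups is None:
        base.meta["coder"] = coder
        base.variance_components = {"sigma2_g": s_g, "sigma2_e": s_e}
        return base

    Mg = asv_groups.loc[design.index].to_numpy(dtype=float)
    s_gamma, _, _ = reml_single_component(
        y, X, Z_random=Mg, fixed_names=coder.columns_, effect_name="group",
    )
    comps = {
        "_sigma2_e": s_e,
        "components": {
            "genotype": (G_geno, lambda v: grm.matrix @ (W.T @ v), genos, s_g),
            "group": (Mg @ Mg.T, lambda v: Mg.T @ v, list(asv_groups.columns), s_gamma),
        },
    }
    Xr, names = _full_rank_basis(X, list(coder.columns_))
    beta, randoms = _solve_kernel_system(y, Xr, names, comps)
    return ModelFit(
        fixed_effects=beta,
        random_effects=randoms,
        variance_components={"sigma2_g": s_g, "sigma2_group": s_gamma, "sigma2_e": s_e},
        meta={"method": "gblup+groups", "n": n, "coder": coder},
    )


def predict(
    fit: ModelFit,
    X_new: np.ndarray,
    **component_matrices: np.ndarray,
) -> np.ndarray:
    """Linear predictor X b + sum_c Z_c u_c for new rows.

    ``component_matrices`` maps random-effect names in the fit to new design
    matrices whose columns align with the stored BLUP vectors.
    """
    X_new = np.asarray(X_new, dtype=float)
    if X_new.shape[1] != len(fit.fixed_effects):
        raise ValueError(
            f"fixed design has {X_new.shape[1]} columns, fit expects {len(fit.fixed_effects)}")
    yhat = X_new @ fit.fixed_effects.to_numpy()
    for name, mat in component_matrices.items():
        if name not in fit.random_effects:
            raise ValueError(f"fit has no random component {name!r}")
        u = fit.random_effects[name].to_numpy()
        mat = np.asarray(mat, dtype=float)
        if mat.shape[1] != len(u):
            raise ValueError(f"component {name!r}: {mat.shape[1]} columns vs {len(u)} BLUPs")
        yhat = yhat + mat @ u
    return yhat
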