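"""Genome-wide mediation scan: ASVs as intermediates between SNPs and phenotype.

Two models per the mediation framework:

* mediator model  M_j = Q A_j + Z B_j + e_j   (per ASV j)
* outcome model   y   = Q v + Z a + M c + e

with Q the confounder matrix (genotype principal components plus the design
factors), fixed-effect confounder coefficients, and ridge-shrunk
(random-effect) SNP and ASV coefficients. The genetic path is tested with a
variance-component score statistic on the confounder-residualized abundance;
the phenotype path with the shrunken ASV coefficient magnitude. Both are
calibrated by within-treatment permutations, studentized per ASV and pooled
across ASVs to give p-value resolution below the per-ASV permutation floor.
An ASV is called a mediator by the joint-significance (MaxP) rule — the
maximum of the two path p-values — screened at a Benjamini–Hochberg FDR.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import linalg, stats
from scipy.optimize import minimize_scalar

from .mixed_models import (
    FixedCoder,
    _full_rank_basis,
    _neg_restricted_ll,
    reml_single_component,
)

logger = logging.getLogger(__name__)

__all__ = [
    "MediationResult",
    "build_confounder_matrix",
    "fit_mediator_model",
    "fit_outcome_model",
    "mediation_scan",
]


def build_confounder_matrix(
    design: pd.DataFrame,
    pcs: pd.DataFrame | None,
    factors: tuple[str, ...] = ("treatment", "block", "splitplot", "splitplot_block"),
) -> tuple[np.ndarray, list[str]]:
    """Confounder matrix Q: intercept + genotype PCs + dummy-coded design factors.

    ``pcs`` is indexed by genotype and expanded to plot level through the
    design's genotype column (pass None to drop the PC block). Aliased
    columns are removed so Q has full column rank.
    """
    use = tuple(f for f in factors if f in design.columns and design[f].nunique() > 1)
    coder = FixedCoder(factors=use)
    extra = None
    if pcs is not None and pcs.shape[1] > 0:
        extra = pcs.loc[design["genotype"]].set_axis(design.index)
    Q = coder.fit(design, extra=extra)
    Q, names = _full_rank_basis(Q, list(coder.columns_))
    return Q, names


def _projector(Q: np.ndarray) -> np.ndarray:
    """Orthogonal projector onto the complement of col(Q)."""
    Uq, _ = np.linalg.qr(Q)
    return np.eye(Q.shape[0]) - Uq @ Uq.T


def _grouped_permutations(groups: np.ndarray | None, n: int, B: int,
                          rng: np.random.Generator) -> np.ndarray:
    """B row permutations restricted to the given grouping (None = free)."""
    perms = np.empty((B, n), dtype=int)
    base = np.arange(n)
    if groups is None:
        for b in range(B):
            perms[b] = rng.permutation(n)
        return perms
    groups = np.asarray(groups)
    idx_by = {g: np.nonzero(groups == g)[0] for g in pd.unique(groups)}
    for b in range(B):
        p = base.copy()
        for rows in idx_by.values():
            p[rows] = rows[rng.permutation(len(rows))]
        perms[b] = p
    return perms


def _score_stat(R: np.ndarray, G: np.ndarray) -> np.ndarray:
    """Columnwise variance-component score statistic r'Gr / r'r."""
    num = np.einsum("ij,ij->j", R, G @ R)
    den = np.einsum("ij,ij->j", R, R)
    with np.errstate(divide="ignore", invalid="ignore"):
        return np.where(den > 0, num / den, 0.0)


def _pooled_pvalues(obs: np.ndarray, null: np.ndarray) -> np.ndarray:
    """Studentize each column's statistic by its own permutation null, then
    pool the studentized null draws across columns for high-resolution p-values.

    ``null`` has shape (B, m). Returns upper-tail p-values of length m.
    """
    mu = null.mean(axis=0)
    sd = null.std(axis=0, ddof=1)
    sd = np.where(sd > 0, sd, 1.0)
    z_obs = (obs - mu) / sd
    z_null = ((null - mu) / sd).ravel()
    z_null.sort()
    # p = (1 + #{null >= obs}) / (1 + total)
    n_ge = len(z_null) - np.searchsorted(z_null, z_obs, side="left")
    return (1.0 + n_ge) / (1.0 + len(z_null))


@dataclass
class MediatorFit:
    A_j: pd.Series
    B_j: np.ndarray
    sigma2_j: float
    genetic_share: float
    p_genetic: float


def fit_mediator_model(
    m_j: np.ndarray | pd.Series,
    Q: np.ndarray,
    Z: np.ndarray,
    n_permutations: int = 200,
    seed: int = 0,
    groups: np.ndarray | None = None,
    q_names: list[str] | None = None,
) -> MediatorFit:
    """Fit M_j = Q A_j + Z B_j + e_j for one ASV.

    A_j by GLS at the REML optimum, B_j as ridge-shrunk SNP BLUPs, and the
    genetic-path p-value from a permutation-calibrated score test of
    H0: Var(Z B_j) = 0 (rows of the residualized abundance permuted within
    ``groups``). ``genetic_share`` is the genotype-attributable fraction of
    the abundance variance implied by the REML components.
    """
    m = np.asarray(m_j, dtype=float).ravel()
    if np.std(m) == 0:
        raise ValueError("constant ASV abundance; mediator model undefined")
    s_u, s_e, fit = reml_single_component(
        m, Q, Z_random=Z, fixed_names=q_names, effect_name="snp")
    G = Z @ Z.T
    gvar = s_u * float(np.mean(np.diag(G)))
    share = gvar / (gvar + s_e) if (gvar + s_e) > 0 else 0.0

    P = _projector(Q)
    r = P @ m
    t_obs = _score_stat(r[:, None], G)[0]
    rng = np.random.default_rng(seed)
    perms = _grouped_permutations(groups, len(m), n_permutations, rng)
    null = np.array([_score_stat((P @ m[p])[:, None], G)[0] for p in perms])
    p_gen = float((1 + np.sum(null >= t_obs)) / (1 + len(null)))
    return MediatorFit(
        A_j=fit.fixed_effects,
        B_j=fit.random_effects["snp"].to_numpy(),
        sigma2_j=s_e,
        genetic_share=share,
        p_genetic=p_gen,
    )


@dataclass
class OutcomeFit:
    v: pd.Series
    a: np.ndarray
    c: pd.Series
    sigma2: float
    sigma2_a: float
    sigma2_c: float
    p_phenotype: pd.Series | None = None


def fit_outcome_model(
    y: np.ndarray | pd.Series,
    Q: np.ndarray,
    Z: np.ndarray,
    M: np.ndarray,
    n_permutations: int = 200,
    seed: int = 0,
    groups: np.ndarray | None = None,
    asv_ids: list | None = None,
    q_names: list[str] | None = None,
) -> OutcomeFit:
    """Fit y = Q v + Z a + M c + e with plug-in variances.

    sigma2_a comes from the SNP-only single-component REML fit (which also
    supplies the residual variance), sigma2_c from the ASV-only fit, exactly
    as in the joint prediction model. Per-ASV phenotype-path p-values are
    permutation-calibrated on |c_j| with M's rows permuted within ``groups``
    (studentized and pooled across ASVs).
    """
    y = np.asarray(y, dtype=float).ravel()
    n = len(y)
    aid = asv_ids if asv_ids is not None else list(range(M.shape[1]))
    s_a, s_e, _ = reml_single_component(y, Q, Z_random=Z, fixed_names=q_names)
    s_c, _, _ = reml_single_component(y, Q, Z_random=M, fixed_names=q_names)
    s_a = max(s_a, 1e-12)
    s_c = max(s_c, 1e-12)
    G_z = Z @ Z.T

    def _solve(Mx: np.ndarray):
        V = s_a * G_z + s_c * (Mx @ Mx.T) + s_e * np.eye(n)
        cf = linalg.cho_factor(V, lower=True)
        Ci_Q = linalg.cho_solve(cf, Q)
        beta = linalg.solve(Q.T @ Ci_Q, Q.T @ linalg.cho_solve(cf, y), assume_a="pos")
        r = y - Q @ beta
        Ci_r = linalg.cho_solve(cf, r)
        return beta, s_a * (Z.T @ Ci_r), s_c * (Mx.T @ Ci_r)

    v, a, c = _solve(M)
    p_phe = None
    if n_permutations > 0:
        rng = np.random.default_rng(seed)
        perms = _grouped_permutations(groups, n, n_permutations, rng)
        null = np.empty((n_permutations, M.shape[1]))
        for b, p in enumerate(perms):
            _, _, c_b = _solve(M[p])
            null[b] = np.abs(c_b)
        p_phe = pd.Series(_pooled_pvalues(np.abs(c), null), index=aid)
    qn = q_names if q_names is not None else [f"q{i}" for i in range(Q.shape[1])]
    return OutcomeFit(v=pd.Series(v, index=qn), a=a, c=pd.Series(c, index=aid),
                      sigma2=s_e, sigma2_a=s_a, sigma2_c=s_c, p_phenotype=p_phe)


@dataclass
class MediationResult:
    """Ranked per-ASV mediation table plus the shared outcome-model pieces."""

    table: pd.DataFrame  # genetic_share, p_genetic, c_estimate, p_phenotype, p_joint, q_value, mediator
    outcome: OutcomeFit
    fdr: float
    meta: dict = field(default_factory=dict)

    @property
    def mediators(self) -> list:
        return self.table.index[self.table["mediator"]].tolist()


def mediation_scan(
    y: pd.Series | np.ndarray,
    design: pd.DataFrame,
    pcs: pd.DataFrame,
    Z: np.ndarray,
    M: np.ndarray,
    asv_ids: list | None = None,
    fdr: float = 0.05,
    n_permutations: int = 200,
    seed: int = 0,
) -> MediationResult:
    """Run the mediator model per ASV and the outcome model once; call mediators.

    Both path tests share one set of within-treatment row permutations. Joint
    p-value = max(p_genetic, p_phenotype) (joint-significance rule), screened
    at Benjamini–Hochberg FDR ``fdr``. Returns the per-ASV table ranked by
    joint p-value; ASVs whose mediator model is degenerate (constant
    abundance) are kept with status "skipped".
    """
    y = np.asarray(y, dtype=float).ravel()
    m_count = M.shape[1]
    aid = list(asv_ids) if asv_ids is not None else list(range(m_count))
    groups = design["treatment"].to_numpy() if "treatment" in design.columns else None
    Q, q_names = build_confounder_matrix(design, pcs)
    n = len(y)

    ok = np.std(M, axis=0) > 0
    if not ok.all():
        logger.warning("skipping %d constant ASVs", int((~ok).sum()))

    # --- genetic path: score statistic on residualized abundances ---
    P = _projector(Q)
    G = Z @ Z.T
    R = P @ M
    t_obs = _score_stat(R, G)
    rng = np.random.default_rng(seed)
    perms = _grouped_permutations(groups, n, n_permutations, rng)
    null_t = np.empty((n_permutations, m_count))
    for b, p in enumerate(perms):
        null_t[b] = _score_stat(P @ M[p], G)
    p_gen = _pooled_pvalues(t_obs, null_t)

    # --- per-ASV REML genetic variance share via the shared spectral basis ---
    s_share = np.zeros(m_count)
    Uc = linalg.null_space(Q.T)
    T = Uc.T @ G @ Uc
    xi, V = linalg.eigh((T + T.T) / 2.0)
    xi = np.clip(xi, 0.0, None)
    H = V.T @ Uc.T  # (n - rank) x n rotation shared by every ASV
    mean_diag = float(np.mean(np.diag(G)))
    df = H.shape[0]
    eta_all = H @ M
    for j in range(m_count):
        if not ok[j]:
            continue
        eta2 = eta_all[:, j] ** 2
        res = minimize_scalar(_neg_restricted_ll, bounds=(-10, 10), args=(xi, eta2, df),
                              method="bounded", options={"xatol": 1e-8})
        lam = 10.0 ** float(res.x)
        if _neg_restricted_ll(-10, xi, eta2, df) <= res.fun + 1e-10:
            lam = 0.0
        s_e = float(np.sum(eta2 / (xi * lam + 1.0)) / df)
        gvar = lam * s_e * mean_diag
        s_share[j] = gvar / (gvar + s_e) if (gvar + s_e) > 0 else 0.0

    # --- phenotype path: outcome model with the same permutations ---
    outcome = fit_outcome_model(y, Q, Z, M, n_permutations=n_permutations,
                                seed=seed, groups=groups, asv_ids=aid,
                                q_names=q_names)
    p_phe = outcome.p_phenotype.to_numpy()

    p_joint = np.maximum(p_gen, p_phe)
    p_joint = np.where(ok, p_joint, np.nan)
    valid = ~np.isnan(p_joint)
    qv = np.full(m_count, np.nan)
    qv[valid] = stats.false_discovery_control(p_joint[valid], method="bh")
    table = pd.DataFrame(
        {
            "genetic_share": s_share,
            "p_genetic": p_gen,
            "c_estimate": outcome.c.to_numpy(),
            "p_phenotype": p_phe,
            "p_joint": p_joint,
            "q_value": qv,
            "mediator": np.where(valid, qv <= fdr, False).astype(bool),
            "status": np.where(ok, "ok", "skipped"),
        },
        index=pd.Index(aid, name="asv_id"),
    ).sort_values("p_joint")
    return MediationResult(table=table, outcome=outcome, fdr=fdr,
                           meta={"n_permutations": n_permutations, "seed": seed,
                                 "q_names": q_names, "n": n})
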