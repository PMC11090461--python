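"""Genotype containers, QC, LD pruning, relationship matrices and principal components.

The pipeline mirrors the standard genomic-selection preprocessing order:
variant filtering (missingness, minor allele frequency), window-based LD
pruning on pairwise r-squared, uniform marker subsampling, then the additive
(VanRaden) relationship matrix and genotype principal components used as
population-structure covariates downstream.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

__all__ = [
    "GenotypeMatrix",
    "Grm",
    "filter_variants",
    "ld_prune",
    "sample_markers",
    "additive_relationship",
    "genotype_pcs",
]


@dataclass
class GenotypeMatrix:
    """Individuals x markers dosage matrix with marker coordinates.

    Dosages are additive allele counts in {0, 1, 2}; missing calls are
    ``np.nan``. Marker positions are 1-based physical coordinates,
    non-decreasing within each chromosome.
    """

    individual_ids: list[str]
    marker_ids: list[str]
    chrom: np.ndarray
    pos_bp: np.ndarray
    dosages: np.ndarray

    def __post_init__(self) -> None:
        self.chrom = np.asarray(self.chrom)
        self.pos_bp = np.asarray(self.pos_bp, dtype=np.int64)
        self.dosages = np.asarray(self.dosages, dtype=float)
        n, m = self.dosages.shape
        if n != len(self.individual_ids):
            raise ValueError("dosage rows do not match individual_ids")
        if m != len(self.marker_ids) or m != len(self.chrom) or m != len(self.pos_bp):
            raise ValueError("dosage columns do not match marker metadata")
        if len(set(self.individual_ids)) != n:
            raise ValueError("duplicated individual identifiers")
        if len(set(self.marker_ids)) != m:
            raise ValueError("duplicated marker identifiers")
        valid = np.isnan(self.dosages) | np.isin(self.dosages, (0.0, 1.0, 2.0))
        if not valid.all():
            raise ValueError("dosage values must be in {0, 1, 2} or missing")
        for c in np.unique(self.chrom):
            p = self.pos_bp[self.chrom == c]
            if np.any(np.diff(p) < 0):
                raise ValueError(f"positions not sorted within chromosome {c!r}")

    @property
    def n_individuals(self) -> int:
        return self.dosages.shape[0]

    @property
    def n_markers(self) -> int:
        return self.dosages.shape[1]

    def take_markers(self, idx: np.ndarray) -> "GenotypeMatrix":
        idx = np.asarray(idx, dtype=int)
        return GenotypeMatrix(
            individual_ids=list(self.individual_ids),
            marker_ids=[self.marker_ids[i] for i in idx],
            chrom=self.chrom[idx],
            pos_bp=self.pos_bp[idx],
            dosages=self.dosages[:, idx],
        )

    def allele_freq(self) -> np.ndarray:
        """Per-marker alternate-allele frequency on non-missing calls (NaN if all missing)."""
        import warnings as _warnings

        with _warnings.catch_warnings():
            _warnings.simplefilter("ignore", RuntimeWarning)  # all-missing markers
            return np.nanmean(self.dosages, axis=0) / 2.0

    def minor_allele_freq(self) -> np.ndarray:
        p = self.allele_freq()
        return np.minimum(p, 1.0 - p)

    def imputed(self) -> np.ndarray:
        """Dosages with missing calls filled by the per-marker mean (all-missing -> 0)."""
        X = self.dosages.copy()
        with np.errstate(invalid="ignore"):
            mu = np.nanmean(X, axis=0)
        mu = np.where(np.isnan(mu), 0.0, mu)
        nan_r, nan_c = np.nonzero(np.isnan(X))
        X[nan_r, nan_c] = mu[nan_c]
        return X

    def centered(self) -> np.ndarray:
        """Mean-imputed, column-centered dosages (the model-facing coding)."""
        X = self.imputed()
        return X - X.mean(axis=0)


@dataclass
class Grm:
    """Additive genomic relationship matrix over a set of individuals."""

    individual_ids: list[str]
    matrix: np.ndarray

    def __post_init__(self) -> None:
        self.matrix = np.asarray(self.matrix, dtype=float)
        if self.matrix.shape != (len(self.individual_ids),) * 2:
            raise ValueError("GRM shape does not match individual_ids")
        if not np.allclose(self.matrix, self.matrix.T, atol=1e-10):
            raise ValueError("GRM is not symmetric within 1e-10")


@dataclass
class FilterReport:
    n_input: int
    n_dropped_missing: int
    n_dropped_maf: int
    n_retained: int
    dropped_all_missing: list[str] = field(default_factory=list)


def filter_variants(
    geno: GenotypeMatrix,
    max_missing: float = 0.3,
    min_maf: float = 0.05,
) -> tuple[GenotypeMatrix, FilterReport]:
    """Drop markers by per-marker missing rate then minor allele frequency.

    A marker is retained when its missing fraction is <= ``max_missing`` and
    its MAF (computed on non-missing calls) is >= ``min_maf``. Marker order is
    preserved. Markers with every call missing are dropped (counted under the
    missingness filter) and listed in the report.
    """
    if geno.n_markers == 0:
        raise ValueError("empty genotype matrix")
    miss = np.isnan(geno.dosages).mean(axis=0)
    all_missing = miss >= 1.0
    pass_missing = miss <= max_missing
    maf = geno.minor_allele_freq()
    pass_maf = np.where(np.isnan(maf), False, maf >= min_maf)
    keep = pass_missing & pass_maf & ~all_missing
    report = FilterReport(
        n_input=geno.n_markers,
        n_dropped_missing=int((~pass_missing | all_missing).sum()),
        n_dropped_maf=int((pass_missing & ~all_missing & ~pass_maf).sum()),
        n_retained=int(keep.sum()),
        dropped_all_missing=[m for m, a in zip(geno.marker_ids, all_missing) if a],
    )
    if report.dropped_all_missing:
        logger.info("dropped %d all-missing markers", len(report.dropped_all_missing))
    return geno.take_markers(np.nonzero(keep)[0]), report


def _pairwise_r2(x: np.ndarray, y: np.ndarray) -> float:
    """Squared Pearson correlation of two dosage vectors; 0 if either is constant."""
    sx, sy = x.std(), y.std()
    if sx == 0.0 or sy == 0.0:
        return 0.0
    r = float(np.mean((x - x.mean()) * (y - y.mean())) / (sx * sy))
    return r * r


def ld_prune(
    geno: GenotypeMatrix,
    window_bp: int = 10_000,
    step_bp: int = 10,
    r2_threshold: float = 0.1,
) -> GenotypeMatrix:
    """Greedy window-based LD pruning on pairwise dosage r-squared.

    Per chromosome, windows of ``window_bp`` are slid in ``step_bp`` increments
    from the first marker position; for every marker pair inside a window with
    r^2 above ``r2_threshold`` the later marker (larger position, ties broken
    by larger column index) is removed. Removed markers never re-enter. The
    window enumeration reduces to: marker *i* is removed iff some retained
    earlier marker *j* co-occurs with it in at least one window and their
    r^2 exceeds the threshold. Monomorphic markers have undefined r^2 against
    anything; that is treated as 0 and never causes a removal.
    """
    X = geno.imputed()
    keep = np.ones(geno.n_markers, dtype=bool)
    for c in np.unique(geno.chrom):
        cols = np.nonzero(geno.chrom == c)[0]
        pos = geno.pos_bp[cols]
        start0 = int(pos.min())
        kept_local: list[int] = []
        for k, gi in enumerate(cols):
            removed = False
            for kj in kept_local:
                gj = cols[kj]
                pj, pi = int(pos[kj]), int(pos[k])
                # latest window grid start at or before the earlier marker
                anchor = start0 + ((pj - start0) // step_bp) * step_bp
                if pi >= anchor + window_bp:
                    continue  # never co-occur in a window
                if _pairwise_r2(X[:, gj], X[:, gi]) > r2_threshold:
                    removed = True
                    break
            if removed:
                keep[gi] = False
            else:
                kept_local.append(k)
    return geno.take_markers(np.nonzero(keep)[0])


def sample_markers(geno: GenotypeMatrix, n: int = 50_000, seed: int = 0) -> GenotypeMatrix:
    """Uniform without-replacement marker subsample; genomic order preserved."""
    if n > geno.n_markers:
        raise ValueError(f"requested {n} markers but only {geno.n_markers} available")
    rng = np.random.default_rng(seed)
    idx = np.sort(rng.choice(geno.n_markers, size=n, replace=False))
    return geno.take_markers(idx)


def additive_relationship(geno: GenotypeMatrix) -> Grm:
    """VanRaden method-1 GRM: W W' / (2 * sum p_k (1 - p_k)) on centered dosages."""
    p = geno.allele_freq()
    p = np.where(np.isnan(p), 0.0, p)
    poly = (p > 0) & (p < 1)
    if not poly.any():
        raise ValueError("no polymorphic markers; GRM undefined")
    X = geno.imputed()[:, poly]
    pk = p[poly]
    W = X - 2.0 * pk
    denom = 2.0 * float(np.sum(pk * (1.0 - pk)))
    A = W @ W.T / denom
    A = (A + A.T) / 2.0
    return Grm(individual_ids=list(geno.individual_ids), matrix=A)


def genotype_pcs(geno: GenotypeMatrix, k: int = 3) -> pd.DataFrame:
    """Top-k principal component scores of the centered dosage matrix.

    Columns are ordered by explained variance and the sign convention fixes
    the largest-magnitude marker loading of each component to be positive.
    """
    Xc = geno.centered()
    n, m = Xc.shape
    if k > min(n - 1, m):
        raise ValueError(f"k={k} exceeds min(n_individuals - 1, n_markers) = {min(n - 1, m)}")
    U, s, Vt = np.linalg.svd(Xc, full_matrices=False)
    rank = int(np.sum(s > s[0] * 1e-12)) if s.size else 0
    if k > rank:
        raise ValueError(f"k={k} exceeds matrix rank {rank}")
    scores = U[:, :k] * s[:k]
    for j in range(k):
        load = Vt[j]
        if load[np.argmax(np.abs(load))] < 0:
            scores[:, j] = -scores[:, j]
    return pd.DataFrame(
        scores, index=pd.Index(geno.individual_ids, name="individual_id"),
        columns=[f"PC{i + 1}" for i in range(k)],
    )
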