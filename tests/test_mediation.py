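"""Mediation machinery: confounder coding, path models, calibration and the
joint-significance scan."""

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from megs import SimulationConfig, simulate_dataset
from megs.evaluation import PredictionData
from megs.mediation import (
    build_confounder_matrix,
    fit_mediator_model,
    fit_outcome_model,
    mediation_scan,
)


@pytest.fixture(scope="module")
def med_data(small_ds):
    return PredictionData.from_simulated(small_ds)


@pytest.fixture(scope="module")
def null_scan():
    """Mediation scan on a dataset with no microbiome signal of any kind."""
    cfg = SimulationConfig(n_genotypes=80, n_snps=300, n_asvs=80, n_groups=10,
                           n_classes=5, ld_block_size=5, n_causal_asvs=0,
                           n_mediators=0, h2_snp=0.3, var_share_asv=0.0,
                           asv_h2=0.0, seed=77)
    ds = simulate_dataset(cfg)
    data = PredictionData.from_simulated(ds)
    res = mediation_scan(data.y, data.design, data.pcs, data.Z, data.M,
                         asv_ids=data.asv_ids, n_permutations=150, seed=5)
    return res


# ------------------------------------------------------- confounder matrix

def test_confounder_matrix_column_count(med_data):
    """Full design cardinalities (2/2/4/3) + 3 PCs + intercept -> 11 columns."""
    Q, names = build_confounder_matrix(med_data.design, med_data.pcs)
    assert Q.shape[1] == 11
    assert len(names) == 11
    assert np.linalg.matrix_rank(Q) == 11


def test_confounder_matrix_without_pcs(med_data):
    Q_full, _ = build_confounder_matrix(med_data.design, med_data.pcs)
    Q_nopc, names = build_confounder_matrix(med_data.design, None)
    assert Q_nopc.shape[1] == Q_full.shape[1] - 3
    assert not any(n.startswith("PC") for n in names)


# ---------------------------------------------------------- mediator model

def test_mediator_model_pure_snp_function(med_data, rng):
    idx = rng.choice(med_data.Z.shape[1], size=5, replace=False)
    m_pure = med_data.Z[:, idx] @ np.array([1.0, -1.0, 0.5, 0.8, -0.6])
    Q, names = build_confounder_matrix(med_data.design, med_data.pcs)
    fit = fit_mediator_model(m_pure, Q, med_data.Z, n_permutations=100, seed=0,
                             groups=med_data.design["treatment"].to_numpy(),
                             q_names=names)
    assert fit.genetic_share > 0.95
    assert fit.p_genetic <= 1.0 / 101 + 1e-12
    assert len(fit.B_j) == med_data.Z.shape[1]


def test_mediator_model_rejects_constant_column(med_data):
    Q, _ = build_confounder_matrix(med_data.design, med_data.pcs)
    with pytest.raises(ValueError, match="constant"):
        fit_mediator_model(np.ones(len(med_data.y)), Q, med_data.Z)


def test_mediator_model_recovers_asv_h2(small_ds, med_data):
    """REML genetic share of heritable ASVs tracks the generator's asv_h2."""
    Q, names = build_confounder_matrix(med_data.design, med_data.pcs)
    shares = []
    for asv in small_ds.truth.heritable_ids:
        j = med_data.asv_ids.index(asv)
        fit = fit_mediator_model(med_data.M[:, j], Q, med_data.Z,
                                 n_permutations=10, seed=0, q_names=names)
        shares.append(fit.genetic_share)
    assert np.median(shares) == pytest.approx(small_ds.config.asv_h2, abs=0.12)


# ----------------------------------------------------------- outcome model

def test_outcome_model_constructed_signal_dominates(med_data, rng):
    Q, names = build_confounder_matrix(med_data.design, med_data.pcs)
    y = med_data.y.to_numpy()
    # genetic prediction via the SNP-only component
    from megs.mixed_models import reml_single_component
    s_a, s_e, fit = reml_single_component(y, Q, Z_random=med_data.Z, fixed_names=names)
    gen_pred = med_data.Z @ fit.random_effects["u"].to_numpy()
    special = y - gen_pred - np.mean(y - gen_pred)
    M = np.column_stack([med_data.M, special])
    out = fit_outcome_model(y, Q, med_data.Z, M, n_permutations=0, seed=0,
                            asv_ids=list(med_data.asv_ids) + ["special"])
    assert out.c.abs().idxmax() == "special"


def test_outcome_model_consistent_with_two_component_fit(med_data):
    """With Q as the fixed design, the outcome model is the joint SNP+ASV fit."""
    from megs.mixed_models import fit_two_component, reml_single_component

    Q, names = build_confounder_matrix(med_data.design, med_data.pcs)
    y = med_data.y.to_numpy()
    out = fit_outcome_model(y, Q, med_data.Z, med_data.M, n_permutations=0,
                            asv_ids=med_data.asv_ids, q_names=names)
    fit = fit_two_component(y, Q, med_data.Z, med_data.M,
                            out.sigma2_a, out.sigma2_c, out.sigma2,
                            fixed_names=names, snp_ids=med_data.snp_ids,
                            asv_ids=med_data.asv_ids)
    np.testing.assert_allclose(out.a, fit.random_effects["snp"].to_numpy(), atol=1e-8)
    np.testing.assert_allclose(out.c.to_numpy(), fit.random_effects["asv"].to_numpy(),
                               atol=1e-8)
    np.testing.assert_allclose(out.v.to_numpy(), fit.fixed_effects.to_numpy(), atol=1e-8)


# -------------------------------------------------------------------- scan

def test_scan_null_pvalues_roughly_uniform(null_scan):
    for col in ("p_genetic", "p_phenotype"):
        p = null_scan.table[col].to_numpy()
        ks = stats.kstest(p, "uniform")
        assert ks.pvalue > 0.01, f"{col} deviates from uniform under the null"


def test_scan_maxp_stochastically_dominates_uniform(null_scan):
    pj = null_scan.table["p_joint"].dropna().to_numpy()
    for t in (0.05, 0.1, 0.25):
        assert np.mean(pj <= t) <= t + 0.05


def test_scan_null_makes_no_calls(null_scan):
    assert null_scan.mediators == []


def test_scan_single_path_asvs_not_called(small_ds, med_data):
    """Heritable-but-neutral ASVs (genetic path only) must not be mediators."""
    res = mediation_scan(med_data.y, med_data.design, med_data.pcs, med_data.Z,
                         med_data.M, asv_ids=med_data.asv_ids,
                         n_permutations=150, seed=3)
    genetic_only = (set(small_ds.truth.heritable_ids)
                    - set(small_ds.truth.mediator_ids))
    assert genetic_only, "fixture should plant genetic-only ASVs"
    assert not set(res.mediators) & genetic_only
    # and the joint rule lower-bounds both path p-values
    tbl = res.table
    assert (tbl["p_joint"].dropna()
            >= np.maximum(tbl["p_genetic"], tbl["p_phenotype"])[tbl["p_joint"].notna()]
            - 1e-12).all()


def test_scan_invariant_to_asv_column_order(med_data, rng):
    perm = rng.permutation(len(med_data.asv_ids))
    ids_p = [med_data.asv_ids[i] for i in perm]
    r1 = mediation_scan(med_data.y, med_data.design, med_data.pcs, med_data.Z,
                        med_data.M, asv_ids=med_data.asv_ids,
                        n_permutations=100, seed=11)
    r2 = mediation_scan(med_data.y, med_data.design, med_data.pcs, med_data.Z,
                        med_data.M[:, perm], asv_ids=ids_p,
                        n_permutations=100, seed=11)
    assert set(r1.mediators) == set(r2.mediators)
    # permutation draws act on rows, so per-ASV statistics agree exactly
    t1 = r1.table.sort_index()
    t2 = r2.table.sort_index()
    np.testing.assert_allclose(t1["genetic_share"], t2["genetic_share"], atol=1e-10)


def test_scan_qvalues_monotone_in_joint_p(med_data):
    res = mediation_scan(med_data.y, med_data.design, med_data.pcs, med_data.Z,
                         med_data.M, asv_ids=med_data.asv_ids,
                         n_permutations=100, seed=2)
    tbl = res.table.dropna(subset=["p_joint"]).sort_values("p_joint")
    assert (np.diff(tbl["q_value"].to_numpy()) >= -1e-12).all()


def test_confounder_adjustment_blocks_structure_driven_false_calls(rng):
    """Population structure driving both M and y inflates calls only when the
    PC columns are removed from the confounder matrix."""
    n_geno, n_snps, n_asvs = 160, 200, 60
    # two diverged subpopulations
    sub = np.repeat([0, 1], n_geno // 2)
    p0 = rng.uniform(0.1, 0.5, size=n_snps)
    shift = rng.uniform(0.25, 0.45, size=n_snps) * rng.choice([-1, 1], size=n_snps)
    freqs = np.clip(np.where(sub[:, None] == 0, p0, p0 + shift), 0.02, 0.98)
    dos = ((rng.random((n_geno, n_snps)) < freqs).astype(float)
           + (rng.random((n_geno, n_snps)) < freqs))
    design = pd.DataFrame({
        "genotype": [f"G{i}" for i in range(n_geno)],
        "treatment": ["HN", "LN"] * (n_geno // 2),
        "block": ["B1"] * n_geno,
        "splitplot": ["SP1"] * n_geno,
        "splitplot_block": ["SPB1"] * n_geno,
    }, index=pd.Index([f"p{i}" for i in range(n_geno)], name="plot_id"))
    Z = dos - dos.mean(axis=0)
    struct = sub.astype(float) - 0.5
    M = rng.normal(size=(n_geno, n_asvs))
    M[:, :8] += 4.0 * struct[:, None]  # structure-driven ASVs, no causal path
    # shared environmental gradient: affects y directly, not through SNPs
    env = struct + 0.2 * rng.normal(size=n_geno)
    y = pd.Series(4.0 * env + rng.normal(size=n_geno), index=design.index)
    from megs.genotypes import GenotypeMatrix, genotype_pcs
    geno = GenotypeMatrix([f"G{i}" for i in range(n_geno)],
                          [f"m{j}" for j in range(n_snps)],
                          np.array(["1"] * n_snps), np.arange(1, n_snps + 1) * 10, dos)
    pcs = genotype_pcs(geno, k=3)
    with_pc = mediation_scan(y, design, pcs, Z, M, n_permutations=120, seed=0)
    no_pc = mediation_scan(y, design, pcs.iloc[:, :0], Z, M, n_permutations=120, seed=0)
    assert len(no_pc.mediators) > len(with_pc.mediators)
    assert len(with_pc.mediators) <= 2
    # joint p-values of the structure ASVs are anticonservative without PCs
    ids = [i for i in range(8)]
    assert (no_pc.table.loc[ids, "p_joint"] < with_pc.table.loc[ids, "p_joint"]).mean() > 0.7
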