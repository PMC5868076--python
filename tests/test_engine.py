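import numpy as np
import pandas as pd
import pytest
from scipy import stats

import rrgwas as r
from rrgwas.basis import basis_matrix, evaluate_basis
from rrgwas.engine import PhenotypeTable
from rrgwas.genotype_qc import KinshipMatrix

from conftest import dense_gls_wald


def tiny_pheno():
    rows = []
    for animal, times in (("a", [10.0, 100.0]), ("b", [50.0, 200.0])):
        for t in times:
            rows.append(
                {"animal_id": animal, "parity": 1, "dim": t,
                 "htd": "h0" if t < 120 else "h1", "group": "g0", "y": 1.0}
            )
    return PhenotypeTable(pd.DataFrame(rows))


# --------------------------------------------------------------------- design

def test_build_design_q_block_structure():
    pheno = tiny_pheno()
    spec1 = r.BasisSpec(order=1)
    design = r.build_design(pheno, r.BasisSpec(order=0), spec1, spec1)
    Q = design.Q_dense()
    assert Q.shape == (4, 4)  # 2 animals x 2 coefficients
    for rec in range(4):
        block = design.rec_ind[rec]
        expected = evaluate_basis(design.times[rec], spec1)
        assert np.allclose(Q[rec, 2 * block : 2 * block + 2], expected)
        other = Q[rec].copy()
        other[2 * block : 2 * block + 2] = 0
        assert np.all(other == 0)


def test_build_design_group_indicator_when_mean_order_zero():
    rows = [
        {"animal_id": a, "parity": 1, "dim": t, "htd": "h0", "group": g, "y": 0.0}
        for a, g, t in [("a", "g0", 10), ("a", "g0", 50), ("b", "g1", 10), ("b", "g1", 50)]
    ]
    pheno = PhenotypeTable(pd.DataFrame(rows))
    design = r.build_design(pheno, r.BasisSpec(order=0), r.BasisSpec(order=0), r.BasisSpec(order=0))
    # one HTD level dropped entirely, two group columns scaled by phi_0
    assert design.X.shape[1] == 2
    phi0 = np.sqrt(0.5)
    assert np.allclose(design.X, [[phi0, 0], [phi0, 0], [0, phi0], [0, phi0]])


def test_build_design_missing_animal_from_panel():
    with pytest.raises(KeyError, match="b"):
        r.build_design(
            tiny_pheno(), r.BasisSpec(order=0), r.BasisSpec(order=0),
            r.BasisSpec(order=0), individual_ids=["a"],
        )


def test_phenotype_table_rejects_duplicates():
    df = pd.DataFrame(
        [{"animal_id": "a", "parity": 1, "dim": 10.0, "htd": "h", "group": "g", "y": 1.0}] * 2
    )
    with pytest.raises(ValueError, match="duplicate"):
        PhenotypeTable(df)


# ----------------------------------------------------------------- covariance

def test_covariance_zero_components_gives_zero():
    pheno = tiny_pheno()
    spec = r.BasisSpec(order=1)
    design = r.build_design(pheno, spec, spec, spec)
    vc = r.VarianceComponents(np.zeros((2, 2)), np.zeros((2, 2)), 1.0)
    W = r.build_covariance_W(design, np.eye(2), vc)
    assert np.all(W == 0)


def test_covariance_order0_closed_form():
    pheno = tiny_pheno()
    spec0 = r.BasisSpec(order=0, normalized=False)
    design = r.build_design(pheno, spec0, spec0, spec0)
    vc = r.VarianceComponents([[2.0]], [[3.0]], 1.0)
    W = r.build_covariance_W(design, np.eye(2), vc)
    same = (design.rec_ind[:, None] == design.rec_ind[None, :]).astype(float)
    assert np.allclose(W, (2.0 + 3.0) * same)


def test_covariance_matches_kronecker_oracle(small_data, small_system):
    data, sys = small_data, small_system
    design = sys["design"]
    vc = data.cfg.true_vc
    Q, Z = design.Q_dense(), design.Z_dense()
    Kal = data.kinship.align(design.ind_ids)
    W_oracle = (
        Q @ np.kron(Kal, vc.G) @ Q.T
        + Z @ np.kron(np.eye(design.n_individuals), vc.P) @ Z.T
    )
    assert np.max(np.abs(sys["W"] - W_oracle)) < 1e-10


# ------------------------------------------------------------------- rotation

def test_rotation_of_zero_W():
    pheno = tiny_pheno()
    spec = r.BasisSpec(order=1)
    design = r.build_design(pheno, spec, spec, spec)
    y = pheno.df["y"].to_numpy(float)
    rot = r.rotate_system(np.zeros((4, 4)), y, design.X, design, 2.0, spec)
    assert np.all(rot.D == 0)
    assert np.allclose(rot.S, 2.0)


def test_rotation_diagonalizes_record_covariance(small_system):
    sys = small_system
    rot = sys["rot"]
    V = sys["W"] + np.eye(len(sys["y"])) * rot.sigma2_e
    rotated = rot.U.T @ V @ rot.U
    assert np.max(np.abs(rotated - np.diag(rot.S))) < 1e-8 * max(rot.D.max(), 1.0)


def test_rotation_rejects_asymmetric_W(small_system):
    W = small_system["W"].copy()
    W[0, 1] += 1.0
    design = small_system["design"]
    with pytest.raises(ValueError, match="symmetric"):
        r.rotate_system(W, small_system["y"], design.X, design, 1.0, r.BasisSpec(order=2))


# ------------------------------------------------------------------------ WLS

def test_wls_orthonormal_projection():
    rng = np.random.default_rng(0)
    X, _ = np.linalg.qr(rng.standard_normal((20, 3)))
    y = rng.standard_normal(20)
    b, cov = r.wls_solve(X, y, np.ones(20))
    assert np.allclose(b, X.T @ y)
    assert np.allclose(cov, np.eye(3), atol=1e-12)


def test_wls_duplicated_rows_consistency():
    rng = np.random.default_rng(1)
    X = rng.standard_normal((15, 3))
    y = rng.standard_normal(15)
    S = rng.uniform(0.5, 2.0, 15)
    b1, _ = r.wls_solve(X, y, S)
    # duplicating a row while doubling its variance leaves the fit unchanged
    b2, _ = r.wls_solve(
        np.vstack([X, X]), np.concatenate([y, y]), np.concatenate([2 * S, 2 * S])
    )
    assert np.allclose(b1, b2)


def test_wls_matches_textbook_formula():
    rng = np.random.default_rng(2)
    X = rng.standard_normal((30, 4))
    y = rng.standard_normal(30)
    S = rng.uniform(0.2, 3.0, 30)
    b, cov = r.wls_solve(X, y, S)
    A = X.T @ np.diag(1 / S) @ X
    assert np.allclose(b, np.linalg.solve(A, X.T @ np.diag(1 / S) @ y), atol=1e-10)
    assert np.allclose(cov, np.linalg.inv(A), atol=1e-10)


def test_wls_rank_deficiency_errors():
    X = np.ones((10, 2))
    with pytest.raises(np.linalg.LinAlgError):
        r.wls_solve(X, np.ones(10), np.ones(10))


# ----------------------------------------------------------------------- Wald

def test_wald_zero_and_hand_values():
    stat, df, p = r.wald_test(np.zeros(3), np.eye(3))
    assert stat == 0 and p == 1.0
    stat, df, p = r.wald_test([2.0], [[1.0]])
    assert stat == pytest.approx(4.0) and df == 1
    assert p == pytest.approx(stats.chi2.sf(4, 1))


def test_wald_df_is_basis_size(small_data, small_system):
    spec4 = r.BasisSpec(order=4)
    data = small_data
    design = small_system["design"]
    rot = r.rotate_system(
        small_system["W"], small_system["y"], design.X, design,
        data.cfg.true_vc.sigma2_e, spec4,
    )
    freqs = r.allele_frequencies(data.geno)
    res = r.scan_snps(rot, data.geno, spec4, freqs, snp_indices=[0])[0]
    assert res.df == 5


def test_wald_singular_covariance_errors():
    with pytest.raises(np.linalg.LinAlgError):
        r.wald_test([1.0, 1.0], [[1.0, 1.0], [1.0, 1.0]])


# ----------------------------------------------------------------------- scan

def test_scan_agrees_with_dense_gls(small_data, small_system):
    data, sys = small_data, small_system
    freqs = r.allele_frequencies(data.geno)
    res = r.scan_snps(sys["rot"], data.geno, data.cfg.snp_spec, freqs, snp_indices=range(10))
    for m, rr in enumerate(res):
        stat, p = dense_gls_wald(
            sys["design"], sys["W"], sys["y"], data.geno, data.cfg.snp_spec,
            data.cfg.true_vc, m,
        )
        assert rr.wald_stat == pytest.approx(stat, rel=1e-8)
        assert rr.p_value == pytest.approx(p, rel=1e-6, abs=1e-12)


def test_scan_flags_monomorphic(small_data, small_system):
    data = small_data
    geno = data.geno
    codes = geno.codes.copy()
    codes[:, 0] = 2
    mono = r.GenotypeMatrix(codes, geno.snp_meta, geno.individual_ids)
    freqs = np.where(np.arange(geno.n_snps) == 0, 1.0, r.allele_frequencies(geno))
    res = r.scan_snps(small_system["rot"], mono, data.cfg.snp_spec, freqs, snp_indices=[0])[0]
    assert res.flag == "monomorphic" and np.isnan(res.p_value)


def test_wald_p_invariant_to_normalization_and_recoding(small_data):
    """Reparameterizing the basis or affinely recoding genotypes must not
    change the SNP p-values."""
    data = small_data
    freqs = r.allele_frequencies(data.geno)
    y = data.pheno.df["y"].to_numpy(float)

    def scan_with(normalized, flip):
        cfg = data.cfg
        specs = {
            name: r.BasisSpec(order=getattr(cfg, name).order, normalized=normalized)
            for name in ("mean_spec", "add_spec", "perm_spec", "snp_spec")
        }
        geno = data.geno
        fr = freqs
        if flip:  # 0/1/2 -> 2/1/0 allele relabeling
            geno = r.GenotypeMatrix(2 - geno.codes, geno.snp_meta, geno.individual_ids)
            fr = 1 - freqs
        design = r.build_design(
            data.pheno, specs["mean_spec"], specs["add_spec"], specs["perm_spec"],
            individual_ids=geno.individual_ids,
        )
        # same true covariances expressed in the chosen basis
        T = np.linalg.solve(
            basis_matrix(np.linspace(5, 305, cfg.add_spec.order + 1), specs["add_spec"]),
            basis_matrix(np.linspace(5, 305, cfg.add_spec.order + 1), cfg.add_spec),
        )
        vc = r.VarianceComponents(
            T @ data.cfg.true_vc.G @ T.T, T @ data.cfg.true_vc.P @ T.T,
            data.cfg.true_vc.sigma2_e,
        )
        W = r.build_covariance_W(design, data.kinship, vc)
        rot = r.rotate_system(W, y, design.X, design, vc.sigma2_e, specs["snp_spec"])
        res = r.scan_snps(rot, geno, specs["snp_spec"], fr, snp_indices=range(8))
        return np.array([x.p_value for x in res])

    base = scan_with(True, False)
    assert np.allclose(scan_with(False, False), base, rtol=1e-6)
    assert np.allclose(scan_with(True, True), base, rtol=1e-6)


def test_permuted_causal_snp_gives_uniform_pvalues(small_data, small_system):
    """Permuting genotype labels breaks the genotype-phenotype link, so the
    permutation p-value distribution must be uniform."""
    data, sys = small_data, small_system
    rot = sys["rot"]
    rng = np.random.default_rng(11)
    geno = data.geno
    freqs = r.allele_frequencies(geno)
    pvals = []
    codes = geno.codes.copy()
    for _ in range(300):
        codes[:, 0] = rng.permutation(geno.codes[:, 0])
        perm = r.GenotypeMatrix(codes, geno.snp_meta, geno.individual_ids)
        res = r.scan_snps(rot, perm, data.cfg.snp_spec, freqs, snp_indices=[0])[0]
        pvals.append(res.p_value)
    assert stats.kstest(pvals, "uniform").pvalue > 0.01


# --------------------------------------------------------------------- curves

def test_variance_curves_identity_and_closed_forms():
    spec0 = r.BasisSpec(order=0, normalized=False)
    vc = r.VarianceComponents([[2.5]], [[1.5]], 0.7)
    t = np.linspace(5, 305, 20)
    add, perm, phe = r.variance_curves(vc, spec0, spec0, t)
    assert np.allclose(add, 2.5)
    assert np.allclose(phe - add - perm, 0.7)

    spec1 = r.BasisSpec(order=1)
    vc1 = r.VarianceComponents(np.eye(2), np.eye(2), 1.0)
    add1, _, _ = r.variance_curves(vc1, spec1, spec1, [305.0])
    assert add1[0] == pytest.approx(0.5 + 1.5)  # sum of squared basis values at s=1


def test_snp_effect_curve_additivity():
    spec = r.BasisSpec(order=2, normalized=False)
    t = np.linspace(5, 305, 7)
    alpha = np.array([1.2, -0.3, 0.05])
    assert np.all(r.snp_effect_curve(alpha, spec, t, 0) == 0)
    assert np.allclose(
        r.snp_effect_curve(alpha, spec, t, 2), 2 * r.snp_effect_curve(alpha, spec, t, 1)
    )
    const = r.snp_effect_curve([1.0, 0.0, 0.0], spec, t, 1)
    assert np.allclose(const, 1.0)
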