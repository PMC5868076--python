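import numpy as np
import pytest

import rrgwas as r


@pytest.fixture(scope="session")
def small_data():
    """50 half-sib individuals, 10 records each, order-2 bases."""
    cfg = r.basic_config(order=2, n_individuals=50, n_families=10, n_snps=80, seed=3)
    return r.simulate_dataset(cfg)


@pytest.fixture(scope="session")
def small_system(small_data):
    """Design, covariance and rotation for the small data set."""
    data = small_data
    cfg = data.cfg
    design = r.build_design(
        data.pheno, cfg.mean_spec, cfg.add_spec, cfg.perm_spec,
        individual_ids=data.geno.individual_ids,
    )
    W = r.build_covariance_W(design, data.kinship, cfg.true_vc)
    y = data.pheno.df["y"].to_numpy(float)
    rot = r.rotate_system(W, y, design.X, design, cfg.true_vc.sigma2_e, cfg.snp_spec)
    return {"design": design, "W": W, "y": y, "rot": rot}


@pytest.fixture(scope="session")
def study_data():
    """The study-scale population for the type-I-error and power checks."""
    return r.simulate_dataset(r.study_config(seed=42))


@pytest.fixture(scope="session")
def null_polygenic(study_data):
    """Null scan under the full model, shared by several checks."""
    return r.null_scan_study(study_data, n_test_snps=1000, seed=5)


def dense_gls_wald(design, W, y, geno, snp_spec, vc, snp_index):
    """Independent oracle: from-scratch GLS with the full record covariance."""
    from rrgwas.basis import basis_matrix

    V = W + np.eye(len(y)) * vc.sigma2_e
    Vi = np.linalg.inv(V)
    Phi = basis_matrix(design.times, snp_spec)
    gi = {a: i for i, a in enumerate(geno.individual_ids)}
    order = np.array([gi[a] for a in design.ind_ids])
    g = geno.codes[:, snp_index].astype(float)[order][design.rec_ind]
    Xf = np.hstack([design.X, Phi * g[:, None]])
    A = Xf.T @ Vi @ Xf
    b = np.linalg.solve(A, Xf.T @ Vi @ y)
    cov = np.linalg.inv(A)
    q = Phi.shape[1]
    bs, cs = b[-q:], cov[-q:, -q:]
    stat = float(bs @ np.linalg.solve(cs, bs))
    from scipy import stats

    return stat, float(stats.chi2.sf(stat, q))
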