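"""Random-regression test-day model and the eigen-rotated SNP scan.

The model for a test-day record of cow *n* in herd-test-date class *j* and
mean-curve group *i* at days-in-milk *t* is::

    y_ijn(t) = mu_i(t) + htd_j + x_nm * SNP_m(t) + a_n(t) + pe_n(t) + e_nt

with mu, SNP, a and pe each expanded on a time basis (``basis.BasisSpec``),
``x_nm`` the 0/1/2 allele count, additive coefficients u ~ N(0, K ⊗ G),
permanent-environment coefficients p ~ N(0, I ⊗ P) and iid residuals.
With variance components held fixed (the two-step / P3D strategy), the
record covariance is

    var(y) = Q (K ⊗ G) Q' + Z (I ⊗ P) Z' + I σ²_e  =  W + I σ²_e .

A single symmetric eigendecomposition W = U D U' rotates the system so
var(U'y) = D + I σ²_e is diagonal; every SNP is then tested by weighted
least squares and a Wald chi-squared statistic on its nf₂+1 basis
coefficients, with no refactorization per SNP.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import linalg, stats

from .basis import BasisSpec, basis_matrix, evaluate_basis
from .genotype_qc import MISSING, GenotypeMatrix, KinshipMatrix

__all__ = [
    "PhenotypeTable",
    "DesignMatrices",
    "VarianceComponents",
    "RotatedSystem",
    "ScanResult",
    "build_design",
    "build_covariance_W",
    "rotate_system",
    "wls_solve",
    "wald_test",
    "scan_snps",
    "scan_table",
    "variance_curves",
    "snp_effect_curve",
]

PHENO_COLUMNS = ["animal_id", "parity", "dim", "htd", "group", "y"]


@dataclass
class PhenotypeTable:
    """Long-format test-day records.

    One row per animal × test day, with columns ``animal_id``, ``parity``,
    ``dim`` (days in milk), ``htd`` (herd-test-date class), ``group``
    (mean-curve group) and ``y`` (trait value).
    """

    df: pd.DataFrame

    def __post_init__(self) -> None:
        missing = [c for c in PHENO_COLUMNS if c not in self.df.columns]
        if missing:
            raise ValueError(f"phenotype table lacks columns {missing}")
        dup = self.df.duplicated(subset=["animal_id", "parity", "dim"])
        if dup.any():
            rows = self.df.loc[dup, ["animal_id", "parity", "dim"]]
            raise ValueError(
                f"duplicate (animal, parity, day) records:\n{rows.head(10)}"
            )
        self.df = self.df.reset_index(drop=True)

    @property
    def n_records(self) -> int:
        return len(self.df)

    @property
    def animals(self) -> list[str]:
        return list(dict.fromkeys(self.df["animal_id"]))


@dataclass
class VarianceComponents:
    """Coefficient covariances G (additive), P (permanent env.) and σ²_e."""

    G: np.ndarray
    P: np.ndarray
    sigma2_e: float

    def __post_init__(self) -> None:
        self.G = np.atleast_2d(np.asarray(self.G, dtype=float))
        self.P = np.atleast_2d(np.asarray(self.P, dtype=float))
        for name, M in (("G", self.G), ("P", self.P)):
            if np.max(np.abs(M - M.T), initial=0.0) > 1e-10:
                raise ValueError(f"{name} is not symmetric")
            ev = np.linalg.eigvalsh(M)
            if ev.size and ev[0] < -1e-8 * max(np.trace(M), 1.0):
                raise ValueError(f"{name} is not positive semi-definite")
        if self.sigma2_e <= 0:
            raise ValueError("sigma2_e must be positive")


@dataclass
class DesignMatrices:
    """Fixed design X plus the random-regression structure.

    The additive and permanent-environment designs are stored compactly:
    ``Phi_add``/``Phi_perm`` hold each record's basis row and ``rec_ind``
    maps records to the owning individual's block (``ind_ids`` order).
    ``Q_dense()`` / ``Z_dense()`` materialize the full block matrices.
    """

    X: np.ndarray
    col_names: list[str]
    times: np.ndarray
    rec_ind: np.ndarray  # record -> index into ind_ids
    ind_ids: list[str]
    Phi_add: np.ndarray
    Phi_perm: np.ndarray

    @property
    def n_records(self) -> int:
        return len(self.times)

    @property
    def n_individuals(self) -> int:
        return len(self.ind_ids)

    def _block_dense(self, Phi: np.ndarray) -> np.ndarray:
        n, q = Phi.shape
        M = np.zeros((n, self.n_individuals * q))
        cols = self.rec_ind[:, None] * q + np.arange(q)[None, :]
        M[np.arange(n)[:, None], cols] = Phi
        return M

    def Q_dense(self) -> np.ndarray:
        return self._block_dense(self.Phi_add)

    def Z_dense(self) -> np.ndarray:
        return self._block_dense(self.Phi_perm)


@dataclass
class RotatedSystem:
    """One-time eigen rotation of the no-SNP system.

    ``snp_projectors[k]`` is B_k = U' diag(φ_k(t)) E with E the
    record-to-individual indicator, so a SNP's rotated covariate column k
    is just B_k @ g for its length-n_ind genotype vector.
    """

    U: np.ndarray
    D: np.ndarray
    S: np.ndarray
    y_star: np.ndarray
    X_star_base: np.ndarray
    snp_projectors: list[np.ndarray]
    rec_ind: np.ndarray
    ind_ids: list[str]
    snp_spec: BasisSpec
    sigma2_e: float


@dataclass
class ScanResult:
    """Per-SNP association result from the rotated WLS fit."""

    snp_id: str
    alpha_hat: np.ndarray
    alpha_cov: np.ndarray
    wald_stat: float
    df: int
    p_value: float
    n_used: int
    flag: str = "ok"


def build_design(
    pheno: PhenotypeTable,
    mean_spec: BasisSpec,
    add_spec: BasisSpec,
    perm_spec: BasisSpec,
    individual_ids: list[str] | None = None,
) -> DesignMatrices:
    """Assemble X (HTD classes + per-group fixed regressions) and the
    random-regression structure.

    Identifiability: the first HTD level (sorted order) is dropped and the
    group fixed-regression blocks absorb the intercept; there is no
    separate global mean.  ``individual_ids`` fixes the individual block
    order (e.g. the genotype panel order); animals with records but absent
    from it raise a ``KeyError``.
    """
    df = pheno.df
    times = df["dim"].to_numpy(dtype=float)

    if individual_ids is None:
        ind_ids = pheno.animals
    else:
        ind_ids = list(individual_ids)
        absent = sorted(set(df["animal_id"]) - set(ind_ids))
        if absent:
            raise KeyError(
                f"{len(absent)} animal(s) with records absent from the "
                f"genotype panel, e.g. {absent[:5]}"
            )
    pos = {a: i for i, a in enumerate(ind_ids)}
    rec_ind = np.array([pos[a] for a in df["animal_id"]])

    blocks: list[np.ndarray] = []
    names: list[str] = []

    htd_levels = sorted(df["htd"].astype(str).unique())
    htd_codes = df["htd"].astype(str).to_numpy()
    for lev in htd_levels[1:]:  # first level dropped
        blocks.append((htd_codes == lev).astype(float)[:, None])
        names.append(f"htd:{lev}")

    Phi_mean = basis_matrix(times, mean_spec)
    group_codes = df["group"].astype(str).to_numpy()
    for lev in sorted(df["group"].astype(str).unique()):
        mask = (group_codes == lev).astype(float)[:, None]
        blocks.append(Phi_mean * mask)
        names.extend(f"group:{lev}:phi{k}" for k in range(Phi_mean.shape[1]))

    X = np.hstack(blocks)
    # rank check via pivoted QR diagnostics
    _, R = np.linalg.qr(X)
    diag = np.abs(np.diag(R))
    tol = max(X.shape) * np.finfo(float).eps * (diag.max() if diag.size else 1.0)
    if np.any(diag < tol):
        bad = [names[j] for j in np.flatnonzero(diag < tol)]
        raise ValueError(f"fixed-effect design rank-deficient; confounded columns {bad}")

    return DesignMatrices(
        X=X,
        col_names=names,
        times=times,
        rec_ind=rec_ind,
        ind_ids=ind_ids,
        Phi_add=basis_matrix(times, add_spec),
        Phi_perm=basis_matrix(times, perm_spec),
    )


def build_covariance_W(
    design: DesignMatrices,
    K: KinshipMatrix | np.ndarray,
    vc: VarianceComponents,
    include_polygenic: bool = True,
) -> np.ndarray:
    """Non-residual record covariance W = Q(K⊗G)Q' + Z(I⊗P)Z'.

    Exploits the block structure: element (r, s) is
    K[n(r), n(s)]·φ_r'Gφ_s + [n(r)=n(s)]·φ_r'Pφ_s, avoiding any explicit
    Kronecker product.  ``include_polygenic=False`` drops the genetic term
    (the "no-polygenic" comparator model).
    """
    Kmat = K.align(design.ind_ids) if isinstance(K, KinshipMatrix) else np.asarray(K)
    n = design.n_records
    if Kmat.shape[0] < design.n_individuals:
        raise ValueError(
            f"kinship covers {Kmat.shape[0]} individuals, design needs "
            f"{design.n_individuals}"
        )
    ri = design.rec_ind
    W = np.zeros((n, n))
    if include_polygenic:
        if design.Phi_add.shape[1] != vc.G.shape[0]:
            raise ValueError(
                f"G is {vc.G.shape} but additive basis has "
                f"{design.Phi_add.shape[1]} functions"
            )
        W += (design.Phi_add @ vc.G @ design.Phi_add.T) * Kmat[np.ix_(ri, ri)]
    if design.Phi_perm.shape[1] != vc.P.shape[0]:
        raise ValueError(
            f"P is {vc.P.shape} but permanent-env basis has "
            f"{design.Phi_perm.shape[1]} functions"
        )
    same = ri[:, None] == ri[None, :]
    W += (design.Phi_perm @ vc.P @ design.Phi_perm.T) * same
    return (W + W.T) / 2.0


def rotate_system(
    W: np.ndarray,
    y: np.ndarray,
    X_base: np.ndarray,
    design: DesignMatrices,
    sigma2_e: float,
    snp_spec: BasisSpec,
) -> RotatedSystem:
    """Eigendecompose W once and rotate response, design and SNP projectors.

    After rotation var(y*) = diag(D + σ²_e); negative eigenvalues within
    -1e-8·max(D) are numerical noise and are clamped to zero.
    """
    W = np.asarray(W, dtype=float)
    scale = np.max(np.abs(W), initial=0.0)
    if np.max(np.abs(W - W.T), initial=0.0) > 1e-8 * max(scale, 1.0):
        raise ValueError("W is not symmetric")
    D, U = np.linalg.eigh(W)
    tol = 1e-8 * max(D.max(initial=0.0), 0.0)
    if D.min(initial=0.0) < -max(tol, 1e-12 * max(scale, 1.0)) - 1e-10:
        raise ValueError(f"W has a substantially negative eigenvalue {D.min():.3e}")
    D = np.clip(D, 0.0, None)
    S = D + sigma2_e
    y_star = U.T @ np.asarray(y, dtype=float)
    X_star = U.T @ np.asarray(X_base, dtype=float)

    Phi_snp = basis_matrix(design.times, snp_spec)
    n_ind = design.n_individuals
    projectors = []
    for k in range(Phi_snp.shape[1]):
        scaled = U * Phi_snp[:, k][:, None]  # row r of U weighted by φ_k(t_r)
        acc = np.zeros((n_ind, U.shape[1]))
        np.add.at(acc, design.rec_ind, scaled)
        projectors.append(acc.T)  # (n_rec*, n_ind)
    return RotatedSystem(
        U=U,
        D=D,
        S=S,
        y_star=y_star,
        X_star_base=X_star,
        snp_projectors=projectors,
        rec_ind=design.rec_ind,
        ind_ids=list(design.ind_ids),
        snp_spec=snp_spec,
        sigma2_e=sigma2_e,
    )


def wls_solve(X_star: np.ndarray, y_star: np.ndarray, S: np.ndarray):
    """Weighted least squares b = (X'S⁻¹X)⁻¹X'S⁻¹y with diagonal weights S.

    Solved by QR on the row-scaled system; returns (b_hat, b_cov) with
    b_cov = (X'S⁻¹X)⁻¹.
    """
    S = np.asarray(S, dtype=float)
    if np.any(S <= 0):
        raise ValueError("weights S must be strictly positive")
    w = 1.0 / np.sqrt(S)
    Xw = X_star * w[:, None]
    yw = y_star * w
    Q, R = np.linalg.qr(Xw)
    diag = np.abs(np.diag(R))
    tol = max(Xw.shape) * np.finfo(float).eps * diag.max(initial=0.0)
    if np.any(diag <= tol):
        raise np.linalg.LinAlgError(
            f"rank-deficient design in WLS (columns {np.flatnonzero(diag <= tol).tolist()})"
        )
    b_hat = linalg.solve_triangular(R, Q.T @ yw)
    Rinv = linalg.solve_triangular(R, np.eye(R.shape[0]))
    b_cov = Rinv @ Rinv.T
    return b_hat, b_cov


def wald_test(alpha_hat: np.ndarray, alpha_cov: np.ndarray):
    """Wald χ² of the SNP coefficient vector: α̂' var(α̂)⁻¹ α̂ ~ χ²(nf₂+1)."""
    alpha_hat = np.atleast_1d(np.asarray(alpha_hat, dtype=float))
    alpha_cov = np.atleast_2d(np.asarray(alpha_cov, dtype=float))
    try:
        c = linalg.cho_factor(alpha_cov)
    except linalg.LinAlgError as exc:
        raise linalg.LinAlgError(
            "singular SNP coefficient covariance (confounded SNP covariates)"
        ) from exc
    stat = float(alpha_hat @ linalg.cho_solve(c, alpha_hat))
    df = alpha_hat.size
    return stat, df, float(stats.chi2.sf(stat, df))


def _impute_genotypes(codes: np.ndarray, freq: float) -> np.ndarray:
    g = codes.astype(float)
    g[codes == MISSING] = 2.0 * freq
    return g


def scan_snps(
    rot: RotatedSystem,
    geno: GenotypeMatrix,
    snp_spec: BasisSpec,
    freqs: np.ndarray,
    snp_indices=None,
    y_star: np.ndarray | None = None,
) -> list[ScanResult]:
    """Per-SNP rotated WLS fit and Wald test.

    For SNP m the rotated covariate block is [B_0 g, ..., B_nf₂ g] with g
    the (mean-imputed) genotype vector over ``rot.ind_ids``; the base
    design is augmented by this block and only the SNP block's
    coefficients are extracted, via the Schur complement of the
    precomputed base normal equations.  Monomorphic-in-sample SNPs are
    returned flagged with missing p-values rather than dropped.

    ``y_star`` overrides the rotated response (used by the power study
    after injecting a QTN effect); ``snp_indices`` restricts the scan.
    """
    if snp_spec.n_basis != rot.snp_spec.n_basis or snp_spec.family != rot.snp_spec.family:
        raise ValueError("snp_spec differs from the one used to build the projectors")
    gpos = {g: i for i, g in enumerate(geno.individual_ids)}
    absent = [a for a in rot.ind_ids if a not in gpos]
    if absent:
        raise KeyError(f"phenotyped individuals absent from genotypes: {absent[:5]}")
    order = np.array([gpos[a] for a in rot.ind_ids])

    if y_star is None:
        y_star = rot.y_star
    invS = 1.0 / rot.S
    X0 = rot.X_star_base
    X0w = X0 * invS[:, None]
    A00 = X0.T @ X0w
    c00 = linalg.cho_factor(A00)
    X0ty = X0w.T @ y_star
    A00inv_X0ty = linalg.cho_solve(c00, X0ty)
    q = snp_spec.n_basis
    n_used = len(rot.ind_ids)

    if snp_indices is None:
        snp_indices = range(geno.n_snps)
    results: list[ScanResult] = []
    for m in snp_indices:
        sid = geno.snp_meta["snp_id"].iat[m]
        g = _impute_genotypes(geno.codes[order, m], float(freqs[m]))
        if np.ptp(g) == 0.0:
            results.append(
                ScanResult(sid, np.full(q, np.nan), np.full((q, q), np.nan),
                           np.nan, q, np.nan, n_used, flag="monomorphic")
            )
            continue
        V = np.column_stack([B @ g for B in rot.snp_projectors])
        Vw = V * invS[:, None]
        C = X0.T @ Vw  # (p0, q)
        Avv = V.T @ Vw
        Vty = Vw.T @ y_star
        Schur = Avv - C.T @ linalg.cho_solve(c00, C)
        try:
            cs = linalg.cho_factor(Schur)
            alpha_cov = linalg.cho_solve(cs, np.eye(q))
            alpha_hat = alpha_cov @ (Vty - C.T @ A00inv_X0ty)
            stat, df, p = wald_test(alpha_hat, alpha_cov)
        except linalg.LinAlgError:
            results.append(
                ScanResult(sid, np.full(q, np.nan), np.full((q, q), np.nan),
                           np.nan, q, np.nan, n_used, flag="singular")
            )
            continue
        results.append(ScanResult(sid, alpha_hat, alpha_cov, stat, df, p, n_used))
    return results


def scan_table(results: list[ScanResult], geno: GenotypeMatrix, freqs: np.ndarray) -> pd.DataFrame:
    """Tabulate scan results with SNP metadata (one row per tested SNP)."""
    meta = geno.snp_meta.set_index("snp_id")
    freq_by_id = dict(zip(geno.snp_meta["snp_id"], freqs))
    rows = []
    for r in results:
        m = meta.loc[r.snp_id]
        p = freq_by_id[r.snp_id]
        row = {
            "snp_id": r.snp_id,
            "chromosome": m["chromosome"],
            "position": m["position"],
            "allele1": m["allele1"],
            "allele2": m["allele2"],
            "maf": min(p, 1 - p),
            "n_used": r.n_used,
        }
        for k, a in enumerate(r.alpha_hat):
            row[f"alpha_{k}"] = a
        row.update(wald_stat=r.wald_stat, df=r.df, p_value=r.p_value, flag=r.flag)
        rows.append(row)
    return pd.DataFrame(rows)


def variance_curves(
    vc: VarianceComponents,
    add_spec: BasisSpec,
    perm_spec: BasisSpec,
    times,
):
    """Time-dependent additive, permanent-environment and phenotypic variances.

    add(t) = φ(t)'Gφ(t), perm(t) = φ(t)'Pφ(t), phe(t) = add + perm + σ²_e.
    """
    Pa = basis_matrix(times, add_spec)
    Pp = basis_matrix(times, perm_spec)
    add = np.einsum("ij,jk,ik->i", Pa, vc.G, Pa)
    perm = np.einsum("ij,jk,ik->i", Pp, vc.P, Pp)
    return add, perm, add + perm + vc.sigma2_e


def snp_effect_curve(alpha_hat, snp_spec: BasisSpec, times, genotype_code: int):
    """Genotypic value of a SNP over time, relative to the code-0 genotype."""
    Phi = basis_matrix(times, snp_spec)
    return genotype_code * (Phi @ np.asarray(alpha_hat, dtype=float))
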