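"""REML estimation of the random-regression variance components.

The scan holds G, P and σ²_e fixed (two-step / P3D strategy); this module
estimates them once from the no-SNP model

    y = Xb + Qu + Zp + e,   u ~ N(0, K ⊗ G),  p ~ N(0, I ⊗ P),  e ~ N(0, Iσ²_e)

by EM-REML with an optional average-information (AI) acceleration.  All
per-iteration algebra runs through Henderson's mixed-model equations, so the
cost is one Cholesky of the (n_fixed + n_ind·(nr₁+nr₂+2)) coefficient matrix
per likelihood evaluation — never an N_records³ dense operation.

The plain EM update is monotone in the restricted likelihood; the AI step is
a Newton-like update using the average of observed and expected information,
accepted only when it improves the restricted likelihood (with step halving,
falling back to the EM update otherwise), so the hybrid is monotone too.
G and P are floored to the PSD cone by eigenvalue truncation after every
update, keeping the model assumptions valid throughout.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import linalg

from .basis import BasisSpec
from .engine import (
    DesignMatrices,
    PhenotypeTable,
    VarianceComponents,
    build_design,
)
from .genotype_qc import KinshipMatrix

__all__ = ["REMLReport", "reml_estimate", "read_varcomp", "write_varcomp"]

DENSE_RECORD_GUARD = 20_000


@dataclass
class REMLReport:
    iterations: int
    loglik: float
    grad_norm: float
    converged: bool
    history: list[float]


def _psd_floor(M: np.ndarray, floor: float) -> np.ndarray:
    """Project a symmetric matrix onto {eigenvalues >= floor}."""
    M = (M + M.T) / 2.0
    ev, V = np.linalg.eigh(M)
    if ev[0] >= floor:
        return M
    return (V * np.clip(ev, floor, None)) @ V.T


class _Workspace:
    """Precomputed cross-products for one data set."""

    def __init__(self, design: DesignMatrices, y: np.ndarray, Kmat: np.ndarray):
        self.y = np.asarray(y, dtype=float)
        X = design.X
        Qd = design.Q_dense()
        Zd = design.Z_dense()
        self.p = X.shape[1]
        self.n_ind = design.n_individuals
        self.q1 = design.Phi_add.shape[1]
        self.q2 = design.Phi_perm.shape[1]
        self.qu = self.n_ind * self.q1
        self.qp = self.n_ind * self.q2
        self.N = design.n_records
        self.T = np.hstack([X, Qd, Zd])
        self.TtT = self.T.T @ self.T
        self.Tty = self.T.T @ self.y
        self.yty = float(self.y @ self.y)
        self.K = Kmat
        # kinship inverse with escalating jitter if K is numerically singular
        jitter = 0.0
        tr = np.trace(Kmat) / Kmat.shape[0]
        while True:
            try:
                cK = linalg.cho_factor(Kmat + jitter * np.eye(Kmat.shape[0]))
                break
            except linalg.LinAlgError:
                jitter = max(jitter * 10.0, 1e-8 * max(tr, 1.0))
        self.Kinv = linalg.cho_solve(cK, np.eye(Kmat.shape[0]))
        self.logdetK = 2.0 * np.sum(np.log(np.diag(cK[0])))

    # slices of the MME solution / coefficient matrix
    @property
    def sl_u(self):
        return slice(self.p, self.p + self.qu)

    @property
    def sl_p(self):
        return slice(self.p + self.qu, self.p + self.qu + self.qp)

    def mme(self, G, P, s2e):
        """Factorize the MME coefficient matrix; return (chol, sol, neg2l)."""
        cG = linalg.cho_factor(G)
        cP = linalg.cho_factor(P)
        Ginv = linalg.cho_solve(cG, np.eye(self.q1))
        Pinv = linalg.cho_solve(cP, np.eye(self.q2))
        logdetG = 2.0 * np.sum(np.log(np.diag(cG[0])))
        logdetP = 2.0 * np.sum(np.log(np.diag(cP[0])))
        C = self.TtT.copy()
        C[self.sl_u, self.sl_u] += s2e * np.kron(self.Kinv, Ginv)
        C[self.sl_p, self.sl_p] += s2e * np.kron(np.eye(self.n_ind), Pinv)
        cC = linalg.cho_factor(C)
        sol = linalg.cho_solve(cC, self.Tty)
        logdetC = 2.0 * np.sum(np.log(np.diag(cC[0])))
        ypy = (self.yty - sol @ self.Tty) / s2e
        qtot = self.qu + self.qp
        neg2l = (
            (self.N - self.p - qtot) * np.log(s2e)
            + self.q1 * self.logdetK
            + self.n_ind * logdetG
            + self.n_ind * logdetP
            + logdetC
            + ypy
        )
        return cC, sol, float(neg2l)

    def em_update(self, G, P, s2e, cC, sol):
        """One EM-REML step from the current MME solution."""
        Cinv = linalg.cho_solve(cC, np.eye(self.TtT.shape[0]))
        uhat = sol[self.sl_u].reshape(self.n_ind, self.q1)
        phat = sol[self.sl_p].reshape(self.n_ind, self.q2)
        Cuu = Cinv[self.sl_u, self.sl_u].reshape(
            self.n_ind, self.q1, self.n_ind, self.q1
        )
        Cpp = Cinv[self.sl_p, self.sl_p].reshape(
            self.n_ind, self.q2, self.n_ind, self.q2
        )
        G_new = (
            np.einsum("ab,aj,bk->jk", self.Kinv, uhat, uhat)
            + s2e * np.einsum("ab,ajbk->jk", self.Kinv, Cuu)
        ) / self.n_ind
        P_new = (
            phat.T @ phat + s2e * np.einsum("ajak->jk", Cpp)
        ) / self.n_ind
        s2e_new = (self.yty - sol @ self.Tty) / (self.N - self.p)
        return (G_new + G_new.T) / 2.0, (P_new + P_new.T) / 2.0, float(s2e_new)

    # ---- score and average information -------------------------------
    def _sym_pairs(self, q):
        return [(j, k) for j in range(q) for k in range(j, q)]

    def score_and_ai(self, G, P, s2e, cC, sol):
        """Restricted-likelihood score and AI matrix at (G, P, σ²_e).

        Uses P_proj = (I − T C⁻¹ T')/σ²_e and ê = σ²_e·P_proj·y = y − T·sol.
        """
        resid = self.y - self.T @ sol
        Py = resid / s2e
        TtPy = self.T.T @ Py
        # Q'P_projQ and Z'P_projZ via the MME inverse
        TtQ = self.TtT[:, self.sl_u]
        TtZ = self.TtT[:, self.sl_p]
        CiTtQ = linalg.cho_solve(cC, TtQ)
        CiTtZ = linalg.cho_solve(cC, TtZ)
        QPQ = (self.TtT[self.sl_u, self.sl_u] - TtQ.T @ CiTtQ) / s2e
        ZPZ = (self.TtT[self.sl_p, self.sl_p] - TtZ.T @ CiTtZ) / s2e
        trP = (self.N - np.trace(linalg.cho_solve(cC, self.TtT))) / s2e

        vq = TtPy[self.sl_u].reshape(self.n_ind, self.q1)
        vz = TtPy[self.sl_p].reshape(self.n_ind, self.q2)
        B_u = QPQ.reshape(self.n_ind, self.q1, self.n_ind, self.q1)
        B_z = ZPZ.reshape(self.n_ind, self.q2, self.n_ind, self.q2)
        Tmat_u = np.einsum("ab,bkaj->jk", self.K, B_u)
        qmat_u = np.einsum("ab,aj,bk->jk", self.K, vq, vq)
        Tmat_z = np.einsum("akaj->jk", B_z)
        qmat_z = vz.T @ vz

        pairs_u = self._sym_pairs(self.q1)
        pairs_z = self._sym_pairs(self.q2)
        n_par = len(pairs_u) + len(pairs_z) + 1
        score = np.zeros(n_par)
        fvecs = np.zeros((self.N, n_par))

        Kv = self.K @ vq  # for f-vectors of G parameters
        Qd = self.T[:, self.sl_u]
        Zd = self.T[:, self.sl_p]
        i = 0
        for j, k in pairs_u:
            if j == k:
                tr_i = Tmat_u[j, j]
                quad = qmat_u[j, j]
                f = np.zeros((self.n_ind, self.q1))
                f[:, j] = Kv[:, j]
            else:
                tr_i = Tmat_u[j, k] + Tmat_u[k, j]
                quad = qmat_u[j, k] + qmat_u[k, j]
                f = np.zeros((self.n_ind, self.q1))
                f[:, j] = Kv[:, k]
                f[:, k] = Kv[:, j]
            score[i] = -0.5 * (tr_i - quad)
            fvecs[:, i] = Qd @ f.ravel()
            i += 1
        for j, k in pairs_z:
            if j == k:
                tr_i = Tmat_z[j, j]
                quad = qmat_z[j, j]
                f = np.zeros((self.n_ind, self.q2))
                f[:, j] = vz[:, j]
            else:
                tr_i = Tmat_z[j, k] + Tmat_z[k, j]
                quad = qmat_z[j, k] + qmat_z[k, j]
                f = np.zeros((self.n_ind, self.q2))
                f[:, j] = vz[:, k]
                f[:, k] = vz[:, j]
            score[i] = -0.5 * (tr_i - quad)
            fvecs[:, i] = Zd @ f.ravel()
            i += 1
        score[i] = -0.5 * (trP - Py @ Py)
        fvecs[:, i] = Py

        # AI_{ij} = 0.5 f_i' P_proj f_j
        TtF = self.T.T @ fvecs
        PF = (fvecs - self.T @ linalg.cho_solve(cC, TtF)) / s2e
        AI = 0.5 * (fvecs.T @ PF)
        return score, AI, pairs_u, pairs_z


def _theta_to_mats(theta, pairs_u, pairs_z, q1, q2):
    G = np.zeros((q1, q1))
    P = np.zeros((q2, q2))
    i = 0
    for j, k in pairs_u:
        G[j, k] = G[k, j] = theta[i]
        i += 1
    for j, k in pairs_z:
        P[j, k] = P[k, j] = theta[i]
        i += 1
    return G, P, float(theta[i])


def _mats_to_theta(G, P, s2e, pairs_u, pairs_z):
    return np.array(
        [G[j, k] for j, k in pairs_u] + [P[j, k] for j, k in pairs_z] + [s2e]
    )


def reml_estimate(
    pheno: PhenotypeTable,
    K: KinshipMatrix,
    mean_spec: BasisSpec,
    add_spec: BasisSpec,
    perm_spec: BasisSpec,
    init: VarianceComponents | None = None,
    max_iter: int = 200,
    tol: float = 1e-6,
    accelerate: bool = True,
    record_guard: int = DENSE_RECORD_GUARD,
):
    """Estimate (G, P, σ²_e) by (AI-accelerated) EM-REML.

    Returns ``(VarianceComponents, REMLReport)``.  ``accelerate=False``
    runs plain EM, whose restricted log-likelihood is non-decreasing; with
    ``accelerate=True`` an AI step is attempted each iteration and kept
    only when it improves the restricted likelihood, so monotonicity is
    preserved.  Non-convergence returns the best estimates with
    ``converged=False`` rather than raising.
    """
    if pheno.n_records > record_guard:
        raise ValueError(
            f"{pheno.n_records} records exceed the dense-REML guard "
            f"({record_guard}); estimate variances on a subset or supply them"
        )
    design = build_design(pheno, mean_spec, add_spec, perm_spec)
    y = pheno.df["y"].to_numpy(dtype=float)
    ws = _Workspace(design, y, K.align(design.ind_ids))
    q1, q2 = ws.q1, ws.q2

    var_y = float(np.var(y))
    if init is None:
        init = VarianceComponents(
            G=0.1 * var_y * np.eye(q1),
            P=0.1 * var_y * np.eye(q2),
            sigma2_e=0.8 * var_y,
        )
    else:
        for name, M, q in (("G", init.G, q1), ("P", init.P, q2)):
            if M.shape != (q, q):
                raise ValueError(f"init {name} has shape {M.shape}, expected ({q},{q})")

    # PSD floor for G and P: small enough not to bias any estimable
    # component, large enough that sigma2_e * Sigma^-1 stays factorizable
    floor = 1e-6 * var_y
    G = _psd_floor(init.G, floor)
    P = _psd_floor(init.P, floor)
    s2e = float(init.sigma2_e)

    cC, sol, neg2l = ws.mme(G, P, s2e)
    history = [-0.5 * neg2l]
    converged = False
    it = 0
    for it in range(1, max_iter + 1):
        G_em, P_em, s2e_em = ws.em_update(G, P, s2e, cC, sol)
        G_new = _psd_floor(G_em, floor)
        P_new = _psd_floor(P_em, floor)
        s2e_new = max(s2e_em, 1e-12 * var_y)
        try:
            cC_new, sol_new, neg2l_new = ws.mme(G_new, P_new, s2e_new)
        except linalg.LinAlgError:
            # boundary collapse made the system numerically indefinite:
            # refloor more aggressively and retry once, else stop here
            G_new = _psd_floor(G_em, 100 * floor)
            P_new = _psd_floor(P_em, 100 * floor)
            try:
                cC_new, sol_new, neg2l_new = ws.mme(G_new, P_new, s2e_new)
            except linalg.LinAlgError:
                converged = False
                break

        if accelerate:
            score, AI, pairs_u, pairs_z = ws.score_and_ai(G, P, s2e, cC, sol)
            theta0 = _mats_to_theta(G, P, s2e, pairs_u, pairs_z)
            try:
                delta = np.linalg.solve(AI + 1e-10 * np.eye(AI.shape[0]), score)
            except np.linalg.LinAlgError:
                delta = None
            if delta is not None:
                step = 1.0
                for _ in range(6):
                    Gc, Pc, sc = _theta_to_mats(
                        theta0 + step * delta, pairs_u, pairs_z, q1, q2
                    )
                    if sc <= 0:
                        step /= 2.0
                        continue
                    Gc = _psd_floor(Gc, floor)
                    Pc = _psd_floor(Pc, floor)
                    try:
                        cC_c, sol_c, neg2l_c = ws.mme(Gc, Pc, sc)
                    except (linalg.LinAlgError, FloatingPointError):
                        step /= 2.0
                        continue
                    if neg2l_c < neg2l_new:
                        G_new, P_new, s2e_new = Gc, Pc, sc
                        cC_new, sol_new, neg2l_new = cC_c, sol_c, neg2l_c
                        break
                    step /= 2.0

        change = abs(neg2l - neg2l_new)
        G, P, s2e = G_new, P_new, s2e_new
        cC, sol, neg2l = cC_new, sol_new, neg2l_new
        history.append(-0.5 * neg2l)
        if change < tol:
            converged = True
            break

    score, _, _, _ = ws.score_and_ai(G, P, s2e, cC, sol)
    vc = VarianceComponents(G=G, P=P, sigma2_e=s2e)
    report = REMLReport(
        iterations=it,
        loglik=-0.5 * neg2l,
        grad_norm=float(np.linalg.norm(score)),
        converged=converged,
        history=history,
    )
    return vc, report


# ---------------------------------------------------------------------------
# plain-text variance-component files
# ---------------------------------------------------------------------------

def write_varcomp(vc: VarianceComponents, path) -> None:
    """Write G, P and σ²_e as labeled lower triangles, full precision."""
    with open(path, "w") as fh:
        fh.write("# random-regression variance components\n")
        for label, M in (("G", vc.G), ("P", vc.P)):
            fh.write(f"{label}\n")
            for i in range(M.shape[0]):
                fh.write(" ".join(repr(float(v)) for v in M[i, : i + 1]) + "\n")
        fh.write("SIGMA2E\n")
        fh.write(repr(float(vc.sigma2_e)) + "\n")


def read_varcomp(path, expected_orders: tuple[int, int] | None = None) -> VarianceComponents:
    """Read the labeled lower-triangle layout written by :func:`write_varcomp`.

    ``expected_orders`` = (nr₁, nr₂) checks the G and P dimensions against
    the configured basis orders and raises on mismatch.
    """
    blocks: dict[str, list[list[float]]] = {}
    current: str | None = None
    with open(path) as fh:
        for raw in fh:
            line = raw.split("#", 1)[0].strip()
            if not line:
                continue
            if line in ("G", "P", "SIGMA2E"):
                current = line
                blocks[current] = []
                continue
            if current is None:
                raise ValueError(f"unlabeled data line in {path}: {raw!r}")
            blocks[current].append([float(tok) for tok in line.split()])
    for label in ("G", "P", "SIGMA2E"):
        if label not in blocks:
            raise ValueError(f"missing block {label!r} in {path}")

    def tri_to_full(rows):
        q = len(rows)
        M = np.zeros((q, q))
        for i, row in enumerate(rows):
            if len(row) != i + 1:
                raise ValueError(f"malformed lower triangle row {row}")
            M[i, : i + 1] = row
            M[: i + 1, i] = row
        return M

    G = tri_to_full(blocks["G"])
    P = tri_to_full(blocks["P"])
    if len(blocks["SIGMA2E"]) != 1 or len(blocks["SIGMA2E"][0]) != 1:
        raise ValueError("SIGMA2E block must hold a single value")
    s2e = blocks["SIGMA2E"][0][0]
    if expected_orders is not None:
        nr1, nr2 = expected_orders
        if G.shape[0] != nr1 + 1 or P.shape[0] != nr2 + 1:
            raise ValueError(
                f"file has G of size {G.shape[0]} and P of size {P.shape[0]}, "
                f"configured basis orders imply {nr1 + 1} and {nr2 + 1}"
            )
    return VarianceComponents(G=G, P=P, sigma2_e=s2e)
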