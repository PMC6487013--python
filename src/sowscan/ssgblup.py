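"""Henderson's mixed-model equations under A⁻¹ or H⁻¹.

Solves

    [X'X       X'W             X'K      ] [b ]   [X'y]
    [W'X   W'W + H⁻¹·λa        W'K      ] [a ] = [W'y]
    [K'X       K'W         K'K + I·λpe  ] [pe]   [K'y]

with λa = σ²e/σ²a and λpe = σ²e/σ²pe. Records of non-genotyped animals are
fully included; genotype status only alters the relationship inverse. A
dense Cholesky is used below 5,000 equations, Jacobi-preconditioned
conjugate gradients above.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import scipy.linalg as sla
import scipy.sparse as sp
import scipy.sparse.linalg as spla

from .errors import DataError
from .reml import ModelSpec, VarianceComponents

DENSE_LIMIT = 5000


@dataclass
class MMESolution:
    """Fixed-effect solutions, breeding values and pe solutions."""

    b_hat: np.ndarray
    a_hat: np.ndarray
    pe_hat: np.ndarray
    genotyped_pos: np.ndarray | None = None
    relative_residual: float = 0.0

    @property
    def a_hat_g(self) -> np.ndarray:
        """GEBV sub-vector for genotyped animals."""
        if self.genotyped_pos is None:
            raise DataError("no genotyped set attached to this solution")
        return self.a_hat[self.genotyped_pos]


def _check_fixed_rank(model: ModelSpec):
    counts = np.asarray(model.X.sum(axis=0)).ravel()
    empty = np.nonzero(counts == 0)[0]
    if empty.size:
        labels = (
            model.cg_labels[empty]
            if model.cg_labels is not None and len(model.cg_labels) == model.X.shape[1]
            else empty
        )
        raise DataError(
            f"fixed-effect levels with no records (confounded/empty): {list(labels)}"
        )


def build_and_solve_mme(
    model: ModelSpec,
    vc: VarianceComponents,
    genotyped_pos: np.ndarray | None = None,
) -> MMESolution:
    """Solve the MME for the given variance components.

    The relationship inverse comes from ``model.rel_inv`` (A⁻¹ for pedigree
    BLUP, H⁻¹ for single-step).
    """
    if vc.sigma_a2 <= 0 or vc.sigma_e2 <= 0:
        raise DataError("σ²a and σ²e must be strictly positive to build the MME")
    _check_fixed_rank(model)
    lam_a = vc.sigma_e2 / vc.sigma_a2
    use_pe = vc.sigma_pe2 > 0 and model.K is not None
    lam_pe = vc.sigma_e2 / vc.sigma_pe2 if use_pe else None

    blocks = [model.X, model.W] + ([model.K] if use_pe else [])
    T = sp.hstack(blocks).tocsr()
    rhs = T.T @ model.y
    p = model.X.shape[1]
    q = model.W.shape[1]
    n_eq = T.shape[1]

    rel_inv = model.rel_inv
    if n_eq <= DENSE_LIMIT:
        C = (T.T @ T).toarray()
        C[p : p + q, p : p + q] += lam_a * (
            rel_inv.toarray() if sp.issparse(rel_inv) else np.asarray(rel_inv)
        )
        if use_pe:
            C[p + q :, p + q :] += lam_pe * np.eye(n_eq - p - q)
        try:
            cf = sla.cho_factor(C, lower=True, check_finite=False)
        except np.linalg.LinAlgError as exc:
            raise DataError(
                "singular MME coefficient matrix (confounded effects?)"
            ) from exc
        sol = sla.cho_solve(cf, rhs, check_finite=False)
        resid = np.linalg.norm(C @ sol - rhs) / max(np.linalg.norm(rhs), 1e-300)
    else:
        sol, resid = _solve_pcg(T, rel_inv, lam_a, lam_pe, p, q, rhs, use_pe)
    if resid > 1e-8:
        raise DataError(f"MME solve did not reach 1e-8 relative residual ({resid:.2e})")

    b_hat = sol[:p]
    a_hat = sol[p : p + q]
    pe_hat = sol[p + q :] if use_pe else np.zeros(0)
    return MMESolution(
        b_hat=b_hat,
        a_hat=a_hat,
        pe_hat=pe_hat,
        genotyped_pos=genotyped_pos,
        relative_residual=float(resid),
    )


def _solve_pcg(T, rel_inv, lam_a, lam_pe, p, q, rhs, use_pe):
    """Jacobi-preconditioned CG on the MME as a linear operator."""
    n_eq = T.shape[1]
    TtT = (T.T @ T).tocsr()
    rel = rel_inv if sp.issparse(rel_inv) else np.asarray(rel_inv)

    def matvec(x):
        out = TtT @ x
        out[p : p + q] += lam_a * (rel @ x[p : p + q])
        if use_pe:
            out[p + q :] += lam_pe * x[p + q :]
        return out

    diag = TtT.diagonal().astype(float)
    rel_diag = rel.diagonal() if sp.issparse(rel) else np.diag(rel)
    diag[p : p + q] += lam_a * rel_diag
    if use_pe:
        diag[p + q :] += lam_pe
    op = spla.LinearOperator((n_eq, n_eq), matvec=matvec)
    M = spla.LinearOperator((n_eq, n_eq), matvec=lambda x: x / diag)
    sol, info = spla.cg(op, rhs, rtol=1e-12, atol=0.0, maxiter=20 * n_eq, M=M)
    if info != 0:
        raise DataError(f"PCG failed to converge (info={info})")
    resid = np.linalg.norm(matvec(sol) - rhs) / max(np.linalg.norm(rhs), 1e-300)
    return sol, resid


def reliability_diagnostics(
    solution: MMESolution,
    model: ModelSpec,
    true_breeding_values: np.ndarray | None = None,
) -> dict:
    """Per-effect summaries and, when truth is supplied, accuracy of â."""
    report = {
        "b_hat_mean": float(np.mean(solution.b_hat)),
        "b_hat_sd": float(np.std(solution.b_hat)),
        "a_hat_mean": float(np.mean(solution.a_hat)),
        "a_hat_sd": float(np.std(solution.a_hat)),
        "pe_hat_sd": float(np.std(solution.pe_hat)) if solution.pe_hat.size else 0.0,
        "relative_residual": solution.relative_residual,
    }
    if true_breeding_values is not None and len(true_breeding_values):
        a = solution.a_hat
        t = np.asarray(true_breeding_values, dtype=float)
        if len(t) != len(a):
            raise DataError("truth length must match number of animals")
        if np.std(a) > 0 and np.std(t) > 0:
            report["accuracy"] = float(np.corrcoef(a, t)[0, 1])
    return report
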