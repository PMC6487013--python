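"""REML variance components for the single-trait repeatability animal model.

Model:  y = Xb + Wa + K·pe + e, with a ~ N(0, A σ²a) (or H), pe ~ N(0, I σ²pe),
e ~ N(0, I σ²e); contemporary group is the fixed effect. Estimation is
average-information REML with EM-REML fallback steps whenever the AI update
is not positive definite or decreases the restricted likelihood. The
permanent-environment equations are absorbed before factorisation (their
coefficient block is diagonal), which is algebraically exact and keeps the
dense factorisation at pedigree size.

Narrow-sense heritability: h² = σ²a / (σ²a + σ²pe + σ²e).
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import scipy.linalg as sla
import scipy.sparse as sp

from .errors import ConvergenceError, DataError
from .relationship import Pedigree, compute_A_inverse

log = logging.getLogger(__name__)


@dataclass
class ModelSpec:
    """Design matrices and relationship inverse for one repeatability model."""

    y: np.ndarray
    X: sp.csr_matrix  # records × contemporary groups (one-hot)
    W: sp.csr_matrix  # records × pedigree animals
    K: sp.csr_matrix | None  # records × animals-with-records (pe); None = no pe
    rel_inv: sp.spmatrix | np.ndarray  # A⁻¹ or H⁻¹, animals × animals
    animal_labels: np.ndarray | None = None
    cg_labels: np.ndarray | None = None
    pe_labels: np.ndarray | None = None

    def __post_init__(self):
        n = len(self.y)
        if self.K is None:
            self.K = sp.csr_matrix((n, 0))
        for name in ("X", "W", "K"):
            mat = getattr(self, name)
            if mat.shape[0] != n:
                raise DataError(f"{name} row count must equal length of y")
        if self.W.shape[1] != self.rel_inv.shape[0]:
            raise DataError("relationship inverse must conform with W columns")

    @property
    def n_records(self) -> int:
        return len(self.y)

    @property
    def n_animals(self) -> int:
        return self.W.shape[1]


@dataclass
class VarianceComponents:
    """σ²a, σ²pe, σ²e with optional standard errors and derived h²."""

    sigma_a2: float
    sigma_pe2: float
    sigma_e2: float
    se: dict = field(default_factory=dict)
    h2_se: float | None = None
    converged: bool = True
    n_iterations: int = 0
    degenerate: bool = False
    trajectory: list = field(default_factory=list)

    @property
    def total(self) -> float:
        return self.sigma_a2 + self.sigma_pe2 + self.sigma_e2

    @property
    def h2(self) -> float:
        return heritability(self)


def heritability(vc: VarianceComponents) -> float:
    """h² = σ²a / (σ²a + σ²pe + σ²e)."""
    total = vc.sigma_a2 + vc.sigma_pe2 + vc.sigma_e2
    if total <= 0.0:
        raise DataError("heritability undefined: all variance components are zero")
    return vc.sigma_a2 / total


def build_model_spec(
    phenotypes: pd.DataFrame,
    pedigree: Pedigree,
    rel_inv: sp.spmatrix | np.ndarray | None = None,
) -> ModelSpec:
    """Incidence matrices from a (animal, cg, parity, value) record table.

    ``rel_inv`` defaults to the pedigree A⁻¹; pass an H⁻¹ for single-step
    prediction. Animals with records must appear in the pedigree.
    """
    if phenotypes.empty:
        raise DataError("phenotype table is empty")
    n = len(phenotypes)
    y = phenotypes["value"].to_numpy(dtype=float)
    cg_codes, cg_labels = pd.factorize(phenotypes["cg"], sort=True)
    X = sp.csr_matrix(
        (np.ones(n), (np.arange(n), cg_codes)), shape=(n, len(cg_labels))
    )
    animal_pos = pedigree.position_of(phenotypes["animal"].to_numpy())
    W = sp.csr_matrix(
        (np.ones(n), (np.arange(n), animal_pos)), shape=(n, len(pedigree))
    )
    pe_codes, pe_labels_pos = pd.factorize(animal_pos, sort=True)
    K = sp.csr_matrix(
        (np.ones(n), (np.arange(n), pe_codes)), shape=(n, len(pe_labels_pos))
    )
    if rel_inv is None:
        rel_inv = compute_A_inverse(pedigree)
    return ModelSpec(
        y=y,
        X=X,
        W=W,
        K=K,
        rel_inv=rel_inv,
        animal_labels=pedigree.ids,
        cg_labels=np.asarray(cg_labels),
        pe_labels=pedigree.ids[np.asarray(pe_labels_pos)],
    )


class _AbsorbedMME:
    """Mixed-model equations with the diagonal pe block absorbed.

    Holds everything that does not change across REML iterations; per-
    iteration work is one dense Cholesky of the reduced system (fixed +
    animal equations) plus its inverse for the traces.
    """

    def __init__(self, model: ModelSpec):
        self.model = model
        X, W, K = model.X, model.W, model.K
        self.U = sp.hstack([X, W]).tocsr()
        self.UtU = (self.U.T @ self.U).toarray()
        self.UtK = (self.U.T @ K).tocsr()
        self.KtK_diag = np.asarray(K.multiply(K).sum(axis=0)).ravel()
        self.Uty = self.U.T @ model.y
        self.Kty = K.T @ model.y
        self.yty = float(model.y @ model.y)
        self.p = X.shape[1]
        self.q = W.shape[1]
        self.q_pe = K.shape[1]
        Ainv = model.rel_inv
        self.Ainv = sp.csr_matrix(Ainv) if not sp.issparse(Ainv) else Ainv.tocsr()
        self._Ainv_dense = self.Ainv.toarray()

    def factorize(self, lam_a: float, lam_pe: float):
        d_pe = self.KtK_diag + lam_pe
        C = self.UtU.copy()
        C[self.p :, self.p :] += lam_a * self._Ainv_dense
        V = (self.UtK.multiply(1.0 / d_pe)).tocsr()  # U'K D⁻¹
        C -= (V @ self.UtK.T).toarray()
        cf = sla.cho_factor(C, lower=True, check_finite=False)
        return _Factor(self, cf, d_pe, V, C)


class _Factor:
    def __init__(self, mme, cf, d_pe, V, C):
        self.mme = mme
        self.cf = cf
        self.d_pe = d_pe
        self.V = V  # U'K D⁻¹, sparse
        self.logdet = 2.0 * np.sum(np.log(np.diag(cf[0]))) + np.sum(np.log(d_pe))
        self._Cinv = None

    def solve(self, f: np.ndarray):
        """Solutions (b,a | pe) for data vector f."""
        mme = self.mme
        Ktf = mme.model.K.T @ f
        rhs = (mme.U.T @ f) - self.V @ Ktf
        theta = sla.cho_solve(self.cf, rhs, check_finite=False)
        pe = (Ktf - (mme.UtK.T @ theta)) / self.d_pe
        return theta, pe

    def P_times(self, f: np.ndarray, sigma_e2: float):
        theta, pe = self.solve(f)
        fitted = self.mme.U @ theta + self.mme.model.K @ pe
        return (f - fitted) / sigma_e2

    @property
    def Cinv(self) -> np.ndarray:
        if self._Cinv is None:
            n = self.mme.p + self.mme.q
            self._Cinv = sla.cho_solve(self.cf, np.eye(n), check_finite=False)
        return self._Cinv

    def traces(self):
        """(tr(A⁻¹ C^aa), tr(C^pepe)) of the FULL coefficient inverse."""
        mme = self.mme
        Caa = self.Cinv[mme.p :, mme.p :]
        tr_a = float(np.sum(mme.Ainv.multiply(Caa)))
        # C^pepe = D⁻¹ + D⁻¹K'U C_red⁻¹ U'K D⁻¹ ; V = U'K D⁻¹
        S = self.V.T @ self.Cinv  # (q_pe × (p+q)), cheap: V is sparse
        tr_pe = float(np.sum(1.0 / self.d_pe) + self.V.T.multiply(S).sum())
        return tr_a, tr_pe


def _minus2_logL(fac: _Factor, theta, pe, sigma, yty, Uty, Kty, n, p, q, q_pe):
    sa, spe, se = sigma
    ypy = (yty - theta @ Uty - pe @ Kty) / se
    # |M| of the full λ-form system = |D_pe| · |C_red|; convert to the
    # σ-scaled coefficient matrix determinant via the standard bookkeeping.
    return (
        (n - p - q - q_pe) * np.log(se)
        + q * np.log(sa)
        + q_pe * np.log(spe)
        + fac.logdet
        + ypy
    )


def estimate_reml(
    model: ModelSpec,
    init: VarianceComponents | None = None,
    tol: float = 1e-8,
    max_iter: int = 200,
    compute_se: bool = True,
) -> VarianceComponents:
    """AI-REML with EM fallback for (σ²a, σ²pe, σ²e).

    Convergence: relative change of every component < ``tol``. Components
    that collapse are clamped at a small positive floor and flagged.
    Raises :class:`ConvergenceError` (carrying the trajectory) if
    ``max_iter`` is exhausted.
    """
    y = model.y
    var_y = float(np.var(y))
    if var_y == 0.0:
        warnings.warn("phenotypes have zero variance; returning degenerate fit")
        return VarianceComponents(0.0, 0.0, 0.0, degenerate=True, n_iterations=0)

    mme = _AbsorbedMME(model)
    n, p, q, q_pe = model.n_records, mme.p, mme.q, mme.q_pe
    if init is None:
        third = var_y / 3.0
        sigma = np.array([third, third, third])
    else:
        sigma = np.array([init.sigma_a2, init.sigma_pe2, init.sigma_e2], dtype=float)
        if np.any(sigma <= 0):
            raise DataError("initial variance components must be positive")
    floor = 1e-8 * var_y
    pin_level = 1e-7 * var_y  # value a boundary component is held at
    pin_threshold = 1e-5 * var_y
    pinned = np.zeros(3, dtype=bool)  # σ²e is never pinned
    no_pe = q_pe == 0
    if no_pe:
        pinned[1] = True  # no permanent-environment effect in the model
        sigma[1] = pin_level if init is None else sigma[1]
    trajectory = []
    prev_m2ll = np.inf
    converged = False
    fac = None

    for it in range(1, max_iter + 1):
        sa, spe, se = sigma
        fac = mme.factorize(se / sa, se / spe)
        theta, pe = fac.solve(y)
        a_hat = theta[p:]
        ehat = y - (mme.U @ theta + model.K @ pe)
        tr_a, tr_pe = fac.traces()
        aAa = float(a_hat @ (mme.Ainv @ a_hat))
        pepe = float(pe @ pe)
        m2ll = _minus2_logL(
            fac, theta, pe, sigma, mme.yty, mme.Uty, mme.Kty, n, p, q, q_pe
        )
        trajectory.append((it, *sigma, m2ll))

        # EM fixed-point updates (always uphill; also the fallback step)
        em = np.array(
            [
                (aAa + se * tr_a) / q,
                (pepe + se * tr_pe) / q_pe if q_pe else 0.0,
                (mme.yty - theta @ mme.Uty - pe @ mme.Kty) / (n - p),
            ]
        )

        # gradient of log-likelihood
        g = np.array(
            [
                -0.5 * (q / sa - (se * tr_a + aAa) / sa**2),
                -0.5 * (q_pe / spe - (se * tr_pe + pepe) / spe**2),
                -0.5
                * (
                    (n - p - q + (se / sa) * tr_a - q_pe + (se / spe) * tr_pe) / se
                    - (ehat @ ehat) / se**2
                ),
            ]
        )

        # average-information matrix from working variates
        fa = (model.W @ a_hat) / sa
        fpe = (model.K @ pe) / spe
        fe = ehat / se
        Pf = [fac.P_times(f, se) for f in (fa, fpe, fe)]
        F = np.column_stack([fa, fpe, fe])
        AI = 0.5 * (F.T @ np.column_stack(Pf))
        AI = (AI + AI.T) / 2.0

        # components collapsing toward the zero boundary are pinned there and
        # removed from the update (AI turns singular otherwise); σ²e stays free
        for i in (0, 1):
            if not pinned[i] and em[i] < pin_threshold and sigma[i] < pin_threshold:
                pinned[i] = True
        active = np.nonzero(~pinned)[0]

        step_ok = False
        try:
            delta = np.zeros(3)
            delta[active] = np.linalg.solve(AI[np.ix_(active, active)], g[active])
            lam = 1.0
            for _ in range(12):
                cand = sigma + lam * delta
                cand[pinned] = pin_level
                if np.all(cand > floor):
                    cf2 = mme.factorize(cand[2] / cand[0], cand[2] / cand[1])
                    th2, pe2 = cf2.solve(y)
                    m2 = _minus2_logL(
                        cf2, th2, pe2, cand, mme.yty, mme.Uty, mme.Kty, n, p, q, q_pe
                    )
                    if m2 <= m2ll + 1e-10:
                        new_sigma = cand
                        step_ok = True
                        break
                lam *= 0.5
        except np.linalg.LinAlgError:
            pass
        if not step_ok:
            new_sigma = np.maximum(em, floor)
            new_sigma[pinned] = pin_level

        rel = np.abs(new_sigma[active] - sigma[active]) / np.maximum(
            sigma[active], floor
        )
        sigma = new_sigma
        if (rel.size == 0 or np.max(rel) < tol) or abs(prev_m2ll - m2ll) < 1e-9:
            converged = True
            break
        prev_m2ll = m2ll

    if not converged:
        raise ConvergenceError(
            f"REML did not converge in {max_iter} iterations", trajectory=trajectory
        )

    sigma[pinned] = 0.0  # boundary components reported as exactly zero
    sa, spe, se = sigma
    vc = VarianceComponents(
        float(sa),
        float(spe),
        float(se),
        converged=True,
        n_iterations=it,
        degenerate=bool(
            np.any(pinned & np.array([True, not no_pe, True]))
            or np.any(sigma[~pinned] <= floor * 1.01)
        ),
        trajectory=trajectory,
    )
    if vc.degenerate:
        warnings.warn("a variance component converged to the zero boundary")
    if compute_se:
        try:
            cov = np.linalg.inv(AI)
            vc.se = {
                "sigma_a2": float(np.sqrt(max(cov[0, 0], 0.0))),
                "sigma_pe2": float(np.sqrt(max(cov[1, 1], 0.0))),
                "sigma_e2": float(np.sqrt(max(cov[2, 2], 0.0))),
            }
            # delta method for h² = sa / (sa+spe+se)
            t = sa + spe + se
            grad = np.array([(t - sa) / t**2, -sa / t**2, -sa / t**2])
            vc.h2_se = float(np.sqrt(max(grad @ cov @ grad, 0.0)))
        except np.linalg.LinAlgError:
            log.warning("AI matrix singular at convergence; no standard errors")
    return vc


def reml_loglik_direct(model: ModelSpec, sigma_a2, sigma_pe2, sigma_e2) -> float:
    """−2·restricted log-likelihood by dense V algebra (small n only).

    Independent of the MME machinery; used as a cross-check oracle.
    """
    n = model.n_records
    if n > 2000:
        raise DataError("direct likelihood is for small instances only")
    W = model.W.toarray()
    K = model.K.toarray()
    X = model.X.toarray()
    Ainv = (
        model.rel_inv.toarray() if sp.issparse(model.rel_inv) else np.asarray(model.rel_inv)
    )
    A = np.linalg.inv(Ainv)
    V = sigma_a2 * W @ A @ W.T + sigma_pe2 * K @ K.T + sigma_e2 * np.eye(n)
    Vi = np.linalg.inv(V)
    XtViX = X.T @ Vi @ X
    beta = np.linalg.solve(XtViX, X.T @ Vi @ model.y)
    r = model.y - X @ beta
    _, ld_v = np.linalg.slogdet(V)
    _, ld_x = np.linalg.slogdet(XtViX)
    return float(ld_v + ld_x + r @ Vi @ r)
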