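"""Weighted single-step GWAS: SNP back-solving, iterative reweighting and
1-Mb window variance decomposition.

SNP effects are recovered from the GEBV of genotyped animals as

    û = λ D Z' G⁻¹ â_g,   λ = σ²u/σ²a = 1 / (2 Σ pᵢ(1−pᵢ)),

per-SNP weights are updated as dᵢ = ûᵢ²·2pᵢ(1−pᵢ) and renormalised so
Σdᵢ equals the SNP count (the additive variance stays constant), and the
percentage of additive variance explained by a window is

    var(Σⱼ zⱼûⱼ) / σ²a × 100

with the variance taken across genotyped animals (population variance).
The iteration is: (i) D = I; (ii) build G; (iii) GEBV by ssGBLUP; (iv)
back-solve SNP effects; (v) weights; (vi) normalise D; (vii) repeat from
(ii). Iteration 1 is therefore the unweighted ssGWAS.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass

import numpy as np
import scipy.linalg as sla

from .errors import DataError
from .relationship import (
    GenotypePanel,
    Pedigree,
    blend_G,
    compute_A,
    compute_A_inverse,
    compute_G,
    compute_H_inverse,
)
from .reml import ModelSpec, VarianceComponents
from .ssgblup import MMESolution, build_and_solve_mme

log = logging.getLogger(__name__)


@dataclass
class SnpEffects:
    """Per-SNP allele-substitution effects and weights for one iteration."""

    u_hat: np.ndarray
    d: np.ndarray
    lambda_ratio: float
    iteration: int

    def __post_init__(self):
        if len(self.u_hat) != len(self.d):
            raise DataError("u_hat and d must have equal length")


@dataclass
class WindowResult:
    """A 1-Mb SNP window and the share of additive variance it explains."""

    chrom: int
    start_bp: int
    end_bp: int
    n_snps: int
    pct_variance: float

    def __post_init__(self):
        if self.end_bp - self.start_bp >= 1_000_000 or self.end_bp < self.start_bp:
            # window span is bounded by the sliding-window definition
            raise DataError("window span must be positive and under 1 Mb")

    def overlaps(self, other: "WindowResult") -> bool:
        return self.chrom == other.chrom and not (
            self.end_bp < other.start_bp or other.end_bp < self.start_bp
        )


def snp_variance_ratio(panel: GenotypePanel) -> float:
    """λ = 1/(2Σpᵢ(1−pᵢ)) at the panel's current allele frequencies."""
    p = panel.allele_frequencies()
    return 1.0 / (2.0 * np.sum(p * (1.0 - p)))


def backsolve_snp_effects(
    panel: GenotypePanel,
    G_inv: np.ndarray,
    a_hat_g: np.ndarray,
    d: np.ndarray | None = None,
    iteration: int = 1,
) -> SnpEffects:
    """û = λ D Z' G⁻¹ â_g with Z centred by twice the current frequencies."""
    if G_inv.shape[0] != panel.n_samples or len(a_hat_g) != panel.n_samples:
        raise DataError("G⁻¹ and â_g must conform with the genotyped set")
    if d is None:
        d = np.ones(panel.n_snps)
    d = np.asarray(d, dtype=float)
    if len(d) != panel.n_snps:
        raise DataError("weights length must equal SNP count")
    p = panel.allele_frequencies()
    lam = 1.0 / (2.0 * np.sum(p * (1.0 - p)))
    Z = panel.genotypes.astype(np.float64) - 2.0 * p
    u_hat = lam * d * (Z.T @ (G_inv @ a_hat_g))
    return SnpEffects(u_hat=u_hat, d=d, lambda_ratio=float(lam), iteration=iteration)


def update_weights(effects: SnpEffects, panel: GenotypePanel) -> np.ndarray:
    """dᵢ = ûᵢ²·2pᵢ(1−pᵢ), normalised so Σdᵢ equals the SNP count."""
    p = panel.allele_frequencies()
    raw = effects.u_hat**2 * 2.0 * p * (1.0 - p)
    total = raw.sum()
    if total == 0.0:
        warnings.warn("all SNP effects are zero; resetting weights to 1")
        return np.ones(panel.n_snps)
    return raw * (panel.n_snps / total)


def window_variance(
    effects: SnpEffects,
    panel: GenotypePanel,
    sigma_a2: float,
    window_bp: int = 1_000_000,
) -> list[WindowResult]:
    """Sliding windows: one starting at every SNP, extending < ``window_bp``.

    Each window's genetic value per genotyped animal is Σⱼ zⱼûⱼ over its
    SNPs; the reported percentage is the population variance of that value
    across animals divided by σ²a, ×100. Windows are reported with the
    positions of their actual first and last SNP.
    """
    if sigma_a2 <= 0:
        raise DataError("σ²a must be positive to express window variance")
    p = panel.allele_frequencies()
    Z = panel.genotypes.astype(np.float64) - 2.0 * p
    S = Z * effects.u_hat  # per-animal, per-SNP genetic contribution
    results: list[WindowResult] = []
    for c in np.unique(panel.chrom):
        mask = panel.chrom == c
        pos = panel.pos_bp[mask]
        Sc = S[:, mask]
        m = len(pos)
        # prefix sums over the SNP axis make every window an O(n) subtraction
        cs = np.concatenate([np.zeros((Sc.shape[0], 1)), np.cumsum(Sc, axis=1)], axis=1)
        ends = np.searchsorted(pos, pos + window_bp, side="left")  # exclusive
        for j in range(m):
            e = ends[j]
            score = cs[:, e] - cs[:, j]
            var = float(np.var(score))  # population variance across animals
            results.append(
                WindowResult(
                    chrom=int(c),
                    start_bp=int(pos[j]),
                    end_bp=int(pos[e - 1]),
                    n_snps=int(e - j),
                    pct_variance=var / sigma_a2 * 100.0,
                )
            )
    return results


def select_significant_windows(
    windows: list[WindowResult],
    threshold_pct: float = 1.0,
    collapse: bool = True,
) -> list[WindowResult]:
    """Windows above the variance threshold, overlap-collapsed by default.

    Collapsing keeps, among each set of mutually overlapping survivors, the
    window with the highest percentage (ties: leftmost), so one QTL region
    is reported once with its actual SNP span.
    """
    surv = [w for w in windows if w.pct_variance > threshold_pct and w.n_snps > 0]
    if not collapse:
        return sorted(surv, key=lambda w: (w.chrom, w.start_bp))
    kept: list[WindowResult] = []
    for w in sorted(surv, key=lambda w: (-w.pct_variance, w.chrom, w.start_bp)):
        if not any(w.overlaps(k) for k in kept):
            kept.append(w)
    return sorted(kept, key=lambda w: (w.chrom, w.start_bp))


def run_wssgwas(
    model: ModelSpec,
    pedigree: Pedigree,
    panel: GenotypePanel,
    vc: VarianceComponents,
    n_iter: int = 2,
    beta: float = 0.05,
    window_bp: int = 1_000_000,
) -> tuple[list[SnpEffects], list[WindowResult], MMESolution]:
    """Full weighted single-step GWAS.

    Variance components are estimated once, outside this loop, and held
    fixed. Returns the per-iteration SNP effects (iteration 1 is the
    unweighted pass), the final iteration's window decomposition, and the
    final MME solution. ``model.rel_inv`` is replaced each iteration by the
    H⁻¹ built from the current weights.
    """
    if n_iter < 1:
        raise DataError("n_iter must be at least 1")
    A22 = compute_A(pedigree, subset=panel.sample_pos)
    A_inv = compute_A_inverse(pedigree)
    d = np.ones(panel.n_snps)
    all_effects: list[SnpEffects] = []
    solution = None
    for it in range(1, n_iter + 1):
        G = blend_G(compute_G(panel, d), A22, beta)
        try:
            c, low = sla.cho_factor(G, check_finite=False)
        except np.linalg.LinAlgError as exc:
            raise DataError(
                "weighted G became singular; extreme weight concentration — "
                "use fewer iterations"
            ) from exc
        G_inv = sla.cho_solve((c, low), np.eye(len(G)), check_finite=False)
        H_inv = compute_H_inverse(A_inv, A22, G, panel.sample_pos)
        model.rel_inv = H_inv
        solution = build_and_solve_mme(model, vc, genotyped_pos=panel.sample_pos)
        # a_hat_g indexes genotyped animals in pedigree order == panel rows
        effects = backsolve_snp_effects(
            panel, G_inv, solution.a_hat_g, d, iteration=it
        )
        all_effects.append(effects)
        d = update_weights(effects, panel)
    windows = window_variance(all_effects[-1], panel, vc.sigma_a2, window_bp)
    return all_effects, windows, solution
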