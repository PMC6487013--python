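"""Pedigree and genomic relationship structures for single-step evaluation.

Builds the numerator relationship matrix A (tabular method), its sparse
inverse (Henderson's rules with Meuwissen–Luo inbreeding), the genomic
relationship matrix G from centred genotypes with optional per-SNP weights,
the 5% blend of G with A22, and the combined single-step inverse H⁻¹:

    H⁻¹ = A⁻¹ + [0 0; 0 G⁻¹ − A22⁻¹]

All matrices are ordered as the pedigree; the genotyped block is addressed
by integer indices into that ordering.
"""

from __future__ import annotations

import heapq
from dataclasses import dataclass, field

import numpy as np
import scipy.linalg as sla
import scipy.sparse as sp

from .errors import DataError, PedigreeError

UNKNOWN = -1


@dataclass
class Pedigree:
    """Topologically ordered pedigree with per-animal inbreeding.

    ``sire``/``dam`` are integer positions into the same ordering
    (:data:`UNKNOWN` for missing parents); ``ids`` carries the original
    labels. Inbreeding coefficients are computed on construction by the
    Meuwissen–Luo algorithm.
    """

    ids: np.ndarray
    sire: np.ndarray
    dam: np.ndarray
    sex: np.ndarray | None = None  # 0 = male, 1 = female
    inbreeding: np.ndarray = field(default=None)  # type: ignore[assignment]

    def __post_init__(self):
        self.sire = np.asarray(self.sire, dtype=np.int64)
        self.dam = np.asarray(self.dam, dtype=np.int64)
        self.ids = np.asarray(self.ids)
        n = len(self.ids)
        if len(self.sire) != n or len(self.dam) != n:
            raise PedigreeError("ids, sire and dam must have equal length")
        for name, par in (("sire", self.sire), ("dam", self.dam)):
            bad = np.nonzero((par >= np.arange(n)) & (par != UNKNOWN))[0]
            if bad.size:
                raise PedigreeError(
                    f"{name} of animal at position {bad[0]} does not precede it; "
                    "pedigree must be topologically ordered"
                )
        if self.inbreeding is None:
            self.inbreeding = meuwissen_luo_inbreeding(self.sire, self.dam)

    def __len__(self) -> int:
        return len(self.ids)

    @property
    def n_animals(self) -> int:
        return len(self.ids)

    def position_of(self, labels) -> np.ndarray:
        """Map id labels to positions in pedigree order."""
        lookup = {lab: i for i, lab in enumerate(self.ids.tolist())}
        try:
            return np.array([lookup[lab] for lab in np.asarray(labels).tolist()])
        except KeyError as exc:
            raise PedigreeError(f"unknown animal id {exc.args[0]!r}") from exc


@dataclass
class GenotypePanel:
    """Genotyped subset of a pedigree with 0/1/2 SNP codes and a map.

    ``sample_pos`` holds pedigree positions of the genotyped animals, in the
    row order of ``genotypes``. Allele frequencies are the "current"
    frequencies, i.e. computed from the genotyped sample itself.
    """

    sample_ids: np.ndarray
    sample_pos: np.ndarray
    genotypes: np.ndarray  # (n_genotyped, n_snps), values in {0,1,2}
    snp_ids: np.ndarray
    chrom: np.ndarray
    pos_bp: np.ndarray

    def __post_init__(self):
        self.genotypes = np.asarray(self.genotypes)
        self.chrom = np.asarray(self.chrom, dtype=np.int64)
        self.pos_bp = np.asarray(self.pos_bp, dtype=np.int64)
        order = np.lexsort((self.pos_bp, self.chrom))
        if not np.array_equal(order, np.arange(len(order))):
            raise DataError("SNP map must be sorted by (chromosome, position)")

    @property
    def n_samples(self) -> int:
        return self.genotypes.shape[0]

    @property
    def n_snps(self) -> int:
        return self.genotypes.shape[1]

    def allele_frequencies(self) -> np.ndarray:
        return self.genotypes.mean(axis=0) / 2.0

    def drop_monomorphic(self) -> tuple["GenotypePanel", int]:
        """Return a panel without monomorphic SNPs and the dropped count."""
        p = self.allele_frequencies()
        keep = (p > 0.0) & (p < 1.0)
        dropped = int((~keep).sum())
        if dropped == 0:
            return self, 0
        return (
            GenotypePanel(
                self.sample_ids,
                self.sample_pos,
                self.genotypes[:, keep],
                self.snp_ids[keep],
                self.chrom[keep],
                self.pos_bp[keep],
            ),
            dropped,
        )


@dataclass
class RelationshipMatrices:
    """Bundle of the matrices a single-step evaluation needs."""

    G: np.ndarray
    A22: np.ndarray
    H_inverse: np.ndarray
    genotyped_pos: np.ndarray


def meuwissen_luo_inbreeding(sire: np.ndarray, dam: np.ndarray) -> np.ndarray:
    """Inbreeding coefficients without forming A.

    Walks each animal's ancestor tree accumulating L-row contributions;
    O(n·ancestors) time, O(n) memory. Animals with any unknown parent get
    F = 0 (founder convention).
    """
    n = len(sire)
    F = np.zeros(n)
    # Mendelian-sampling variance d_j depends only on parental inbreeding.
    for i in range(n):
        s, d = sire[i], dam[i]
        if s == UNKNOWN or d == UNKNOWN:
            continue
        weights: dict[int, float] = {i: 1.0}
        heap = [-i]
        a_ii = 0.0
        while heap:
            j = -heapq.heappop(heap)
            lj = weights.pop(j, 0.0)
            if lj == 0.0:
                continue
            sj, dj = sire[j], dam[j]
            if sj != UNKNOWN and dj != UNKNOWN:
                dvar = 0.5 - 0.25 * (F[sj] + F[dj])
            elif sj != UNKNOWN or dj != UNKNOWN:
                known = sj if sj != UNKNOWN else dj
                dvar = 0.75 - 0.25 * F[known]
            else:
                dvar = 1.0
            a_ii += lj * lj * dvar
            for par in (sj, dj):
                if par != UNKNOWN:
                    if par in weights:
                        weights[par] += 0.5 * lj
                    else:
                        weights[par] = 0.5 * lj
                        heapq.heappush(heap, -par)
        F[i] = a_ii - 1.0
    return F


def compute_A(pedigree: Pedigree, subset=None) -> np.ndarray:
    """Numerator relationship matrix by the tabular (recursive) method.

    ``subset`` restricts the returned matrix to the given pedigree
    positions (the full recursion is still run; desk-scale pedigrees only).
    """
    n = len(pedigree)
    sire, dam = pedigree.sire, pedigree.dam
    A = np.zeros((n, n))
    for i in range(n):
        s, d = sire[i], dam[i]
        if s != UNKNOWN and d != UNKNOWN:
            A[i, :i] = 0.5 * (A[s, :i] + A[d, :i])
            A[i, i] = 1.0 + 0.5 * A[s, d]
        elif s != UNKNOWN or d != UNKNOWN:
            p = s if s != UNKNOWN else d
            A[i, :i] = 0.5 * A[p, :i]
            A[i, i] = 1.0
        else:
            A[i, i] = 1.0
        A[:i, i] = A[i, :i]
    if subset is not None:
        idx = np.asarray(subset, dtype=np.int64)
        return A[np.ix_(idx, idx)]
    return A


def compute_A_inverse(pedigree: Pedigree) -> sp.csr_matrix:
    """Sparse A⁻¹ via Henderson's rules with inbreeding.

    Uses the Meuwissen–Luo coefficients stored on the pedigree, so the
    product with :func:`compute_A` is the identity also for inbred
    pedigrees.
    """
    n = len(pedigree)
    F = pedigree.inbreeding
    rows, cols, vals = [], [], []

    def add(i, j, v):
        rows.append(i)
        cols.append(j)
        vals.append(v)

    for i in range(n):
        s, d = pedigree.sire[i], pedigree.dam[i]
        if s != UNKNOWN and d != UNKNOWN:
            b = 0.5 - 0.25 * (F[s] + F[d])
        elif s != UNKNOWN or d != UNKNOWN:
            known = s if s != UNKNOWN else d
            b = 0.75 - 0.25 * F[known]
        else:
            b = 1.0
        alpha = 1.0 / b
        add(i, i, alpha)
        for par in (s, d):
            if par != UNKNOWN:
                add(i, par, -alpha / 2.0)
                add(par, i, -alpha / 2.0)
                add(par, par, alpha / 4.0)
        if s != UNKNOWN and d != UNKNOWN:
            add(s, d, alpha / 4.0)
            add(d, s, alpha / 4.0)
    return sp.csr_matrix((vals, (rows, cols)), shape=(n, n))


def compute_G(panel: GenotypePanel, weights: np.ndarray | None = None) -> np.ndarray:
    """Genomic relationship G = Z D Z' / (2 Σ pᵢ(1−pᵢ)).

    Z is the 0/1/2 genotype matrix centred by twice the current allele
    frequencies; D = diag(weights), identity when ``weights`` is None.
    """
    p = panel.allele_frequencies()
    if np.any((p <= 0.0) | (p >= 1.0)):
        raise DataError(
            "monomorphic SNPs present; filter them upstream "
            "(GenotypePanel.drop_monomorphic) before building G"
        )
    Z = panel.genotypes.astype(np.float64) - 2.0 * p
    denom = 2.0 * np.sum(p * (1.0 - p))
    if weights is None:
        G = (Z @ Z.T) / denom
    else:
        w = np.asarray(weights, dtype=np.float64)
        if w.shape != (panel.n_snps,):
            raise DataError("weights length must equal SNP count")
        if np.any(w < 0):
            raise DataError("SNP weights must be non-negative")
        G = ((Z * w) @ Z.T) / denom
    return (G + G.T) / 2.0


def blend_G(G: np.ndarray, A22: np.ndarray, beta: float = 0.05) -> np.ndarray:
    """(1−β)·G + β·A22 — guards against a singular G."""
    if not 0.0 <= beta <= 1.0:
        raise DataError(f"blending proportion must be in [0, 1], got {beta}")
    if G.shape != A22.shape:
        raise DataError("G and A22 must be conformable")
    return (1.0 - beta) * G + beta * A22


def compute_H_inverse(
    A_inv: sp.spmatrix | np.ndarray,
    A22: np.ndarray,
    G_blended: np.ndarray,
    genotyped_pos: np.ndarray,
) -> np.ndarray:
    """Dense H⁻¹: A⁻¹ plus (G⁻¹ − A22⁻¹) in the genotyped block."""
    H = A_inv.toarray() if sp.issparse(A_inv) else np.array(A_inv, dtype=float)
    idx = np.asarray(genotyped_pos, dtype=np.int64)
    if idx.size == 0:
        return H
    try:
        c, low = sla.cho_factor(G_blended, check_finite=False)
        G_inv = sla.cho_solve((c, low), np.eye(len(G_blended)), check_finite=False)
    except np.linalg.LinAlgError as exc:
        raise DataError(
            "blended G is singular; increase the blending proportion beta"
        ) from exc
    A22_inv = sla.inv(A22, check_finite=False)
    H[np.ix_(idx, idx)] += G_inv - A22_inv
    return (H + H.T) / 2.0


def single_step_matrices(
    pedigree: Pedigree,
    panel: GenotypePanel,
    weights: np.ndarray | None = None,
    beta: float = 0.05,
) -> RelationshipMatrices:
    """Convenience: A22, (blended) G and H⁻¹ for one panel in one call."""
    A22 = compute_A(pedigree, subset=panel.sample_pos)
    G = blend_G(compute_G(panel, weights), A22, beta)
    A_inv = compute_A_inverse(pedigree)
    H_inv = compute_H_inverse(A_inv, A22, G, panel.sample_pos)
    return RelationshipMatrices(G, A22, H_inv, np.asarray(panel.sample_pos))
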