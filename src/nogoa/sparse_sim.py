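"""Sparse-representation semantic similarity between genes.

Each gene's propagated annotation row A(i, .) is reconstructed as a sparse
nonnegative combination of the other genes' rows:

    min_{g >= 0}  1/2 || A(i,.) - g^T A_-i ||_2^2 + lambda * ||g||_1

The coefficient g_j measures how much gene j contributes to reconstructing
gene i, i.e. their semantic similarity. Collecting the coefficient vectors
row-wise (with a zero diagonal) and symmetrising S <- (S + S^T)/2 yields the
similarity matrix used for weighted kNN-style voting: the aggregated vote of
term t for gene i is V_SR(i, t) = sum_j S(i, j) A(j, t). Terms annotated to
a gene but rarely to its (automatically selected) neighbours receive low
votes and are candidate noisy annotations.

The solver contract is the KKT condition of the nonnegative lasso, not a
named algorithm: for every coordinate j with gradient g_j of the smooth
part, g_j + lambda ~ 0 if the coefficient is active and g_j + lambda >= 0
otherwise.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import scipy.sparse as sp
from sklearn.linear_model import Lasso

from .gaf import GeneTermMatrix

#: coefficients below this are reported as exact zeros
ZERO_TOL = 1e-10

#: KKT residual the solver polishes to (contract allows 1e-4)
KKT_TOL = 1e-6


@dataclass
class SparseCode:
    """Nonnegative sparse code of one gene against the others."""

    gene_index: int
    coefficients: np.ndarray
    lam: float
    objective: float
    kkt_residual: float

    @property
    def support(self) -> np.ndarray:
        return np.flatnonzero(self.coefficients > ZERO_TOL)


@dataclass
class SimilarityMatrix:
    """Symmetric, zero-diagonal, nonnegative gene x gene similarity."""

    genes: list[str]
    values: np.ndarray

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        n = len(self.genes)
        if self.values.shape != (n, n):
            raise ValueError("similarity shape does not match gene list")


@dataclass
class VoteMatrix:
    """Genes x terms matrix of aggregated votes or fused scores."""

    genes: list[str]
    terms: list[str]
    values: np.ndarray
    kind: str  # "V_SR", "A_ec" or "fused"
    alpha: float | None = None


def sparse_objective(
    gamma: np.ndarray, target: np.ndarray, design: np.ndarray, lam: float
) -> float:
    """1/2 ||target - design @ gamma||^2 + lam * sum(gamma) for gamma >= 0."""
    resid = target - design @ gamma
    return 0.5 * float(resid @ resid) + lam * float(np.sum(gamma))


def kkt_residual(
    gamma: np.ndarray, target: np.ndarray, design: np.ndarray, lam: float
) -> float:
    """Max violation of the nonnegative-lasso stationarity conditions."""
    grad = design.T @ (design @ gamma - target)
    active = gamma > ZERO_TOL
    viol = np.zeros_like(gamma)
    viol[active] = np.abs(grad[active] + lam)
    viol[~active] = np.maximum(0.0, -(grad[~active] + lam))
    return float(viol.max(initial=0.0))


def _cd_polish(
    gamma: np.ndarray,
    target: np.ndarray,
    design: np.ndarray,
    lam: float,
    tol: float = KKT_TOL,
    max_sweeps: int = 200,
) -> np.ndarray:
    """Exact coordinate-descent sweeps until the KKT residual is <= tol."""
    norms = np.einsum("ij,ij->j", design, design)
    resid = target - design @ gamma
    for _ in range(max_sweeps):
        if kkt_residual(gamma, target, design, lam) <= tol:
            break
        for j in range(gamma.size):
            if norms[j] <= 0.0:
                continue
            old = gamma[j]
            rho = design[:, j] @ resid + norms[j] * old
            new = max(0.0, (rho - lam) / norms[j])
            if new != old:
                resid += design[:, j] * (old - new)
                gamma[j] = new
    return gamma


def solve_sparse_code(
    target_row: np.ndarray,
    dictionary: np.ndarray,
    lam: float,
    gene_index: int = -1,
) -> SparseCode:
    """Solve the nonnegative l1-regularised reconstruction of one gene row.

    Parameters
    ----------
    target_row:
        Length-|T| annotation vector of the gene being coded.
    dictionary:
        (N-1) x |T| matrix whose rows are the other genes' vectors.
    lam:
        Regularisation weight, > 0. Larger values give sparser codes; above
        the max correlation of any dictionary row with the target the code
        is exactly zero.
    """
    if lam <= 0:
        raise ValueError(f"lambda must be positive, got {lam}")
    target = np.asarray(target_row, dtype=float).ravel()
    dic = np.asarray(dictionary, dtype=float)
    if dic.ndim != 2 or dic.shape[0] < 1:
        raise ValueError("dictionary must be a nonempty 2-d array")
    if dic.shape[1] != target.size:
        raise ValueError("dictionary/target length mismatch")
    if not (np.isfinite(target).all() and np.isfinite(dic).all()):
        raise FloatingPointError("non-finite values in sparse-coding input")

    design = dic.T  # |T| x (N-1): columns are candidate genes
    n_samples = design.shape[0]

    if not target.any():
        gamma = np.zeros(dic.shape[0])
    else:
        # sklearn minimises 1/(2 n) ||y - Xw||^2 + a ||w||_1; a = lam / n
        # gives the same minimiser as the unscaled objective above.
        solver = Lasso(
            alpha=lam / n_samples, positive=True, fit_intercept=False,
            tol=1e-10, max_iter=100_000,
        )
        solver.fit(design, target)
        gamma = np.asarray(solver.coef_, dtype=float)
        gamma = _cd_polish(gamma, target, design, lam)

    gamma[gamma <= ZERO_TOL] = 0.0
    return SparseCode(
        gene_index=gene_index,
        coefficients=gamma,
        lam=lam,
        objective=sparse_objective(gamma, target, design, lam),
        kkt_residual=kkt_residual(gamma, target, design, lam),
    )


def build_similarity(A: GeneTermMatrix | np.ndarray, lam: float,
                     genes: list[str] | None = None) -> SimilarityMatrix:
    """Sparse-representation similarity matrix over all genes.

    Each gene is coded against the matrix with its own row removed; the
    coefficients fill the gene's similarity row (diagonal 0) and the result
    is symmetrised S <- (S + S^T)/2. A gene whose row cannot be reconstructed
    from the others (e.g. orthogonal annotations) gets a (numerically) zero
    row. Rows are solved independently, so the result does not depend on
    gene order of computation.
    """
    if isinstance(A, GeneTermMatrix):
        dense = A.toarray()
        genes = list(A.genes)
    else:
        dense = np.asarray(A, dtype=float)
        if genes is None:
            genes = [str(i) for i in range(dense.shape[0])]
    n = dense.shape[0]
    if n < 2:
        raise ValueError("similarity needs at least two genes")

    S = np.zeros((n, n))
    others = np.arange(n)
    for i in range(n):
        mask = others != i
        code = solve_sparse_code(dense[i], dense[mask], lam, gene_index=i)
        S[i, mask] = code.coefficients
    S = (S + S.T) / 2.0
    np.fill_diagonal(S, 0.0)
    return SimilarityMatrix(genes=genes, values=S)


def aggregate_votes(
    S: SimilarityMatrix, A: GeneTermMatrix
) -> VoteMatrix:
    """Similarity-weighted votes V_SR(i, t) = sum_j S(i, j) A(j, t)."""
    if S.genes != A.genes:
        raise ValueError("gene orders of S and A differ")
    votes = S.values @ A.toarray()
    return VoteMatrix(
        genes=list(A.genes), terms=list(A.terms), values=votes, kind="V_SR"
    )


def save_similarity(S: SimilarityMatrix, path) -> None:
    """Cache S as a sparse triplet TSV (gene_i, gene_j, value), i < j."""
    with open(path, "w") as fh:
        fh.write("gene_i\tgene_j\tvalue\n")
        coo = sp.coo_matrix(np.triu(S.values, k=1))
        order = np.lexsort((coo.col, coo.row))
        for k in order:
            fh.write(f"{S.genes[coo.row[k]]}\t{S.genes[coo.col[k]]}"
                     f"\t{coo.data[k]:.12g}\n")


def load_similarity(path, genes: list[str]) -> SimilarityMatrix:
    """Load a triplet TSV cache back into a SimilarityMatrix."""
    idx = {g: i for i, g in enumerate(genes)}
    values = np.zeros((len(genes), len(genes)))
    with open(path) as fh:
        header = fh.readline()
        if not header.startswith("gene_i"):
            raise ValueError(f"{path} is not a similarity cache")
        for line in fh:
            gi, gj, v = line.rstrip("\n").split("\t")
            values[idx[gi], idx[gj]] = float(v)
            values[idx[gj], idx[gi]] = float(v)
    return SimilarityMatrix(genes=list(genes), values=values)
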