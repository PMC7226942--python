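"""Biclustering of the binary clique x gene regulation matrix.

Rows are maximal cliques, columns genes; entry 1 means the clique
regulates the gene.  A sparse factor-analysis model in the FABIA family
is fitted to the column-centered matrix, X ~ sum_i lambda_i z_i^T: each
factor's loading vector marks a group of cliques (a "superclique") and
its factor vector marks the gene group they co-regulate.  Fitting is by
alternating exact rank-one updates with L1 (soft-threshold) shrinkage
on both sides, which monotonically decreases the penalized objective
0.5 ||X - Lambda Z||^2 + alpha (|Lambda|_1 + |Z|_1).  Memberships are
thresholded per factor at a quantile of the absolute loadings, and the
superclique-to-gene-group bipartite graph is weighted by the number of
regulated (clique, gene) pairs between the two groups.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

__all__ = [
    "BiclusterModel",
    "SupercliqueGraph",
    "build_clique_gene_matrix",
    "fit_fabia",
    "extract_superclique_graph",
]


@dataclass
class BiclusterModel:
    loadings: np.ndarray  # n_cliques x F  (Lambda)
    factors: np.ndarray  # F x n_genes    (Z)
    F: int
    iterations_run: int
    seed: int
    objective_history: list[float] = field(default_factory=list)
    reconstruction_history: list[float] = field(default_factory=list)
    column_means: np.ndarray | None = None


@dataclass
class SupercliqueGraph:
    supercliques: list[list[str]]  # clique labels per factor (may be empty)
    gene_groups: list[list[str]]  # gene labels per factor
    edges: list[tuple[int, int, int]]  # (factor i, factor j, weight >= 1)


def build_clique_gene_matrix(
    cliques, regulated: list[set[str]], gene_universe: list[str]
) -> pd.DataFrame:
    """Binary matrix with one row per clique and one column per gene in the
    universe; all-zero columns are retained."""
    if len(set(gene_universe)) != len(gene_universe):
        raise ValueError("duplicate gene names in universe")
    missing = set().union(*regulated, set()) - set(gene_universe)
    if missing:
        raise ValueError(f"regulated genes outside universe: {sorted(missing)}")
    rows = []
    labels = []
    for c, genes in zip(cliques, regulated):
        labels.append(",".join(sorted(c.members)) if hasattr(c, "members") else str(c))
        rows.append([1 if g in genes else 0 for g in gene_universe])
    return pd.DataFrame(rows, index=labels, columns=list(gene_universe), dtype=float)


def _soft(x: np.ndarray, alpha: float) -> np.ndarray:
    return np.sign(x) * np.maximum(np.abs(x) - alpha, 0.0)


def fit_fabia(
    matrix: pd.DataFrame | np.ndarray,
    F: int = 10,
    max_iter: int = 10000,
    sparseness: float = 0.01,
    seed: int = 0,
    tol: float = 1e-6,
    center: bool = False,
) -> BiclusterModel:
    """Sparse multiplicative factor model of the clique x gene matrix.

    Factors are initialized from the truncated SVD (deterministic up to
    a fixed sign convention) and refined by alternating exact rank-one
    minimizations with soft-threshold shrinkage ``sparseness`` on
    loadings and factors.  Sweeps stop at ``max_iter`` or when the
    relative change of the reconstruction error drops below ``tol``.

    The binary regulation matrix is fitted as-is by default: its
    factors then align with blocks of 1s (the biclusters).  With
    ``center=True`` columns are mean-centered first, which turns each
    block into a two-sided contrast against its complement rows.
    """
    X = np.asarray(matrix, dtype=float)
    if X.size == 0:
        raise ValueError("empty matrix")
    n, m = X.shape
    if F > min(n, m):
        raise ValueError(f"F={F} exceeds min(matrix dims)={min(n, m)}")
    if F < 1:
        raise ValueError("F must be >= 1")
    mu = X.mean(axis=0) if center else None
    Xc = X - mu[None, :] if center else X.copy()

    U, s, Vt = np.linalg.svd(Xc, full_matrices=False)
    L = U[:, :F] * np.sqrt(s[:F])[None, :]
    Z = np.sqrt(s[:F])[:, None] * Vt[:F, :]
    for i in range(F):  # fix the SVD sign ambiguity
        if L[np.abs(L[:, i]).argmax(), i] < 0:
            L[:, i] *= -1
            Z[i, :] *= -1

    alpha = sparseness

    def objective(R: np.ndarray) -> float:
        return 0.5 * float((R**2).sum()) + alpha * (
            float(np.abs(L).sum()) + float(np.abs(Z).sum())
        )

    R = Xc - L @ Z
    obj_hist = [objective(R)]
    rec_hist = [float(np.sqrt((R**2).sum()))]
    it = 0
    for it in range(1, max_iter + 1):
        for i in range(F):
            R += np.outer(L[:, i], Z[i, :])
            nl = float(L[:, i] @ L[:, i])
            if nl > 0:
                Z[i, :] = _soft(L[:, i] @ R, alpha) / nl
            else:
                Z[i, :] = 0.0
            nz = float(Z[i, :] @ Z[i, :])
            if nz > 0:
                L[:, i] = _soft(R @ Z[i, :], alpha) / nz
            else:
                L[:, i] = 0.0
            R -= np.outer(L[:, i], Z[i, :])
        obj = objective(R)
        assert obj <= obj_hist[-1] + 1e-8, "penalized objective increased"
        obj_hist.append(obj)
        rec = float(np.sqrt((R**2).sum()))
        rec_hist.append(rec)
        prev = rec_hist[-2]
        if prev == 0.0 or abs(prev - rec) / max(prev, 1e-12) < tol:
            break
    return BiclusterModel(
        loadings=L,
        factors=Z,
        F=F,
        iterations_run=it,
        seed=seed,
        objective_history=obj_hist,
        reconstruction_history=rec_hist,
        column_means=mu,
    )


def _members_above_quantile(values: np.ndarray, q: float) -> np.ndarray:
    """Indices with |value| at (or above) the per-factor membership cutoff.

    The cutoff is the ``q`` quantile of |values|, capped at half the
    factor's peak magnitude so that a support wider than ``1 - q`` of
    the dimension (where the quantile falls inside the near-tied member
    values) is kept intact.  Exact zeros are never members; an all-zero
    factor has no members.
    """
    absv = np.abs(values)
    if absv.max() == 0.0:
        return np.array([], dtype=int)
    thr = min(np.quantile(absv, q), 0.5 * absv.max())
    return np.flatnonzero((absv >= thr) & (absv > 0.0))


def extract_superclique_graph(
    model: BiclusterModel,
    matrix: pd.DataFrame,
    membership_quantile: float = 0.9,
) -> SupercliqueGraph:
    """Threshold factor memberships and emit the weighted bipartite graph.

    Superclique S_i = cliques whose |loading| on factor i reaches the
    per-factor ``membership_quantile``; gene group G_j likewise on the
    factor matrix.  Edge weight (S_i, G_j) = number of regulated
    (clique, gene) pairs between the two sets; zero-weight edges are
    omitted.  A clique or gene may appear in several groups.
    """
    clique_labels = list(matrix.index)
    gene_labels = list(matrix.columns)
    X = matrix.to_numpy()
    supercliques, gene_groups = [], []
    for i in range(model.F):
        supercliques.append(
            [clique_labels[k] for k in _members_above_quantile(model.loadings[:, i], membership_quantile)]
        )
        gene_groups.append(
            [gene_labels[k] for k in _members_above_quantile(model.factors[i, :], membership_quantile)]
        )
    edges = []
    for i, rows in enumerate(supercliques):
        if not rows:
            continue
        ridx = [clique_labels.index(r) for r in rows]
        for j, cols in enumerate(gene_groups):
            if not cols:
                continue
            cidx = [gene_labels.index(g) for g in cols]
            w = int(X[np.ix_(ridx, cidx)].sum())
            if w >= 1:
                edges.append((i, j, w))
    return SupercliqueGraph(supercliques, gene_groups, edges)
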