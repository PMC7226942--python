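"""Fuse the 1D co-localization matrix with the PPI-restricted 3D matrix.

The 3D matrix is a binary TF adjacency: an edge requires the pair to be
present in STRING with combined score > 400 AND in BioGRID with
experimental evidence, and both endpoints to sit in the final TF list
(motif-present in both anchor classes).  The 1D and 3D matrices,
restricted to their shared TFs, are merged by similarity network
fusion: each matrix becomes a full transition kernel and a K-nearest-
neighbour local kernel, and the two networks exchange information by
cross-diffusion for ``t`` iterations.  The fused similarity is
binarized into the final TF network, onto which directions derived
from the 1D asymmetry are overlaid.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import networkx as nx
import numpy as np

from .colocalization import SimilarityMatrix
from .formats import PPIEdge

log = logging.getLogger(__name__)

__all__ = [
    "FusionConfig",
    "TFNetwork",
    "build_3d_matrix",
    "snf_fuse",
    "binarize_and_orient",
]


@dataclass(frozen=True)
class FusionConfig:
    K: int | None = None  # neighborhood size; None -> max(2, n // 10)
    t: int = 20  # diffusion iterations
    eps: float = 1e-3  # off-diagonal affinity floor
    binarize_rule: str = "mean_offdiag"  # or "quantile"
    quantile: float = 0.9
    string_min_score: float = 400.0
    experimental_evidence: tuple[str, ...] = ("experimental",)

    def resolve_k(self, n: int) -> int:
        k = self.K if self.K is not None else max(2, n // 10)
        if not (2 <= k < n):
            raise ValueError(f"neighborhood size K={k} invalid for n={n} TFs")
        return k


@dataclass
class TFNetwork:
    """The final fused TF network: weighted, binarized, plus directed overlay."""

    tf_names: list[str]
    fused_weights: np.ndarray
    edges: list[tuple[str, str]] = field(default_factory=list)
    directed_edges: list[tuple[str, str]] = field(default_factory=list)

    def graph(self) -> nx.Graph:
        g = nx.Graph()
        g.add_nodes_from(self.tf_names)
        idx = {t: i for i, t in enumerate(self.tf_names)}
        for a, b in self.edges:
            g.add_edge(a, b, weight=float(self.fused_weights[idx[a], idx[b]]))
        return g

    def directed_graph(self) -> nx.DiGraph:
        g = nx.DiGraph()
        for a, b in self.directed_edges:
            g.add_edge(a, b)
        return g

    def to_json(self, path: str | Path) -> None:
        payload = {
            "tf_names": self.tf_names,
            "fused_weights": [[round(float(x), 12) for x in row] for row in self.fused_weights],
            "edges": [list(e) for e in self.edges],
            "directed_edges": [list(e) for e in self.directed_edges],
        }
        Path(path).write_text(json.dumps(payload, indent=1, sort_keys=True))

    @classmethod
    def from_json(cls, path: str | Path) -> "TFNetwork":
        payload = json.loads(Path(path).read_text())
        return cls(
            payload["tf_names"],
            np.array(payload["fused_weights"], dtype=float),
            [tuple(e) for e in payload["edges"]],
            [tuple(e) for e in payload["directed_edges"]],
        )


def build_3d_matrix(
    final_tf_list: list[str],
    edges: list[PPIEdge],
    cfg: FusionConfig | None = None,
) -> np.ndarray:
    """Binary adjacency over ``final_tf_list`` from the PPI intersection.

    An edge is kept iff both endpoints are listed TFs, the pair appears
    in STRING with combined score strictly above 400, and in BioGRID
    with experimental evidence.
    """
    cfg = cfg or FusionConfig()
    if not final_tf_list:
        raise ValueError("final TF list is empty")
    idx = {t: i for i, t in enumerate(final_tf_list)}
    string_ok: set[tuple[str, str]] = set()
    biogrid_ok: set[tuple[str, str]] = set()
    for e in edges:
        pair = (e.protein_a, e.protein_b)
        if e.source == "string_db" and e.score is not None and e.score > cfg.string_min_score:
            string_ok.add(pair)
        elif e.source == "biogrid" and e.evidence is not None and any(
            tok.lower() in e.evidence.lower() for tok in cfg.experimental_evidence
        ):
            biogrid_ok.add(pair)
    adj = np.zeros((len(final_tf_list), len(final_tf_list)))
    for a, b in string_ok & biogrid_ok:
        if a in idx and b in idx:
            adj[idx[a], idx[b]] = adj[idx[b], idx[a]] = 1.0
    return adj


def _transition_full(W: np.ndarray) -> np.ndarray:
    """Full kernel: off-diagonal mass 1/2 split proportionally, diagonal 1/2."""
    n = W.shape[0]
    P = np.zeros_like(W)
    off = W.copy()
    np.fill_diagonal(off, 0.0)
    rowsum = off.sum(axis=1)
    rowsum[rowsum == 0] = 1.0
    P = off / (2.0 * rowsum[:, None])
    np.fill_diagonal(P, 0.5)
    return P


def _transition_local(W: np.ndarray, K: int) -> np.ndarray:
    """Row-stochastic kernel supported on each row's K strongest neighbours."""
    n = W.shape[0]
    off = W.copy()
    np.fill_diagonal(off, -np.inf)
    S = np.zeros_like(W)
    for i in range(n):
        nn = np.argsort(-off[i], kind="stable")[:K]
        w = np.maximum(W[i, nn], 0.0)
        tot = w.sum()
        if tot > 0:
            S[i, nn] = w / tot
    return S


def snf_fuse(
    matrix_1d: SimilarityMatrix,
    matrix_3d: np.ndarray,
    cfg: FusionConfig | None = None,
) -> np.ndarray:
    """Similarity-network-fusion of the (symmetrized) 1D matrix and the
    binary 3D adjacency over the same TF ordering.

    Both affinities get an ``eps`` off-diagonal floor (so isolated rows
    stay stochastic), are converted to full and K-NN local kernels, and
    are cross-diffused: at each iteration each network's full kernel is
    propagated through the other's local kernel,
    ``P1 <- S1 . P2 . S1^T`` and ``P2 <- S2 . P1 . S2^T`` (in parallel),
    then re-symmetrized.  The fused matrix is the average of the two
    diffused kernels, symmetric and non-negative by construction.
    """
    cfg = cfg or FusionConfig()
    W1 = matrix_1d.symmetrized()
    W2 = np.asarray(matrix_3d, dtype=float)
    if W1.shape != W2.shape:
        raise ValueError("1D and 3D matrices must cover the same TF set")
    if not (np.isfinite(W1).all() and np.isfinite(W2).all()):
        raise ValueError("non-finite affinity input")
    n = W1.shape[0]
    K = cfg.resolve_k(n)

    def floored(W: np.ndarray) -> np.ndarray:
        F = W + cfg.eps
        np.fill_diagonal(F, np.diag(W))
        return F

    W1, W2 = floored(W1), floored(np.where(W2 > 0, W2, 0.0) * 1.0)
    P1, P2 = _transition_full(W1), _transition_full(W2)
    S1, S2 = _transition_local(W1, K), _transition_local(W2, K)
    for _ in range(cfg.t):
        P1n = S1 @ P2 @ S1.T
        P2n = S2 @ P1 @ S2.T
        # re-impose the half-diagonal row-stochastic form each round so the
        # diffusion exchanges structure instead of washing out to uniform
        P1 = _transition_full((P1n + P1n.T) / 2.0)
        P2 = _transition_full((P2n + P2n.T) / 2.0)
        P1 = (P1 + P1.T) / 2.0
        P2 = (P2 + P2.T) / 2.0
        assert (P1 >= -1e-12).all() and (P2 >= -1e-12).all()
    fused = (P1 + P2) / 2.0
    fused = (fused + fused.T) / 2.0
    return np.maximum(fused, 0.0)


def binarize_and_orient(
    fused_weights: np.ndarray,
    tf_names: list[str],
    directed: list[tuple[str, str]],
    cfg: FusionConfig | None = None,
) -> TFNetwork:
    """Threshold the fused similarity into the final network and overlay
    the 1D-derived directions.

    Undirected edge iff weight strictly above the rule threshold (mean
    off-diagonal weight by default, or a quantile).  The directed
    overlay keeps only directed pairs whose undirected edge survived;
    TFs with no incident directed pair simply do not appear in the
    directed view.
    """
    cfg = cfg or FusionConfig()
    W = np.asarray(fused_weights, dtype=float)
    n = W.shape[0]
    mask = ~np.eye(n, dtype=bool)
    offdiag = W[mask]
    if np.allclose(offdiag, offdiag.flat[0] if offdiag.size else 0.0):
        log.warning("degenerate fused matrix: all off-diagonal weights equal; no edges kept")
        return TFNetwork(list(tf_names), W, [], [])
    if cfg.binarize_rule == "mean_offdiag":
        thr = float(offdiag.mean())
    elif cfg.binarize_rule == "quantile":
        thr = float(np.quantile(offdiag, cfg.quantile))
    else:
        raise ValueError(f"unknown binarize rule {cfg.binarize_rule!r}")
    edges = [
        (tf_names[i], tf_names[j])
        for i in range(n)
        for j in range(i + 1, n)
        if W[i, j] > thr
    ]
    edge_set = {frozenset(e) for e in edges}
    directed_kept = [e for e in directed if frozenset(e) in edge_set]
    return TFNetwork(list(tf_names), W, edges, directed_kept)
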