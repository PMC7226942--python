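"""Community, clique and coherence analyses of the fused TF network.

Overlapping communities are grown greedily on the cohesiveness
objective f(V) = w_in / (w_in + w_bound + p|V|): from each unused seed
the single node addition or removal that most increases f is applied
until no step helps, heavily overlapping grown sets are merged, and
small or sparse sets are discarded — so one TF may belong to several
communities.  Maximal cliques (fully connected subsets not extendable
by any node) are enumerated by Bron-Kerbosch with pivoting and kept at
sizes 3..10.  Cliques are then mapped onto the hierarchy levels and
communities, compared across cell lines by exact member-set identity,
linked to the genes they regulate through enhancer-promoter loops, and
tested for expression coherence (within-clique vs between-clique
Spearman correlation, one-sided Wilcoxon rank-sum).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from itertools import combinations

import networkx as nx
import numpy as np
import pandas as pd
from scipy.stats import mannwhitneyu, spearmanr

from .formats import IntervalSet
from .hierarchy import HierarchyAssignment
from .motifs import MotifOccurrence

log = logging.getLogger(__name__)

__all__ = [
    "Community",
    "Clique",
    "CoherenceResult",
    "cohesiveness",
    "find_communities",
    "maximal_cliques",
    "map_clique_spans",
    "compare_cliques_across_cells",
    "regulated_genes",
    "classify_clique_patterns",
    "expression_coherence",
]


@dataclass(frozen=True)
class Community:
    members: frozenset[str]
    cohesiveness: float


@dataclass(frozen=True)
class Clique:
    members: frozenset[str]
    cell_line: str = ""


@dataclass
class CoherenceResult:
    within_pair_correlations: list[float]
    between_pair_correlations: list[float]
    wilcoxon_p: float


def cohesiveness(graph: nx.Graph, subset, penalty: float = 2.0) -> float:
    """f(V) = w_in / (w_in + w_bound + penalty * |V|).

    ``w_in`` is the total weight of edges with both endpoints in V,
    ``w_bound`` of edges with exactly one.  Missing edge weights count
    as 1.  Empty denominator (isolated node, penalty 0) yields 0.
    """
    V = set(subset)
    if not V:
        raise ValueError("empty subset")
    missing = V - set(graph.nodes)
    if missing:
        raise ValueError(f"nodes not in graph: {sorted(missing)}")
    w_in = w_bound = 0.0
    for a, b, data in graph.edges(V, data=True):
        w = data.get("weight", 1.0)
        if a in V and b in V:
            w_in += w
        else:
            w_bound += w
    denom = w_in + w_bound + penalty * len(V)
    return w_in / denom if denom > 0 else 0.0


def _grow(graph: nx.Graph, seed: str, penalty: float) -> frozenset[str]:
    V = {seed}
    f = cohesiveness(graph, V, penalty)
    while True:
        best_step, best_f = None, f
        boundary = {n for v in V for n in graph.neighbors(v)} - V
        for n in sorted(boundary):
            cand = cohesiveness(graph, V | {n}, penalty)
            if cand > best_f:
                best_step, best_f = ("add", n), cand
        if len(V) > 1:
            for n in sorted(V):
                cand = cohesiveness(graph, V - {n}, penalty)
                if cand > best_f:
                    best_step, best_f = ("remove", n), cand
        if best_step is None:
            return frozenset(V)
        op, n = best_step
        V = V | {n} if op == "add" else V - {n}
        f = best_f


def _overlap_score(a: frozenset, b: frozenset) -> float:
    inter = len(a & b)
    return inter * inter / (len(a) * len(b))


def find_communities(
    graph: nx.Graph,
    penalty: float = 2.0,
    merge_overlap: float = 0.8,
    min_size: int = 3,
    min_density: float = 0.5,
) -> list[Community]:
    """Greedy overlapping community detection on the cohesiveness score.

    Seeds are taken in descending (weighted) degree among nodes not yet
    covered by a grown set; each grown set is the local optimum of the
    add/remove dynamics.  Sets with overlap score
    |A∩B|²/(|A||B|) >= ``merge_overlap`` are merged, and final sets
    failing ``min_size`` or edge density < ``min_density`` are dropped.
    """
    degree = dict(graph.degree(weight="weight"))
    order = sorted(graph.nodes, key=lambda n: (-degree.get(n, 0.0), n))
    grown: list[frozenset[str]] = []
    covered: set[str] = set()
    for seed in order:
        if seed in covered:
            continue
        V = _grow(graph, seed, penalty)
        grown.append(V)
        covered |= V
    # transitive merge of heavily overlapping sets
    merged = True
    while merged:
        merged = False
        for i, j in combinations(range(len(grown)), 2):
            if _overlap_score(grown[i], grown[j]) >= merge_overlap:
                grown[i] = grown[i] | grown[j]
                del grown[j]
                merged = True
                break
    out = []
    seen: set[frozenset] = set()
    for V in grown:
        if V in seen or len(V) < min_size:
            continue
        seen.add(V)
        sub = graph.subgraph(V)
        possible = len(V) * (len(V) - 1) / 2
        density = sub.number_of_edges() / possible if possible else 1.0
        if density < min_density:
            continue
        out.append(Community(V, cohesiveness(graph, V, penalty)))
    return sorted(out, key=lambda c: (-len(c.members), sorted(c.members)))


def maximal_cliques(
    graph: nx.Graph, min_size: int = 3, max_size: int = 10, cell_line: str = ""
) -> list[Clique]:
    """All maximal cliques of size ``min_size``..``max_size`` (Bron-Kerbosch
    with pivoting), sorted by size then lexicographic member order."""
    cliques = [
        Clique(frozenset(c), cell_line)
        for c in nx.find_cliques(graph)
        if min_size <= len(c) <= max_size
    ]
    return sorted(cliques, key=lambda c: (len(c.members), sorted(c.members)))


def map_clique_spans(
    cliques: list[Clique],
    hierarchy: HierarchyAssignment,
    communities: list[Community],
) -> pd.DataFrame:
    """Per clique: number of hierarchy levels spanned and communities touched."""
    rows = []
    for c in cliques:
        missing = [t for t in c.members if t not in hierarchy.levels]
        if missing:
            raise ValueError(f"clique members missing from hierarchy: {sorted(missing)}")
        levels = {hierarchy.levels[t] for t in c.members}
        touched = sum(1 for com in communities if com.members & c.members)
        rows.append(
            {
                "clique": ",".join(sorted(c.members)),
                "size": len(c.members),
                "levels_spanned": len(levels),
                "communities_touched": touched,
            }
        )
    return pd.DataFrame(rows)


def compare_cliques_across_cells(
    per_cell_cliques: dict[str, list[Clique]],
) -> dict[tuple[str, ...], list[frozenset[str]]]:
    """Venn partition of clique member-sets across cell lines.

    Keys are sorted tuples of cell-line names; each distinct member set
    lands in exactly one region (the set of cells containing it).
    """
    if len(per_cell_cliques) < 2:
        raise ValueError("need cliques from at least 2 cell lines")
    membership: dict[frozenset[str], set[str]] = {}
    for cell, cliques in per_cell_cliques.items():
        for c in cliques:
            membership.setdefault(c.members, set()).add(cell)
    regions: dict[tuple[str, ...], list[frozenset[str]]] = {}
    for members, cells in membership.items():
        regions.setdefault(tuple(sorted(cells)), []).append(members)
    return regions


def _anchor_key(anchor) -> str:
    return f"{anchor.chrom}:{anchor.start}-{anchor.end}"


def regulated_genes(
    clique: Clique,
    ep_loops,
    occurrences: list[MotifOccurrence],
    tss: IntervalSet,
) -> set[str]:
    """Genes regulated by a clique through enhancer-promoter loops.

    Gene g counts as regulated iff some EP loop's promoter anchor
    overlaps g's TSS and every clique TF has at least one motif
    occurrence in that loop's promoter or enhancer anchor.  Antitone in
    clique size: adding a TF can only shrink the result.
    """
    from .loops import enhancer_promoter_anchors

    if len(tss) == 0:
        raise ValueError("TSS annotation is empty")
    hits_by_anchor: dict[str, set[str]] = {}
    for occ in occurrences:
        hits_by_anchor.setdefault(occ.anchor_id, set()).add(occ.tf_name)
    genes: set[str] = set()
    for lp in ep_loops:
        pair = enhancer_promoter_anchors(lp)
        if pair is None:
            continue
        enh, prom = pair
        present = hits_by_anchor.get(_anchor_key(enh), set()) | hits_by_anchor.get(
            _anchor_key(prom), set()
        )
        if not clique.members <= present:
            continue
        for t in tss.overlapping(prom):
            if t.label is not None:
                genes.add(t.label)
    return genes


def classify_clique_patterns(
    per_cell: dict[str, list[tuple[frozenset[str], set[str]]]],
    gene_jaccard_cutoff: float = 0.9,
    min_shared_tfs: int = 3,
) -> list[dict]:
    """Cross-cell clique pattern taxonomy.

    For each pair of cells and each clique pair: identical member sets
    with regulated-gene Jaccard >= ``gene_jaccard_cutoff`` are
    "same-clique-same-genes"; identical member sets below the cutoff
    are "same-clique-different-genes"; different member sets sharing at
    least ``min_shared_tfs`` TFs are "partial-TF-sharing".  Pairs
    sharing fewer TFs are unrelated and not reported.
    """
    records = []
    cells = sorted(per_cell)
    for ca, cb in combinations(cells, 2):
        for mem_a, genes_a in per_cell[ca]:
            for mem_b, genes_b in per_cell[cb]:
                if mem_a == mem_b:
                    union = genes_a | genes_b
                    jac = len(genes_a & genes_b) / len(union) if union else 1.0
                    pattern = (
                        "same-clique-same-genes"
                        if jac >= gene_jaccard_cutoff
                        else "same-clique-different-genes"
                    )
                elif len(mem_a & mem_b) >= min_shared_tfs:
                    pattern = "partial-TF-sharing"
                else:
                    continue
                records.append(
                    {
                        "cell_a": ca,
                        "cell_b": cb,
                        "clique_a": ",".join(sorted(mem_a)),
                        "clique_b": ",".join(sorted(mem_b)),
                        "pattern": pattern,
                    }
                )
    return records


def expression_coherence(
    cliques: list[Clique], expression: pd.DataFrame
) -> CoherenceResult:
    """Within-clique vs between-clique expression correlation.

    Spearman rank correlation (average ranks on ties) for every pair of
    clique TFs co-occurring in at least one clique, and for every pair
    never co-occurring; one-sided Wilcoxon rank-sum tests whether the
    within-clique correlations are larger (exact null for combined
    n <= 20, tie-corrected normal approximation otherwise).
    """
    tfs = sorted({t for c in cliques for t in c.members})
    missing = [t for t in tfs if t not in expression.index]
    if missing:
        raise ValueError(f"TFs missing from expression table: {missing}")
    if expression.shape[1] < 3:
        raise ValueError("need >= 3 expression samples per TF")
    within_pairs = {
        frozenset(p) for c in cliques for p in combinations(sorted(c.members), 2)
    }
    within, between = [], []
    n_dropped = 0
    for a, b in combinations(tfs, 2):
        x = expression.loc[a].to_numpy(dtype=float)
        y = expression.loc[b].to_numpy(dtype=float)
        if np.ptp(x) == 0 or np.ptp(y) == 0:
            n_dropped += 1
            continue
        rho = spearmanr(x, y).statistic
        (within if frozenset((a, b)) in within_pairs else between).append(float(rho))
    if n_dropped:
        log.warning("dropped %d TF pairs with constant expression", n_dropped)
    if not within or not between:
        raise ValueError("need both within- and between-clique pairs")
    method = "exact" if len(within) + len(between) <= 20 else "asymptotic"
    res = mannwhitneyu(within, between, alternative="greater", method=method)
    return CoherenceResult(within, between, float(res.pvalue))
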