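"""Asymmetric 1D TF-TF co-localization matrix from ChIP-Seq peak sets.

The per-peak statistic follows the IntervalStats idea: for a query peak
``q`` against a reference peak set, the p-value is the fraction of all
placements of an interval of length ``|q|`` inside the analysis domain
whose distance to the reference set is no larger than the observed
distance.  Distances are genomic gaps on the half-open convention
(overlap = distance 0).  The similarity of an ordered TF pair (a -> b)
is the fraction of a's peaks whose p-value against b's peaks falls
below ``alpha``; the matrix is asymmetric because query and reference
roles are not exchangeable.

Placement counting is done analytically: the set of start positions at
distance <= d from reference ``[bs, be)`` is the integer range
``[bs - |q| - d, be + d]``, so the p-value numerator is the size of a
union of integer ranges intersected with the valid start positions of
the domain — no enumeration is required, and the result equals the
brute-force placement count exactly.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .formats import GenomicInterval, IntervalSet

__all__ = [
    "SimilarityMatrix",
    "interval_distance",
    "intervalstats_pvalue",
    "build_1d_matrix",
    "derive_directions",
    "chromosome_extents",
]


@dataclass
class SimilarityMatrix:
    """Named, asymmetric TF x TF similarity table with entries in [0, 1].

    ``values[i, j]`` is s(tf_names[i] -> tf_names[j]); the diagonal is
    NaN and ignored everywhere.
    """

    tf_names: list[str]
    values: np.ndarray
    alpha: float = 0.05

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        n = len(self.tf_names)
        if self.values.shape != (n, n):
            raise ValueError("similarity matrix shape does not match TF list")

    @property
    def n_ordered_pairs(self) -> int:
        """Number of ordered off-diagonal TF pairs covered by the matrix."""
        n = len(self.tf_names)
        return n * (n - 1)

    def s(self, a: str, b: str) -> float:
        i, j = self.tf_names.index(a), self.tf_names.index(b)
        return float(self.values[i, j])

    def restrict(self, tfs: list[str]) -> "SimilarityMatrix":
        idx = [self.tf_names.index(t) for t in tfs]
        return SimilarityMatrix(list(tfs), self.values[np.ix_(idx, idx)], self.alpha)

    def symmetrized(self) -> np.ndarray:
        """Arithmetic-mean symmetrization with zero diagonal."""
        v = np.nan_to_num(self.values, nan=0.0)
        sym = 0.5 * (v + v.T)
        np.fill_diagonal(sym, 0.0)
        return sym

    def to_dataframe(self) -> pd.DataFrame:
        return pd.DataFrame(self.values, index=self.tf_names, columns=self.tf_names)

    def write_tsv(self, path) -> None:
        self.to_dataframe().to_csv(path, sep="\t", index_label="query")

    @classmethod
    def read_tsv(cls, path, alpha: float = 0.05) -> "SimilarityMatrix":
        df = pd.read_csv(path, sep="\t", index_col=0)
        return cls(list(df.index), df.to_numpy(), alpha)


def interval_distance(q: GenomicInterval, refs: IntervalSet) -> float:
    """Genomic gap from ``q`` to the nearest reference interval on its
    chromosome; 0 on overlap, ``inf`` when the chromosome has no references."""
    starts, ends = refs.arrays(q.chrom)
    if len(starts) == 0:
        return math.inf
    gaps = np.maximum(0, np.maximum(starts - q.end, q.start - ends))
    return float(gaps.min())


def _domain_positions(domain: IntervalSet, chrom: str, length: int):
    """Valid start ranges [a, b] (inclusive) for placing an interval of
    ``length`` inside each domain segment on ``chrom``."""
    dstarts, dends = domain.arrays(chrom)
    if len(dstarts) == 0:
        raise ValueError(f"analysis domain has no segment on chromosome {chrom}")
    lo = dstarts
    hi = dends - length
    keep = hi >= lo
    return lo[keep], hi[keep]


def intervalstats_pvalue(
    q: GenomicInterval, refs: IntervalSet, domain: IntervalSet
) -> float:
    """Placement p-value of query ``q`` against ``refs`` inside ``domain``.

    p = (# start positions where an interval of length |q| lies at
    distance <= observed distance from the references) / (# valid start
    positions).  Equals 1 when the chromosome carries no references.
    """
    d = interval_distance(q, refs)
    if math.isinf(d):
        return 1.0
    length = len(q)
    vlo, vhi = _domain_positions(domain, q.chrom, length)
    total = int(np.sum(vhi - vlo + 1))
    if total == 0:
        raise ValueError(
            f"query of length {length} does not fit in any domain segment on {q.chrom}"
        )
    bs, be = refs.arrays(q.chrom)
    hits = _count_positions_within(bs, be, length, d, vlo, vhi)
    return hits / total


def _count_positions_within(bs, be, length, d, vlo, vhi) -> int:
    """Size of (union_i [bs_i - length - d, be_i + d]) ∩ (union_j [vlo_j, vhi_j])
    over the integers.  ``bs`` sorted ascending."""
    lo = bs - length - d
    hi = be + d + 1  # half-open
    prev = np.concatenate(([-np.inf], np.maximum.accumulate(hi)[:-1]))
    hits = 0
    for a, b in zip(vlo, vhi):
        start_eff = np.maximum(np.maximum(lo, prev), a)
        end_eff = np.minimum(hi, b + 1)
        hits += int(np.maximum(0, end_eff - start_eff).sum())
    return hits


def chromosome_extents(peaksets: list[IntervalSet], pad: int = 0) -> IntervalSet:
    """Default analysis domain: one segment [0, max end + pad] per chromosome
    seen in any peak set."""
    maxend: dict[str, int] = {}
    for ps in peaksets:
        for chrom in ps.chroms:
            _, ends = ps.arrays(chrom)
            maxend[chrom] = max(maxend.get(chrom, 0), int(ends.max()))
    return IntervalSet(
        "domain",
        [GenomicInterval(c, 0, e + pad) for c, e in maxend.items()],
    )


def build_1d_matrix(
    peaksets: list[IntervalSet],
    domain: IntervalSet | None = None,
    alpha: float = 0.05,
) -> SimilarityMatrix:
    """Similarity s(a -> b) = fraction of a's peaks significantly close to
    b's peaks (per-peak placement p-value < ``alpha``).

    Every TF acts as query once against each other TF as reference; for
    n peak sets the matrix covers n(n-1) ordered off-diagonal pairs.
    """
    if len(peaksets) < 2:
        raise ValueError("need at least two peak sets")
    for ps in peaksets:
        if len(ps) == 0:
            raise ValueError(f"peak set {ps.name!r} is empty")
    names = [ps.name for ps in peaksets]
    if len(set(names)) != len(names):
        raise ValueError("peak set names are not unique")
    if domain is None:
        domain = chromosome_extents(peaksets)

    n = len(peaksets)
    # per-TF, per-chromosome cached arrays plus per-chromosome domain ranges
    chroms = sorted({c for ps in peaksets for c in ps.chroms})
    dom_ranges: dict[str, dict[int, tuple[np.ndarray, np.ndarray, int]]] = {}

    def domain_for(chrom: str, length: int):
        by_len = dom_ranges.setdefault(chrom, {})
        if length not in by_len:
            vlo, vhi = _domain_positions(domain, chrom, length)
            by_len[length] = (vlo, vhi, int(np.sum(vhi - vlo + 1)))
        return by_len[length]

    values = np.full((n, n), np.nan)
    for i, qset in enumerate(peaksets):
        nq_total = len(qset)
        # per-chromosome query arrays
        qarr = {c: qset.arrays(c) for c in qset.chroms}
        for j, rset in enumerate(peaksets):
            if i == j:
                continue
            nsig = 0
            for chrom, (qs, qe) in qarr.items():
                bs, be = rset.arrays(chrom)
                if len(bs) == 0:
                    continue  # p = 1 for every query on this chromosome
                gaps = np.maximum(
                    0,
                    np.maximum(bs[None, :] - qe[:, None], qs[:, None] - be[None, :]),
                )
                dobs = gaps.min(axis=1)
                lens = qe - qs
                hi = be[None, :] + dobs[:, None] + 1
                lo = bs[None, :] - lens[:, None] - dobs[:, None]
                prev = np.concatenate(
                    (np.full((len(qs), 1), -np.inf), np.maximum.accumulate(hi, axis=1)[:, :-1]),
                    axis=1,
                )
                for length in np.unique(lens):
                    vlo, vhi, total = domain_for(chrom, int(length))
                    if total == 0:
                        raise ValueError(
                            f"peak of length {length} does not fit in domain on {chrom}"
                        )
                    rows = lens == length
                    hits = np.zeros(int(rows.sum()))
                    for a, b in zip(vlo, vhi):
                        start_eff = np.maximum(np.maximum(lo[rows], prev[rows]), a)
                        end_eff = np.minimum(hi[rows], b + 1)
                        hits += np.maximum(0, end_eff - start_eff).sum(axis=1)
                    nsig += int(np.sum(hits / total < alpha))
            values[i, j] = nsig / nq_total
    return SimilarityMatrix(names, values, alpha)


def derive_directions(S: SimilarityMatrix) -> list[tuple[str, str]]:
    """Ordered pairs (a, b) with s(a->b) > s(b->a); symmetric-similarity
    pairs carry no direction and are omitted."""
    edges = []
    v = S.values
    n = len(S.tf_names)
    for i in range(n):
        for j in range(i + 1, n):
            if np.isnan(v[i, j]) or np.isnan(v[j, i]):
                continue
            if v[i, j] > v[j, i]:
                edges.append((S.tf_names[i], S.tf_names[j]))
            elif v[j, i] > v[i, j]:
                edges.append((S.tf_names[j], S.tf_names[i]))
    return edges
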