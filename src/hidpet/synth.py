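"""Desk-scale synthetic inputs with planted truth for every pipeline stage.

The generator stands in for the real data downloads (ChIA-PET contact
lists, chromatin-state segmentations, ReMap peak sets, motif
collections, STRING/BioGRID tables, RNA-Seq expression): it emits the
same file formats at toy scale, with known planted structure so every
stage's recovery is assertable:

* enhancer-promoter loops whose anchors sit in "Strong_Enhancer" /
  "Active_Promoter" segments, promoter anchors overlapping a TSS;
* per-loop TF occupancy: each EP loop is owned by one planted clique
  and the consensus of every member TF is implanted verbatim in both
  anchors (exact consensus, so motif-scan recovery is deterministic);
* ChIP-Seq peak sets in which TFs of one planted clique share >= 80%
  of peak midpoints within 50 bp (jitter <= 20 bp), the rest private;
* a PPI table where planted cliques are complete (and maximal)
  subgraphs supported by both STRING (score > 400) and BioGRID
  (experimental) records, embedded in denser planted communities;
* a directed influence list in which >= 95% of edges point from higher
  planted levels to lower ones;
* expression tables (five replicates per cell line) with one shared
  latent profile per planted clique, so within-clique Spearman
  correlations are high (exactly 1 at zero noise);
* a binary clique x gene matrix holding planted noise-free biclusters.

All randomness flows from ``FixtureConfig.seed``; a fixed seed gives
byte-identical output files.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import pandas as pd

from .formats import (
    BASES,
    GenomicInterval,
    IntervalSet,
    Loop,
    PPIEdge,
    PWMRecord,
    write_edge_table,
    write_expression,
    write_fasta,
    write_intervals,
    write_loops,
    write_pwms,
)

__all__ = [
    "FixtureConfig",
    "LandscapeBundle",
    "NetworkTruthBundle",
    "simulate_regulatory_landscape",
    "simulate_network_truth",
    "write_input_bundle",
]

PEAK_WIDTH = 200
JITTER = 20  # bp; midpoint jitter within a shared peak core (pairwise <= 40 < 50)
LOOP_GAP = 2000  # bp between enhancer and promoter anchor
SHARED_FRACTION = 0.9  # fraction of a clique TF's peaks drawn from the shared core


@dataclass
class FixtureConfig:
    seed: int = 0
    n_chroms: int = 2
    chrom_len: int = 1_000_000  # peaks must stay sparse for overlap significance
    n_tfs: int = 12
    n_loops: int = 40
    fraction_ep: float = 0.8
    motif_width: int = 18  # long enough that a consensus site clears p = 1e-10
    anchor_len: int = 400
    peaks_per_tf: int = 30
    planted_levels: list[int] | None = None  # level sizes, level 1 first
    planted_communities: list[set[str]] | None = None
    planted_cliques: list[set[str]] | None = None
    planted_biclusters: list[tuple[set[int], set[int]]] | None = None
    n_matrix_cliques: int = 20  # rows of the planted clique x gene matrix
    n_matrix_genes: int = 60
    expression_noise_sd: float = 0.1
    upward_edge_fraction: float = 0.02  # hierarchy noise; must stay <= 0.05
    cell_lines: tuple[str, ...] = ("cellA", "cellB")
    n_replicates: int = 5  # expression replicates per cell line

    def __post_init__(self) -> None:
        for name in ("n_chroms", "chrom_len", "n_tfs", "n_loops", "motif_width",
                     "anchor_len", "peaks_per_tf", "n_matrix_cliques", "n_matrix_genes"):
            if getattr(self, name) < 1:
                raise ValueError(f"{name} must be >= 1")
        if not (0.0 <= self.fraction_ep <= 1.0):
            raise ValueError("fraction_ep must be in [0, 1]")
        if self.planted_levels is None:
            third = self.n_tfs // 3
            self.planted_levels = [third, third, self.n_tfs - 2 * third]
        if sum(self.planted_levels) != self.n_tfs:
            raise ValueError("planted level sizes must sum to n_tfs")
        if min(self.planted_levels) < 1:
            raise ValueError("every planted level needs >= 1 TF")
        names = self.tf_names
        if self.planted_cliques is None:
            self.planted_cliques = self._default_cliques(names)
        if self.planted_communities is None:
            k = max(1, len(self.planted_cliques) // 2 + len(self.planted_cliques) % 2)
            comms = []
            for i in range(0, len(self.planted_cliques), 2):
                group = set().union(*self.planted_cliques[i : i + 2])
                comms.append(group)
            leftovers = set(names) - set().union(*comms) if comms else set(names)
            if leftovers and comms:
                comms[-1] |= leftovers
            self.planted_communities = comms
        for c in self.planted_cliques:
            if not any(c <= com for com in self.planted_communities):
                raise ValueError(f"planted clique {sorted(c)} lies in no planted community")
        if self.planted_biclusters is None:
            half_r = self.n_matrix_cliques // 2
            half_g = self.n_matrix_genes // 2
            self.planted_biclusters = [
                (set(range(half_r)), set(range(0, max(1, half_g - 5)))),
                (
                    set(range(half_r, self.n_matrix_cliques)),
                    set(range(half_g + 1, self.n_matrix_genes)),
                ),
            ]
        for rows, cols in self.planted_biclusters:
            if max(rows) >= self.n_matrix_cliques or max(cols) >= self.n_matrix_genes:
                raise ValueError("planted bicluster indices exceed matrix shape")
        # genome capacity for the requested loops
        loops_per_chrom = math.ceil(self.n_loops / self.n_chroms)
        slot = self.chrom_len // loops_per_chrom
        if slot < 2 * self.anchor_len + LOOP_GAP + 200:
            raise ValueError(
                "genome capacity exceeded: "
                f"{self.n_loops} loops of {self.anchor_len} bp anchors do not fit "
                f"{self.n_chroms} x {self.chrom_len} bp chromosomes"
            )

    @property
    def tf_names(self) -> list[str]:
        return [f"TF{i + 1:02d}" for i in range(self.n_tfs)]

    @property
    def level_of(self) -> dict[str, int]:
        out = {}
        i = 0
        for lvl, size in enumerate(self.planted_levels, start=1):
            for _ in range(size):
                out[self.tf_names[i]] = lvl
                i += 1
        return out

    def _default_cliques(self, names: list[str]) -> list[set[str]]:
        """Cross-level cliques of size 3-4 over consecutive TFs of each level."""
        levels: list[list[str]] = []
        i = 0
        for size in self.planted_levels:
            levels.append(names[i : i + size])
            i += size
        n_cliques = max(2, min(len(l) for l in levels)) if len(levels) > 1 else 2
        n_cliques = min(n_cliques, 3)
        cliques = []
        for k in range(n_cliques):
            members = {lvl[k % len(lvl)] for lvl in levels}
            if len(members) >= 3:
                cliques.append(members)
        if len(cliques) < 2:  # tiny configs: fall back to sliding windows
            cliques = [set(names[:3]), set(names[-3:])]
        return cliques


@dataclass
class LandscapeBundle:
    genome: dict[str, str]
    states: IntervalSet
    loops_by_cell: dict[str, list[Loop]]
    peaksets: list[IntervalSet]
    pwms: list[PWMRecord]
    tss: IntervalSet
    truth: dict


@dataclass
class NetworkTruthBundle:
    ppi_edges: list[PPIEdge]
    directed_influences: list[tuple[str, str]]
    expression_by_cell: dict[str, pd.DataFrame]
    clique_gene_matrix: pd.DataFrame
    truth: dict


def _random_consensus(rng: np.random.Generator, width: int, taken: set[str]) -> str:
    while True:
        s = "".join(BASES[i] for i in rng.integers(0, 4, size=width))
        if s not in taken:
            taken.add(s)
            return s


def simulate_regulatory_landscape(config: FixtureConfig) -> LandscapeBundle:
    """Genome, chromatin states, loops, peak sets, PWMs and TSS with planted
    occupancy/co-localization truth.  Deterministic given ``config.seed``."""
    rng = np.random.default_rng(config.seed)
    names = config.tf_names
    chroms = [f"chr{i + 1}" for i in range(config.n_chroms)]
    genome = {
        c: bytearray(
            "".join(BASES[i] for i in rng.integers(0, 4, size=config.chrom_len)), "ascii"
        )
        for c in chroms
    }

    taken: set[str] = set()
    consensus = {t: _random_consensus(rng, config.motif_width, taken) for t in names}
    pwms = []
    for t in names:
        m = np.full((config.motif_width, 4), 0.01)
        for j, base in enumerate(consensus[t]):
            m[j, BASES.index(base)] = 0.97
        pwms.append(PWMRecord(f"M_{t}", t, m))

    # --- loops, states, TSS, implanted motifs -----------------------------
    loops_per_chrom = math.ceil(config.n_loops / config.n_chroms)
    slot = config.chrom_len // loops_per_chrom
    n_ep = round(config.fraction_ep * config.n_loops)
    cliques = config.planted_cliques
    states_iv: list[GenomicInterval] = []
    tss_iv: list[GenomicInterval] = []
    all_loops: list[tuple[Loop, int | None]] = []  # (loop, owning clique index)
    for i in range(config.n_loops):
        chrom = chroms[i % config.n_chroms]
        j = i // config.n_chroms
        base = j * slot + 100
        enh = GenomicInterval(chrom, base, base + config.anchor_len)
        pstart = base + config.anchor_len + LOOP_GAP
        prom = GenomicInterval(chrom, pstart, pstart + config.anchor_len)
        if i < n_ep:
            k = i % len(cliques)
            states_iv.append(GenomicInterval(chrom, enh.start, enh.end, label="Strong_Enhancer"))
            states_iv.append(GenomicInterval(chrom, prom.start, prom.end, label="Active_Promoter"))
            tss_pos = prom.start + config.anchor_len // 2
            tss_iv.append(GenomicInterval(chrom, tss_pos, tss_pos + 1, label=f"GENE{i:03d}", strand="+"))
            for rank, t in enumerate(sorted(cliques[k])):
                off = 5 + rank * (config.motif_width + 3)
                for anchor in (enh, prom):
                    pos = anchor.start + off
                    genome[chrom][pos : pos + config.motif_width] = consensus[t].encode()
            tags = 6 + int(rng.integers(0, 10))
            all_loops.append((Loop(enh, prom, tags), k))
        else:
            # non-EP decoys: promoter-promoter or quiescent pairs, mixed tags
            label = "Active_Promoter" if i % 2 == 0 else "Quiescent"
            states_iv.append(GenomicInterval(chrom, enh.start, enh.end, label=label))
            states_iv.append(GenomicInterval(chrom, prom.start, prom.end, label=label))
            tags = 3 if i % 3 == 0 else 8
            all_loops.append((Loop(enh, prom, tags), None))

    # per-cell loop subsets: each cell misses a different residue class, so
    # most loops (and cliques) are shared and some are cell-specific
    loops_by_cell: dict[str, list[Loop]] = {}
    for ci, cell in enumerate(config.cell_lines):
        kept = [
            lp for idx, (lp, _) in enumerate(all_loops)
            if len(config.cell_lines) == 1 or idx % 5 != ci % 5
        ]
        loops_by_cell[cell] = kept

    # --- ChIP-Seq peak sets with planted co-localization ------------------
    half = PEAK_WIDTH // 2
    lo, hi = half + JITTER + 1, config.chrom_len - half - JITTER - 1
    n_shared = math.ceil(SHARED_FRACTION * config.peaks_per_tf)
    core_mids = {
        k: [
            (chroms[int(rng.integers(0, config.n_chroms))], int(rng.integers(lo, hi)))
            for _ in range(n_shared)
        ]
        for k in range(len(cliques))
    }
    clique_of: dict[str, int | None] = {}
    for t in names:
        clique_of[t] = next((k for k, c in enumerate(cliques) if t in c), None)
    peaksets = []
    level_of = config.level_of
    for t in names:
        mids: list[tuple[str, int]] = []
        k = clique_of[t]
        if k is not None:
            for chrom, mid in core_mids[k]:
                mids.append((chrom, mid + int(rng.integers(-JITTER, JITTER + 1))))
        # private peaks; lower planted levels carry a few more, which makes
        # the 1D similarity asymmetric in the downward direction
        n_private = config.peaks_per_tf - len(mids) + 2 * (level_of[t] - 1)
        for _ in range(max(n_private, 1)):
            mids.append((chroms[int(rng.integers(0, config.n_chroms))], int(rng.integers(lo, hi))))
        peaksets.append(
            IntervalSet(t, [GenomicInterval(c, m - half, m + half) for c, m in mids])
        )

    truth = {
        "consensus": consensus,
        "clique_of_loop": {i: k for i, (_, k) in enumerate(all_loops) if k is not None},
        "gene_of_loop": {i: f"GENE{i:03d}" for i in range(n_ep)},
        "planted_cliques": [sorted(c) for c in cliques],
        "planted_levels": config.planted_levels,
    }
    return LandscapeBundle(
        genome={c: g.decode() for c, g in genome.items()},
        states=IntervalSet("states", states_iv),
        loops_by_cell=loops_by_cell,
        peaksets=peaksets,
        pwms=pwms,
        tss=IntervalSet("tss", tss_iv),
        truth=truth,
    )


def _clique_is_maximal(adj: dict[str, set[str]], clique: set[str]) -> bool:
    others = set(adj) - clique
    return not any(clique <= adj[z] for z in others)


def simulate_network_truth(config: FixtureConfig) -> NetworkTruthBundle:
    """PPI table, directed influences, expression and clique x gene matrix
    with planted hierarchy/communities/cliques/biclusters."""
    rng = np.random.default_rng(config.seed + 1)
    names = config.tf_names
    cliques = config.planted_cliques
    for c in cliques:
        if not any(c <= com for com in config.planted_communities):
            raise ValueError("inconsistent plant: clique outside every community")

    # --- PPI: planted cliques complete and maximal, communities denser ----
    adj: dict[str, set[str]] = {t: set() for t in names}

    def add_edge(a: str, b: str) -> None:
        adj[a].add(b)
        adj[b].add(a)

    for c in cliques:
        mem = sorted(c)
        for i in range(len(mem)):
            for j in range(i + 1, len(mem)):
                add_edge(mem[i], mem[j])
    # sparse intra-community bridges that do not extend any planted clique
    for com in config.planted_communities:
        mem = sorted(com)
        for a, b in zip(mem, mem[1:]):
            if b in adj[a]:
                continue
            add_edge(a, b)
            if not all(_clique_is_maximal(adj, c) for c in cliques):
                adj[a].discard(b)
                adj[b].discard(a)

    edges: list[PPIEdge] = []
    for a in sorted(adj):
        for b in sorted(adj[a]):
            if a < b:
                score = 500 + int(rng.integers(0, 400))
                edges.append(PPIEdge(a, b, "string_db", score=float(score)))
                edges.append(PPIEdge(a, b, "biogrid", evidence="experimental"))
    # decoys exercising the intersection filters
    if len(names) >= 4:
        edges.append(PPIEdge(names[0], "NONTF1", "string_db", score=800.0))
        edges.append(PPIEdge(names[0], names[-1], "string_db", score=300.0))
        edges.append(PPIEdge(names[1], names[-1], "biogrid", evidence="text-mining"))

    # --- directed influences consistent with the planted levels -----------
    level_of = config.level_of
    down = [
        (a, b)
        for a in names
        for b in names
        if level_of[a] < level_of[b]
    ]
    rng.shuffle(down)
    # keep a layered subset: every adjacent-level pair plus extra density
    chosen = [e for e in down if level_of[e[1]] - level_of[e[0]] == 1]
    extra = [e for e in down if level_of[e[1]] - level_of[e[0]] > 1]
    chosen += extra[: max(1, len(extra) // 3)]
    n_up = int(config.upward_edge_fraction * len(chosen))
    influences = [(b, a) for a, b in chosen[:n_up]] + chosen[n_up:]

    # --- expression: one latent profile per clique, per cell --------------
    clique_of: dict[str, int | None] = {
        t: next((k for k, c in enumerate(cliques) if t in c), None) for t in names
    }
    expression_by_cell: dict[str, pd.DataFrame] = {}
    for cell in config.cell_lines:
        cols = [f"{cell}_rep{r + 1}" for r in range(config.n_replicates)]
        latent = {k: rng.uniform(1.0, 10.0, size=config.n_replicates) for k in range(len(cliques))}
        data = {}
        for t in names:
            k = clique_of[t]
            if k is None:
                prof = rng.uniform(1.0, 10.0, size=config.n_replicates)
            else:
                prof = latent[k] + rng.uniform(0.0, 2.0)  # per-TF offset keeps ranks
            noise = (
                rng.normal(0.0, config.expression_noise_sd, size=config.n_replicates)
                if config.expression_noise_sd > 0
                else 0.0
            )
            data[t] = prof + noise
        expression_by_cell[cell] = pd.DataFrame.from_dict(
            data, orient="index", columns=cols
        ).round(6)

    # --- planted clique x gene bicluster matrix ---------------------------
    M = np.zeros((config.n_matrix_cliques, config.n_matrix_genes))
    for rows, colset in config.planted_biclusters:
        M[np.ix_(sorted(rows), sorted(colset))] = 1.0
    matrix = pd.DataFrame(
        M,
        index=[f"clique{r:02d}" for r in range(config.n_matrix_cliques)],
        columns=[f"gene{g:03d}" for g in range(config.n_matrix_genes)],
    )

    truth = {
        "levels": level_of,
        "n_levels": len(config.planted_levels),
        "planted_cliques": [sorted(c) for c in cliques],
        "planted_communities": [sorted(c) for c in config.planted_communities],
        "planted_biclusters": [
            [sorted(r), sorted(g)] for r, g in config.planted_biclusters
        ],
    }
    return NetworkTruthBundle(edges, influences, expression_by_cell, matrix, truth)


def write_input_bundle(config: FixtureConfig, outdir: str | Path) -> Path:
    """Write the full synthetic input bundle (plus ``truth/*.json``) to disk.

    Layout: shared genome/motifs/peaks/PPI/TSS at the top level, per-cell
    contact lists (split into two "antibody" files with a few duplicated
    contacts), states and expression under ``cells/<cell>/``.
    """
    out = Path(outdir)
    land = simulate_regulatory_landscape(config)
    net = simulate_network_truth(config)
    (out / "peaks").mkdir(parents=True, exist_ok=True)
    (out / "truth").mkdir(exist_ok=True)
    write_fasta(land.genome, out / "genome.fa")
    write_pwms(land.pwms, out / "motifs.meme")
    write_intervals(land.tss, out / "tss.bed")
    write_intervals(land.states, out / "states.bed")
    write_edge_table(net.ppi_edges, out / "ppi.tsv")
    for ps in land.peaksets:
        write_intervals(ps, out / "peaks" / f"{ps.name}.bed")
    for cell in config.cell_lines:
        cdir = out / "cells" / cell
        cdir.mkdir(parents=True, exist_ok=True)
        loops = land.loops_by_cell[cell]
        write_loops(loops[::2] + loops[:2], cdir / "loops_ab1.bedpe")
        write_loops(loops[1::2] + loops[:2], cdir / "loops_ab2.bedpe")
        write_expression(net.expression_by_cell[cell], cdir / "expression.tsv")
    net.clique_gene_matrix.to_csv(out / "clique_gene_matrix.tsv", sep="\t", index_label="clique")
    with open(out / "truth" / "landscape.json", "w") as fh:
        json.dump(land.truth, fh, indent=1, sort_keys=True)
    with open(out / "truth" / "network.json", "w") as fh:
        json.dump(
            {**net.truth, "directed_influences": net.directed_influences},
            fh,
            indent=1,
            sort_keys=True,
        )
    cfg = asdict(config)
    cfg["planted_communities"] = [sorted(c) for c in config.planted_communities]
    cfg["planted_cliques"] = [sorted(c) for c in config.planted_cliques]
    cfg["planted_biclusters"] = [[sorted(r), sorted(g)] for r, g in config.planted_biclusters]
    with open(out / "truth" / "config.json", "w") as fh:
        json.dump(cfg, fh, indent=1, sort_keys=True)
    return out
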