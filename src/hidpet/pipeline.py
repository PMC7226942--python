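"""End-to-end orchestration: from input bundle to all network analyses.

``run_pipeline`` wires the stages in dependency order for every
configured cell line — enhancer-promoter loop filtering, the 1D
co-localization matrix (shared across cells), motif-based TF lists,
the PPI-restricted 3D matrix, similarity network fusion, hierarchy
inference, overlapping communities, maximal cliques, cross-cell clique
comparison and patterns, expression coherence, and clique-gene
biclustering — writing every stage's output plus a deterministic run
manifest (input hashes, parameters, seed).  A stage failure aborts the
run with the failing stage named; outputs written so far are retained.
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import yaml

from . import __version__
from .biclustering import build_clique_gene_matrix, extract_superclique_graph, fit_fabia
from .cliques import (
    classify_clique_patterns,
    compare_cliques_across_cells,
    expression_coherence,
    find_communities,
    map_clique_spans,
    maximal_cliques,
    regulated_genes,
)
from .colocalization import build_1d_matrix, chromosome_extents, derive_directions, SimilarityMatrix
from .formats import (
    IntervalSet,
    read_edge_table,
    read_expression,
    read_fasta,
    read_intervals,
    read_loops,
    read_pwms,
    write_loops,
)
from .fusion import FusionConfig, binarize_and_orient, build_3d_matrix, snf_fuse
from .hierarchy import AnnealConfig, fit_hierarchy, level_link_ratios
from .loops import LoopSet, annotate_anchors, filter_ep_loops, merge_contacts
from .motifs import ScanConfig, build_tf_lists

log = logging.getLogger(__name__)

__all__ = ["CellConfig", "RunConfig", "PipelineError", "run_pipeline"]


class PipelineError(RuntimeError):
    """Raised when a stage fails; the message names the stage."""


@dataclass
class CellConfig:
    name: str
    loops: list[str]  # one BEDPE per antibody
    states: str
    expression: str


@dataclass
class RunConfig:
    out_dir: str
    genome: str
    pwms: str
    tss: str
    ppi: str
    peaks_dir: str
    cells: list[CellConfig]
    seed: int = 0
    min_tags: int = 5
    alpha: float = 0.05
    p_threshold: float = 1e-10
    pastaa_p: float = 0.05
    string_min_score: float = 400.0
    fusion_K: int | None = None
    fusion_t: int = 20
    L_min: int = 2
    L_max: int = 8
    anneal_restarts: int = 10
    anneal_steps_per_node: int = 200
    anneal_permutations: int = 1000
    clique_min_size: int = 3
    clique_max_size: int = 10
    bicluster_factors: int = 10
    bicluster_iters: int = 10000

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        raw = yaml.safe_load(Path(path).read_text())
        cells = [CellConfig(**c) for c in raw.pop("cells")]
        return cls(cells=cells, **raw)

    def input_paths(self) -> list[str]:
        paths = [self.genome, self.pwms, self.tss, self.ppi]
        for c in self.cells:
            paths += list(c.loops) + [c.states, c.expression]
        return paths


def _sha256(path: str | Path) -> str:
    h = hashlib.sha256()
    h.update(Path(path).read_bytes())
    return h.hexdigest()


def _write_json(obj, path: Path) -> None:
    path.write_text(json.dumps(obj, indent=1, sort_keys=True) + "\n")


def run_pipeline(config: RunConfig) -> dict:
    """Run every stage and return the artifact manifest (also written to
    ``<out_dir>/manifest.json``).  Deterministic for a fixed config/seed."""
    out = Path(config.out_dir)

    missing = [p for p in config.input_paths() if not Path(p).exists()]
    peaks_dir = Path(config.peaks_dir)
    if not peaks_dir.is_dir():
        missing.append(str(peaks_dir))
    if missing:
        raise PipelineError(f"stage preflight failed: missing inputs: {sorted(missing)}")
    if not config.cells:
        raise PipelineError("stage preflight failed: no cell lines configured")

    out.mkdir(parents=True, exist_ok=True)
    outputs: list[str] = []

    def emit(rel: str) -> Path:
        outputs.append(rel)
        p = out / rel
        p.parent.mkdir(parents=True, exist_ok=True)
        return p

    def stage(name):
        class _Ctx:
            def __enter__(self):
                log.info("stage %s: start", name)

            def __exit__(self, exc_type, exc, tb):
                if exc is not None:
                    raise PipelineError(f"stage {name} failed: {exc}") from exc
                log.info("stage %s: done", name)

        return _Ctx()

    # --- shared inputs ----------------------------------------------------
    with stage("load_inputs"):
        genome = read_fasta(config.genome)
        pwms = read_pwms(config.pwms)
        tss = read_intervals(config.tss, "bed6")
        ppi = read_edge_table(config.ppi)
        peaksets = [
            read_intervals(p, "bed3") for p in sorted(peaks_dir.glob("*.bed"))
        ]

    # --- 1D co-localization matrix (cell-independent) ---------------------
    with stage("matrix_1d"):
        domain = IntervalSet(
            "domain",
            [
                iv
                for iv in chromosome_extents(peaksets)
            ],
        )
        m1d = build_1d_matrix(peaksets, domain, alpha=config.alpha)
        m1d.write_tsv(emit("matrix_1d.tsv"))

    scan_cfg = ScanConfig(p_threshold=config.p_threshold)
    fusion_cfg = FusionConfig(
        K=config.fusion_K, t=config.fusion_t, string_min_score=config.string_min_score
    )
    anneal_cfg = AnnealConfig(
        restarts=config.anneal_restarts,
        steps_per_node=config.anneal_steps_per_node,
        permutations=config.anneal_permutations,
        seed=config.seed,
    )

    per_cell_cliques = {}
    per_cell_patterns_input = {}
    per_cell_artifacts = {}
    for cell in config.cells:
        cdir = f"cells/{cell.name}"

        with stage(f"{cell.name}:loops"):
            states = read_intervals(cell.states, "bed4")
            loopsets = []
            for path in cell.loops:
                raw = read_loops(path)
                annotated = annotate_anchors(raw, states)
                loopsets.append(
                    filter_ep_loops(annotated, cell.name, min_tags=config.min_tags)
                )
            ep_loops = merge_contacts(loopsets)
            write_loops(ep_loops, emit(f"{cdir}/ep_loops.bedpe"))

        with stage(f"{cell.name}:tf_lists"):
            tf_lists = build_tf_lists(
                ep_loops, genome, pwms, scan_cfg, pastaa_p=config.pastaa_p
            )
            _write_json(
                {
                    "list_A": sorted(tf_lists.enhancer_tfs),
                    "list_B": sorted(tf_lists.promoter_tfs),
                    "final": tf_lists.final,
                },
                emit(f"{cdir}/tf_lists.json"),
            )

        with stage(f"{cell.name}:fusion"):
            shared = [t for t in m1d.tf_names if t in set(tf_lists.final)]
            if len(shared) < 3:
                raise ValueError(
                    f"only {len(shared)} TFs shared between 1D matrix and final list"
                )
            m3d = build_3d_matrix(shared, ppi, fusion_cfg)
            m1d_sub = m1d.restrict(shared)
            fused = snf_fuse(m1d_sub, m3d, fusion_cfg)
            directed = derive_directions(m1d_sub)
            network = binarize_and_orient(fused, shared, directed, fusion_cfg)
            network.to_json(emit(f"{cdir}/network.json"))

        with stage(f"{cell.name}:hierarchy"):
            hierarchy = fit_hierarchy(
                network, range(config.L_min, config.L_max + 1), anneal_cfg
            )
            _write_json(
                {
                    "L": hierarchy.L,
                    "corrected_score": round(hierarchy.corrected_score, 6),
                    "raw_score": round(hierarchy.raw_score, 6),
                    "levels": hierarchy.levels,
                    "level_probabilities": hierarchy.level_probabilities,
                    "scores_by_L": {
                        str(L): round(s, 6) for L, s in hierarchy.scores_by_L.items()
                    },
                },
                emit(f"{cdir}/hierarchy.json"),
            )
            ratios, flagged = level_link_ratios(network, hierarchy)
            with open(emit(f"{cdir}/level_link_ratios.tsv"), "w") as fh:
                fh.write("# flagged_levels: " + ",".join(map(str, flagged)) + "\n")
                for row in ratios:
                    fh.write("\t".join(f"{x:.6f}" for x in row) + "\n")

        with stage(f"{cell.name}:communities"):
            graph = network.graph()
            communities = find_communities(graph)
            _write_json(
                [
                    {"members": sorted(c.members), "cohesiveness": round(c.cohesiveness, 6)}
                    for c in communities
                ],
                emit(f"{cdir}/communities.json"),
            )

        with stage(f"{cell.name}:cliques"):
            cliques = maximal_cliques(
                graph, config.clique_min_size, config.clique_max_size, cell.name
            )
            spans = map_clique_spans(
                [c for c in cliques if all(t in hierarchy.levels for t in c.members)],
                hierarchy,
                communities,
            )
            spans.to_csv(emit(f"{cdir}/clique_spans.tsv"), sep="\t", index=False)
            reg = [
                regulated_genes(c, ep_loops, tf_lists.occurrences, tss) for c in cliques
            ]
            _write_json(
                [
                    {"members": sorted(c.members), "regulated_genes": sorted(g)}
                    for c, g in zip(cliques, reg)
                ],
                emit(f"{cdir}/cliques.json"),
            )
            per_cell_cliques[cell.name] = cliques
            per_cell_patterns_input[cell.name] = [
                (c.members, g) for c, g in zip(cliques, reg)
            ]

        with stage(f"{cell.name}:coherence"):
            expr = read_expression(cell.expression)
            expr = expr.loc[[t for t in expr.index if t in set(network.tf_names)]]
            try:
                coh = expression_coherence(cliques, expr)
                payload = {
                    "wilcoxon_p": coh.wilcoxon_p,
                    "n_within": len(coh.within_pair_correlations),
                    "n_between": len(coh.between_pair_correlations),
                    "mean_within": round(float(np.mean(coh.within_pair_correlations)), 6),
                    "mean_between": round(float(np.mean(coh.between_pair_correlations)), 6),
                }
            except ValueError as exc:
                payload = {"note": f"coherence not computable: {exc}"}
            _write_json(payload, emit(f"{cdir}/coherence.json"))

        per_cell_artifacts[cell.name] = {
            "ep_loops": ep_loops,
            "cliques": cliques,
            "regulated": reg,
        }

    # --- cross-cell analyses ----------------------------------------------
    if len(config.cells) >= 2:
        with stage("clique_venn"):
            regions = compare_cliques_across_cells(per_cell_cliques)
            _write_json(
                {
                    "+".join(cells): sorted(",".join(sorted(m)) for m in members)
                    for cells, members in regions.items()
                },
                emit("clique_venn.json"),
            )
        with stage("clique_patterns"):
            patterns = classify_clique_patterns(per_cell_patterns_input)
            _write_json(patterns, emit("clique_patterns.json"))

    # --- biclustering on the first cell's clique x gene matrix ------------
    first = config.cells[0].name
    art = per_cell_artifacts[first]
    with stage("biclustering"):
        universe = sorted(set().union(*art["regulated"], set()))
        if art["cliques"] and universe:
            matrix = build_clique_gene_matrix(art["cliques"], art["regulated"], universe)
            F = min(config.bicluster_factors, min(matrix.shape))
            model = fit_fabia(
                matrix, F=F, max_iter=config.bicluster_iters, seed=config.seed
            )
            graph = extract_superclique_graph(model, matrix)
            payload = {
                "F": F,
                "iterations_run": model.iterations_run,
                "supercliques": graph.supercliques,
                "gene_groups": graph.gene_groups,
                "edges": [list(e) for e in graph.edges],
            }
        else:
            payload = {"note": "no cliques with regulated genes; biclustering skipped"}
        _write_json(payload, emit("supercliques.json"))
        matrix_path = emit("clique_gene_matrix.tsv")
        if art["cliques"] and universe:
            matrix.to_csv(matrix_path, sep="\t", index_label="clique")
        else:
            matrix_path.write_text("clique\n")

    # --- manifest ----------------------------------------------------------
    with stage("manifest"):
        manifest = {
            "version": __version__,
            "seed": config.seed,
            "parameters": {
                k: v
                for k, v in vars(config).items()
                if k not in ("cells",) and not k.startswith("_")
            },
            "cells": [c.name for c in config.cells],
            "inputs": {str(p): _sha256(p) for p in sorted(config.input_paths())},
            "outputs": sorted(outputs),
        }
        _write_json(manifest, out / "manifest.json")
    return manifest
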