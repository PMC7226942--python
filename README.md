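# hidpet

Hierarchy and dynamics of transcription-factor (TF) cooperation at
enhancer–promoter chromatin loops, from the integration of three data
layers: 1D TF co-localization (ChIP-Seq peak sets), 3D chromatin
contacts (ChIA-PET-style loop lists with tag counts), and
protein–protein interactions (STRING + BioGRID style edge tables).

The package is for regulatory genomicists who have, per cell line, a
contact list with chromatin-state annotations, a collection of TF peak
sets and motifs, and PPI tables — and who want to know *which TFs
cooperate at enhancer–promoter loops, how that cooperation is
organized (hierarchy, communities, cliques), and how it changes across
cell lines*.

## Method

For each cell line the pipeline builds a fused TF network and then
characterizes it:

1. **EP loops.** Contacts are annotated with chromatin states; loops
   with more than five supporting tags whose anchors carry concurrent
   enhancer-class and promoter-class states are kept, and duplicate
   contacts across antibodies are merged (tags summed).
2. **1D matrix.** For TF peak sets, the per-peak significance of
   proximity to another TF's peaks is the placement p-value: the
   fraction of all placements of an interval of length |q| in the
   analysis domain that lie at distance ≤ the observed distance from
   the reference set. The ordered similarity is
   `s(a→b) = |{q ∈ peaks(a) : p(q | peaks(b)) < α}| / |peaks(a)|`
   with α = 0.05 — an asymmetric TF×TF matrix (237 TFs give 55,932
   ordered pairs).
3. **TF lists.** Enhancer anchors are scanned with PWMs using exact
   log-odds p-values (dynamic programming over the discretized null
   score distribution, threshold 1e-10); promoter-side presence uses a
   minimal-hypergeometric rank enrichment of anchors ordered by best
   site score. The final list is the intersection of the
   enhancer-present and promoter-present TFs.
4. **3D matrix and fusion.** PPI edges kept only when supported by
   STRING (score > 400) *and* BioGRID (experimental evidence), and
   restricted to the final TF list, give a binary 3D matrix. The 1D
   and 3D matrices over their shared TFs are merged by similarity
   network fusion (cross-diffusion of full kernels through K-NN local
   kernels), binarized at the mean off-diagonal weight, and oriented
   by the 1D asymmetry (`a→b` iff `s(a→b) > s(b→a)`).
5. **Network analyses.** Hierarchy levels by simulated annealing on
   the permutation-corrected hierarchy score (raw score = mean edge
   direction sign; levels L searched over 2..8); overlapping
   communities by greedy growth on cohesiveness
   `f(V) = w_in / (w_in + w_bound + p|V|)`; maximal cliques (sizes
   3–10) by Bron–Kerbosch with pivoting; cross-cell Venn partition and
   pattern classes of shared cliques; within- vs between-clique
   expression coherence (Spearman ρ, one-sided Wilcoxon rank-sum);
   and biclustering of the binary clique×gene regulation matrix with a
   sparse factor model `X ≈ ΛZ` into supercliques and gene groups.

Because the real datasets behind the method are external downloads,
the package ships a first-class synthetic-data generator
(`hidpet.synth`) that emits every input format at desk scale with
planted truth — co-localized peak cores, implanted motif consensus
sites, planted PPI cliques/communities, a planted 3-level influence
network, correlated expression blocks, and planted biclusters — so
every stage's recovery is testable.

## Worked example

```bash
hidpet sim --seed 1 --out bundle/          # synthetic 2-cell input bundle
hidpet run --config run.yaml               # or drive the API directly
```

```python
from hidpet.synth import FixtureConfig, write_input_bundle
from hidpet.pipeline import RunConfig, CellConfig, run_pipeline

write_input_bundle(FixtureConfig(seed=1), "bundle")
cells = [CellConfig(c, [f"bundle/cells/{c}/loops_ab1.bedpe",
                        f"bundle/cells/{c}/loops_ab2.bedpe"],
                    "bundle/states.bed", f"bundle/cells/{c}/expression.tsv")
         for c in ("cellA", "cellB")]
run_pipeline(RunConfig(out_dir="run", genome="bundle/genome.fa",
                       pwms="bundle/motifs.meme", tss="bundle/tss.bed",
                       ppi="bundle/ppi.tsv", peaks_dir="bundle/peaks",
                       cells=cells, seed=7,
                       anneal_restarts=5, anneal_steps_per_node=100))
```

On this bundle (12 TFs, 40 loops, 2 cells) the run writes, for cellA:

- `tf_lists.json` — 9 TFs motif-present in both anchor classes (the
  three TFs planted in no clique are absent, as expected);
- `communities.json` — two overlapping communities,
  `{TF01,TF02,TF05,TF06,TF09,TF10}` and `{TF03,TF07,TF11}`;
- `cliques.json` — 3 maximal cliques, all shared with cellB
  (`clique_venn.json`: `cellA+cellB: 3`);
- `hierarchy.json` — a raw hierarchy score of 1.0 (every directed
  edge points downward under the fitted levels, corrected score 3.19);
- `coherence.json` — mean within-clique Spearman ρ 0.74 vs 0.22
  between cliques, one-sided Wilcoxon p = 5.4e-06: TFs that form a
  clique are co-expressed, TFs from different cliques are not;
- `supercliques.json` — the clique–gene bicluster graph, here a
  single superclique regulating one 8-gene group.

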