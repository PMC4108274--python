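# hrrgcn

Gene co-expression network inference from microarray (or any normalized,
log-scale) expression compendia using the **highest reciprocal rank (HRR)**
index, with permutation-based significance thresholds, guide-gene and Markov
(MCL) clustering, hypergeometric GO enrichment, and expression-specificity
profiling. It is aimed at researchers who want to go from an expression
matrix plus array metadata to annotated, condition-aware co-expression
modules — the guilt-by-association workflow used for gene function
prediction in non-model plants.

## The method

Pearson's *r* is computed between every probeset pair over the arrays of a
compendium (or a metadata-selected sub-compendium, e.g. fruit arrays only).
Each gene's partners are ranked by decreasing *r* (rank 1 = closest
partner), and the co-expression index of a pair is

```
HRR(A, B) = max(rank(A, B), rank(B, A))
```

Low HRR means *mutually* strong co-expression; taking the worse of the two
directional ranks discards one-sided relationships while retaining weak but
reciprocal ones. Downstream:

- **Significance** — the HRR null distribution is estimated by repeatedly
  shuffling every gene's values across arrays (100 permutations by default)
  and recomputing the full HRR matrix; a network-wide cutoff at level α is
  the largest h with P(HRR_null ≤ h) < α.
- **Guide clusters** — each gene seeds one cluster containing its top-k
  (default 100) partners by HRR: one overlapping cluster per probeset.
- **Thresholded networks & MCL** — pairs with HRR ≤ cutoff form an edge list
  with a uniform weight (0.2, 0.067, 0.04, 0.028, 0.022 for cutoffs 10, 20,
  30, 40, 50; w = 1/(cutoff−5) otherwise). A from-scratch Markov Cluster
  Algorithm (expansion/inflation flow simulation) partitions the graph;
  clusters with fewer than 3 members are discarded.
- **Enrichment & parameter selection** — per-cluster hypergeometric GO tests
  with Benjamini–Hochberg FDR per namespace (significant: FDR < 0.05 and ≥ 2
  genes). Clustering quality for an inflation sweep is scored by
  specificity (fraction of clusters with ≥ 1 significant term), sensitivity
  (fraction of annotations significant in ≥ 1 cluster) and their harmonic
  mean (F-measure).
- **Expression specificity** — ESI z-scores expression within each array and
  then within each gene (>1 well expressed, >5 specifically expressed);
  a cluster's cESI in an array or condition group is the fraction of members
  with ESI > 1 there.

A synthetic-data generator (`hrrgcn.synthetic_data`) plants latent-factor
co-expression modules — optionally active only under selected conditions —
with known ground truth and matching GO annotations, so the whole pipeline
is testable without any external download.

## Worked example

```python
import hrrgcn as h

modules = [
    h.ModuleSpec("M1", size=35, within_correlation=0.9, planted_terms=("GO:0000101",)),
    h.ModuleSpec("M2", size=35, within_correlation=0.9,
                 active_conditions={"organ": "fruit"}, planted_terms=("GO:0000102",)),
]
matrix, metadata, annotations, truth = h.generate(
    n_genes=300, n_arrays=40, modules=modules, seed=7
)

net = h.hrr_network(matrix)
dist = h.permutation_null(matrix, n_permutations=100, seed=7)
print("HRR cutoff at P<0.01:", dist.cutoff_at(0.01))   # HRR cutoff at P<0.01: 4
print("HRR cutoff at P<0.05:", dist.cutoff_at(0.05))   # HRR cutoff at P<0.05: 17

edges = h.threshold_network(net, cutoff=30)
print(len(edges.edges), edges.weight)                  # 3191 0.04

clustering = h.mcl(edges.edges, h.MCLParams(inflation=1.3))
print({cid: len(m) for cid, m in clustering.clusters.items()})
# {1: 230, 2: 35, 3: 35}

results = h.enrich_clustering(clustering, annotations, set(matrix.probeset_ids))
print(results[results["significant"]][["cluster_id", "term_id", "n_in_cluster", "fdr"]])
#  cluster_id    term_id  n_in_cluster          fdr
#           2 GO:0000101            35 6.645749e-38
#           3 GO:0000102            35 7.668172e-38

profile = h.cesi(clustering.clusters[3], h.esi(matrix), metadata, grouping="organ")
print(profile.per_group.round(3))
# flower 0.049 | fruit 0.580 | leaf 0.023 | root 0.037
```

The two planted 35-gene modules come back as clusters 2 and 3 (the 230-gene
cluster is the background hairball of reciprocal-rank noise edges), each
with its planted GO term at vanishing FDR, and the fruit-restricted module's
cESI peaks in fruit arrays. The permutation cutoff of 4 at P < 0.01 reflects
the network's size — null HRR cutoffs scale roughly like 0.012 × n.

The same pipeline is scriptable from the shell:

```
hrrgcn simulate --config sim.yaml --seed 7 --out data/
hrrgcn build-network --expr data/expression.tsv --meta data/metadata.tsv \
    --select organ=fruit --cutoff 30 --out fruit
hrrgcn cluster --edges fruit.edges.tsv --sweep 1.1:2.0:0.1 \
    --annot data/annotations.tsv --out fruit
hrrgcn run --config pipeline.yaml --seed 7 --out results/
```

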