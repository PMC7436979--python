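# netpharm

A tested, reusable network-pharmacology screening pipeline:

1. **Target integration** — compound→target association tables and disease
   target lists are loaded, normalized (uppercase/trim, de-duplicated,
   provenance-tagged), and intersected into a common-target set.
2. **Network construction** — a STRING-style PPI edge list (0–1 or 0–1000
   score dialect, auto-detected) is filtered at a strict confidence
   threshold (default `> 0.4`) and induced on the union of compound and
   disease targets; isolated targets are removed.
3. **Hub subnetwork** — the common targets plus their distance-1 neighbors
   are extracted as a full induced subgraph.
4. **Topological screening** — degree, normalized betweenness (Brandes,
   normalized by `(N−1)(N−2)/2`), and closeness (reciprocal mean distance
   to reachable nodes) are computed from scratch; key targets are the nodes
   with degree strictly above 2× the median and betweenness/closeness
   strictly above their medians.
5. **Over-representation analysis** — hypergeometric or EASE (one-overlap-
   discounted) tail tests against a GMT collection, BH adjustment, top-k
   selection, and case-insensitive mapping to a disease-pathway list.
6. **Downstream assembly** — compound–key-target networks, typed
   compound–target–pathway tripartite networks, and ligand-normalized
   docking-score ratio matrices with weak/moderate/strong categories and a
   heat-map + CSV twin.
7. **Synthetic data** — a fully seeded generator (preferential-attachment
   PPI with planted hubs, target sets sharing a planted common core, a
   planted over-represented gene set, a docking table with planted strong
   pairs) so every stage runs and is testable with no database access.

## CLI

Full pipeline from a YAML config:

```bash
netpharm run --config run.yaml --outdir out/
```

Config is a declarative tree with either an `inputs:` block
(`compound_targets`, `disease_targets`, `ppi`, optional `genesets`,
`disease_pathways`, `docking`) or a `simulate:` block (synthetic-generator
fields incl. `seed`), plus an optional `params:` block
(`min_score: 0.4`, `degree_fold: 2`, `alpha: 0.05`, `top_k: 15`,
`method: ease`, `adjust: bh`, `ratio_cutoffs: [0.8, 1.0]`). The run writes
GraphML networks, the centrality/key-target table, the enrichment table,
docking ratio/category matrices, and a deterministic `report.json`
(identical config + seed ⇒ byte-identical outputs).

Stage-wise subcommands:

```bash
netpharm simulate --seed 7 --outdir fixtures/
netpharm build-network --compound-targets ct.tsv --disease-targets dt.tsv \
    --ppi ppi.tsv --min-score 0.4 --out ctot.graphml
netpharm hub --network ctot.graphml --seeds common --out hub.graphml
netpharm screen --network hub.graphml --degree-fold 2 \
    --out key_targets.tsv --report thresholds.json
netpharm enrich --genes key_targets.tsv --gmt kegg.gmt --method ease \
    --adjust bh --alpha 0.05 --top 15 \
    --disease-pathways ctd_list.txt --out enrichment.tsv
netpharm ctp-net --targets key_targets.tsv --gmt kegg.gmt \
    --pathways "TNF signaling pathway,HIF-1 signaling pathway" \
    --compound-targets ct.tsv --out ctp.graphml
netpharm dock-ratios --scores dock.csv --cutoffs 0.8,1.0 \
    --out ratios.csv --heatmap ratios.png
```

## Layout

```
src/netpharm/
  model.py       # domain types (targets, edges, networks, gene sets, docking)
  io.py          # TSV/CSV/GMT/docking/GraphML/SIF readers and writers
  network.py     # common targets, CT-OT build, hub extraction
  topology.py    # centralities from scratch + median-threshold screen
  enrichment.py  # hypergeometric/EASE ORA, BH, top-k, disease mapping
  downstream.py  # tripartite networks, docking ratios, heat map
  synthetic.py   # seeded generators with planted, recoverable structure
  pipeline.py    # orchestration, config validation, run report
  cli.py         # click command group
tests/           # unit, property (hypothesis) and acceptance suites
scripts/acceptance.py
```
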