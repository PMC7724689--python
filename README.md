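# netpharm

A local, tested network-pharmacology pipeline for herb–compound–target–disease
analysis. Every stage that the original workflow delegated to web databases is
either driven by local tables in the same dialects (TCMSP/BATMAN-style
ingredient TSVs, ingredient→target maps, gene lists, STRING-style interaction
TSVs, GMT annotation sets) or emulated by synthetic generators with planted,
exactly recoverable ground truth.

Stages:

1. **chem** — molecular formula parsing (subscript markup accepted), average /
   monoisotopic mass from an embedded atomic-weight table, the two
   pharmacokinetic candidate filters (OB/Caco-2/DL, score/adjusted-P), and
   cross-herb deduplication by normalized ingredient name.
2. **target_sets** — gene-symbol normalization against a supplied mapping
   table, per-ingredient target union, disease-source integration, and the
   overlap (Venn) summary.
3. **ppi_network** — scored undirected interaction graph at a confidence
   threshold; degree, unnormalized betweenness, Wasserman–Faust closeness and
   k-core coreness; network summary statistics; SIF/GraphML/TSV exports.
4. **enrichment** — hypergeometric over-representation per annotation term,
   Benjamini–Hochberg FDR per namespace, top-N selection, bubble/chord data
   exports.
5. **synthetic_data** — deterministic generators (ingredient tables, target
   maps, disease lists, interaction tables, annotation sets) that plant exact
   counts, overlaps and enriched terms, plus a one-call bundle writer.
6. **pipeline_cli** — YAML-configured end-to-end orchestration with a
   stage-count run log, and a `netpharm` CLI exposing each stage.

## CLI

```sh
# write a synthetic input bundle (tables + config.yaml + truth.json)
netpharm simulate --out bundle/ --seed 7

# run the full pipeline from its config
netpharm run --config bundle/config.yaml

# individual stages
netpharm filter --table ingredients_xuanshen.tsv --dialect TCMSP ...
netpharm targets --map ingredient_targets.tsv --out drug_targets.tsv
netpharm venn --drug drug.txt --disease-a a.txt --disease-b b.txt
netpharm network --edges string_interactions.tsv --out net/
netpharm enrich --query overlap.txt --gmt pathways.gmt --out enr.tsv
```

`run` writes candidate/target/overlap tables, Cytoscape-ready network exports
(SIF, GraphML, TSV), a per-node topology table, per-namespace enrichment
tables with bubble/chord exports, the tripartite herb–ingredient–target–disease
edge list, and `run_log.json` whose stage counts equal the artifact row counts.
All thresholds default to the published values (OB ≥ 30, Caco-2 ≥ 0.4,
DL ≥ 0.18; score ≥ 20, adjusted P < 0.05; interaction score 0.4; FDR 0.05).

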