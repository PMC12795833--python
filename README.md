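# cytoreg

Reconstruction and analysis of cytokine regulatory networks over typed
molecular knowledge graphs, with topology- and annotation-based
prioritization of cytokines as drug-repurposing candidates.

## The problem

Dysregulated cytokine signaling is repeatedly implicated in autism spectrum
disorder (ASD): pro-inflammatory cytokines secreted by activated microglia
shape synaptic pruning, neuronal migration and other neurodevelopmental
processes. Given a knowledge graph of molecular interactions — genes,
proteins, and five typed regulatory relations between them — one can ask:
*which cytokines exert the strongest regulatory influence on ASD-associated
genes and proteins, and which of those are already druggable?*

`cytoreg` answers this with a three-stage pipeline:

1. **Reconstruction.** Five declarative path templates describe the routes
   by which a cytokine protein can regulate an ASD-associated target:
   directly at the protein level (activity / transport / degradation
   regulation), transcriptionally, or relayed through a mediator gene-protein
   pair or a cytokine receptor. Matching each template against the knowledge
   graph yields a subnetwork; the subnetworks are merged into a consolidated
   regulatory network whose edges remember which templates produced them.
2. **Enrichment and prioritization.** The cytokine-regulated ASD genes are
   tested for GO biological-process over-representation with the exact
   upper-tail hypergeometric test,
   `P(X ≥ k), X ~ Hypergeom(N, K, n)`,
   with Bonferroni and Benjamini–Hochberg (FDR) adjustment. Cytokines are
   then ranked three ways: typed degree centrality, unnormalized Freeman
   betweenness centrality on the undirected simple projection, and a
   term-space hypergeometric test of each cytokine's representation in the
   disease-associated processes.
3. **Consensus and drug cross-reference.** The candidate set is the union of
   the three top lists, the consensus set their intersection, and every
   candidate is cross-referenced against a local drug-target table to
   classify it as an approved-drug target, investigational-only, or
   undrugged.

Because curated knowledge bases of this kind are proprietary, the package
ships a seeded synthetic generator that emulates the statistical structure
of such a graph (planted hub cytokines, enriched annotations, partial drug
coverage) together with a ground-truth record, plus a deterministic
structural benchmark with known outcome cardinalities.

## Worked example

```bash
cytoreg benchmark --out bench          # deterministic benchmark bundle
cat > bench/pipeline.yaml <<EOF
nodes: nodes.tsv
edges: edges.tsv
annotations: annotations.gmt
drugs: drugs.tsv
outdir: out
EOF
cytoreg run --config bench/pipeline.yaml
```

prints

```json
{
  "n_cytokines": 30,
  "top_degree_size": 15,
  "top_betweenness_size": 15,
  "process_list_size": 13,
  "candidate_count": 21,
  "consensus_count": 8
}
```

Reading: of the 30 regulator cytokines in the benchmark network, the top-15
lists by degree and betweenness and the 13 cytokines significantly
represented in disease processes (FDR < 0.05) union to 21 candidate
regulators, 8 of which rank at the top of **all three** metrics (the
consensus set). `out/xref.tsv` additionally classifies 8 of the 21
candidates as approved-drug targets. Per-stage artifacts
(`consolidated.tsv`, `summary.json`, `enrichment.tsv`, `ranking.tsv`,
`xref.tsv`, `report.json`) are written to `bench/out/`.

Synthetic data with a planted ground truth instead of the fixed benchmark:

```bash
cytoreg simulate --seed 7 --out fixture/   # nodes/edges/annotations/drugs + truth.json
```

## Library overview

| module | contents |
| --- | --- |
| `cytoreg.graph` | typed graph model, TSV/GraphML/SIF/GMT readers and writers |
| `cytoreg.templates` | path templates, DFS matcher, subnetwork merge, summary |
| `cytoreg.enrichment` | exact hypergeometric ORA, Bonferroni, BH-FDR |
| `cytoreg.prioritize` | centralities, process representation, consensus ranking |
| `cytoreg.drugs` | drug-target table, candidate cross-reference |
| `cytoreg.simulate` | seeded synthetic generator and fixture bundles |
| `cytoreg.fixtures` | deterministic structural benchmark |
| `cytoreg.pipeline`, `cytoreg.cli` | end-to-end orchestration and CLI |

See `docs/methods.md` for the statistical model, parameter defaults, and
known limitations.
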