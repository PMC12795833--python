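# Methods

This note documents the models, statistics and design choices behind
`cytoreg`, in the order the pipeline applies them.

## Knowledge-graph model

The graph is a directed multigraph keyed by
`(source, target, interaction_type)` — at most one edge per triple, with
duplicate inputs collapsed and their provenance sets unioned. Nodes have
exactly one kind (`gene` or `protein`) and a set of role categories
(`cytokine`, `cytokine_receptor`, `asd_associated`, `mediator`, `other`;
an empty set defaults to `other`). Gene symbols are upper-cased at every
input boundary, since symbol-case conventions differ between source
databases and silent join failures are worse than forced normalization.

Five interaction types carry direction-typing rules enforced at load time:

| type | source kind | target kind |
| --- | --- | --- |
| `expression` | gene | protein |
| `expression_regulation` | any | gene |
| `activity_regulation` | any | protein |
| `transport_regulation` | any | protein |
| `degradation_regulation` | any | protein |

Edges carry no activation/inhibition sign: the upstream knowledge sources
this model mirrors do not consistently provide one, so the pipeline ranks
regulators by connectivity, not by direction of effect.

Node ids are opaque; the generators use the `SYMBOL:gene` /
`SYMBOL:protein` convention so that a gene and its product can coexist
under one symbol. TSV is the primary on-disk format (edge table plus a
`.nodes.tsv` companion); GraphML round-trips all metadata; SIF is a lossy
export for viewers and requires the node table on re-import.

## Path templates and reconstruction

A template is a chain of slot constraints (kind + required categories, with
the first slot labelled `source_cytokine` and the last `asd_target`) joined
by sets of allowed interaction types. The five defaults:

* **T1** cytokine protein → ASD protein (activity/transport/degradation);
* **T2** cytokine protein → mediator gene (`expression_regulation`) →
  mediator protein (`expression`) → ASD protein;
* **T3** cytokine protein → ASD gene (`expression_regulation`);
* **T4** cytokine protein → mediator protein (`activity_regulation`) →
  ASD gene;
* **T5** cytokine protein → receptor protein (`activity_regulation`) →
  ASD gene.

These cover direct and one-step-mediated regulation of both proteins and
genes; longer mediator chains are deliberately out of scope (each extra
slot multiplies the match space without changing which cytokines reach
which targets in one documented hop class). All five are overridable from
a YAML config with the same controlled vocabularies.

Matching enumerates **injective** assignments (all slot nodes distinct;
a path that revisits a node is not a regulatory chain) by depth-first
extension from the candidate set of the first slot. When two allowed edge
types connect the same slot pair, each satisfying edge yields its own
match, so the merged subnetwork retains every typed interaction.
Correctness is defined by a brute-force oracle — exhaustive filtering of
all ordered node tuples — and the test suite checks exact agreement on
hundreds of random type-valid graphs. All outputs are sorted by node-id
tuple, making every downstream artifact byte-reproducible.

Merging subnetworks unions nodes, edges (provenance sets unioned per
triple) and slot-role indices; the operation is idempotent, commutative
and associative, which the suite asserts on random triples. Manual
curation of extracted interactions is not computable; an optional edge
blacklist file takes its place.

## Over-representation statistics

The enrichment null is the standard one-sided upper-tail hypergeometric
(equivalently one-sided Fisher exact): for a background of `N` genes, a
term annotating `K` of them and a query of `n`, the p-value of an overlap
`k` is `P(X ≥ k)`. The tail is computed with arbitrary-precision integer
binomials and converted to float once, so every reported p-value is the
correctly rounded double of the exact rational — there is no asymptotic
approximation anywhere in the statistics.

Both corrections are computed for every analysis: Bonferroni (`p·m`
clamped at 1) and Benjamini–Hochberg step-up FDR
(`q_(i) = min_{j≥i} p_(j)·m/j`, clamped). Selection uses FDR < α with
α = 0.05 by default. Terms never annotating a background gene are excluded
before correction — untestable hypotheses only inflate `m`. The enrichment
background defaults to all gene symbols of the input graph and can be
overridden by supplying an explicit background to the annotation reader.

The enrichment query for stage 2 is the set of symbols of all
ASD-associated nodes under cytokine regulation in the consolidated
network — both regulated genes and regulated proteins, since annotations
are symbol-level and a regulated protein maps to its gene.

## Cytokine prioritization

Three metrics, deliberately simple and rank-based:

* **Degree** — typed multigraph degree over the consolidated network
  (incident edges, both directions). A cytokine regulating one target
  through two interaction types is more connected than one using a single
  type, mirroring how the consolidated network counts interactions.
* **Betweenness** — unnormalized Freeman betweenness via Brandes'
  algorithm on the **undirected simple projection** with unit weights,
  unordered pairs, endpoints excluded. Informal definitions of this metric
  vary between "number" and "fraction" of pass-through shortest paths; all
  such variants are monotone transformations of each other on a fixed
  graph, and only the rank order enters the pipeline. The projection
  choice (undirected, simple) makes the metric insensitive to edge-type
  multiplicity, which degree already captures.
* **Process representation** — a term-space hypergeometric test per
  cytokine: among the `N` terms of the annotation table, `K` are
  disease-associated (by default, the FDR-significant terms from stage 2);
  a cytokine annotated to `n` terms, `k` of them disease-associated, gets
  `P(X ≥ k)` with Bonferroni and BH correction **across the cytokines
  tested**, and enters the process list when FDR < 0.05 (a fixed-size
  `process_top_k` override exists).

Per-metric ranks are dense and 1-based after tie grouping; ties everywhere
break by descending score then ascending symbol, so rankings are
deterministic. The top-`k` lists default to k = 15 for both centralities.
The **candidate set** is the union of the three lists; the **consensus
set** is their intersection. Cytokine symbols are scored at their protein
node (the regulator); in the degenerate case of several regulator nodes
sharing a symbol their scores are summed.

Drug cross-reference matches candidates against a local drug-target TSV by
exact case-normalized symbol — no synonym resolution, because silent
synonym expansion would change counts unreproducibly. A candidate with at
least one approved record is an `approved_target`; only-investigational
matches give `investigational_target`; otherwise `no_known_drug`. The
three classes partition the candidate set.

## Synthetic generator

The generator emulates the statistical shape of a curated interaction
knowledge base, not its literal topology or gene identities:

* every symbol contributes a gene/protein node pair joined by one
  `expression` edge — this mirrors the two-node-type structure of such
  knowledge bases and makes all five templates instantiable;
* default population sizes follow the real input lists: 186 cytokines,
  114 receptors, 234 high-confidence ASD genes, plus 100 mediators and 50
  background symbols;
* each cytokine receives a Poisson number of planted regulatory paths
  (mean `paths_per_hub` = 20 for the `n_hubs` = 8 randomly chosen hubs,
  `paths_per_nonhub` = 1 otherwise), each path instantiating one
  uniformly chosen feasible template with uniformly chosen intermediates
  and targets;
* `noise_edges` (default 100) are sampled uniformly among type-valid
  triples — the simplest null with tunable signal-to-noise;
* annotations: the first `n_asd_terms` of `n_go_terms` flat GO-style terms
  annotate every targeted ASD symbol with probability
  `annotation_enrichment` (0.9) and every other symbol with
  `background_annotation` (0.05); a cytokine whose planted targets
  intersect a disease-like term's gene set is annotated to it with
  probability `regulator_annotation` (0.9) — regulators participate in the
  processes they regulate, which is what links the planted topological
  signal to the functional metric;
* the drug table covers a `drug_coverage` fraction of cytokines (default
  8/21, the approved-target fraction among prioritized candidates in the
  motivating analysis) with approved records.

Everything derives from one integer seed (annotations and drug sampling use
fixed derived streams), so identical configs give byte-identical fixture
bundles; `truth.json` records hubs, targeted symbols, disease-like terms
and drugged cytokines, and tests compare pipeline output against it rather
than against hard-coded identities.

What the generator does **not** emulate: publication-evidence counts,
degree heterogeneity beyond the hub/non-hub contrast, correlated annotation
structure (GO term nesting), or synonymy. Passing the recovery tests
therefore shows that the pipeline extracts a planted connectivity/annotation
signal through all stages — it does not certify performance on the
idiosyncrasies of any real knowledge base.

## Structural benchmark

`cytoreg.fixtures.structural_benchmark()` builds, without randomness, a
graph engineered so the pipeline's selection outcome has known
cardinalities (top lists 15/15/13, union 21, intersection 8, 8 of 21
candidates approved-drug targets). It exploits two independences: typed
degree counts edge multiplicity while betweenness on the simple projection
counts distinct neighbors (an exclusive target star of `t` leaves gives the
hub betweenness exactly `C(t, 2)`), and process-list membership is set by
annotation alone. Unregulated filler symbols keep the regulated set a small
fraction of the annotation background, as in any genome-scale background.
The module docstring tabulates the per-group construction.

## Numerical and degenerate-input choices

* Hypergeometric tails are exact rationals; no tolerance is needed below
  the float rounding level.
* BH-FDR is computed with a reverse cumulative minimum over the stably
  argsorted p-vector; permutation equivariance and elementwise domination
  of raw p are asserted as properties.
* Empty inputs degrade gracefully: an empty match set yields an empty
  consolidated network and an all-zero summary; a pipeline run with no
  regulated targets completes with zero counts rather than failing;
  empty p-vectors return empty corrections.
* `k` larger than the scored population is capped with a logged warning.
* Betweenness of disconnected pairs contributes zero; isolated nodes score
  zero in both centralities.

## Problem sizes used in validation

Oracle suites run on ~100 random graphs of ≤ 12 nodes / ≤ 30 edges
(template matching, betweenness) and ~300 sampled count configurations
with N ≤ 200 (hypergeometric), where brute-force enumeration is cheap and
exact. The recovery study uses 100 seeded graphs of 12 cytokines / 15 ASD
genes with a 15× hub contrast and ≤ 10 % noise — small enough to analyze
in seconds, large enough that the hub/non-hub margin is statistical rather
than structural. These sizes are validation choices; the pipeline itself
has no size assumptions beyond memory.

## Known limitations

* Regulatory sign (activation vs inhibition) is not modelled.
* Templates are simple paths; branching or cyclic motifs are out of scope.
* Annotations are flat — no GO-graph propagation; terms are treated as
  independent in the term-space test, which overstates independence when
  terms nest.
* The process-representation null conditions on the cytokine's annotation
  breadth `n`; cytokines absent from the annotation background are dropped
  (with a warning) rather than imputed.
* Drug matching is exact-symbol only.
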