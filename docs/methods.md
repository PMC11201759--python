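# Methods

## Overview

`netprio` turns three inputs — a differential-expression (DE) table,
gene-set memberships with an optional hierarchy, and one PPI edge table
per gene set — into per-structure summaries and a ranked key-gene list.
The stages are independent library functions; the pipeline only wires
them together. This note records the model, the parameters that matter,
the numerical conventions, and what the synthetic benchmark does and
does not demonstrate.

## DEG definition and gene identity

A DEG is a gene with BH-adjusted q-value strictly below `q_threshold`
(default 0.05). Rows with a missing adjusted p-value are dropped as not
significant — DESeq2 emits NA under independent filtering, and treating
NA as significant would be indefensible. The tested universe is every
gene of the primary contrast's table with a defined q-value. Gene
identity is the symbol, upper-cased on input, because DE tables and
STRING preferred names must join on a common key; no alias or identifier
mapping is attempted, and genes absent from a network simply carry no
weight (both the annotated and the weight-bearing counts are reported).

## Overrepresentation and term selection

Each term is tested with the two-sided Fisher exact test on the 2×2
table (overlap, DEG-only, term-only, neither), members intersected with
the universe first; `fisher_alternative` switches to one-sided if
wanted. P-values are BH-adjusted across all tested terms. Direction is
*positive* iff the overlap strictly exceeds the expectation
`n_deg·n_term/n_universe`; a tie counts as negative, since a term
exactly at expectation is not over-represented. Retention requires
FDR < `fdr_threshold` (0.05), positive direction, and at most
`max_term_size` genes (2000 — the practical node limit for building a
PPI network). The manual practice of walking down to the most specific
significant term is formalized as: drop any retained term that has a
retained descendant in the hierarchy's transitive closure. Every
exclusion is logged with its reason (`fdr`, `direction`, `size`,
`ancestor`) and written to the enrichment table.

## Node metrics and the weight W

Networks are undirected, unweighted simple graphs; the combined score
only gates edge membership (threshold 0.900, "highest confidence") and
never weights an edge. Conventions, all configurable:

- **BC** — betweenness, unnormalized shortest-path pair counts (the
  common graph-toolkit default);
- **CCe** — closeness normalized within the connected component,
  (V−1)/Σd, so it is bounded in (0,1] and comparable across networks of
  different size; the alternative 1/Σd convention differs only by the
  positive factor (V−1) and preserves within-network ranking;
- **NC** — mean degree of the node's neighbors (≥ 1 for any connected
  node, so log2(NC) ≥ 0);
- **CCo** — local clustering coefficient; degree < 2 gives 0;
- **AVP** — mean shortest-path distance to the rest of the node's
  component;
- **V** — the size of the node's connected component ("number of
  vertices" is read per node; the whole-graph count is available via
  `whole_graph_v`). Distance metrics are computed per component, which
  keeps every value finite without infinite-distance conventions.

The weight is

    W = BC · CCe · log2(NC) · CCo² − log2(V · AVP)

implemented in one function (`weight_formula`) so alternative operator
groupings are one-line changes; the parse used is recorded in the run
manifest. The product term demands simultaneous bottleneck position
(BC), proximity (CCe), well-connected neighbors (NC) and local density
(CCo); the penalty grows with membership in a large, sparse component.

**Zero substitution.** BC, CCe or CCo can legitimately be zero and would
zero the whole product, so per network each zero is replaced by the
smallest non-zero value of that metric; if the metric is zero on every
node, by 10⁻⁷, a value below anything observed. NC, AVP and V are never
substituted. The operation is idempotent and the substituted metric
names are recorded per gene.

## Aggregation, sharing, ranking

Structure categories are a user-supplied map (YAML) from labels to term
ids; a term may belong to at most one category. Within a category a gene
annotated to several term networks keeps its **maximum** W (winning term
retained as provenance; exact ties go to the lexicographically smallest
term id). Fold-change summaries (Σ|fc|, Σfc⁺, Σfc⁻) run over the union
of the category's term members intersected with the DEG list; weight
summaries (mean W, mean fc·W) run over weight-bearing DEGs, which can be
a subset. The product fc·W is used as the "combined" regulation measure
because it preserves the sign of the fold change while scaling by
network importance; a category with no weighted gene reports NaN means
rather than a silent zero. The shared-DEG table counts pairwise
intersections of the categories' DEG sets and records each gene's
categories and regulation sign. Top lists take the first
⌈fraction · n⌉ genes (default 10%) per category by W descending, ties
broken by |fc| descending then symbol ascending — stable under any
input row permutation.

## Synthetic data: what it emulates

The generators provide ground truth for every downstream claim, with
defaults chosen as the study conditions:

- **DE table** (`simulate_deg_table`): 2000 genes, 15% true DEGs —
  the order of magnitude of a strong neuronal perturbation contrast
  (~1500–2300 DEGs among ~13k tested genes, scaled down). q-values are
  drawn directly (uniform [0, 0.05) for DEGs, [0.05, 1] otherwise)
  rather than via a count model: the pipeline never touches counts.
  DEG log2 fold changes are N(0, 0.6); non-DEGs carry N(0, 0.12)
  residual noise.
- **Annotation** (`simulate_annotation`): terms of 150–250 genes sampled
  without replacement, DEGs up-weighted by odds 6 in enriched terms —
  enough to make enrichment unambiguous without saturating the term.
  Terms come in parent/child pairs with the child a subset of its
  parent, so deepest-child selection has real work to do. With odds 1
  the construction is exactly null, which is what the calibration test
  exploits.
- **Networks** (`simulate_term_network`): the background grows by
  preferential attachment (`mean_degree` 6, i.e. 3 edges per incoming
  node). Each planted hub is the gateway of a complex-like clique of
  roughly a third of its target degree — satellites have no outside
  edges, emulating the dense complex cores (ribosome, COX, mediator)
  that dominate high-confidence STRING networks — and carries extra
  attraction mass that is switched off once its degree reaches
  `hub_degree_factor · mean_degree`, pinning its expected degree at that
  product. Newcomers whose first edge lands on a hub spend their
  remaining edges inside that hub's complex, closing triangles the way
  a complex's interactors do. Hubs therefore stand out in degree,
  betweenness, closeness *and* clustering — the full profile the W
  formula rewards. An earlier pure-preferential-attachment design was
  abandoned after measurement: its hubs had near-zero clustering, and
  the CCo² factor let mid-degree nodes with accidental triangles
  outrank them. In the study generator the hubs are chosen among the
  term's true DEGs with |log2fc| ≥ 0.3 and the satellites among
  non-DEG members (unperturbed complex partners), so hub recovery is
  judged on the DEG ranking the pipeline actually outputs. Edge scores
  are uniform on [0.900, 0.999]: the pipeline thresholds, not weights,
  edges.

What passing the synthetic benchmark does **not** show: robustness to
symbol/alias mismatches between DE tables and STRING, to annotation bias
(real GO terms overlap heavily and non-randomly), to correlated
fold-change noise, or to PPI false edges below the score threshold.
The generator's networks are cleaner than STRING subgraphs — real
networks mix several complexes per term and their hubs are not planted.

## Numerical and testing choices

- Fisher p-values come from `scipy.stats.fisher_exact`, BH from
  `statsmodels`; both are validated against independent oracles
  (exhaustive fixed-margin table enumeration in rational arithmetic for
  every universe ≤ 25; a literal step-up implementation), to 1e-12.
- Graph metrics come from `networkx` (`betweenness_centrality`
  unnormalized, `closeness_centrality` with `wf_improved=False`,
  `average_neighbor_degree`, `clustering`) and are validated to 1e-10
  against a brute-force Floyd–Warshall + shortest-path-enumeration
  implementation on every connected graph up to 6 nodes (the 142
  isomorphism classes) and 200 random 7–8-node graphs.
- The weight fixtures (path center W = −log2 3, triangle
  W = 10⁻⁷ − log2 3) are asserted to 1e-12.
- All randomness flows through `numpy.random.default_rng(seed)`; every
  generator is byte-deterministic under a fixed seed, and a pipeline
  rerun reproduces identical TSVs and manifest (no timestamps are
  written; floats use a fixed `%.10g` format).
- Benchmark sizes (400 null terms; 50 replicate studies at 200-node
  networks, hub degree factor 8) were fixed as the study conditions
  before measurement and keep the whole suite around one to two minutes.

## Known limitations

- The W formula's operator grouping follows the reading documented
  above; `weight_formula` is the single place to change if another
  grouping is preferred.
- Gene matching is symbol-equality only; unmatched genes are reported,
  not resolved.
- The deepest-child rule needs the hierarchy restricted to the supplied
  terms; cross-ontology relations outside the GMT are invisible.
- `mean_weighted_fc` mixes a signed, roughly ±1-bounded quantity (fc)
  with a heavy-tailed one (W); it is a ranking/reading aid, not a
  calibrated effect size.
- Weights are topology-only: edge confidence beyond the threshold and
  edge directionality (activation/inhibition) are ignored.
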