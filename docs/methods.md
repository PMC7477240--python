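# Methods

## Scope and model of the data

`comorbnet` treats the input as four flat, curated relations: a bipartite
gene–disease association set, an undirected protein–protein interaction
graph over gene symbols, named gene sets (pathways, or GO terms of the
biological-process and molecular-function namespaces), and
disease→miRNA / miRNA→target maps. Identifiers are opaque case-sensitive
strings; no symbol aliasing, ID mapping or ontology-DAG processing is
performed. GO annotations are used as *flat* term sets — terms are not
propagated to ancestors before the Jaccard comparison — so two diseases
annotated at different granularity of the same branch score lower than they
would after propagation. Callers who want propagated semantics should
propagate before loading.

## The four comorbidity scores

Let G_i be the genes of disease D_i and D^T the number of diseases in the
*loaded* dataset (not in the selection passed to the matrix builder).

**Shared genes.** `100 · |G_i ∩ G_j| / min(|G_i|, |G_j|)`. The denominator
is the cardinality of the smaller set — the only dimensionally coherent
reading — so the score is 100 whenever one gene set contains the other.

**Uniqueness.** `Uniqueness(g) = 1 − √(D_g / D^T)`; the pair score is the
plain sum over shared genes, reported *unnormalised*. It therefore grows
with the overlap size as well as with gene specificity: two diseases sharing
twenty moderately specific genes outscore two sharing one perfectly specific
gene. This is deliberate and documented rather than corrected.

**Ontology.** 100 × Jaccard index of the unions of BP+MF terms over each
disease's genes (set semantics; a term contributes once however many genes
carry it). An empty term union raises an error instead of returning 0 —
silence would fabricate evidence of independence where there is simply no
annotation.

**Network separation.** `s_ij = D_ij − (D_ii + D_jj)/2` on the unweighted
interactome. Conventions, chosen to match the standard network-medicine
separation statistic:

* D_ii: for each gene, the shortest distance to the nearest *other* gene of
  the same disease, averaged; a single-gene disease has D_ii = 0.
* D_ij: for each gene of either disease, the shortest distance to the
  nearest gene of the other disease, averaged over the union of both gene
  lists; a gene shared by both diseases contributes distance 0.
* Genes absent from the interactome are dropped with a logged count. Genes
  with no reachable counterpart (different connected component) are excluded
  from the relevant average rather than being assigned an arbitrary large
  distance. If a disease retains no usable gene, or no finite cross-distance
  exists, the score is *missing* (NaN), never 0 or infinity.

Under these conventions s(D, D) ≤ 0 for any disease with a network gene
(the cross term is 0 on identical sets), and the score is exactly symmetric.
Edge confidence scores are used only for filtering at load time; all
distances are unweighted hop counts, as no weighted-path semantics is
defined for the statistic.

## Enrichment

The upper-tail hypergeometric probability P(X ≥ k) for a query of n genes
overlapping a pathway of K genes in k, within a universe of N, is computed
with `scipy.stats.hypergeom.sf` (log-space-stable) and validated in the test
suite against exact rational enumeration of all C(N, n) draws for small N.
The support edge k = max(0, n+K−N) returns exactly 1.

The background universe defaults to the union of all pathway member genes
and is overridable; this is the biggest free choice in overlap enrichment
and changing it changes p-values, so the universe actually used is recorded
in every run manifest. Query genes outside the universe are dropped (logged),
making results invariant to out-of-universe noise. Raw p-values are compared
to the threshold — 0.05 for gene queries, 0.001 for the much larger
miRNA-target queries, both configurable — with no multiple-testing
correction by default, matching the procedure the scores come from; an
optional Benjamini–Hochberg flag (`fdr=True`) switches flagging to q-values.
All pathways in the collection are tested, not only those pre-associated
with the selected diseases.

## Gene-network prioritisation

The subnetwork for a pathway selection is the interactome induced on the
union of member genes; members missing from the interactome remain isolated
nodes. Centralities are computed on the full subnetwork, not per component:

* closeness = harmonic closeness (Σ 1/d), finite on disconnected graphs;
* betweenness = unnormalised Brandes node betweenness, endpoints excluded,
  equal-length paths split evenly (normalisation would cancel against the
  table-mean threshold anyway);
* thresholds use the *population* standard deviation (divide by N) over the
  table's own rows, and strict inequalities — exact threshold equality is
  not flagged. A regression test pins the population-vs-sample choice on a
  boundary fixture.

A degree-hub can never be a bottleneck (mean + 2·sd ≥ mean); a closeness-hub
that is also a bottleneck is possible and permitted.

## Venn partitions and disease networks

Venn regions are exclusive: each member of the union belongs to exactly one
region, keyed by the sorted tuple of labels containing it; all 2^n − 1 keys
are materialised (possibly empty) for a fixed output schema. "Pathways of a
disease" means pathways containing at least one of the disease's genes.
Disease networks connect selected diseases whenever they share ≥ 1 gene
(or miRNA), with the shared count as edge weight.

## The synthetic generator

The generator emulates the *structure* the analyses exploit, not real
biology: communities of a preferential-attachment (Barabási–Albert, m = 3)
graph chained into a path by sparse inter-community edges give a
heavy-tailed degree distribution and controllable network distance between
modules; disease gene sets are drawn either from single communities
(planted "same-module" pairs), from community pairs ≥ 3 hops apart in the
quotient path (planted "distant" pairs), or from a background pool sized so
genes average roughly `pleiotropy` diseases each. Planted enrichments embed
a chosen fraction of a disease's genes into one pathway and attach one
dedicated miRNA targeting that pathway, so both enrichment modes carry a
recoverable signal (upper-tail p far below 10⁻⁴ at the default sizes).

Defaults — 500 genes, 8 communities, 30 diseases of 8–15 genes, 40 pathways,
150 GO terms split evenly between BP and MF, 60 miRNAs, pleiotropy 2 — are
the standard study conditions used throughout the tests and the acceptance
script. Planted pairs default to `overlap_fraction = 0`, so the
separation-ranking experiment measures topological proximity only and is
never trivially won by shared genes sitting at distance 0. One
`numpy.random.Generator` seeded from the single config seed drives every
draw; identical config + seed yields byte-identical files (writers sort all
rows lexicographically).

What the generator does **not** emulate: real STRING topology beyond degree
heterogeneity, correlated annotations (GO terms are assigned independently
of the graph), literature-biased gene–disease curation, or realistic miRNA
target multiplicity. Passing tests therefore demonstrate algorithmic
correctness and recoverability of planted structure, not performance on
curated human data.

## Numerical and engineering choices

* Scores are plain floats; missing separation scores are NaN in matrices
  and empty cells in TSV output.
* Duplicate association rows are collapsed (counted and logged); reciprocal
  interactome edges are merged keeping the maximum confidence; self-loops
  are dropped and counted.
* Conflicting disease names for one id resolve to the lexicographically
  smallest, keeping loading order-invariant.
* The CLI maps validation/format errors to exit 1 and usage errors to
  exit 2, and writes a `run_manifest.json` (parameters, input SHA-256
  checksums, version, timestamp) next to every output set; primary tables
  are byte-stable across re-runs.
* Problem sizes in the test suite and acceptance script (universes of
  120–500 genes, 100 ranking replicates, exhaustive graph checks up to 7
  nodes plus a seeded sample of 8-node graphs) were chosen so the full
  suite completes in well under a minute while still exercising every
  guarantee exhaustively where enumeration is feasible.

## Known limitations

* No GO ancestor propagation (see above) and no ID mapping.
* The uniqueness score is scale-dependent by design; compare it only within
  one dataset.
* Network separation is reported raw, with no permutation significance
  test.
* Enrichment tests every pathway independently; the default lacks
  multiple-testing control unless `fdr=True` is passed.
* The 6-way Venn output is tabular (regions + counts); no diagram is drawn.
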