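# Methods

This note documents the models, the defaults and the numerical choices
behind `hetgo`, and what the synthetic benchmark does and does not show.

## Network construction

Six layers are built and unioned into one weighted undirected graph with
typed vertices (miRNA, protein, disease):

- **coexpr** — Pearson correlation of miRNA expression profiles. Precursor
  profiles mapping to the same mature miRNA are arithmetically averaged
  first. Only strictly positive correlations become edges; there is no
  additional magnitude cutoff. Profiles with zero variance have undefined
  correlation; their pairs are skipped with a warning rather than aborting
  a build over one degenerate row.
- **ppi** — confidence-scored protein interactions; STRING-style 0–999
  scores are divided by 1000.
- **disease_sim** — phenotype similarity scores, assumed already in [0, 1].
- **mirna_target / mirna_disease / protein_disease** — curated
  associations, weight 1.

All layers therefore share a [0, 1] weight scale before embedding. This
normalization is a package choice: without it, edge-sampling probabilities
in the embedding would be dominated by whichever layer uses the largest
numeric range. Duplicate pairs within a layer collapse to their maximum
weight; a weight of zero means "no edge" and is never stored.

Edges are stored once. Same-type layers order endpoints lexicographically;
bipartite layers keep the layer's role order (miRNA/protein first), because
with lexicographic ordering the endpoint types of, say, an miRNA–disease
edge could not be recovered from the edge alone. An identifier appearing
with two different vertex types across layers is a hard input error.

## LINE embedding

The embedding is a from-scratch implementation of LINE with the
conventional internals, each visible in `EmbeddingConfig` or module
constants:

- sigmoid negative-sampling objective; n_negative = 10 noise nodes per
  positive draw, drawn ∝ (weighted degree)^0.75;
- alias-method O(1) edge sampling ∝ edge weight, each undirected edge
  doubled into two directed edges;
- learning rate decaying linearly from ρ0 = 0.025 to a floor of ρ0·1e-4;
- node vectors initialized uniform(−0.5, 0.5)/dim, context vectors (second
  order only) initialized to zero; for the first order the node table is
  its own context table;
- total dimension d = 64 split 32/32 between the first- and second-order
  halves, each half L2-normalized per node before concatenation so neither
  half dominates downstream distances. The split reading (rather than
  concatenating two full-d halves into 2d) keeps the advertised feature
  dimension exact.

The default budget of 10^6 edge draws per order is a desk-scale choice; the
full-scale setting of 10^11 draws is reachable through
`EmbeddingConfig.total_samples` but is not a default anywhere. The
per-sample SGD loop is numba-compiled and seeded, so embeddings are
bitwise reproducible for a given seed. Nodes incident to no edge receive no
embedding row; downstream featurization gives such entities (and any entity
never seen in the graph) a zero vector.

A windowed trace of the training loss (50 blocks) is recorded per half; the
test suite checks that its tail is below its head rather than asserting
per-sample monotonicity, which SGD noise would violate.

## Ontology handling

OBO 1.2 files are parsed with `obonet`; `is_a` and, by default, `part_of`
relations are kept (restrictable to `is_a` via a flag). Obsolete terms are
dropped, alt_ids resolve to their primary term, cross-namespace parent
links are discarded with a warning, and a cycle is a hard error. Annotation
tables may carry an evidence column; IEA rows (inferred from electronic
annotation) are filtered at load time when the column is present.

Propagation closes each entity's term set under the ancestor relation (the
true-path rule); it is idempotent and monotone. The trainable term set per
namespace is "terms with ≥ min_count annotated entities, root excluded,
ordered children-before-parents". The count threshold (default 50 on real
data, 5 on desk-scale fixtures) is a package choice — it is the standard
construction in hierarchy-aware function prediction, and nothing finer is
derivable from the published term counts alone.

## Hierarchical classifier

A compact numpy implementation: shared dense layer (ReLU, default 1024
units) → inverted dropout (rate 0.2) → one sigmoid unit per selected term
→ maximum merge. The merge replaces each term's score with the maximum of
its own raw score and all its selected descendants' raw scores; because max
is associative this equals the bottom-up merge over immediate children and
is idempotent. Consistency (parent ≥ child) holds for every prediction,
trained or not.

Training: multi-output binary cross-entropy computed on the merged outputs
(a flag moves it to the raw heads), RMSprop (decay 0.9, lr 0.01, minibatch
64), weights drawn from a uniform Glorot-range distribution, gradients
routed through the merge to the argmax source term. An internal random
80/20 split selects the epoch checkpoint with the lowest validation loss;
early stopping uses a patience of 10 epochs. The published description of
this classifier reports two starting learning rates in different places
(0.025 in the tuning summary, 0.01 in the training protocol); the training
protocol's 0.01 is the default and both are reachable in `ModelConfig`.
An optional small per-term dense layer (`head_hidden`) interposes between
the shared layer and each sigmoid unit for the deeper per-term reading of
the architecture; the default is the single shared layer. Training is
end-to-end over all terms at once; the level-by-level phrasing of the
original description is read as topological evaluation order, not as a
curriculum.

The model is entity-type agnostic: it trains on protein features and is
applied unchanged to miRNA features, which live in the same embedding
space.

## Evaluation

Protein-centric precision/recall over a threshold grid with step 0.01.
Averaged precision divides by m(t), the number of entities with ≥ 1
prediction at t; averaged recall divides by N, all evaluated entities.
Thresholds with m(t) = 0 or Pre + Rec = 0 are skipped in the Fmax scan.
Entities lacking any truth term in the evaluated namespace are excluded
from N (the intended benchmarks guarantee at least one annotation per
entity). Namespace roots are vacuous predictions and are excluded from both
predicted and truth sets by default (`include_roots` restores them). Truth
terms the predictor never scores still count in |R_i|, capping attainable
recall. `EvalResult.coverage` is m(t*) — the number of entities with at
least one prediction at the Fmax threshold.

## Synthetic benchmark

The generator emulates the statistical structure the method assumes, not
any real database:

- entities are assigned round-robin to `n_modules` modules (default 4;
  120 miRNAs, 150 proteins, 40 diseases);
- expression profiles are module archetypes (Gaussian, sd 2) plus
  independent Gaussian noise (sd `expression_noise`, default 0.5); ~20% of
  miRNAs get two precursor rows to exercise homolog averaging;
- PPI and disease-similarity layers are planted partitions (default
  p_in = 0.3 within modules, p_out = 0.02 across); PPI weights are written
  as STRING-style integers in 500–999, similarities as uniforms in
  [0.5, 1];
- bipartite layers link same-module pairs with probability p_in/3 and
  cross-module pairs with p_out/3; the miRNA–target contrast can be
  overridden (`target_p_in/target_p_out`) to build fixtures in which the
  disease layers are the only route from miRNAs to module identity —
  the fixture used for the disease-ablation contrast
  (expression_noise = 3, target_p_in = target_p_out = 0.08);
- the GO-like BP DAG (default 60 terms) gives the root one child per
  module; each branch grows as a deep random subtree (primary parent
  biased toward recent terms, occasional second parent anywhere), and each
  module's characteristic terms (default 4) are deep terms of its own
  branch — mirroring how distinct biological processes occupy distinct
  subtrees of the real ontology. A token 5-term MF namespace exercises
  namespace filtering;
- each protein and miRNA carries each of its module's characteristic terms
  with probability `annotation_signal` (default 0.9) plus
  Poisson(`noise_term_rate` = 0.3) uniformly random decoy terms, and a 20%
  chance of one IEA-evidence decoy row that load-time filtering removes.
  The decoy rate is kept low deliberately: each decoy drags in its whole
  ancestor chain under propagation, and much higher rates make even an
  oracle module predictor indistinguishable from a frequency prior.

What passing on this benchmark shows: the pipeline recovers planted
community structure from the integrated graph, transfers protein-trained
term models to miRNAs sharing that structure, respects the DAG everywhere,
and beats a label-permutation null by a wide margin. What it does not
show: performance on real databases — real expression dynamics, scale-free
interactomes, realistic GO topology (tens of thousands of terms), annotation
incompleteness and literature bias are all outside the generator's scope.

## Problem sizes and determinism

Desk-scale experiment settings used by the test suite and the acceptance
script: 2×10^5 embedding samples per order, 256 hidden units, ≤ 40 epochs —
a full pipeline run takes a few seconds on one CPU. One global seed fans
out to per-stage seeds through a fixed hash, every random draw flows from
`numpy.random.default_rng` or the seeded numba loop, and run summaries
exclude wall-clock timings, so identical configs and seeds reproduce every
artifact byte for byte.

## Known limitations

- The classifier is a single shared hidden layer; very large term sets
  (thousands of heads) would train slowly in pure numpy.
- The embedding treats the graph as homogeneous once weights are set;
  no type-specific metapath sampling.
- `select_terms` counts propagated annotations; alternative selections
  (information content, depth) are not implemented.
- The generator's DAG is small and single-rooted per namespace; it does not
  reproduce GO's term-depth or branching distributions.
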