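# hetgo

Predicting Gene Ontology (GO) functions of miRNAs by embedding a
heterogeneous miRNA–protein–disease network and transferring a
hierarchy-consistent protein function classifier to the miRNA nodes.

miRNAs regulate most human protein-coding genes, but very few carry
experimentally validated GO annotations, so a classifier cannot be trained
on miRNAs directly. `hetgo` sidesteps this by placing miRNAs, proteins and
diseases in one weighted undirected graph — miRNA co-expression, protein–
protein interaction (PPI) and disease phenotype similarity networks, glued
together by miRNA–target, miRNA–disease and protein–disease associations —
and learning one topological feature vector per node. A deep multi-label
classifier is then trained on the richly annotated *protein* nodes and
applied unchanged to the *miRNA* nodes, which live in the same feature
space.

## Method

**Network integration.** Co-expression edges carry the Pearson correlation
`r(x_i, x_j)` of two miRNAs' expression profiles (precursor profiles of the
same mature miRNA averaged first); pairs with `r <= 0` are screened out.
PPI edges carry STRING-style confidence scores divided by 1000, disease
edges their phenotype similarity, association edges weight 1 — all layers
share a [0, 1] scale.

**LINE embedding.** Each node `v_i` receives a `d`-dimensional vector (d =
64 by default) built from two halves trained separately and concatenated:
a first-order half modelling the joint edge probability
`p_1(v_i, v_j) = sigma(u_i . u_j)` and a second-order half modelling
neighbourhood context `p_2(v_j | v_i) ∝ exp(c_j . u_i)` with a separate
context table. Both are fit by SGD with negative sampling (n = 10 noise
nodes per edge draw, noise ∝ degree^0.75, alias-method edge sampling ∝
weight, learning rate decaying linearly from ρ0 = 0.025).

**Hierarchical classifier.** For each GO namespace, terms annotated to at
least `min_count` training proteins form the label set. One shared dense
layer (1024 units by default) feeds one sigmoid unit per term; a maximum-
merge layer then replaces each parent's score with
`max(score(parent), merged(children))`, so predictions always respect the
true-path rule. Training minimizes multi-output binary cross-entropy with
RMSprop (lr 0.01, minibatch 64, dropout 0.2) and keeps the epoch checkpoint
with the lowest loss on an internal 80/20 hold-out split. Entities missing
from the network are featurized as zero vectors.

**Evaluation.** CAFA-style protein-centric metrics over a threshold grid
`t ∈ {0, 0.01, …, 1}`:

    Pre(t) = (1/m(t)) Σ_i |P_i(t) ∩ R_i| / |P_i(t)|
    Rec(t) = (1/N)    Σ_i |P_i(t) ∩ R_i| / |R_i|
    Fmax   = max_t 2·Pre(t)·Rec(t) / (Pre(t) + Rec(t))

where `P_i(t)` is the set of terms scoring ≥ t for entity i, `R_i` its true
(propagated) term set, `m(t)` the number of entities with at least one
prediction at t, and `N` the number of evaluated entities. Coverage counts
entities with ≥ 1 predicted term at the operating threshold.

A synthetic benchmark generator ships with the package: planted-partition
entity networks, module-archetype expression profiles, module-preferential
associations, a random rooted GO-like DAG whose top-level branches host
each module's characteristic terms, and annotation tables correlated with
module membership. It makes every stage testable without any database
downloads.

## Worked example

```python
from hetgo import (SynthConfig, EmbeddingConfig, ModelConfig,
                   PipelineConfig, run_pipeline)

cfg = PipelineConfig(
    seed=7,
    synth=SynthConfig(),                      # default planted-module benchmark
    embedding=EmbeddingConfig(total_samples=200_000),
    model=ModelConfig(hidden_units=256, max_epochs=40, patience=8),
)
summary = run_pipeline(cfg, "run7")
```

prints (abridged) the summary also written to `run7/summary.json`:

```json
{
  "Fmax": 0.953183,
  "avg_precision": 0.951168,
  "avg_recall": 0.955208,
  "t_max": 0.25,
  "N": 120,
  "coverage": 120,
  "n_vertices": 310,
  "n_edges": 6231,
  "n_terms_trained": 41,
  "namespace": "BP"
}
```

Read: the integrated graph has 310 nodes; 41 biological-process terms were
trainable on the 150 synthetic proteins; transferring the classifier to the
120 miRNAs gives a maximum F-measure of 0.95 at score threshold 0.25, with
every miRNA receiving at least one BP prediction there. The same pipeline
is available from the shell:

```bash
hetgo run --out run7 --seed 7            # synthetic data end to end
hetgo simulate --out data --seed 7       # or stage by stage
hetgo build-net --data-dir data --out net.tsv
hetgo embed --network net.tsv --out emb.txt --dim 64 --samples 1000000 --seed 7
```

Pass `--ablate-disease` to `hetgo run` to drop the disease similarity and
disease association layers before embedding and measure their contribution.

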