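# Methods

## Data model

A prescription is modelled as a *set* of standardized herb names with a
group label, `anti_recurrence` or `general`. Dosage, preparation method
and prescription order are not modelled: every downstream statistic
(support, co-occurrence, frequency bands, forest features) is
presence-based. Within one group, formulas with identical composition are
collapsed to a single record (earliest id kept); identical compositions in
*different* groups are retained, because the group contrast is exactly
what the differential stage measures. The vocabulary is the
lexicographically sorted union of all herb sets, which fixes binary-matrix
columns and graph node order and makes every stage deterministic.

Name standardization is table-driven: a lexicon maps raw names to
standard names plus nature (cold/cool/neutral/warm/hot) and flavors.
Unmapped names pass through with a warning rather than failing — the
authoritative nomenclature lives outside the package, and dropping
records for a missing lexicon row would silently bias frequencies.

## Synthetic generator

The generator emulates the statistical structure the mining stages
assume, with three independent inclusion mechanisms united per
prescription:

* **modules** — a module activates with probability `activation_prob`
  (multiplied by `group_bias` in the general group); each member is then
  included with `inclusion_prob`. This is the co-prescription signal the
  rule miner and the graph clustering should recover.
* **differential herbs** — included with a group-specific frequency; the
  signal for the frequency bands and the forest.
* **background** — every other vocabulary herb included with
  `background_prob`.

Sizes outside `size_range` are rejection-sampled (not truncated), which
preserves the within-prescription dependence structure at the cost of a
mild conditioning bias when the clamp is tight; the generator aborts if
1000 consecutive draws are rejected. One `numpy` Generator seeded once
streams all randomness.

Reference conditions (the package defaults): 150 anti-recurrence + 120
general prescriptions over a 216-herb vocabulary, one planted 8-herb
module (activation 0.6, inclusion 0.9, general-group bias 0.5),
background inclusion 0.03, and three module herbs carrying a 40-point
frequency differential (0.60 vs 0.20). Vocabulary size and the 2–25 size
clamp were fixed once as typical of real formula collections (most
formulas hold roughly 5–20 herbs). These conditions produce corpora of
realistic sparsity but deliberately *cleaner* structure than real
prescription data: real corpora have several overlapping, partially
expressed modules, herb synonymy noise and strong frequency skew. Passing
recovery tests on generated corpora therefore demonstrates correctness of
the machinery, not expected effect sizes on clinical collections.

The screening-table generator draws OB ~ U(0, 60), DL ~ U(0, 0.5) and
target scores ~ U(0, 1)², mixing draws from the passing region
(probability `pass_fraction`) with rejection draws from its complement,
so the expected filter pass rate equals `pass_fraction` exactly.

## Association rules

The Apriori miner is written from scratch (level-wise join on sorted
(k−1)-prefixes, downward-closure pruning, vectorized support counting on
boolean columns). Two numerical choices matter:

* Thresholds are inclusive, and both support and confidence are compared
  as exact rationals: `Fraction(count, N) >= Fraction(str(threshold))`.
  Using the *decimal* the caller wrote (via `str`) rather than the binary
  float avoids both float round-off and the subtler artifact where
  `Fraction(0.7)` is slightly above 7/10, which would silently exclude
  rules whose confidence is exactly 0.7.
* Ties in the lift ranking break by confidence, then support, then
  lexicographic antecedent, making output order total and reproducible.

Consequents default to a single herb (`rhs_size=1`), the standard
association-rule output; multi-consequent partitions are available behind
the parameter. Itemset size is unbounded by default with an optional
safety cap.

## Co-occurrence graph and GCN embedding

Edges connect herbs co-appearing in at least one formula, weighted by the
count of such formulas; isolated herbs stay as degree-0 nodes.
Propagation uses the symmetric normalization with self-loops,
D̃^-½(A+I)D̃^-½, on the *weighted* adjacency — edge weights are the only
quantitative signal in the graph, so they should steer the smoothing (an
unweighted-degree flag exists).

The initial node feature is the standardized weighted degree, augmented
by default with an 8-dimensional seeded random feature block. The
augmentation is load-bearing, not cosmetic: a GCN is equivariant under
graph automorphisms of its input, so with a degree scalar alone any two
structurally equivalent nodes (e.g. the two halves of a symmetric pair of
cliques) provably receive *identical* embeddings and no objective can
separate them. Random features break those ties and give the encoder
enough input rank to actually minimize the link-prediction loss;
`feature_noise_dim=0` restores the bare degree feature.

Training: two layers (1+8 → 32 ReLU → 16 linear), inner-product decoder,
mean binary cross-entropy over all observed edges (label 1) and one
uniformly resampled non-edge per positive per epoch (label 0), Adam at
lr 0.01 for 200 epochs, Glorot initialization. There is no
train/validation edge split: the objective is self-supervised
representation learning on the whole graph, and the downstream consumer
is the clustering, not a held-out AUC. Gradients are analytic (the model
is two dense layers over a fixed sparse operator); a divergence error
reports the epoch if the loss ever goes non-finite. Everything is
reproducible from the single hyperparameter seed.

## Clustering and cluster prioritization

K-means (10 restarts per K, deterministic seed stream) runs for every K
in the candidate range (default 2–10; K=1 is rejected since the
silhouette is undefined there), and the assignment with the highest mean
Euclidean silhouette wins. Clusters are then scored on three components:

* mean weighted degree of members in the *full* graph;
* intra-cluster weighted edge mass divided by member-pair count (this
  density can exceed 1 — weights are counts — which is harmless because
  of the normalization below; singletons score 0);
* coverage: fraction of formulas containing ≥ 1 member (a flag switches
  to a stricter ≥ m members).

Each component is min–max normalized across clusters (a constant
component maps to 0.5 for everyone, so it neither rewards nor penalizes)
and the composite is their unweighted mean. The unweighted mean is this
package's choice — the three components are reported raw alongside it so
alternative aggregations can be audited.

## Two-group differential

"Frequency variance" is interpreted as the signed difference of per-group
frequencies in percentage points; the high/moderate/slight labels only
make sense on a bounded difference scale. Band edges partition the
positive axis as (20, ∞) / (10, 20] / (0, 10], i.e. strict ">" at 20 and
at 10; a zero difference is slight/balanced.

The forest is a 1000-tree scikit-learn `RandomForestClassifier`
(bootstrap, √p feature subsampling, Gini, unlimited depth) over the
stacked presence matrix on the union vocabulary (a minimum-count floor is
available but off by default). OOB error comes from the out-of-bag vote.
Mean decrease Gini is the impurity importance. Mean decrease accuracy is
computed here per tree — permute one feature column on the tree's
out-of-bag samples, measure the accuracy drop, average over trees — i.e.
the classical OOB permutation importance, which no installed estimator
exposes directly. Only features a tree actually split on are permuted
(others cannot change its output), which makes the 1000-tree computation
cheap.

## Consensus

The rule arm nominates the union of herbs in the top-N rules by lift
(default N=1: the single highest-lift rule is the natural headline
combination); the cluster arm nominates the members of the top-M
composite clusters (default M=1). The consensus is their intersection,
tagged per herb with `apriori`, `gcn`, `frequency_high` (high band and
anti-enriched) and `rf_top` (within the top 14 of the
mean-decrease-accuracy ranking). The path from the consensus spectrum to
a final short combination is left to the user: `core_herbs(top_herbs=k)`
orders by evidence-tag count, ties by frequency differential.

For *recovery scoring* against the planted 8-herb module (tests and the
acceptance script), the rule window is widened to N=10: a single rule
contains at most a handful of herbs, so the top-1 default caps the
intersection below the module size by construction, while the top-10
union covers the module whenever mining succeeds.

## Screening arm

All four thresholds (OB ≥ 30, DL ≥ 0.18, SVM ≥ 0.8, RF ≥ 0.7) are
inclusive as written. Filters are pure row predicates — commuting and
idempotent by construction. The compound–target network is a simple
bipartite graph (duplicate links collapse; multiplicity is not
biologically meaningful), restricted to links whose compound survived
filtering, with dropped-link counts reported; rankings are degree
descending with lexicographic tie-break.

## Problem sizes and determinism

The test suite and the acceptance script run the reference conditions
(270 prescriptions, 216 herbs) for the full pipeline, 5 seeds for
module-recovery rates, 10 seeds for the forest null check, and 100 random
corpora (≤ 12 herbs, ≤ 20 prescriptions) for exhaustive Apriori
cross-validation — sizes at which exhaustive enumeration is exact and the
whole suite completes in well under a minute of compute per stage. Every
random draw flows from explicit seeds; the pipeline report is
byte-identical across reruns with the same configuration.

## Known limitations

* Prescriptions are unweighted sets; dose-dependent compatibility is
  invisible.
* The GCN trains on the full graph without a held-out edge split, so the
  loss trace is a training diagnostic, not a generalization estimate.
* The composite cluster metric's equal weighting is a convention;
  different weightings can reorder mid-table clusters (the raw components
  are exported for exactly that reason).
* Real-data OOB error depends on corpus overlap between groups;
  the synthetic null/separator checks bracket behaviour but do not
  predict clinical values.
* The screening arm trusts its input tables; it performs no gene-symbol
  validation or database reconciliation.
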