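# herbminer

Mining the core herb combination from traditional-medicine prescription
corpora — specifically, formulas prescribed against colorectal-cancer
recurrence versus general-treatment formulas.

Clinical TCM prescriptions encode implicit compatibility knowledge: some
herbs are systematically co-prescribed, and some are over-represented in
formulas targeting a specific outcome. `herbminer` extracts that signal
from a two-group prescription corpus (an *anti-recurrence* collection and
a *general-treatment* collection) and distils it into a small core herb
combination with per-herb evidence, for researchers doing prescription
data mining or preparing a network-pharmacology follow-up.

## The method

A prescription is a set of herbs; the corpus is a binary transaction
matrix. Four analysis arms run over it:

1. **Apriori association rules** (from scratch, level-wise with downward
   closure). For a rule X → Y:
   supp(X→Y) = P(X ∪ Y), conf(X→Y) = P(X ∪ Y)/P(X),
   lift(X→Y) = conf(X→Y)/P(Y).
   Defaults: support ≥ 0.08, confidence ≥ 0.80, rules ranked by lift.
   Thresholds are compared as exact rationals, so boundary cases never
   depend on floating-point round-off.
2. **GCN embedding + clustering.** The weighted co-occurrence graph
   (edge weight = number of formulas containing both herbs) is encoded by
   a two-layer graph convolution, H⁽ˡ⁺¹⁾ = σ(D̃^-½ Ã D̃^-½ H⁽ˡ⁾ W⁽ˡ⁾)
   with Ã = A + I, hidden/output dimensions 32/16, trained 200 epochs with
   Adam (lr 0.01) under a self-supervised link-prediction loss
   (inner-product decoder, one resampled negative per edge). Embeddings
   are clustered by K-means with K chosen by maximal mean silhouette, and
   clusters ranked by a composite of average weighted degree, intra-cluster
   edge density and formula coverage.
3. **Two-group differential.** Per-herb frequency differences in
   percentage points, banded as high (> 20), moderate (10–20] and slight
   (0–10]; plus a 1000-tree random forest (herb presence → group label)
   reporting OOB error, mean decrease Gini and mean decrease accuracy
   (per-tree OOB permutation importance).
4. **Consensus.** The herbs nominated by the rule arm and the cluster arm
   are intersected; each consensus herb carries evidence tags
   (`apriori`, `gcn`, `frequency_high`, `rf_top`).

A downstream screening arm filters compound tables (OB ≥ 30 %,
DL ≥ 0.18) and compound→target links (SVM ≥ 0.8, RF ≥ 0.7) and ranks
nodes of the resulting bipartite network by degree.

A synthetic two-group generator with planted co-prescription modules and
differential herbs provides ground truth for every stage.

## Worked example

```python
import herbminer as hm

model, truth = hm.CoreHerbModel.from_synthetic(
    hm.default_config(seed=1),
    hm.PipelineConfig(gcn=hm.GcnHyperparams(seed=1), seed=1, rule_top_n=10))
res = model.fit()
print(res.summary())
```

prints

```
Core-herb prescription mining
================================================================
Corpora: 150 anti-recurrence / 120 general prescriptions; vocabularies 214 / 213 herbs
----------------------------------------------------------------
Association rules  (support >= 0.08, confidence >= 0.8)
  frequent itemsets: 257   rules: 952
  top rule by lift: {herb_000, herb_001, herb_005, herb_007} -> {herb_004} (supp=0.3467, conf=0.9123, lift=1.75)
----------------------------------------------------------------
GCN embedding (32/16 dims, 200 epochs)  K=2 (silhouette 0.632)
  top cluster (8 herbs, composite 0.667): herb_000, herb_001, herb_002, herb_003, herb_004, herb_005, herb_006, herb_007
----------------------------------------------------------------
Differential: 8 high-band herbs; forest OOB error 32.59% (1000 trees)
----------------------------------------------------------------
Consensus core (8 herbs):
  herb_001  [apriori, frequency_high, gcn, rf_top]
  ...
```

The generator planted one 8-herb module (`herb_000`…`herb_007`); the top
rule is a within-module implication (the presence of four module herbs
predicts a fifth with confidence 0.91, lifting its base frequency 1.75×),
the top-composite cluster is exactly the planted module, and the consensus
recovers all 8 herbs, each supported by all four evidence arms. On real
data the same objects are built with
`CoreHerbModel.from_files(anti.csv, general.csv)` from long-format CSV
(`prescription_id,group,herb`), optionally standardizing names through a
user-supplied lexicon.

A CLI mirrors the stages:

```bash
herbminer simulate --seed 1 --out-dir out
herbminer run-all --synthetic --seed 1 --out-dir out
herbminer mine-rules out/corpus_anti.csv --min-support 0.08 --min-confidence 0.80
```

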