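# gdnrepo — genetics-based drug repositioning over a genetic disease network

`gdnrepo` prioritizes drug-repositioning candidates for a target disease
*indirectly* through disease genetics: instead of linking the target's risk
genes to drug targets, it asks which *other* diseases share genetic
architecture with the target, and which drugs treat many of those related
diseases.  The underlying assumption is that genetic overlap between
diseases often reflects overlapping pathophysiology, so treatments can
transfer between genetically related diseases even when the shared biology
is uncharacterized.

The pipeline has four stages:

1. **Genetic disease network (GDN).**  From a disease–gene association
   table (e.g. a GWAS-catalog download), every disease becomes a node and
   two diseases are connected whenever their gene sets overlap.  Edge
   weights are the cosine similarity of the gene sets,
   `|A∩B| / √(|A|·|B|)` (Jaccard and overlap coefficient are available).
2. **Random walk with restart (RWR).**  Diseases related to a seed disease
   are scored by iterating `p(t+1) = (1−γ) M p(t) + γ p0` to convergence,
   where `M` is the column-normalized adjacency matrix, `γ = 0.1` is the
   restart probability, and `p0` puts probability 1 on the seed.  Iteration
   stops when the L1 change falls below `10⁻⁶`.  Diseases are ranked by the
   steady-state probabilities (seed and zero-score nodes excluded).
3. **Drug scoring.**  With the target's own treatment pairs removed from a
   multi-source drug–disease treatment knowledge base (*de-novo* masking),
   each drug is scored as `R_drug = Σᵢ R_diseaseᵢ` over the distinct
   diseases it treats, so drugs treating many top-ranked related diseases
   rise to the top.
4. **Evaluation and enrichment.**  Rankings are evaluated against
   gold-standard drug lists (recall, mean/median percentile position,
   precision/recall/F1 at fractional cutoffs) and characterized by class
   composition (ICD-10 chapters for diseases, ATC level-3 codes for
   drugs), reporting fold enrichment of classes in the top of the ranking.

A synthetic-data module generates fixtures with planted genetic
relatedness and treatment signal, so the complete pipeline is testable and
calibratable without any external download.

## Worked example

Generate a synthetic dataset (20 diseases genetically related to the seed,
200 background diseases, 10 planted "signal" drugs biased toward treating
related diseases among 200 decoys), then run the pipeline:

```python
from gdnrepo import (build_gdn, column_normalize, rank_from_matrix,
                     de_novo_mask, score_drugs, retrospective_eval)
from gdnrepo.synthetic import SyntheticConfig, generate
from gdnrepo.enrich import top_class_enrichment

ds = generate(SyntheticConfig(rng_seed=7))
net = build_gdn(ds.associations, method="cosine")
ranking = rank_from_matrix(column_normalize(net), ds.seed_disease)
drugs = score_drugs(ranking, de_novo_mask(ds.kb, ds.seed_disease))
report = retrospective_eval(drugs, ds.gold)
```

This prints (via the objects' frames / fields):

```
network: 221 diseases, 440 edges, 22 isolated
ranked 186 diseases in 68 iterations
scored 210 of 210 drugs
top drug: signal drug 005  score=0.2081  n_diseases=5  percentile=0.48
recall=1.0  mean%=3.38  median%=2.62
 cutoff   k  n_hits  precision  recall       f1
   0.01   2       2   1.000000     0.2 0.333333
   0.05  11       7   0.636364     0.7 0.666667
   0.10  21      10   0.476190     1.0 0.645161
```

All ten planted drugs are retrieved (recall 1.0) at a median percentile of
2.62 % of the 210-drug universe, and the class planted on the related
diseases is 9.3-fold enriched in the top decile of the disease ranking:

```python
top_class_enrichment(list(ranking.diseases), ds.class_map).table
#        class  percent_in_top  percent_overall  fold
# seed-related           100.0        10.752688   9.3
```

The same run is available from the shell:

```sh
gdnrepo simulate --seed 7 --out fixtures/
gdnrepo run-all --config run.yaml        # chains all five stages
gdnrepo rank-diseases --associations fixtures/associations.tsv \
    --seed "seed disease" --gamma 0.1 --tol 1e-6 --out diseases.tsv
```

`run-all` writes every intermediate artifact plus `manifest.json`
recording parameters, input checksums, iteration counts and versions;
reruns with identical inputs are byte-identical.

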