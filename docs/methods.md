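# Methods

## Model

The method treats drug repositioning as inference over two layered
relations: a *genetic* relation between diseases, and a *treatment*
relation between drugs and diseases.

**Genetic disease network.**  Let each disease `d` carry a set of
associated genes `G(d)` from a disease–gene association catalog.  The
network has one node per disease and an undirected edge between every
disease pair whose similarity is strictly positive (any shared gene, with
the default `min_weight = 0`).  Edge weights are

* cosine: `|A∩B| / √(|A|·|B|)` (default),
* Jaccard: `|A∩B| / |A∪B|`,
* overlap coefficient: `|A∩B| / min(|A|, |B|)`.

For any pair, Jaccard ≤ cosine ≤ overlap, a property the test suite
checks.  Isolated diseases (no shared genes with anyone) are kept as
nodes, so node counts match the input catalog; they cannot receive walk
probability and therefore drop out of the ranked list, which is why the
ranked list is shorter than the node count.

**Random walk with restart.**  With `M` the column-normalized weighted
adjacency matrix, restart probability `γ ∈ (0,1)` (default 0.1) and the
seed distribution `p0` (all mass on the seed disease; multiple seeds split
the mass uniformly), iterate

    p(t+1) = (1 − γ) · M · p(t) + γ · p0

until `‖p(t+1) − p(t)‖ < tol` (default `10⁻⁶`).  The fixed point equals
the direct linear solution `p = γ (I − (1−γ)M)⁻¹ p0`; the suite verifies
agreement within `10·tol` in L1 on random graphs up to 200 nodes.
Diseases are ranked by descending steady-state score, ties broken
lexicographically, the seed and exact-zero scores excluded.

**Drug scoring.**  Treatment pairs come from up to four source-tagged
tables (drug labels, post-marketing surveillance, clinical trials,
literature), combined as a union; the same pair attested by several
sources still names one *distinct disease*.  After removing the target
disease's own pairs (de-novo masking — the drug universe is deliberately
preserved so masked drugs stay rankable at score 0), each drug scores

    R_drug = Σ_i R_disease_i

over the distinct ranked diseases it treats.  Drugs are ordered by
`(−score, name)`; a drug's percentile position is `100 · rank / universe`,
reported to two decimals.

**Evaluation.**  Against a gold-standard list: overall recall is the
fraction of gold drugs with positive score; mean/median percentiles are
computed over retrieved gold drugs only (misses affect recall, not the
percentile summaries).  At a fractional cutoff `c`, the top
`k = round(c · universe)` entries (round half up: 1 % of 2484 → 25) give
`precision = hits/k`, `recall = hits/|gold|`, `F1 = 2PR/(P+R)` (0 when
both are 0).  The baseline precision is retrieved-gold over the universe,
which makes precision at the 100 % cutoff equal the baseline exactly.
`prf_from_counts` puts comparator methods on the same axes when only
their printed prediction counts are available.  Novel-prediction mode
removes a supplied approved-drug list from both the entries and the
universe before cutoffs are applied; keeping the universe instead is
available by evaluating the unmodified ranking.

**Class enrichment.**  For a ranked entity list and a (possibly
multi-label) class map, the class percentage at cutoff `c` is the share
of the top-`k` entities carrying the class; unclassified entities count
in denominators.  Fold enrichment contrasts the top fraction (default the
top decile) with the whole list and retains classes at `fold ≥ 2` by
default; at the 100 % cutoff every fold is exactly 1.

## Numerical choices and degenerate inputs

* Convergence is measured in L1 by default (natural for probability
  vectors, and it gives the geometric tail bound
  `‖p∞ − p(t)‖₁ ≤ (1−γ)/γ · change`); L2 and max-norm stopping are
  configurable and converge to the same fixed point, without the tight
  L1 guarantee.
* Zero columns (isolated nodes) are left zero in `M`.  Probability mass
  that walks into them leaks; only the restart term reinjects mass.  In
  the degenerate case of an isolated *seed*, the fixed point is exactly
  `γ·p0`, reached in two sweeps.
* Name normalization is case-fold + trim + whitespace-collapse and
  nothing else: joins are deterministic, and no ontology mapping is
  attempted.  Placeholder gene tokens (`NR`, `NA`, `intergenic`, empty)
  are dropped during parsing.
* In the GWAS-catalog dialect the mapped-gene column (the catalog's
  curated field) is preferred over reported genes; cells are split on
  `","`, `";"` and `" - "` so intergenic flank pairs become two genes
  while hyphenated symbols stay intact.
* Ties anywhere break lexicographically, making every ranking a pure
  function of its inputs; reruns are byte-identical and manifests record
  input checksums.

## The synthetic generator

The generator plants the one statistical feature the method consumes —
gene-set overlap aligned with treatment structure — and nothing else.

* One seed disease plus `n_related = 20` diseases that copy
  `⌈shared_fraction · genes_per_disease⌉` of the seed's genes
  (`shared_fraction = 0.5`), plus `n_unrelated = 200` background
  diseases.
* `genes_per_disease = 25`, matching the order of genes-per-trait in
  GWAS association catalogs (tens of thousands of pairs over ~900
  traits).  Background genes are drawn from a pool of
  `10 ×` the total gene slots; any two background draws then collide
  with probability ≈ 1 %, giving the background the sparse incidental
  connectivity of a real catalog (most background diseases acquire small
  positive walk scores) while planted edges are an order of magnitude
  stronger.
* 10 signal drugs and 200 decoys each treat 5 distinct diseases.  Every
  drug picks, per treated disease, the related pool with probability
  `true_drug_bias` (signal, default 0.9) or 0.5 (decoys), then uniformly
  within the pool.  Because decoys use the same two-step draw, setting
  `true_drug_bias = 0.5` makes signal drugs statistically identical to
  decoys — the null configuration used to check calibration.  The seed
  disease itself is never sampled as a treated disease (the related set
  is defined as the diseases sharing genes with the seed).
* Randomness flows from one seed through independently spawned
  sub-streams for genes, signal drugs and decoys, so resizing one
  component does not perturb the others, and identical seeds write
  byte-identical fixtures.

What passing on this fixture shows — and does not show.  The generator
produces exchangeable gene draws and independent treatment choices; real
catalogs have heavy-tailed gene-set sizes, correlated trait definitions,
study-selection bias and name ambiguity.  Recovery of planted drugs
(median percentile < 15 % under the signal configuration in ≥ 95 % of
seeds; ≈ 50 % under the null) validates the machinery and its
calibration, not the biological hypothesis; headline numbers from any
real catalog/treatment corpus depend on those corpora and are not
reproduced here.

## Problem sizes

The default study conditions (221 diseases, 210 drugs) solve in well
under a second per replicate; the recovery analyses aggregate 50
independently seeded replicates per configuration, and the walk-versus-
linear-solve equivalence check uses 100 random graphs of up to 200
nodes.  These sizes were chosen so the whole suite and the acceptance
script each complete in minutes on one CPU while keeping Monte-Carlo
error on the reported summaries near one percentage point.

## Known limitations

* Disease and drug names are joined by string normalization only;
  synonymous names (or cross-vocabulary identifiers) count as distinct
  entities unless the caller harmonizes them upstream.
* The walk is run on the weighted adjacency; a binarized variant exists
  behind a flag but no claim is made about which matches any particular
  published analysis.
* No statistical significance is attached to fold enrichments; the
  tables are descriptive.
* Protein-interaction- or pathway-mediated disease linking is out of
  scope; only direct gene-set overlap defines edges.
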