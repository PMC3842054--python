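# Methods

`sigrank` compares gene-ranking (biomarker selection) methods on
two-class expression data along three axes: how much their selected
signatures overlap, how functionally similar those signatures are in GO
terms, and how stable and predictive each method is under sample
perturbation. This note records the models, conventions and numerical
choices behind each component, and what the synthetic benchmark does and
does not establish.

## Data model

A study is a `Z × N` real matrix (samples × genes) with a binary class
symbol per sample. Loaders validate rather than repair: missing values,
duplicate gene identifiers and more than two class symbols are rejected,
because silent imputation or merging would change every downstream
ranking. No preprocessing (log transform, thresholding, normalisation)
is applied by loaders; rankers that need scaling do it internally. The
negative class is the lexicographically smaller symbol unless
overridden — AUC orientation depends on this, so it must be
deterministic.

## Supervised discretization

The univariate scorers are defined on discrete variables, so each gene
is binned against the class by recursive entropy minimisation with an
MDL stopping rule. Candidate cuts are midpoints between distinct
adjacent values; the gain-maximising cut is accepted iff

```
gain > ( log2(n−1) + log2(3^k − 2) − [k·H(S) − k1·H(S1) − k2·H(S2)] ) / n
```

with `k, k1, k2` the class counts present in the node and its halves,
and accepted halves are split recursively. Ties on gain resolve to the
lowest cut. Bins are left-open/right-closed, so a value exactly at a cut
falls in the lower bin; this convention only matters for exact ties but
is fixed so results are bit-reproducible. A gene with no accepted cut
collapses to one bin and scores zero under every univariate criterion.
The implementation is vectorised over candidate cuts; a scalar
re-derivation serves as its oracle in the test suite.

## The eight rankers

* **CHI2** — Pearson χ² of the discretized-gene × class table.
* **IG** — information gain `H(C) − H(C|X)`; entropies in base 2 with
  `0·log 0 = 0` throughout.
* **SU** — `2·IG / (H(C) + H(X))`, 0 when both entropies vanish.
* **GR** — `IG / H(X)`, defined as 0 when `H(X) = 0` (constant genes),
  avoiding the division by zero without inventing relevance.
* **ONER** — training accuracy (%) of a one-gene bucket rule. Sorted
  instances accumulate into a bucket until some class reaches the
  minimum bucket size (default 6, the classic choice); the bucket then
  extends through value ties and the run of that majority class, a
  trailing majority-less bucket merges backwards, and adjacent buckets
  with equal majority merge. On datasets too small to fill a bucket the
  rule degenerates to the majority class — intended behaviour. OneR is
  scored on its training data; internal cross-validation variants exist
  and would shift absolute scores slightly.
* **RELIEFF** — nearest hit/miss margin weights: k = 10 neighbours per
  class (truncated to availability), all instances used, Manhattan
  distance on features min-max scaled to [0, 1], miss contributions
  weighted by class priors. No distance weighting.
* **SVM_ONE** — one linear soft-margin SVM fit (C = 1, exact QP via
  libsvm) on min-max-scaled features; genes ordered by descending
  squared weight.
* **SVM_RFE** — recursive feature elimination: refit the SVM on the
  survivors and drop the `⌈0.10 · survivors⌉` genes of lowest squared
  weight (at least one, never all) each round. The final ranking is the
  reverse elimination order, batches internally ordered by descending
  squared weight. Note this *proportional* schedule differs from
  implementations that remove a fixed 10% of the original feature count
  each round; the schedules diverge most in the late rounds and select
  visibly different signatures.

Ties everywhere break by original gene (column) index, so every ranking
is a deterministic permutation of the genes.

## Signature similarity

Signatures are the top-`t` genes of a ranking. The overlap index is the
Jaccard ratio `|A∩B| / |A∪B|`; the Kuncheva index additionally subtracts
the chance overlap `t²/N` of random equal-sized subsets,
`(|A∩B| − t²/N) / (t − t²/N)`. For `t = 10` drawn from thousands of
genes the correction changes the value by at most ~0.005, so the plain
overlap is an adequate stability measure at biomarker-scale signature
sizes. Cross-method agreement is summarised as the mean of the
off-diagonal entries of the pairwise similarity matrix (the diagonal is
stored as the self-similarity but always excluded from averages).
Unequal-sized sets are legal for Jaccard but rejected for Kuncheva.

## Functional similarity

Two signatures sharing few genes can still describe the same biology.
Each signature maps to the union of the molecular-function GO terms
annotating its genes (unannotated genes are flagged, not dropped
silently). A term's information content is `−log2 p`, with `p` the
fraction of annotated genes covered by the term or any `is_a`
descendant; the corpus is the supplied annotation table itself, so
results are self-contained and do not drift with external frequency
tables. Term pairs are compared with the Lin measure
`2·IC(MICA) / (IC(t1) + IC(t2))` and term sets with the symmetric
best-match average. This combination was chosen as a transparent,
bounded-in-[0,1] default; the term-pair measure is pluggable. An empty
term set yields NaN (missing), not 0 — no functional profile is not the
same as a dissimilar one. Because functional similarity depends on the
ontology release and annotation corpus, absolute values are comparable
only within one corpus.

## Stability / performance protocol

`P` reduced datasets (default 20) are drawn from the study, each a
stratified random `⌊f·Z⌋`-sample subset (default f = 0.9) without
replacement, independently per split; the held-out remainder is the test
set. Stratification draws `⌊f·n_c⌋` per class, topped up by largest
remainder to `⌊f·Z⌋`, so every split is trainable and testable in both
classes. Rankers see only the training subsample — the no-leakage
property is asserted metamorphically in the tests (perturbing held-out
rows never changes a selected signature).

Stability of a ranker at size `t` is the mean pairwise Jaccard overlap
of its `P` signatures. Performance is the mean (and SD) over splits of
the held-out AUC of a linear SVM (C = 1) trained on the signature's
genes, min-max scaling fitted on the training split only. AUC is the
Mann–Whitney statistic with ties half-credited. One master seed expands
to per-split child seeds via `numpy` seed sequences, making entire runs
byte-reproducible.

The public surface is a model/results pair: `RankerComparison(dataset,
rankers, thresholds, p_count, fraction_f).fit(seed)` returns a results
object with `stability_`, `auc_mean_`, `auc_sd_` tables, `summary()`,
tidy/JSON export and stability/AUC curve plots. Functional wrappers
(`evaluate_stability`, `evaluate_performance`, `joint_evaluation`) cover
single-ranker use.

## Synthetic benchmark

The generator emulates the statistical shape of small-sample microarray
studies: tens of samples, ~10³ genes, i.i.d. standard-normal background,
a handful of informative genes shifted by `effect_size` SD units in the
positive class, and optional redundant blocks. Block genes share a
latent signal: `sqrt(ρ)·latent + sqrt(1−ρ)·noise` plus the class shift,
giving pairwise *within-class* correlation ≈ ρ (the realized-correlation
check removes class means first, since the shift itself induces
between-class correlation). Labels are assigned deterministically
(`⌈balance·Z⌉` positives) and rows shuffled under the seed, so class
proportions are exact and stratification always feasible.

Defaults — 60 samples, 1000 genes, 10 informative genes at 2 SD,
balanced classes — are the study conditions for the recovery and
protocol experiments; the redundancy experiment
(`redundancy_scenario()`) places all signal in two blocks of 10 markers
at ρ = 0.8, the regime of co-regulated gene modules. Sizes were chosen
as representative of the small-sample/high-dimensional regime while
keeping a full 8-ranker protocol run around a quarter of a minute.

What the synthetic data does **not** model: heavy-tailed intensity
distributions, probe-level artifacts, batch effects, nonlinear
class-feature relations. Passing tests therefore demonstrate the
correctness and the qualitative mechanisms of the framework — not that
any ranker's absolute stability or AUC on real microarray data will
match the synthetic values.

## Known behaviours and limitations

* Under the proportional elimination schedule, SVM_RFE recovers ≥8 of
  10 independently informative planted markers in only ~78% of seeds
  (the other seven rankers: ~100%): once noise genes are eliminated,
  the separable SVM needs only a subset of the informative genes and
  down-weights the rest, so markers can be discarded when 10–25
  survivors remain. This is the same mechanism that makes SVM_RFE the
  least stable method in the redundancy experiment, where it is
  nonetheless highly predictive.
* OneR's score is training accuracy; with fewer samples than the
  minimum bucket size per class it cannot split and scores at the
  majority rate.
* Kuncheva's index is undefined at `t = N` and rejected there; stability
  at `t = N` equals 1 by construction.
* Functional similarity values are corpus-relative; only comparisons
  within a fixed ontology + annotation set are meaningful.
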