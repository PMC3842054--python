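# sigrank

Comparing gene-ranking (biomarker selection) methods on two-class
expression data.

Different feature-selection techniques applied to the same
high-dimensional expression study — tumor vs. normal tissue, one tumor
subtype vs. another — routinely nominate different gene signatures,
which raises the question of how much these candidate biomarker panels
actually agree, and what the disagreement costs. `sigrank` is for
computational biologists and method developers who want to quantify
that, on their own data or on controlled synthetic studies.

The package implements:

* **Eight rankers** spanning the standard families — χ² (`CHI2`),
  information gain (`IG`), symmetrical uncertainty (`SU`), gain ratio
  (`GR`), the OneR rule scorer (`ONER`) among univariate methods;
  ReliefF (`RELIEFF`), linear-SVM weights (`SVM_ONE`) and SVM recursive
  feature elimination with 10% proportional removal (`SVM_RFE`) among
  multivariate ones. Univariate scorers operate on MDL-discretized
  expression (recursive entropy splitting with the
  minimum-description-length stopping rule). Each ranker returns a full
  deterministic permutation of the genes; cutting at a threshold *t*
  yields a signature.
* **Signature similarity.** Overlap (Jaccard) index
  |A∩B|/|A∪B|, the chance-corrected Kuncheva index
  (|A∩B| − t²/N)/(t − t²/N), pairwise similarity matrices and their
  off-diagonal averages; and *functional* similarity of signatures via
  their molecular-function GO term sets, using information-content Lin
  term similarity with symmetric best-match averaging over an `is_a`
  DAG parsed from OBO files.
* **Joint stability/performance protocol.** P stratified subsamples of
  fraction *f* (defaults P = 20, f = 0.9); per ranker and signature
  size: stability = mean pairwise overlap of the P selected signatures,
  performance = mean held-out AUC of a linear SVM trained on each
  signature. Selection never sees test instances.
* **A synthetic-study generator** with planted informative genes and
  correlated redundant marker blocks, so every claim is testable
  without external downloads.

## Worked example

```python
from sigrank import RankerComparison, SyntheticSpec, generate_dataset, rank_features

dataset, markers = generate_dataset(SyntheticSpec(seed=7))   # 60×1000, 10 planted genes
model = RankerComparison(dataset, rankers=["CHI2", "IG", "RELIEFF", "SVM_RFE"],
                         thresholds=[5, 10, 20])
results = model.fit(seed=7)
print(results.summary())
```

```
Ranker comparison under subsampling
  Z = 60 samples, N = 1000 genes
  P = 20 reduced datasets, f = 0.9, seed = 7

ranker      stab@5    auc@5       stab@10   auc@10      stab@20   auc@20
CHI2           0.727  1.000         0.965  1.000         0.546  1.000
IG             0.727  1.000         0.982  1.000         0.545  1.000
RELIEFF        0.793  1.000         1.000  1.000         0.539  1.000
SVM_RFE        0.766  1.000         0.543  1.000         0.438  1.000
```

Read: every method is perfectly predictive here (the 10 planted genes
carry a 2-SD class shift), but they differ sharply in *stability* —
ReliefF reselects the identical 10-gene signature on all 20 subsamples
(stab@10 = 1.0), while SVM-RFE picks substantially different genes each
time (0.543). Stability peaks at t = 10 because exactly 10 informative
genes were planted. On the full dataset,

```python
ranking = rank_features(dataset, "CHI2")
len(set(ranking.ordered_genes[:10]) & set(markers))   # -> 10
```

all ten planted markers head the χ² ranking. `results.stability_`,
`results.auc_mean_` and `results.to_tidy()` expose the tables;
`results.plot_stability()` / `results.plot_auc()` draw the curves.

## Command line

```sh
sigrank simulate --out sim/ --z-samples 60 --n-genes 1000 --seed 1
sigrank rank     --data sim/expression.csv --out rankings/
sigrank compare  --data sim/expression.csv -t 10 --out cmp/ \
                 [--obo go.obo --annotations gene2go.tsv]
sigrank evaluate --data sim/expression.csv --p-count 20 --fraction-f 0.9 \
                 --thresholds 5,10,20,30 --seed 1 --out eval/
```

`compare` writes the pairwise overlap (and, with an ontology, the
functional) similarity matrix with its off-diagonal average; `evaluate`
writes tidy TSV/JSON stability and AUC profiles. Every command is
deterministic given its seed and writes a provenance JSON.

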