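# mgrselect

Biomarker **interaction** selection and disease detection for binary
outcomes. Many diseases are determined not by single biomarkers but by the
joint configuration of several; a variable with no marginal signal can be
decisive together with a partner (the extreme case being an XOR pair),
and any single-variable ranking will miss it. `mgrselect` scores variable
*subsets* of a discrete design matrix, searches the subset space for
influential interactions, and builds a classifier from the survivors. It is
aimed at gene-expression, SNP, protein and cell-morphology tables with tens
of samples and up to thousands of variables.

## The measures

For a subset S of k discrete predictors partitioning n samples into cells
j (cell total n_j, case count n₁(j), overall case fraction π₁):

- **I-score**:  I(S) = Σⱼ [n₁(j) − n_j·π₁]²  — squared deviation of each
  cell's case count from its no-association expectation.
- **Multivariate gain ratio**:
  MGR(S) = [Info(Y) − Info_S(Y)] / SplitInfo(S) — the information the joint
  partition provides about the outcome, normalized by the partition's own
  entropy. For k = 1 this is the classical gain ratio (GR).

Both grow spuriously with subset size on pure noise, but with opposite
shapes (I-score saturating, MGR accelerating), which is why MGR is the
better arbiter among *small* candidate interactions. The package implements
both, plus:

- **Backward dropping (BDA)** — from each of B random k-subsets, greedily
  drop the variable whose removal most raises the measure and return the
  best subset seen; with overlap filtering and forward adding to remove
  false positives, and calculators for workable k and B.
- **Triple screening** — for p in the thousands, rank all C(p,3) triples
  and keep the variables with high retention frequency in top triples.
- **Classification** — per-interaction ridge regression with all product
  terms (so XOR-type joint action is expressible), AdaBoost-style
  combination, stratified cross-validated evaluation.
- **Preprocessing** — exact 1-D two-means discretization, intensity
  clamps/filters, and a verification probe that judges a candidate recipe
  on ~100 random variables before committing to it.
- **Simulation** — planted-interaction generators and the two experiments
  characterizing the measures' null bias and co-growth.

## Worked example

The planted benchmark: n=200 samples, 10 iid uniform binary biomarkers,
Y = X1 with probability 0.5 and (X2+X3) mod 2 otherwise — a marginal
signal on X1 and a pure pair interaction on {X2, X3}.

```python
from mgrselect import (gen_module2, Module2Model, gr_ranking, score_subset,
                       run_bda, BDAConfig, filter_overlaps, forward_add)
from mgrselect.pipeline import PipelineConfig, run_pipeline

mat = gen_module2(Module2Model(n=200, p=10, seed=7))

gr_ranking(mat)[:3]
# [('X1', 0.2823), ('X3', 0.0123), ('X8', 0.0038)]
score_subset(mat, (1, 2), "mgr")
# 0.1129

sets = run_bda(mat, BDAConfig(k=4, B=2000, z=2, measure="mgr", seed=1))
final = forward_add(mat, filter_overlaps(sets), "mgr")
# top sets: (['X1'], 0.2823), (['X2','X3'], 0.1129), ...

report = run_pipeline(mat, PipelineConfig(measure="mgr", k=4, B=2000,
                                          z=2, folds=5, seed=17))
report["metrics"]["average"]
# {'accuracy': 0.805, 'sensitivity': 0.6906, 'specificity': 0.8991}
```

Reading the numbers: the single-variable ranking finds X1 (GR 0.28 in this
draw; 0.189 in expectation) but scores X2 and X3 near noise — alone they
carry nothing. Joint scoring exposes the pair (MGR 0.11; 0.094 in
expectation), and the search returns both `{X1}` and `{X2, X3}` as disjoint
interactions. The cross-validated accuracy of the boosted classifier sits
near the 75% Bayes limit of this generating model (per-draw CV estimates
scatter around it).

The same stages are available from a shell:

```sh
mgr-select simulate module2 --n 200 --p 10 --seed 7 --out m2.csv
mgr-select bda --input m2.csv --label-col label --measure mgr \
    --k 4 --B 2000 --seed 1 --out interactions.json
mgr-select classify --input m2.csv --label-col label \
    --interactions interactions.json --report metrics.json
mgr-select run --config pipeline.json      # end-to-end from one config
```

For real tables, `mgr-select preprocess` applies either the per-variable
two-means recipe (`--recipe bcw`, for small dense feature tables) or the
expression-array recipe (`--recipe golub`: clamp to [100, 16000], drop
genes with max/min ≤ 5 or max−min ≤ 500, log10, per-sample two-means).
`scripts/real_data.py` chains preprocessing and the pipeline for locally
supplied copies of the public breast-cancer and leukemia datasets.

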