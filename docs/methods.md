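# Methods

## The problem

Many diseases are driven not by single biomarkers but by *interactions* —
subsets of biomarkers whose joint configuration determines the outcome. A
variable with no marginal association (so invisible to any single-variable
ranking) can be decisive in combination with a partner, the canonical case
being an XOR-type pair. This package scores candidate subsets of a discrete
design matrix against a binary outcome, searches the subset space for
influential interactions, and turns the survivors into a classifier.

## Influence measures

Let a subset S of k discrete predictors partition the n samples into cells
j (one per observed code combination), with cell totals n_j, case counts
n_1(j), and overall case fraction pi_1.

**I-score.**  I(S) = sum_j [n_1(j) − n_j·pi_1]^2 — the squared deviation of
each cell's case count from its no-association expectation, unnormalized.

**Multivariate gain ratio (MGR).**
MGR(S) = [Info(Y) − Info_S(Y)] / SplitInfo(S), where Info(Y) is the outcome
entropy, Info_S(Y) the outcome entropy conditional on the cell, and
SplitInfo(S) = −sum_j (n_j/n) log(n_j/n) the entropy of the cell occupancy
itself. For k = 1 this is Quinlan's gain ratio; the SplitInfo denominator
penalizes subsets that fragment the sample into many cells. The ratio is
invariant to the logarithm base; natural logs are used internally.
Conventions: 0·log 0 = 0; a subset with a single occupied cell
(SplitInfo = 0) scores 0, as does single-class data (Info(Y) = 0); these
are returned, not raised.

Both are plug-in statistics and both are biased upward on pure noise as the
subset grows, but with opposite shapes: the I-score's null level scales
like n·pi_1(1−pi_1)·(1 − 2^−k) — fast early growth that saturates — while
the MGR's scales like (2^k − 1)/(2n·k·log 2) — negligible at small k,
accelerating afterwards (its null distribution is approximately
chi-square with 2^k − 1 degrees of freedom over 2n·k·log 2). The
`simulate.experiment_bias_vs_order` experiment measures both curves.

## Search

**Backward dropping.**  From a random initial subset of size k, repeatedly
remove the variable whose removal yields the highest measure, recording
every intermediate subset (sizes k down to 1, including the start); return
the best intermediate ("return set"). Ties in the drop choice remove the
smallest variable index; ties across intermediates resolve toward the
smaller subset. Repeated over B independent uniform draws; duplicate return
sets are collapsed keeping the earliest origin.

**Sizing.**  `initial_size_bounds(n)` reports the largest k for which a
random (k−1)-subset's partition is still expected to receive collisions
(n²/(2·c^(k−1)) ≥ 1, Poisson approximation, c codes per variable) and the
largest k keeping ≥ 4 observations per cell on average; any k between the
two is workable. `repetitions(p, k, z)` returns
B̂ = ceil[(C(p,z)/C(k,z))·ln C(p,z)], the expected number of draws needed to
cover every z-subset, and 2·B̂ as a safe upper bound.

**Post-filters.**  Overlap filtering sorts return sets by descending score
(ties: lexicographically smaller set first) and greedily keeps only sets
disjoint from everything already kept. Forward adding then rebuilds each
survivor from its best single variable, re-admitting remaining members
greedily and keeping a variable only if it raises the measure by more than
a tolerance (default 1e−9). The one-at-a-time re-admission scheme is this
package's own reconstruction of a "forward adding" false-positive filter;
note it requires each true member to carry *marginal* information given the
variables already admitted — a pure 3-way XOR, which has no 1- or 2-variable
signal, cannot be rebuilt by any such scheme and would be trimmed to a pair
or singleton.

**Triple screening** (for p in the thousands). All C(p,3) triples are
scored and sorted; scores are sampled every `stride` ranks (default 1000,
auto-shrunk to n_triples/10 for small problems) and the retained-triple
count is set where the second difference of that strided sequence first
falls within 1% of its maximum magnitude ("first time near zero"). Variables
are then ranked by how often they occur in the retained triples, and the
keep count is set where the first difference of that frequency sequence
first falls within 1% of its maximum drop. Degenerate sequences (flat
frequencies, flat start) keep everything, with a warning — an absent elbow
means the screen has no evidence to exclude anyone. The 1% "near zero"
threshold is a design choice; it is exposed as `epsilon_frac`.

## Classification

Each selected interaction of size m yields one ridge-regression
sub-classifier on the m variables plus *all* products of ≥ 2 of them
(2^m − 1 columns; for binary codes the products are joint-occurrence
indicators). The product terms are what let a linear fit express
non-additive joint action: balanced XOR is fit exactly with the pair
product, while ridge on the raw pair cannot exceed 75%. Interaction size is
capped at 12 to bound the expansion. The ridge penalty is chosen from a
10-point log grid over [1e−3, 1e3] by internal 5-fold CV on squared error;
prediction is 1 iff the fitted value reaches 0.5.

Sub-classifiers are combined AdaBoost-style: per round, every remaining
interaction is refit under the current sample weights (coefficients only —
the penalty chosen once, unweighted; weights are rescaled to sum to n so
the data-versus-penalty balance is weight-scale invariant), the lowest
weighted-error member joins with vote weight α = ½·log((1−ε)/ε), and sample
weights update multiplicatively. Rounds stop when the pool is exhausted or
no member beats chance; ε is clamped to [1e−12, 1−1e−12] so a perfect round
yields a large finite α. If even the first member has ε ≥ 0.5, the single
best sub-classifier is returned alone with a warning.

Evaluation is stratified k-fold (default 5) cross-validation with the
*entire* selection pipeline re-run inside each training fold, reporting
per-fold and average accuracy, sensitivity and specificity. Fold class
proportions match the global pi_1 to within one sample.

## Preprocessing

Continuous tables are cleaned (binary status column mapped to 0/1,
all-missing rows/columns dropped, then rows with any remaining missing
entry dropped and counted — imputation is out of scope), optionally
clamped to [floor, ceiling], filtered by post-clamp max/min ratio and
max−min range, optionally screened per-variable by Welch t-test or
fold-change, log10-transformed, and discretized.

Discretization is 1-D two-means per slice (a variable across samples, or a
sample across variables for expression arrays), solved *exactly*: because
an optimal 1-D 2-clustering is a threshold in sorted order, enumerating the
n−1 admissible thresholds and minimizing within-cluster SSE gives the
global optimum with no initialization sensitivity; SSE ties take the lower
threshold, and the lower-mean cluster always receives code 0, so codes are
stable across runs. Constant slices become all-0 with a warning.

Because the right recipe is dataset-dependent, `verify_preprocessing`
probes a candidate: apply it, sample ~100 variables, run the subset search
and boosted classifier on them under CV, and call the recipe *reasonable*
iff accuracy beats the majority-class baseline by a margin (default 5
points — "reasonable" made operational; configurable).

## Synthetic data and what it does (not) show

`gen_module2(n=200, p=10, mix_prob=0.5)` is the planted benchmark: iid
uniform binary predictors; Y = X1 with probability 0.5, else
(X2 + X3) mod 2. It plants a marginal signal (GR(X1) = 0.1887
analytically) and a pure pair interaction (MGR({X2,X3}) = 0.0944;
{X1,X2,X3} jointly 0.1667) in one dataset, so single-variable rankings,
joint scoring, the search, and the classifier can all be exercised; the
Bayes accuracy of any classifier on it is 75%. `gen_null` gives iid noise
for bias experiments. These generators emulate the *structure* of biomarker
interaction problems, not real data's correlated variables, batch effects,
or class imbalance — passing tests demonstrate that the machinery recovers
planted structure at realistic n, not that any particular dataset will
yield a given accuracy.

Defaults follow the study conditions throughout: n=200, p=10, mix 0.5 for
the planted model; n=10,000, sizes 1–9 for the null-bias experiment with
2,000 repetitions by default (the full 20,000 is a flag away; 2,000 keeps a
full sweep near a minute and leaves median standard errors well below the
contrasts being tested); 500 draws per size for the co-growth experiment.

## Numerical and design notes

- Hot-path scoring packs each subset's codes into a mixed-radix integer and
  tallies cells with `bincount`; the `PartitionTable` dict API and a naive
  double-loop oracle in the tests cross-check it.
- All randomness flows from explicit seeds; pipeline stages derive seeds as
  `blake2s(root_seed, stage_name)`, so adding a stage never shifts another
  stage's stream, and identical config + seed gives byte-identical reports
  (JSON with sorted keys).
- Monotonicity checks on the null-bias medians allow adjacent decreases up
  to 3× the median's distribution-free standard error
  (1.253·IQR/(1.349·√reps)): the I-score's median saturates, so adjacent
  sizes differ by less than replication noise and a strict check would test
  the noise, not the trend.
- Empirically, the MGR's accelerating null bias makes backward drops on
  pure noise at desk sample sizes (n ≤ a few hundred) retain the *full*
  initial subset more often than the I-score does, whose greedy
  noise-chasing tends to peak at small subsets; directional claims about
  return-set sizes therefore depend strongly on the n-versus-2^k regime and
  are documented here rather than promised as invariants.
- Known limitations: binary outcomes only; discrete (or discretized)
  predictors only; full C(p,3) enumeration in the screen (exact but
  quadratic-ish in memory for p in the several thousands); the forward-add
  marginality requirement above.
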