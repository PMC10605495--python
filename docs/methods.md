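# Methods

This note documents the models, procedures and design choices behind
`sigtransfer`, in the spirit of a methods section: what is computed, under
which assumptions, and what the synthetic experiments do and do not show.

## The classifier model class

A formula model is a binary expression tree over at most three genes. Leaves
apply an affine transform `w·x + b` to a normalized expression value;
internal nodes are `add` or `multiply`; a final logistic link with output
bias `c` maps the tree value to a disease probability. Three-gene models have
seven free parameters. The class is deliberately minimal: it can express
published colon-signature forms such as "(LYZ + FABP1) × LGALS4" or a purely
additive three-gene sum, while staying readable. Biases live on leaves rather
than on internal nodes — for additive nodes the two parameterizations are
identical (node biases are sums of leaf biases), and for multiply nodes
leaf-level biases are what make factors like `(w·LGALS4 + e)` expressible.
Only the output carries the logistic; intermediate nodes are linear/bilinear.

Predicted probabilities are clipped to `[1e-12, 1 − 1e-12]` so downstream
log-losses are finite.

## Parameter fitting

Parameters minimize mean binary cross-entropy (nats). The objective and its
exact gradient are evaluated by one recursive pass over the tree; L-BFGS runs
from `n_restarts` random initializations (N(0, 0.5²), the scale of normalized
log-expression effects). The closed-form intercept-only solution
(probability = class prevalence) is always a candidate, so a fit can never be
worse than predicting the prevalence; for any tree, all-zero weights and
biases realize that floor exactly.

Inside the evolutionary search each L-BFGS run is capped at 60 iterations
(`ftol` 1e-9): empirically this sits within ~2×10⁻³ nats of full convergence
at a tenth of the cost, and ranking structures — not polishing them — is what
the search needs. The final shortlist is refitted at 300 iterations with
three extra restarts. Multiply nodes introduce sign symmetries and hence
non-convexity; restarts handle this, and equal-loss ties keep the first
restart found under the seeded order.

## Structure search

For one (dataset, cell type) training slice the search explores structures
over a gene pool (default: the 500 highest-variance genes of the slice, or
all genes for small panels):

1. An initial population (default 64) is drawn uniformly: feature count
   uniform on {1, 2, 3}, distinct genes, independent uniform operators on a
   left-deep tree.
2. Every structure is fitted; the better half survives (elitism, so the best
   training loss is non-increasing by construction).
3. The population is refilled with single-move mutants of random survivors
   (swap one gene, flip one operator, grow a leaf, shrink a leaf; an illegal
   draw redraws among the legal moves) and 20% fresh immigrants.
4. Immigrant genes and swap/grow replacements are drawn from a 50/50 mixture
   of the uniform distribution and the gene frequency among current elites.

Step 4 is the one place the search deviates from the plain
uniform-plus-mutation scheme, and it exists for a measured reason: with
uniform draws only, two genes that are each individually informative have no
mechanism to end up in the *same* structure (there is no crossover), and in
pilot runs on 60-gene panels the planted two-gene signature was fully
recovered in barely over half of the seeds. Reinforcing elite features —
while keeping half the mass uniform so every gene remains reachable —
resolves this without changing the model class or the selection rules; it is
the estimation-of-distribution idea that guided symbolic-regression samplers
use. With a single-gene cap and any budget covering the pool, the search
still reduces to exhaustive enumeration of single-gene fits, which the test
suite verifies.

Fitted structures are cached by a canonical key that flattens chains of the
same commutative operator and sorts operands, so `add(add(a,b),c)` and
`add(add(c,a),b)` are one structure. Fit seeds are derived by hashing
(search seed, structure key), making results independent of visit order. The
run returns the 10 best distinct structures by (loss, complexity, key);
complexity is the lexicographic pair (distinct features, internal nodes).

## Transfer scoring and model selection

Every cell type observed in ≥ 2 datasets generates transfer runs in both
directions. All 10 candidates from the training slice are evaluated on the
test slice (features matched by exact gene identifier; a candidate whose
gene is absent from the test panel is skipped rather than zero-filled, since
zero-filling silently changes the formula's meaning). Selection follows the
overfitting-gap-then-simplicity strategy: candidates with
|AUC_PR,train − AUC_PR,test| ≥ 0.10 are dropped (the gap is read as an
absolute PR AUC difference; a relative variant is available), and survivors
are ranked by fewest features, additive-only before any multiply, then
highest transfer score, with the canonical key as a final deterministic
tie-break. If nothing survives, the highest-scoring candidate is kept and
flagged. Selecting on test-set performance reproduces the historical
convention of such transfer tables; a `holdout_fraction` option instead
computes the gap on a training-internal split for users who want selection
untouched by test information. A `rank_score_first` switch flips the
simplicity/score order, since either reading of "simple and explainable
first" is defensible.

PR AUC is step-wise average precision (trapezoidal interpolation
over-estimates PR curves); ROC AUC is the Mann–Whitney statistic with half
credit for ties; both are computed by scikit-learn and are checked against
independent brute-force oracles in the tests. The transfer score
`s = (a+b)/2 − |a−b|` satisfies `s = min(a,b) − |a−b|/2 ≤ min(a,b)` with
equality iff the AUCs agree; it is symmetric, so the per-direction records
differ only through the models, not the scoring. Disease is the positive
class (label 1) everywhere; a `positive_class="healthy"` switch flips the
encoding, which changes PR AUC values on imbalanced slices.

Report tables round half-up to 2 decimals (so a computed 0.935 prints as
0.94) and display disease fractions as integer percents. Scores assembled
from 2-decimal AUCs are exact multiples of 0.005 that float arithmetic can
land one ulp below the boundary; display rounding therefore snaps to 9
decimals first.

## The synthetic cohort generator

The generator emulates a multi-center case/control scRNA-seq study: each
dataset has its own per-gene batch shift (Gaussian on the natural-log mean
scale, SD `batch_log_sd`), its own cell-type repertoire (partially
overlapping across datasets), and samples labeled diseased with probability
`disease_fraction` (labels live on samples and are inherited by cells). Each
(sample, cell type) contributes Poisson-many cells; counts are negative
binomial via the gamma–Poisson mixture, `NB(mean μ, dispersion θ)` with
`Var = μ + μ²/θ`, the standard scRNA-seq noise model. Defaults: θ = 10
(moderate overdispersion), baseline log-means uniform on a range spanning
typical detected-gene mean counts (~0.1–4.5), 200-gene panels in the generic
recipe, θ and panel sizes configurable.

Disease enters only through the planted signatures: in diseased cells of a
signature's cell type, each signature gene's log-mean shifts by
`log(2)·log2_effect`. With `interaction="additive"` the genes shift
independently; with `"multiplicative"` a shared per-cell Gamma(4, 1/4) latent
(mean 1, SD 0.5) scales all effects jointly, emulating a coordinated program
of varying strength. One seeded generator drives everything, so equal
configurations give bit-identical cohorts.

Two canned recipes set the study conditions. `uc_study_config` mirrors the
motivating four-dataset design: sample counts of 30/8/9/14, per-dataset
disease fractions 0.28–0.45 (landing per-cell-type disease fractions in the
~16–45% band such cohorts report), epithelial/mesenchymal/immune repertoires
with one plasma-cell type shared by all four, and 2–3-gene signatures per
type. `recovery_cohort_config` is the canonical recovery experiment: two
datasets, one shared type, a 2-gene additive signature at log2 effect 2.0,
batch SD 0.2, 24 samples × 35 cells per type (≈ 350 expected cells per class
per dataset), a 60-gene panel, and baseline log-means on (−1, 1.5) — the
well-expressed regime where marker-like signature genes live.

What the simulator does **not** model: read-level artifacts, UMI collapsing,
ambient RNA, doublets, cell-level dropout beyond NB sampling, annotation
noise (cell-type labels are taken as given, as the pipeline consumes them),
or the inflamed/non-inflamed distinction within disease. Passing recovery
tests therefore show that the pipeline finds planted NB-scale signal through
multiplicative batch shifts — not that it would survive every artifact of
real tissue atlases.

## Experiment sizes and numerical conventions

The Monte-Carlo experiments in the acceptance suite use the recovery recipe
at 20 cohort seeds with a search budget of population 64, 16 generations and
2 fit restarts — the budget at which pilot runs showed pool-sized exploration
is adequate. The permutation null permutes the test dataset's cell→sample
assignment (a cell-level label permutation preserving both marginals) and
reuses the identical pipeline. Determinism claims are byte-level on the
written summary TSV. Degenerate inputs are contracts, not crashes:
single-class slices are rejected at fit/search time and skipped with a
logged reason in the pipeline; zero-count cells stay all-zero through
normalization; empty record lists produce header-only tables.

Normalization is per-cell total-count scaling to 10⁴ followed by log1p,
applied identically to every dataset (cross-dataset comparability of feature
scales is a precondition for transfer). Gene matching across datasets is
exact string identity; unmatched genes drop the affected candidate, with a
log entry.
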