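# Methods

## Problem setting

Expression profiling produces matrices with tens of samples and thousands of
genes. Classifying samples (e.g. tumor subtypes) from such data overfits
badly unless the gene space is reduced first. This package implements a
two-stage hybrid selector: a cheap statistical **filter** ranks genes by
univariate (or pairwise, for mRMR/ReliefF) relevance and keeps a pool of the
top *s* genes; a **wrapper** then searches that pool for the *k*-gene subset
that maximizes cross-validated classifier accuracy, using the Nuclear
Reaction Optimization (NRO) metaheuristic and a linear support-vector
machine as the evaluator.

## Preprocessing

Datasets are read from ARFF or delimited text into a samples × genes matrix
with integer class codes. Three steps are applied, in order, to the full
dataset:

1. **Mean imputation** — each missing entry is replaced by the mean of the
   observed entries of its gene column. Idempotent; observed values are
   never altered. A fully missing column is an error.
2. **Z-score standardization** — each gene column is transformed to
   `(x − μ)/σ` with the *population* standard deviation (divide by *n*).
   Constant columns map to all zeros and are flagged (not dropped), so gene
   indices stay stable across stages.
3. **Label encoding** — distinct labels are sorted (lexicographically for
   strings) and assigned dense codes `0..m−1`, making encodings
   deterministic across platforms.

Normalization and filtering are computed on the full dataset *before* any
cross-validation. This mirrors the standard protocol in this literature and
keeps the pipeline comparable to it, but it leaks information from each
held-out sample into the preprocessing and the pool: cross-validated
accuracies are therefore optimistic relative to truly external validation.
This is a deliberate fidelity choice, not an oversight; see Limitations.

## Filter criteria

All rankings sort scores descending with ties broken by ascending gene
index, so every ranking is a deterministic permutation of the gene indices.

* **F-score (two classes)** —
  `F = [(μ₊−μ)² + (μ₋−μ)²] / [s₊² + s₋²]` with per-class *sample* variances
  (n−1 divisor). A gene with zero within-class variance but distinct class
  means gets a `+inf` sentinel that sorts first: it is a perfect separator.
  Each class needs at least two samples.
* **ANOVA F (m ≥ 2 classes)** — between-group mean square over within-group
  mean square; the multiclass generalization used whenever the data have
  more than two classes. Both statistics are invariant to shifting and
  scaling a gene, and they induce the same ranking on balanced binary data.
* **Information Gain** — entropy of the class labels minus the expected
  entropy after partitioning samples by the discretized gene. Genes are
  discretized into equal-frequency bins (quantile edges, duplicate edges
  merged; default 10 bins, 4 recommended below ~15 samples). The histogram
  estimator was chosen over continuous MI estimators because it is exactly
  testable against direct enumeration.
* **ReliefF** — multiclass nearest-hit/nearest-miss weighting: for each
  visited instance, a feature's weight decreases by its mean range-scaled
  difference to the `n_neighbors` nearest same-class neighbors and increases
  by the class-prior-weighted mean difference to the nearest neighbors of
  every other class. Distances are Manhattan on range-scaled features.
  Defaults: `n_neighbors=10`, a deterministic pass over all samples.
  Weights lie in [−1, 1].
* **mRMR** — greedy forward selection by the difference criterion
  `MI(f, c) − (1/|S|) Σ_{s∈S} MI(f, s)`, with mutual information (in nats)
  estimated on the same equal-frequency discretization used for IG. The
  first pick is the pure-relevance argmax; exact duplicates of selected
  genes are heavily penalized through the redundancy term.

The pool is the top *s* genes of the chosen ranking (the full-scale protocol
uses s = 500 after sweeping s ∈ {50, 100, …, 500}).

## The NRO search

Each individual is a continuous position in `[0,1]^d` over the pooled genes,
decoded to a subset by taking the *k* largest components (ties by ascending
index). The continuous encoding keeps every NRO operator applicable verbatim
and guarantees the fixed subset size the reporting sweep requires; a
threshold decoder (≥ 0.5 → selected, variable size) is available as an
option.

Per generation three candidate sets are produced:

* **Fission** — with probability `p_beta` the candidate is a Gaussian draw
  centered on the global best, else centered on the current solution. The
  per-dimension scale is `(log g / g)·|X − X_best|` (X the solution itself
  in the first branch, a random peer in the second), so moves start broad
  and shrink over generations; at g = 1 the scale is exactly zero and the
  Gaussian degenerates to its center. A recoil term
  `randn·(X_best − Pne·Nei)` perturbs further, where the *heated neutron*
  `Nei` is the elementwise mean of two random distinct peers and the
  mutation factor `Pne` is `round(u+1) ∈ {1,2}` (best-centered branch) or
  `round(u+2) ∈ {2,3}` (self-centered branch) with a fresh uniform draw `u`.
* **Ionization** — per dimension, recombine coordinates of two random
  distinct peers: `x = X_{r1,d} ± rand·(X_{r2,d} − X_{i,d})`, the sign
  chosen by whether the (per-dimension) uniform draw is ≤ 0.5. Dimensions
  whose difference term is below `similarity_tol` instead take a Lévy
  flight `x = X_{i,d} + α·Levy(β)·(X_{i,d} − X_{best,d})`.
* **Fusion** — `x = X_i + u₁·(X_{r1} − X_best) + u₂·(X_{r2} − X_best)` with
  two independent uniform scalars; when the two peers nearly coincide
  (vector norm below `similarity_tol`) a Lévy flight along the direction to
  the best is taken instead.

Lévy steps use Mantegna's algorithm: `u/|v|^{1/β}` with
`u ~ N(0, σ_u²)`, `v ~ N(0,1)` and
`σ_u = {Γ(1+β)sin(πβ/2)/[Γ((1+β)/2)·β·2^{(β−1)/2}]}^{1/β}`
(σ_u ≈ 0.6966 at the default β = 1.5). All candidate positions are clipped
to `[0,1]`.

Survivor selection is greedy elitist after each phase: a candidate replaces
its parent iff *strictly* better. The global best is tracked separately; a
patience counter increments on every generation without strict improvement
of the global best (plateaus count) and stops the search at `patience`
consecutive stagnant generations, or at `max_generations`. Strictness
matters: fitness is a cross-validated accuracy with finitely many values, so
non-strict acceptance would never trigger early stopping.

Defaults follow the full-scale protocol — population 500, 30 generations,
patience 5 — while the bundled tests and the acceptance script use scaled
population/generation sizes (stated inline) appropriate to their synthetic
problem sizes. `p_beta = 0.5` (uninformative branch split), `α = 0.01`,
`β = 1.5` (the canonical Mantegna choice) and `similarity_tol = 1e−10` are
the package's own defaults; all are configurable. Random peers are always
drawn distinct from each other and from the current index so difference
terms never silently vanish. Every run is bit-reproducible from its seed.

## Fitness

A subset's fitness is the leave-one-out cross-validated accuracy of a
linear-kernel SVM with C = 1 trained on the (globally normalized) data
restricted to the subset. Stratified k-fold with seeded shuffling is
available as a cheaper alternative; with folds equal to the sample count it
degenerates to leave-one-out. Pooled held-out predictions also yield
support-weighted precision, recall and F1 (macro averaging optional).
Because the optimizer revisits duplicate subsets constantly, results are
memoized by the sorted gene-index tuple; with identical inputs the cache is
exact, not approximate. Every class must have at least two samples (a
singleton class can never be predicted correctly under LOOCV).

Degenerate case worth documenting: on constant features with balanced binary
labels, every held-out sample faces a training majority of the opposite
class and the SVM predicts that majority, so LOOCV accuracy is exactly 0 —
verified against the bundled classifier's deterministic behavior.

## Experiment protocol

`evaluate_filters` scores every (method, pool size) pair by the plain LOOCV
accuracy of the top-*s* genes (no search); ties prefer the smaller pool,
then the method order fscore, infogain, relieff, mrmr. `run_fnro_sweep`
then runs NRO `repeats` times (seeds `base_seed + i`) at every subset size
*k*, reporting best/average/worst accuracy, a 95% confidence interval on
the mean (`mean ± 1.96·s/√n`, sample standard deviation; Student-t variant
optional; zero width at n = 1), and precision/recall/F1 recomputed on the
best run's subset — a reporting convention, since those metrics pair with
the "best" column. With `stop_at_perfect` the sweep stops enlarging *k* at
the first size reaching accuracy 1.0.

## Synthetic data generator

The generator emulates small-n / large-p microarray structure: all genes are
independent Gaussians with `noise_sd = 1`; a planted set of informative
genes additionally carries class-dependent mean shifts on a ladder
(0, Δ, 2Δ, …) with `Δ = effect_size·noise_sd`, so any two classes are
separated on every informative gene. Defaults (60 samples, 2000 genes,
2 classes, effect 2.0, optional missing entries at a few percent) mirror the
scale of classic two-class microarray benchmarks. The planted index set is
the recovery oracle: `recovery_score` is the fraction of planted genes in a
selected subset.

What the generator does **not** model: gene–gene correlation blocks,
heavy-tailed or multiplicative microarray noise, batch effects, and
class-conditional variance changes. Consequently, passing tests demonstrate
that the machinery is correct and that the pipeline finds strongly
predictive subsets under the generative model — not that selected genes on
real arrays are biologically meaningful.

## Identifiability of planted genes — a known limitation

The wrapper maximizes LOOCV accuracy, and at these sample sizes accuracy
does not identify the planted subset. With 60 samples and a 2-sd effect,
the filter pool's non-planted members are precisely the noise genes with
the largest apparent class separation (a selection bias), and subsets mixing
two or three planted genes with such noise genes routinely reach LOOCV
accuracy equal to or *higher* than the all-planted subset. Any correct
maximizer will then return one of many accuracy-equivalent subsets, most of
which are not the planted one. The acceptance script therefore reports both
the accuracy of the found subsets (high, stable) and their planted-gene
recovery (substantially lower and seed-dependent) — the gap is a property
of wrapper selection at small n, not of the optimizer. Users should treat
the selected subset as *a* maximally predictive panel, not *the* causal
gene set; stability selection across repeats is the pragmatic mitigation
and is exposed via the sweep's per-run subsets.

## Numerical choices

* Equal-frequency binning merges duplicate quantile edges; constant genes
  fall into a single bin (IG 0, MI 0).
* `+inf` filter sentinels sort first; they never propagate into arithmetic.
* Tiny negative information-gain round-off is clamped to 0.
* All tie-breaks — rankings, top-k decoding, mRMR steps — use ascending
  index; every advertised output is bit-reproducible from seeds.
* Clipping to `[0,1]` is the only constraint handling in the search.

## Scaled problem sizes

The bundled tests and `scripts/acceptance.py` run the full pipeline on
synthetic problems of 40–60 samples and 60–200 genes with pools of 12–20
genes and NRO populations of 6–30 over 4–15 generations. These sizes were
chosen so the planted structure is comfortably detectable by the filter
stage while whole-protocol runs stay interactive; the algorithms are
identical at full scale, only `NROConfig`/`SweepConfig` defaults change.
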