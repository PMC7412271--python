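# Methods

## Model

`mklselect` fits a binary SVM over a convex (ℓ1) or ℓp-normalized weighted
sum of per-source kernels. Given a dataset of N samples split into P
feature blocks x₁ᵐ … x_Nᵐ (m = 1…P) and labels y ∈ {−1,+1}ᴺ:

1. **Per-source local scaling.** Within each source's own feature space,
   σᵢᵐ = d(xᵢᵐ, x_(K)ᵐ), the Euclidean distance to the K-th nearest other
   sample. The locally-scaled Gaussian kernel is
   Kₘ(xᵢ,xⱼ) = exp(−‖xᵢᵐ−xⱼᵐ‖²/(2σᵢᵐσⱼᵐ)).
2. **Kernel fusion.** K_η = Σₘ ηₘKₘ with ‖η‖ₚ = 1, η ≥ 0. For p = 1 this is
   the simplex condition and the solution is sparse; p = 2 spreads weight.
3. **Alternating optimization.** Starting from uniform η (ℓp-normalized),
   repeat: (a) solve the soft-margin SVM dual on K_η (0 ≤ α ≤ C,
   Σαᵢyᵢ = 0) via libsvm's SMO with stopping tolerance τ; (b) set
   ‖wₘ‖² = ηₘ²·(α∘y)ᵀKₘ(α∘y) and update ηₘ ∝ ‖wₘ‖^(2/(p+1)), renormalized
   to the unit ℓp ball. Stop when the max-abs change in η ≤ `eta_tol`
   (1e−4) or after `max_outer_iters` (100); a final SVM solve makes
   (α, b) consistent with the converged η. This fixed point is the saddle
   of the joint problem: empirically (and by multiple-kernel-learning
   theory) the converged η minimizes, over the weight simplex, the per-η
   SVM dual optimum — the property the grid-search oracle test checks.

The trained η is the source-relevance vector. Weights below 1e−8 are
displayed as exactly 0.

## Prediction-stage bandwidths

Local scaling is defined only on training data, so test samples need σ
values. Three algorithms are provided (selected by `algorithm_id`):

1. **Full-training lookup** — σ(test) = distance to the K-th nearest
   training sample (1-indexed over the training set as-is; an exact
   duplicate of a training point contributes its zero distance, caught by
   the floor). Most faithful, but retains the whole training set.
2. **Nearest support vector** — σ(test) = the stored σ of the nearest SV
   (ties broken toward the lowest SV index). Retains only the SVs.
3. **Nearest-SV mean σ** — each non-SV training sample is attached to its
   nearest SV; each SV's mean σ averages its own σ with its attached
   samples'; test samples look up the mean σ of their nearest SV. Retains
   only the SVs while recycling the discarded samples' local statistics.

When every training sample is a support vector, algorithm 3's mean σ equals
the plain σ and algorithms 2 and 3 coincide. Under algorithm 1, a test
point coinciding with a training point inserts a zero distance at the front
of that point's neighbour list, so its K-th training neighbour at index K+1
reproduces the training σ (floored), and K = 1 returns the floor itself.
Nearest-SV distances are measured per source, consistent with each kernel
seeing only its own block.

## Numerical choices

- **Bandwidth floor** ε = 1e−12 on every σ keeps the kernel well-defined
  when duplicate samples give zero nearest-neighbour distances.
- **Indefiniteness.** The locally-scaled kernel is not guaranteed PSD. The
  combined training Gram is spectrally clipped (negative eigenvalues zeroed,
  with a logged warning) whenever its minimum eigenvalue falls below
  −1e−8·max(λ_max, 1); otherwise it passes through untouched. Prediction
  cross-Grams are used as computed.
- **Support-vector threshold** α > 1e−8; below that, α is numerical zero.
- **Tie rules.** Equal η ranks keep manifest order; nearest-SV ties go to
  the lowest index; a decision score of exactly 0 predicts +1; equal-accuracy
  subset sizes resolve to the smaller subset (sources and features alike).
- **Standardization** (pipeline, not model): per-feature z-score with
  training-set mean and population std, zero-variance columns mapped to 0,
  the identical transform applied to validation/test data. The method
  itself does not prescribe feature scaling; since Gaussian kernels are
  scale-sensitive, leakage-free z-scoring is this package's default
  pipeline choice.

## Tunable parameters

| parameter | meaning | default | notes |
|---|---|---|---|
| C | SVM regularization | 1.0 | PSO-searched in [1e−2, 1e3], log scale |
| p | η-penalty norm order | 1 | 1 (sparse) or 2 exposed in the CLI; update implemented for any p ≥ 1 |
| K | local-scaling neighbour index | 7 | integer, 1 ≤ K < N; PSO-searched in {1,…,min(20, N−1)} |
| τ | SMO stopping tolerance | 1e−3 | PSO-searched in [1e−6, 1e−1], log scale |
| algorithm_id | test-bandwidth strategy | 1 | see above |

PSO uses 40 particles, cognitive = social = 1.1931, inertia decreasing
linearly 1.1 → 0.1 over 60 iterations, velocity clamped to half the box
width per dimension; the objective is the mean geometric mean of
sensitivity and specificity over a stratified 10-fold cross-validation
(geo-mean is robust to class imbalance). The decreasing direction of the
inertia schedule is the common convention and is configurable. Objective
failures (e.g. K infeasible for a fold) score −∞.

## Source selection and baselines

Sources are ranked by descending η and eliminated least-relevant-first.
The default elimination mode (`reweight`) renormalizes the retained η onto
the model's ℓp ball and re-predicts with the stored α and b — prediction-
stage reduction with the already-trained global model; `retrain` refits the
full MKL per subset. Both are exposed because either protocol is defensible
for "best subset" reporting; neither is asserted to be canonical. The
minimal subset is the smallest size attaining the curve's maximum accuracy,
reported with the reduction rate 1 − n/P. Across repeated runs,
`aggregate_relevance` sums accuracy-weighted η vectors and rescales to
sum 100 — the scale is this package's own normalization.

The Fisher-score baseline ranks individual features by
FS(fᵢ) = Σⱼ nⱼ(μᵢⱼ−μᵢ)² / Σⱼ nⱼs²ᵢⱼ with *population* class variances
(the variance convention is pinned by a hand-computed test case); zero
within-class variance with class-separated means scores +∞ and ranks
first. Two protocols connect features to sources: a Fisher sweep over all
concatenated features followed by source survival (a source survives if it
keeps ≥ 1 feature at the best count), and MKL source selection followed by
a Fisher sweep restricted to the kept sources (sources fixed in stage 2).
The sweep evaluator is a single-kernel locally-scaled Gaussian SVM — the
P = 1 case of the same core — keeping the comparison inside one model
family; sweeps are evaluated on the held-out split.

## Synthetic data: what it does and does not emulate

The generator produces blocks with known relevance structure:
`informative_shift` (class-conditional mean ±δ/2 per feature, noise sd 1),
`informative_rings` (class −1 on an annulus of radius 1, class +1 at
radius 3, radial sd 0.25 — separable by the locally-scaled Gaussian kernel
but not by a linear one), and `noise` (class-independent standard normal).
The recovery fixture used throughout the tests is 2 informative (δ = 3,
5 features each) + 6 noise sources at n = 200 with an 80/20 stratified
split — sized so a single CPU runs the full 20-seed recovery check in
seconds. Class imbalance is supported (e.g. a 61/85 split).

These fixtures validate the machinery — weight sparsity, ranking, the
bandwidth algorithms, elimination — under known ground truth. They do not
imitate real EEG/MRI feature distributions: real sources are correlated
with one another, non-Gaussian and rarely cleanly informative-or-noise, so
passing recovery tests demonstrates correctness of the algorithm, not
expected field performance.

## Known limitations

- Binary classification only; one SVM base learner; Gaussian base kernels
  only, fused only as a weighted sum.
- The spectral clip changes the training kernel slightly whenever it fires;
  prediction kernels are not clipped, a deliberate asymmetry.
- ℓ1 fits can oscillate near sparse solutions; the η-tolerance/iteration
  cap always terminates, but non-converged fits are flagged in `summary()`.
- Alignment of samples across sources is by row order; there is no
  ID-based joining.
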