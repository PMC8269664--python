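# Methods

This note records the models, conventions and numerical choices behind
`homnet`, in the order the pipeline runs.

## Dynamic FC and the windowing convention

Windowed connectivity uses plain (sample) Pearson correlation per segment —
no Fisher z-transform and no tapering anywhere in the pipeline. The segment
count is K = ⌊(M−W)/s⌋ + 1: a trailing partial segment is discarded rather
than shortened, so every window estimates correlation from the same number of
samples (a partial window would silently change W). Segments are 0-based
half-open ranges [k·s, k·s+W) internally; reports use 1-based indices.

A region that is constant within a segment has undefined correlations there.
These entries are set to 0 with a warning, and the unit diagonal is kept. The
alternative — propagating NaN — would poison every downstream moment; a zero
is neutral for the moment features and the event remains visible in logs.
Validation of constant columns is deliberately *not* done at load time: a
column can be constant in one window and informative in another, so the check
belongs where the failure occurs.

## Central-moment networks

CM(d) uses population moments (normalisation 1/K, not 1/(K−1)), with the mean
substituted at d = 1 because the first central moment is identically zero.
The d-th root is applied as sign(S)·|S|^{1/d}: odd-order moments keep their
skew sign and stay real for negative radicands. The alternative (absolute
root) would discard the direction of asymmetry, which is exactly what the
odd orders are there to measure.

Diagonals are set exactly: 1 for CM(1) (the self-correlation series is the
constant 1) and 0 for CM(d≥2). An edge series that is exactly constant gets
moment exactly 0, short-circuiting the floating-point cancellation that would
otherwise leave an eps-sized residue which the d-th root amplifies.

**Canonical ordering.** The scientific point of CM(d) is insensitivity to the
chronological order of the windows. Naive reductions only deliver that up to
rounding, because floating-point summation depends on operand order. Every
moment (and RMS) reduction therefore sorts the edge series first: the
computation becomes canonical in the window order, and permutation invariance
holds *bitwise*. The cost is one O(K log K) sort per edge.

## High-order networks

Ho(d) is the row-wise Pearson correlation of CM(d). By default the full
R-entry rows participate, including the diagonal entries. For d ≥ 2 the
diagonal is a constant 0 shared by every row, which slightly inflates
positive correlations; `build_hofcn(..., include_diagonal=False)` instead
drops columns i and j from both rows before correlating the pair. Both paths
are tested; the inclusive default matches the row-profile definition used
throughout (m_i(d) = (m_i1, …, m_iR)). Zero-variance rows correlate as 0 with
a warning, mirroring the low-order convention. Ho requires R ≥ 3 (correlation
of length-R rows needs variance).

## Feature extraction and selection

Networks are vectorized to the strict lower triangle — R(R−1)/2 features in a
fixed column-major edge order ((2,1), (3,1), …, (3,2), … in 1-based terms) so
the feature↔edge bijection is identical across subjects and network types.
For R = 116 that is 6670 features.

Selection is a two-stage funnel fitted on training folds only:

1. **t-test filter**: two-sided two-sample t-test per feature; keep p <
   p_threshold. Zero-variance features are excluded with a warning. If the
   filter empties, the single smallest-p feature is kept so downstream stages
   always have input.
2. **LASSO**: min ½‖I − Ŷω‖² + λ‖ω‖₁ on column-standardized features
   (z-scored with training-fold statistics — L1 penalties are
   scale-sensitive), no intercept, labels ±1. Solved by scikit-learn
   coordinate descent with α = λ/L; an independent LARS solver serves as the
   oracle in tests. Support = |ω| > 1e−8. λ is parameterised as a fraction of
   λ_max = max|X^T y| (the smallest λ with an empty solution), computed per
   training fold. If LASSO empties the support, the t-test set is used
   unchanged.

The classifier is a linear-kernel soft-margin SVM (cost C).

## Cross-validation

Evaluation is repetitions × stratified 5-fold CV. Within each outer training
fold, an inner stratified 5-fold CV scores every (p_threshold, λ-fraction, C)
combination by mean validation accuracy; ties break toward smaller
p_threshold, larger λ, then smaller C — the more parsimonious model. Default
grids: p_threshold ∈ {0.01, 0.05, 0.1}; λ on a 10-point log grid from
0.01·λ_max to λ_max; C ∈ {0.1, 1, 10}. The outer test fold is touched exactly
once; a test verifies that corrupting test-fold labels changes neither the
tuned hyperparameters nor the selected features nor the predictions.

All randomness derives from one master seed via NumPy `SeedSequence`
(per-repetition partition seeds, per-fold inner-CV seeds), making results
bit-reproducible. Aggregate metrics (ACC, TPR, TNR, F1, as percentages) are
the mean over all outer folds of all repetitions; a metric with a zero
denominator in some fold is NaN there and excluded from the mean with a
warning. Per-feature selection frequency is the fraction of outer folds in
which the feature survived both stages (with 10 repetitions the denominator
is 50).

## Majority voting

A strategy combines T per-network classifiers by majority vote: a label needs
strictly more than T/2 votes. With odd T and binary labels a majority always
exists; for even panels a tie is formally a rejection and is resolved by the
vote of a designated fallback member — by default the member with the highest
mean inner-CV accuracy. Combining requires aligned out-of-fold predictions,
i.e. every member evaluated under the same master seed; this is checked and a
mismatch is an error. Strategy metrics are aggregated per outer fold exactly
like a single learner's, so a one-member strategy reproduces that member's
result identically.

## Synthetic cohorts

The generator emulates the post-parcellation stage of a resting-state study:
correlated Gaussian region signals whose pairwise target correlation is
piecewise-constant over blocks, centred on a deterministic community-
structured base coupling (4 contiguous communities; within 0.35, between
0.05). Per block, the coupling of each edge is perturbed by volatility·ε with
ε standard normal (or standardized skew-normal when a group skew shift is
set); the perturbed matrix is projected to the nearest usable correlation
matrix (eigenvalue clipping at 1e−6, diagonal renormalisation) before
Cholesky sampling, and i.i.d. observation noise is added. Requested
correlations outside (−0.99, 0.99) are clipped with a warning.

Defaults — the generator's study conditions — are 30 subjects per group, 20
regions, 170 time points (a 6-minute scan at TR = 2 s after discarding
equilibration volumes), block length 30 matching the default window length,
observation noise sd 0.25, and a variance-level effect of 0.3 (patients) vs
0.05 (controls) on the 10 edges among the first five regions, against a
background volatility of 0.05 on all other edges in both groups. The affected
edges deliberately share regions: the moment profiles of those five rows then
shift coherently, which is what gives the *high-order* networks something to
detect. `SyntheticCohortSpec.null()` equalises the groups for calibration
runs.

Blocks rather than a continuous Ornstein–Uhlenbeck modulation keep effect
sizes analytically controllable and map directly onto the sliding window;
signals are Gaussian with no hemodynamic convolution, since the pipeline
consumes only second-order structure. Consequently, passing tests demonstrate
that the machinery recovers moment-level group structure from data shaped
like parcellated BOLD — they say nothing about autocorrelated noise,
motion or site effects in real cohorts, nor about any particular clinical
population. Each subject draws from an independent RNG stream keyed by
(seed, group, subject index), so cohorts are reproducible and independent of
generation order.

## Problem sizes in tests and the acceptance script

Unit and property tests run on small instances (R ≤ 6, M ≤ 50) where
brute-force oracles are exact and cheap. End-to-end checks use cohorts of
20–30 subjects per group at R = 20 with 3 CV repetitions — large enough for
the stochastic assertions (binomial and rank tests at α = 0.01, a 99%
Monte-Carlo band for null calibration) while keeping a full run of suite plus
acceptance script around two minutes. Because out-of-fold predictions for the
same subject are correlated across repetitions, the null band uses n = the
number of unique subjects, and the effect-recovery binomial test uses a
single repetition's predictions.

Oracle-agreement checks draw instances with K ≥ 3 windows: at K = 2 every odd
central moment is exactly zero, and the d-th root inflates the oracle's
eps-level rounding noise to ~1e−7, which says nothing about either
implementation.

## Known limitations

* The printed feature dimensionality of a symmetric R×R network is taken as
  R(R−1)/2 (the strict lower triangle); reports index regions 1-based.
* Confidence in stochastic tests is bought with fixed seeds; different seeds
  move the reported accuracies by a few points (the acceptance script exposes
  this via `--seed`).
* The t-test threshold is tuned by default; a fixed threshold can be
  requested by passing a single-value grid.
* Voting is classifier-level only; feature-level fusion, weighted voting and
  nonlinear kernels are out of scope.
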