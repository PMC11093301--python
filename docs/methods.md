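# Methods

This note documents the models, numerical choices and limitations of
`fchybrid` in the order the pipeline runs. Nothing here states an empirical
result that the test suite or `scripts/acceptance.py` does not itself compute.

## Inputs and assumptions

The pipeline consumes per-subject ROI time-series matrices (rows = time
points, columns = regions) that are assumed already band-pass filtered to
0.01–0.08 Hz and atlas-extracted, plus a phenotype table with a binary
diagnosis (ASD = 1, TC = 0) and the five SRS subscale scores (awareness,
cognition, communication, motivation, mannerisms). The SRS scaling convention
(raw vs T-scores) is deliberately left open: the reader accepts any finite
reals, and the per-fold z-scoring downstream removes the scale anyway.
Sampling interval (TR) is a configuration parameter, default 2 s. Scans may
have different lengths T across subjects; every per-subject representation
the classifier sees (R×R and R×R×Q) is T-independent by construction.

## Static functional connectivity

Pearson correlation per ROI pair over the full scan. The matrix is
symmetrized against floating asymmetry, the diagonal forced to exactly 1, and
zero-variance columns rejected (detected as max = min rather than
variance = 0, which is vulnerable to floating residue). Correctness is tested
against a from-scratch formula evaluation at 1e-12 on random draws.

## Wavelet-coherence dynamic functional connectivity

**Frequency grid.** The analysis band [0.01, 0.08] Hz is partitioned into
Q = 40 contiguous segments, linearly spaced by default (a log option exists;
neither spacing is claimed to be canonical, and the choice is recorded in the
config). Segment centers map to Morlet scales through f = ω₀ / (2π s TR)
with ω₀ = 6 — the standard admissible choice balancing time and frequency
resolution; the parameter is configurable.

**CWT.** The continuous wavelet transform uses the analytic Morlet evaluated
in the frequency domain: the signal's FFT (zero-padded to the next power of
two to curb wraparound) is multiplied per scale by
√(2πs)·π^(−1/4)·exp(−(sω−ω₀)²/2) on positive frequencies. Linearity and the
zero-input case are tested exactly; scale-to-frequency mapping is validated
on pure sinusoids and cross-checked row-by-row against an independent CWT
implementation (PyWavelets' complex Morlet) at matched scale conventions.

**Smoothing.** Wavelet coherence requires smoothing — without it the ratio
|W_x W_y*|² / (|W_x|²|W_y|²) is identically 1 for *any* pair, a degeneracy the
test suite asserts as a regression guard on operator placement. The smoother
is a separable moving average: per scale row, a boxcar in time whose length
grows with the scale (max(3, round(factor·s)) samples, factor default 1.0,
forced odd, reflective edges), followed by a 3-bin boxcar across scales. The
window sizes are declared package defaults, not canonical values. The
operator is linear, preserves constants exactly, and — being a convex
average — keeps the Cauchy–Schwarz bound, so coherence stays in [0, 1]
without correction (values are clipped only against ≤1e-9 floating error, and
larger excursions raise an error instead of being hidden).

No cone-of-influence masking is applied; edge effects are accepted and a
warning is emitted when the series is shorter than twice the largest wavelet
support.

**PCA over time.** Each Q×T coherence map is reduced along the time axis:
subtract each scale row's time mean, eigendecompose (1/T)·ŴC·ŴCᵀ, find the
minimal k whose cumulative eigenvalue fraction reaches the threshold (default
0.99), and return the leading component scores u_i·σ_i (the columns of U_k Σ_k
from the demeaned map's SVD). Eigenvector signs are fixed by requiring a
nonnegative entry sum (ties: first nonzero entry positive) so that CNN inputs
are reproducible. Only the *first* component populates the R×R×Q tensor even
when k > 1; pairs needing more components are collected into a single warning
rather than failing, keeping the tensor shape fixed. On band-limited noise
cohorts k is typically ≫ 1 — the warning fires routinely and the retained
fraction for the stored component is recorded per pair. The diagonal is zero:
a self-coherence map is constant 1 and demeans to nothing. The implementation
is tested against an independent SVD oracle at 1e-8.

Note the demeaning has a methodological consequence: the *mean* coherence
level per band is removed, so the dynamic tensor encodes the band profile of
coherence *fluctuation*, not of average coupling. A persistently coupled pair
therefore shows up as a stability (low-fluctuation) signature in its coupled
band rather than a large tensor value.

## CNN feature extraction

Both branches are implemented in NumPy with explicit forward and backward
passes (the kernels span whole rows/columns, so every convolution reduces to
a dense contraction; a loop-based oracle in the tests guards the vectorized
code, and analytic gradients are verified against central differences).

* Static branch: (1, R, R) → 32 filters @ 1×R → (32, R) → 64 filters @ R×1 →
  (64,) → 16 filters @ 1×1 → (16,), each convolution followed by batch norm
  (momentum 0.1, ε = 1e-5, running statistics used at inference) and
  LeakyReLU(α = 0.01); valid padding, stride 1, biases on.
* Dynamic branch: (Q, R, R) is first compressed by a single 1×1 filter over
  the Q channels, then runs the same stack.
* After flatten: dropout 0.5, then the attention block (dense 16→8, ReLU,
  dense 8→16, sigmoid); the extracted feature vector is the sigmoid gate
  times the 16 activations. The 16→2 softmax head is trained with Adam
  (lr 10⁻⁴, cross-entropy, ≤ 50 epochs) purely to fit parameters; per-subject
  features are read out in inference mode, which is deterministic.

Two training-regime choices are the package's own, since they are not fixed
by the published recipe:

* **Batch size 8.** At desk scale (≈100–200 training subjects) a batch of 32
  yields only ~5 optimizer updates per epoch and the dynamic head visibly
  undertrains within the fixed 50-epoch budget; batch 8 restores roughly the
  update count per epoch that the original cohort size implies (~20–25) and
  gives converged heads on every seed tried.
* **Small initialization of the interpretable kernel banks.** The Q
  compression weights and the 32×R first row-convolution initialize at one
  tenth of the usual fan-in-scaled uniform bound (all other layers are
  standard). These two banks are read back as band/region importance, and at
  this learning rate and epoch budget total Adam movement is comparable to a
  full-scale random init, which would otherwise dominate the |weight|
  rankings. Adam's step size is invariant to init scale and batch norm
  renormalizes the forward pass, so optimization is unaffected.

## Fusion, cross-validation and metrics

Features are fused in fixed order — SRS (0:5), static-deep (5:21),
dynamic-deep (21:37) — z-scored per column with training-fold statistics
(SRS scores would otherwise dwarf the deep features on a linear kernel), and
classified by a linear-kernel SVM (C = 1 default). Cross-validation is
stratified k-fold (k = 10), seeded, with both CNN branches retrained inside
each fold; the leakage contract (validation labels can never influence any
fitted parameter) is asserted bitwise in the tests. Mean metrics are
arithmetic means over folds, and the fold with the highest validation
accuracy (ties → lowest fold index) is kept as the deployable model.

Reported metrics are accuracy, sensitivity, specificity, FPR, FNR, precision
and F1 from the confusion counts with ASD as the positive class; a metric
with a zero denominator is reported as NaN, never as 0. Reference classifiers
(linear SVM, MLP with hidden layers 64 and 16, random forest with 100 trees,
logistic regression thresholded at 0.5 with ties positive) run on the same
fused features for comparison. Subgroup reports recompute metrics within sex,
site, or decade age bins.

## Interpretation

Region importance: column-wise sum of absolute kernel weights over the 32
filters of the first row-spanning convolution (bias excluded); dynamic-branch
rankings use the convolution after channel compression. Ties break toward
the lower index. Band importance: |w_q| of the compression weights, reported
with the grid's Hz edges. Block-level Shapley values enumerate all 2³
coalitions of the three feature blocks exactly on the SVM decision value
(a real-valued f; hard labels would degenerate), replacing absent blocks with
the training-set feature means — the single imputation convention used
everywhere. Efficiency, dummy and symmetry hold exactly; for a linear
decision function the values match the closed form Σ w_j (x_j − baseline_j)
per block at 1e-10.

## Synthetic cohort generator

Each ROI signal is unit-variance Gaussian noise brick-wall filtered to the
analysis band. A planted pair additionally shares a unit-variance latent
confined to the planted sub-band, mixed with weight β where
β² = c/(1−c) · W_sub/W_full maps the target in-band coherence c to the
flat-spectrum construction analytically. SRS subscales are drawn from
group-specific normals on a T-score-like scale (TC mean 50, SD 10) separated
by a configurable standardized effect. Per-subject RNG streams spawn from one
master seed.

Default study conditions (also the acceptance-script conditions): R = 20
ROIs, T = 150 points at TR = 2 s, 100 subjects per group, one planted pair
(2, 7) with coherence targets 0.9 (ASD) vs 0.1 (TC) in 0.04–0.05 Hz, SRS
effect 1.0 SD per subscale. The ten region/band-recovery replicates use 50
subjects per group so that a full recovery study stays within minutes on one
core; classification and permutation-null runs use the full 100 per group.

What the generator does *not* emulate: hemodynamic response shape, scanner
and site effects, head motion, autocorrelated physiological noise,
non-stationary coupling. Passing tests therefore demonstrate that the
pipeline recovers planted statistical structure of the stated kind, not that
it reproduces clinical classification accuracy on real data.

Two properties of the construction matter when reading recovery results.
First, the Morlet spectral tails leak the planted latent into neighbouring
and even distant coherence rows, so high-frequency bands carry genuine group
contrast too; second, the PCA time-demeaning converts the planted-band mean
contrast into a subtler stability contrast (see above). Both effects make the
*band* ranking the noisiest of the three interpretability readouts — region
recovery is robust across seeds, band recovery is marginal (roughly 6–8 of
10 independent cohorts place a planted band in the top 5 of 40, depending on
the master seed), and the acceptance script simply reports the measured rate.

## Known limitations

* Only the first principal component of each coherence map is kept even when
  the variance threshold demands more; the loss is logged, not fatal.
* No cone-of-influence handling; short scans inflate edge coherence.
* The smoother's window sizes and the band spacing are declared defaults; no
  claim is made that they match any particular published analysis.
* The auxiliary heads are trained without early stopping or validation
  monitoring (fixed 50-epoch budget), so head training accuracy is a
  convergence diagnostic, not a performance estimate.
* Shapley values are computed at the block level (3 players) only; per-feature
  attribution within a block is out of scope.
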