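# Methods

This note documents the models, algorithms, and numerical choices in
`stclust`, what the synthetic-data generators do and do not emulate,
and the design decisions taken where more than one reasonable option
existed.

## Response model

A neuron's expected spike count in stimulus bin t is

    lambda_t = g( G_t ),    G_t = sum_n w_n exp(K_n · X_t),

with `X_t` a D-pixel stimulus frame, `K_n` (n = 1..N) spatial subunit
filters, `w_n >= 0` subunit weights, and output nonlinearity
`g(x) = x^a / (1 + b x)` with `a > 0`, `b >= 0`.  Spike counts are
conditionally Poisson.  Rates are expected counts *per bin*; the bin
width (default 1/120 s) is absorbed into the weights, so no separate
dt factor appears anywhere.  The exponential subunit nonlinearity is a
modeling choice that buys closed-form updates (below); the saturating
`g` absorbs global response compression and is near-identity after
fitting in practice.  The printed form of `g` admits two readings; we
use `x^a/(1+bx)`, under which `a=1, b=0` is exactly the identity and
both special cases used in testing (pure exponent, pure saturation)
are nested.

The Poisson negative log-likelihood is reported per bin with the
data-only `log(Y_t!)` constant dropped: values are comparable across
models on the same data, not across datasets.

## The clustering estimator

For standardized Gaussian-like stimuli, `E[G] = sum_n w_n
exp(|K_n|^2/2)` (Gaussian moment generating function), so replacing
the rate term of the likelihood by its stimulus expectation gives an
objective that touches the data only through bins with spikes:

    F(K, w) = sum_n w_n e^{|K_n|^2/2} - (1/T) sum_{t: Y_t>0} Y_t log G_t.

Each iteration minimizes a convex upper bound of F that is tight at
the current parameters (the log of a sum is linearized through the
responsibilities `alpha_{t,n}`), yielding the three closed-form
updates: softmax responsibilities, responsibility-weighted centroids,
and `w_n = (sum_t Y_t alpha_{t,n}/T) e^{-|K_n|^2/2}`.  This is a
majorize–minimize scheme, so F never increases; the fit trace records
F per iteration and the package treats a rise beyond 1e-8 (relative)
as a defect.  The weight update's normalization by the total bin count
T is required for the fixed-point identity below; spike bins with
`Y_t > 1` enter with multiplicity `Y_t` throughout.

At any unregularized fixed point the strength-weighted filter sum
reproduces the spike-triggered average:
`sum_n (w_n e^{|K_n|^2/2}) K_n ∝ sum_t Y_t X_t`, and the strengths sum
to the mean spike count per bin.  Both identities are asserted in the
tests; proximal regularization breaks the algebra and the residual is
then only reported.

Numerical details:

- Softmax responsibilities use max subtraction; `log G` uses
  logsumexp.  Zero-weight subunits receive zero responsibility.
- Initialization: `K_n` = STA direction plus i.i.d. Gaussian noise with
  sd `0.1 |STA| / sqrt(D)`; `w_n` = mean rate / N.  A purely random
  init is available.
- Convergence: relative change of the surrogate below 1e-6, or 100
  iterations (fits typically converge in tens of steps).
- A subunit whose responsibility mass underflows is reinitialized from
  a random spike-triggered frame and the event is logged in the trace.
- Returned banks are sorted by descending strength.

### Stage 2: output nonlinearity

With filter directions fixed, per-subunit weight scales and (a, b) are
fit by full Poisson maximum likelihood (L-BFGS on `log` scales, `log a`,
softplus-parameterized b; three seeded starts, best kept).  The
softplus start is b ≈ 0.05: starting it much lower flattens the
gradient and the optimizer cannot leave the init.  Model selection
does *not* refit g by default (see below).

## Regularization

Priors enter as proximal operators applied to each centroid after the
filter update.  L1 uses the soft-thresholding operator.  The locally
normalized L1,

    L(k) = sum_i |k_i| / (eps + sum_{j in nbr(i)} |k_j|),   eps = 0.01,

penalizes a pixel only when its spatial neighbors are weak.  Its
proximal step is a weighted soft threshold with per-pixel threshold
`a_i lambda`, where the weights `a_i = 1/(eps + sum_nbr |k_j|)` are
evaluated at the majorization expansion point — the *pre-update*
filter from the previous iteration (one Taylor step per clustering
iteration).  Isolated pixels face thresholds up to `lambda/eps` and
are suppressed; pixels inside a contiguous region are barely shrunk.
Neighborhoods are 4-connected grid adjacency (8-connectivity is a
config option; the pixel itself is excluded).  Because the
normalization amplifies thresholds, useful LNL1 lambdas are roughly an
order of magnitude smaller than L1 ones at the same filter scale.

Regularization is applied per subunit independently (the surrogate is
separable across subunits).  With a proximal step the monotonicity
guarantee is no longer exact; in practice traces remain monotone and
the tests assert it only for unregularized fits.

## Hierarchical estimation

The flat estimator applied at increasing N partitions the receptive
field: each additional subunit typically splits one existing subunit.
`fit_path` builds this in: starting from the N = 1 (STA) fit, every
subunit is tentatively split into two children (`K_m ± noise`, weights
exactly `w_m/2`, i.e. `e^{b} = e^{b_m}/2` with `b = log w`), the
children are refined under the factorized assignment
`alpha_child = alpha_parent · sigma_t` (a two-way softmax between the
children; mass is conserved to the last bit by computing the second
child as the remainder), and the split with the largest decrease of
the approximate negative log-likelihood is kept.  Non-descendant
subunits are frozen during child refinement, which makes greedy
evaluation cheap; `refine="joint"` additionally refits the whole bank
after each accepted split.  Split noise defaults to
`0.05 |K_m| / sqrt(D)`.  Child refinement runs up to 300 iterations at
tolerance 1e-8: the children start nearly identical and the symmetry
breaking amplifies slowly, so a short budget can let the split
collapse back onto the parent.

## Population model

Several cells share one filter bank; cell c has weights `w_{n,c} >= 0`
(zero = not connected) and its own g.  The clustering loop pools the
filter update over cells (`K_n` from the responsibility-weighted sum of
all cells' spike-triggered frames, optionally through a prox — LNL1 by
default for retinal data) while responsibilities and weights stay per
cell; the per-cell weight update includes the spike counts `Y_{t,c}`,
matching the single-cell derivation.  Single-cell fitting is literally
the one-cell case of the same loop, so the reduction is bit-exact.
Stage 2 runs per cell.  Connectivity emerges from the weight update;
`weak_subunits` marks subunits below 1% of a cell's total strength for
display only.  `best_separate_combination` allocates a total subunit
budget across separately fitted cells by exact dynamic programming over
validation log-likelihood tables.

## Preprocessing

The STA is computed over 15 lag bins (125 ms at 120 Hz) with
zero-padded early frames.  The receptive field mask thresholds the
rank-1 (SVD) spatial factor of the STA at 2.5 sigma, with sigma the
median absolute deviation over all pixels scaled by 1.4826 — the SVD
factor pools SNR coherently across lags, which matters at realistic
recording lengths.  The mask is the largest 4-connected component; the
analysis window is its bounding box plus a one-pixel border.  The
common time course is the sign-aligned average of significant pixels'
lag traces (each multiplied by the sign of its peak, so ON- and
OFF-dominated pixels reinforce), unit-normalized.  The raw movie is
causally filtered with this time course and each pixel standardized to
zero mean, unit variance — per-pixel standardization only; no
cross-pixel whitening, since binary white noise is pixelwise
independent.  For null stimuli the receptive field is the rank-1
spatial factor restricted to significant pixels.

## Null stimuli

Spatial nulling projects each frame onto the null space of the RF
matrix A (columns = vectorized RFs):
`S_n = (I − A(AᵀA)⁻¹Aᵀ) S_w`, the closest orthogonal stimulus in l2.
Spatio-temporal nulling transforms each pixel's time series to the
temporal frequency domain, where the convolution constraints decouple;
at each frequency the complex spatial vector is projected onto the
null space of the filters' transforms (rank-deficient systems handled
by least squares; frequencies where a filter's transform is
numerically zero impose no constraint).  Conjugate symmetry is
preserved, so the output is real; the temporal boundary is circular —
all discrete frequencies are nulled, which subsumes the continuous
argument that a finite-support time course has full spectral support.
For space-time separable filters the two constructions coincide to
numerical precision.

Display constraints are enforced by Dykstra-corrected cyclic
projections onto three sets: the null space, the pixel box
[−0.5, 0.5], and the per-pixel temporal variance sphere (the
mean-removed time series rescaled to the target norm — variance is
enforced about each pixel's mean).  The variance set is a sphere, not
a convex set, so Dykstra's convergence theory does not formally cover
it; convergence is monitored and per-constraint residuals are
reported, and in practice the iteration converges in tens of cycles at
48% input contrast (full-contrast noise leaves no feasible slack,
which is why the default input contrast is 48%).  A final exact null
projection and clip make the reported orthogonality residual
machine-level whenever the box is inactive.  Movies are discretized to
8 bits with round-half-even; quantization re-introduces a small
orthogonality residual that is reported, never assumed away.

## Simulators

**Model RGC (`rgc_cell`).**  Two-layer cascade: 64 cones on a
hexagonal lattice (nearest-neighbor spacing 5 grid units, rows offset,
lattice rotated 60° to the stimulus grid, i.i.d. Gaussian positional
jitter sd 0.35 g.u.); each cone pools the stimulus with a separable
filter — Gaussian spatial profile (sd 1 g.u., integrated over pixel
areas) and a shared biphasic temporal kernel (difference of gamma
bumps, peak ~50 ms, undershoot ~80 ms, unit norm, 15 taps at 120 Hz).
Cones are partitioned into 12 bipolar subunits by k-means on their
positions; each bipolar exponentiates its summed cone drive; the cell's
rate is a positively weighted sum of bipolar outputs (weights ~
Normal(1, 0.1), truncated positive) followed by Poisson spiking.  Two
gains close the model: the bipolar input gain is set analytically so
bipolar log-drives have unit variance under the default 48% binary
noise (the exponent scaling is otherwise unidentified), and a global
output gain is calibrated on an internal one-minute white-noise run to
a mean rate of 19 spikes/s.  The default stimulus grid is 12×12 pixels
of 6 g.u., so the receptive field spans ~6×6 pixels with a majority of
background pixels left for robust noise estimation.  Exported ground
truth: each bipolar's cone-pooling map projected onto stimulus pixels.

What the simulator does *not* emulate: photoreceptor adaptation and
cone noise, natural-image statistics, recording artifacts, spike
history. Passing tests therefore demonstrate correctness of the
estimator under the model's own assumptions (Poisson spiking,
separable subunits, Gaussianized stimuli), not robustness to every
property of real recordings.  One quantitative difference from fits to
real data matters for interpreting the regularization comparison: the
simulated cell's per-pixel filter values are ~0.1–0.3, whereas fits to
recorded cells put typical nonzero pixels at order unity.  In this
lower per-pixel SNR regime the locally normalized threshold cannot
discriminate receptive-field from background pixels (neighbor sums are
noise-dominated everywhere), and uniform L1 shrinkage is the stronger
variance reducer: on 3-minute simulated recordings both priors improve
held-out likelihood substantially, with L1 slightly ahead of LNL1 —
the opposite ordering from fits to recorded cells, where LNL1's
advantage was demonstrated.

**Toy cells (`toy_cell`).**  Explicit LNLN cells with known filters:
unit-norm filters at distinct angles in 2-D, or unit-norm Gaussian
bumps at well-separated centers on a pixel grid (3 or 5 subunits,
equal weights, identity or saturating g), with the gain set in closed
form (or calibrated numerically for saturating g) to a target mean
rate of 0.12 spikes/bin.  These drive all recovery, selection,
hierarchy, and population tests.

## Evaluation and selection

Partitioning: the last 10% of bins is a contiguous test segment; the
remainder splits 90/10 into training and validation at random.  Model
selection averages validation log-likelihood over repeated fits with
fresh splits and initializations; the same splits and seeds are shared
across all (N, lambda) grid cells, so comparisons are paired — without
this common-random-numbers design, split-to-split variance (~5e-3/bin)
swamps the model-order signal (~1e-3/bin) and selection is
noise-driven.  Validation likelihood is computed for the
clustering-stage model (identity g), which the fitted g closely
approximates; stage-2 refitting per grid cell is available but off by
default.

PSTHs are trial means smoothed with a Gaussian kernel (sd 16.67 ms,
truncated at 4 sigma) by normalized convolution, so edge bins are
renormalized and kernel mass is conserved.  Prediction accuracy is the
Pearson correlation between the recorded PSTH and the PSTH of freshly
simulated Poisson trials matching the recorded repeat count.  Response
structure is the variance of the PSTH over time.

Subunit geometry: 2-D Gaussians are fit to max-normalized subunit
images by Levenberg–Marquardt least squares (moment-based init,
Cholesky-parameterized precision, flat images flagged); compactness is
tested against a null in which pixel values are permuted across the
subunits of a cell; tiling is quantified by nearest-neighbor center
distances normalized by the geometric mean of the two Gaussians' SDs
along the center-joining line.  The sharing fraction counts cross-cell
nearest-neighbor subunit pairs closer than one such SD.

## Validation studies (`stclust.validation`)

Problem sizes were chosen to exercise each property at desk scale:
monotonicity over 20 random fits (toy and RGC data, up to 40
iterations each); recovery and selection on the 3-subunit toy at
2×10⁵ frames over 10 runs (selection grid N = 1..6, 3 repeats);
the regularization comparison on the default simulator with 3-minute
training segments of 24-minute recordings, N = 12, lambda grids
l1 {0, 0.01, 0.02, 0.05, 0.1, 0.2} and lnl1 {0, 0.02, 0.05, 0.1, 0.3,
0.6}, 10 seeds; population parsimony with two 3-subunit cells sharing
one of five filters at 2×10⁴ frames (the limited-data regime in which
sharing matters), 10 seeds; hierarchy against flat fits at 6×10⁴
frames; null-stimulus contracts on a 6×6 grid at 48% contrast; and
calibration on a fresh 5-minute draw.  `scripts/acceptance.py` runs
all of them from a single seed.

## Known limitations

- Retinal fitting assumes space-time separable subunits with a common
  time course; full spatio-temporal filters are supported only through
  stimuli whose columns encode space×time (as for cortical flickering-
  bar data).
- The LNL1-versus-L1 ordering depends on the per-pixel SNR regime (see
  above); on the bundled simulator L1 wins slightly.
- Greedy subunit matching and greedy hierarchical splitting are not
  globally optimal; the tests document a case where greedy matching
  differs from the exhaustive assignment.
- The variance constraint in null-stimulus construction is non-convex;
  convergence is empirical, with residuals reported.
- The estimator's expected-rate approximation assumes standardized,
  approximately Gaussian stimuli; heavy-tailed or strongly correlated
  stimuli (e.g. natural images) violate it, and subunits should then be
  estimated from white noise with only scales and g refit on the other
  stimulus.
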