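# Methods

This note records the models implemented in `stgf`, the parameters that
matter, and the design decisions taken where the design was genuinely
open. Nothing here states an empirical result that the test suite or
`scripts/acceptance.py` does not itself compute.

## Simulation model

**Phantom.** A parametric head phantom on an odd-sided square grid
(default 111×111): an elliptical brain outline (semi-axes 0.44/0.48 of the
side), a gray-matter shell, a white-matter core (inner ellipse at 0.72 of
the outer axes) and a square lesion (default 5×5) centered on the middle
pixel. It is a look-alike of an anatomical atlas built from analytic
shapes so that no external data is needed; the label map is replaceable
wholesale, and nothing downstream depends on how it was produced.

**Kinetics.** Regional time-activity curves come from the two-tissue
(three-compartment) model

    dC1/dt = K1·Cp − (k2+k3)·C1 + k4·C2
    dC2/dt = k3·C1 − k4·C2,     TAC = (1−vb)(C1+C2) + vb·Cp

driven by a Feng-style tri-exponential plasma input
`Cp(t) = (A1·t − A2 − A3)e^(−λ1 t) + A2 e^(−λ2 t) + A3 e^(−λ3 t)` with the
conventional parameter set (A = 851.12, 21.88, 20.81; λ = 4.134, 0.01043,
0.1191 min⁻¹). The default regional rate constants are an
implementer-chosen FDG-like set (min⁻¹):

| region     | K1    | k2    | k3    | k4     |
|------------|-------|-------|-------|--------|
| background | 0.020 | 0.200 | 0.010 | 0.010  |
| gray       | 0.102 | 0.130 | 0.062 | 0.0068 |
| white      | 0.054 | 0.109 | 0.045 | 0.0058 |
| lesion     | 0.150 | 0.120 | 0.080 | 0.0050 |

chosen so the lesion has the largest net influx and the background is
nearly cold. Absolute simulated activities are therefore arbitrary units;
all reported errors are normalized or relative quantities. The ODE system
is integrated with LSODA at rtol 1e-8; the one-tissue closed form
(analytic convolution) serves as the test oracle.

**Acquisition.** The 24-frame schedule is 4×20 s, 4×40 s, 4×60 s, 4×180 s,
8×300 s (3600 s total). Frame values are interval *averages* of the TAC
(consistent with count integration), and frame count sinograms are
`duration × (H·activity)`, so early short frames are count-starved exactly
as in a real dynamic scan. Noise enters in two exact stages: (1) a
background of randoms+scatter, uniform across bins within each frame and
apportioned across frames proportionally to each frame's true counts, with
Σr = 0.20·Σtrues; (2) a global rescale so the total expectation is 8×10⁶
counts, followed by one Poisson draw per bin. Twenty independent
realizations (five in the reduced profile) share one expectation; all
randomness flows through sub-seeds spawned deterministically from one
master seed. The simulator models no positron range, detector blur,
attenuation, decay or dead time — passing tests therefore validate the
filtering mechanism itself, not robustness to those physical confounders,
and say nothing about scanner data with uncorrected physics.

## Projector and MLEM

`H` is an explicit sparse matrix of Siddon-style exact intersection
lengths between rays and pixels (default geometry: angles = radial bins =
image side, unit ray spacing, angles uniform on [0, π)). Backprojection is
the literal transpose, so the adjoint identity holds to machine precision
and MLEM's convergence theory applies unchanged. MLEM uses the standard
multiplicative update with an additive background term, denominators
clamped at 1e-12, initialized to 1 inside the inscribed field-of-view disk
and 0 outside; pixels with zero sensitivity stay 0. The dynamic sequence
is updated for all frames simultaneously (one sparse matrix–matrix product
per direction per iteration). 100 iterations are used uniformly — inside
the filtering loop and for final reconstructions — matching the
protocol's reconstruction depth; the inner count is independently
configurable for speed.

## Graph filters

**Spatial.** The 24 frames are fused into four composite frames (1–8,
9–16, 17–20, 21–24), each a duration-weighted average of its members
(count-weighted fusion matches Poisson statistics), and each composite
column is divided by its standard deviation. Bin m's feature vector is its
row of this matrix (optionally augmented with a local patch per composite
frame, off by default). The k = 80 nearest neighbors by Euclidean distance
are kept (ties resolved deterministically), weighted by
`exp(−d²/σ_s²)` with σ_s = 0.5, symmetrized by elementwise maximum, and
given unit self-loops. The squared-norm Gaussian kernel is used (the
plain-norm variant is a one-line change and was not needed).

**Temporal.** Frames are pre-smoothed with a 3×3 Gaussian (σ = 0.85 px,
reflect edges); bins whose time-summed smoothed value exceeds τ = 0.1 of
the maximum form the high-activity mask (empty masks fall back to all
bins with a warning). Within the mask, each frame is divided by its
standard deviation and frames p, q with |p−q| ≤ 4 (window 9) are connected
with weight `exp(−d²(p,q)/σ_t²)`, σ_t = 1. Two deliberate choices:

* *Mean rather than summed squared distance.* The summed squared distance
  over thousands of masked bins makes `exp(−d²)` underflow for any σ_t of
  order one, collapsing the temporal graph to the identity; `stgf`
  therefore uses the per-bin mean squared distance by default
  (`temporal_distance="sum"` restores the literal norm).
* *Scale-equalized filtering.* Frame count scales span two orders of
  magnitude (duration × activity), while similarity is judged on
  variance-normalized frames. Filtering raw frames with any nonzero
  cross-scale weight floods early low-count frames with counts from late
  frames (observed: early-frame error inflated by two orders of
  magnitude). The temporal filter is therefore applied in the same
  normalized space the similarity is measured in, and each frame's scale
  is restored afterwards: the effective operator is `N F_T N^(−1)` with
  `N = diag(frame stds)`. This reduces exactly to plain `F_T` when frame
  scales agree, and preserves `F_T`'s spectrum.

Both filters satisfy the normalized-adjacency contract: symmetric
nonnegative `W` with unit diagonal, all eigenvalues of
`D^(−1/2) W D^(−1/2)` in [−1, 1], top eigenpair `(1, D^(1/2)·1)` per
connected component. The test suite verifies this against a dense
eigensolver.

## The iterative loop

Each pass rebuilds both filters from the current sinogram (the method's
central mechanism — caching the kNN index across passes is available as an
opt-in approximation, off by default), applies the two-sided update,
optionally restores each frame's total counts, reconstructs by MLEM, and
evaluates the dual-domain measure (ε = 0.01, w1 = w2 = 0.5, strict
inequality, T_max = 50; 12 in the reduced profile).

Two loop-level choices required judgment:

* *Count preservation (default on).* Symmetric normalization is not
  mass-preserving on graphs with heterogeneous degrees; measured drift is
  3–6% of each frame's counts per pass, which compounds into a systematic
  scale bias within a few passes. Since total counts are a sufficient
  statistic the filter has no business altering, each column's sum is
  restored after filtering (`rescale_counts=False` disables).
* *Stagnation stop (default on).* Filter re-estimation has a churn floor:
  kNN neighbor sets keep reshuffling under residual noise and the graph
  spectrum is dense near 1, so the per-pass relative change plateaus
  (empirically at 0.05–0.15 at the 63×63 scale) instead of decaying below
  ε. Running to T_max in that regime only diffuses signal mass along the
  graph. The loop therefore also halts at the first pass that fails to
  *decrease* the measure; the stagnating pass is rejected and the previous
  iterate returned. The rule is parameter-free and leaves ε-convergent
  runs untouched (temporal-only runs routinely cross ε in 3–5 passes;
  combined runs typically stop by stagnation after 3–5).

Termination is guaranteed by construction (ε, stagnation, or T_max);
non-convergence is reported via `stop_reason`/`converged` flags, never an
exception. Iterates remain nonnegative because every operator involved is
nonnegative.

## Metrics

MSE is truth-energy-normalized (`Σ(x−x_t)²/Σx_t²`, reported in percent),
bias and variance are the ensemble definitions over O realizations
normalized by the truth, MAE is the plain mean absolute deviation over a
region mask (computed per frame, then averaged over frames), and SSIM uses
uniform 8×8 windows with C1 = (0.01L)², C2 = (0.03L)², L = dynamic range
of the truth (window size, range and sample-covariance convention are
parameters; the cross-check test matches scikit-image's settings).
Contrast-to-noise reporting (ROI mean vs background std normalized by its
mean over configured boxes) supports iteration-sweep curves.

## Problem sizes

The default profile mirrors the full protocol (111×111 phantom,
111×111-bin sinograms, 20 realizations). Tests and the acceptance script
use the reduced profile — 63×63 phantom and geometry, 5 realizations,
T_max = 12, full 100-iteration MLEM — for which the complete three-mode
study runs in about a minute on one core. At this scale each bin holds
roughly 3× more counts than at 111², so the noisy baseline is relatively
cleaner than in the full protocol; error *orderings* (combined ≤ ablations
< noisy) are stable across seeds, while absolute error levels are
scale-specific. One observed consequence: regional MAE of the
spatially-filtered reconstructions can exceed the (relatively clean) noisy
baseline at 63² — spatial smoothing trades a small-region bias for a large
variance reduction — whereas the temporal-only filter improves regional
MAE outright.

## Known limitations

* The spatial graph treats sinogram bins as nodes; no learned or
  embedding-based similarity is provided.
* No attenuation, normalization or PSF factors in the projector; no OSEM
  or regularized reconstruction variants.
* The stagnation rule stops at the first non-improving pass; it does not
  search past a local plateau.
* Kinetic parameter values are plausible defaults, not fits to measured
  data; simulated activities are in arbitrary units.
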