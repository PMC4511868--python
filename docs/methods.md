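# Methods

This note documents the models behind `hypersr`, the parameters that
matter, the numerical choices, and what the synthetic benchmarks do and do
not demonstrate.

## Acquisition model and the super-resolution inverse problem

A low-resolution chemical map is treated as a degraded observation of one
high-resolution scene `c` on a grid refined by the integer factor `k`:

```
C_k = X H T_k c + E_k ,   k = 1..N
```

* `T_k` — translation by the known stage shift of frame `k`, expressed in
  high-resolution (HR) pixels. Shifts must be integer multiples of the HR
  pitch (`lr_pixel_size / k`), so `T_k` is an exact permutation; it is
  implemented as a circular shift. Shifts are trusted as commanded — no
  registration is estimated from the data.
* `H` — space-invariant blur by the optical PSF. Default model: isotropic
  Gaussian parameterized by its FWHM in μm (default 0.59 μm, a typical
  measured confocal Raman resolution with a 100×/0.9 NA objective and a
  200 μm pinhole); explicit kernels are accepted. The kernel is sampled at
  the HR pitch, truncated at 4σ, normalized to unit sum, and materialized
  once per solve as a sparse matrix with **symmetric (edge-mirrored)
  boundary**. Its adjoint is literally the transpose, so the
  forward/adjoint pair is exact by construction (verified against dense
  operators to 1e-12 in the tests).
* `X` — decimation: stride-`k` subsampling at phase 0. Detector-area
  integration, if wanted, belongs in `H`.
* `E_k` — additive Gaussian noise.

The frame-count rule `k = ⌊√N⌋` (largest `k` with `k² ≤ N`) keeps the
number of unknowns `k²·M₁M₂` at or below the number of measurements
`N·M₁M₂`: 100 frames support k = 10 (8×8 → 80×80), 25 frames support
k = 5 (12×6 → 60×30 at 200 nm pixels).

### MAP estimation, L1 + bilateral total variation

The reconstruction minimizes

```
f(c) = Σ_k ‖X H T_k c − C_k‖₁ + λ Σ_{(l,m)} α^{|l|+|m|} ‖c − S_x^l S_y^m c‖₁
```

over the half-plane window `m = 0..P`, `l = −P..P` (`l ≥ 1` when `m = 0`).
The L1 data term is robust to outlier pixels; BTV penalizes differences
against shifted copies at several offsets, preserving edges better than a
quadratic prior. BTV shift operators use mirrored boundaries and their
adjoints are applied by scatter-add on the same index map, so the
analytic sub-gradient (convention `sign(0) = 0`) matches finite
differences of the penalty away from kinks.

Solver: steepest descent on the sub-gradient from a shift-and-add initial
estimate (zero-order upsample each frame, translate back, average). Every
iteration backtracks — the trial step is halved until the objective does
not increase — so the recorded objective trace is non-increasing. If no
decrease exists even at a vanishing step the solver treats a
within-tolerance stall as convergence, halves the nominal step once
otherwise, and finally aborts with a diagnostic carrying the objective
trace. That abort is the operational analogue of acquisitions whose frame
positions were not reproducible (e.g. stage vibrations), where no
high-resolution image consistent with the data exists.

Defaults (all config-exposed, logged in run reports): `λ = 0.01`,
`α = 0.7`, `P = 2`, `β = 1/N`, `n_iter = 50`, relative objective tolerance
1e-6. The defaults favour mild regularization: with exact shifts and a
good PSF guess the data term dominates; raise `λ` for noisier series.
Because `H` is part of the model, the solution is a *deblurred* scene
estimate — resolution beyond the PSF is expected on high-SNR targets.

## Baseline correction (AsLS / WLS)

Per pixel spectrum `y`, the baseline `z` minimizes
`Σ w_i (y_i − z_i)² + λ_b Σ (Δ²z)²` (Whittaker smoother, second-order
differences, exact sparse solve), iterating weights
`w_i = p` if `y_i > z_i` else `1 − p` until the weight set stops changing
(max 10 iterations). Defaults `λ_b = 1e5`, `p = 1e-3`.

Two practical notes, both visible in the tests:

* With noisy spectra, very small `p` pins the baseline to the *lower
  envelope* of the noise, leaving a positive offset in the corrected
  spectra and partially absorbing weak bands; this biases downstream
  factorizations. The aerosol workflow therefore defaults to `p = 0.05`,
  which holds the baseline mid-noise. Use small `p` for strongly
  fluorescent spectra with sparse sharp peaks.
* The smoother can only track backgrounds whose curvature is gentle on the
  scale `λ_b^{1/4}` samples; steeply curved fluorescence leaves a
  percent-level residual that MCR then absorbs into an extra component —
  mirroring real analyses where one contribution is recognizably
  "uncorrected fluorescence".

Corrected spectra are *not* clipped; small negatives are expected and are
handled by the MCR non-negativity constraint.

## MCR-ALS on augmented multisets

The unfolded cubes (rows = pixel spectra, raster order, y outer) are
stacked into `D` (e.g. 25 cubes of 12×6 pixels → 1800 rows) and factored
as `D = C Sᵀ + E`:

* rank probing by SVD: suggested rank = number of singular values above
  `1e-2 · σ₁` (a suggestion, confirmed by the analyst);
* initial spectra by SIMPLISMA on pixel rows: purity
  `σ_i / (μ_i + 0.05·max μ)`, subsequent picks weighted by the determinant
  of the correlation-around-origin matrix of the already-selected scaled
  rows (drives selections toward mutually independent "purest" pixels);
* alternating constrained least squares: non-negativity on both factors
  (row/column-wise active-set NNLS; a "clip" fast mode plain-LS-then-clip
  is available), unit Euclidean norm on each Sᵀ row with the
  concentration columns rescaled so `C Sᵀ` is unchanged;
* convergence when the relative change of lof between cycles is below
  0.1% (default), max 50 cycles; lof is measured after each C update, so
  the trace is non-increasing on noiseless data;
* components reported sorted by explained-variance share; comparisons in
  tests are permutation-invariant.

The identity `r² = 100·(1 − (lof/100)²)` holds to rounding for every
fitted model by construction of the two metrics.

## Step-edge resolution metrology

Edge-response ("LSF" in Raman-imaging usage) profiles are single-pixel
lines perpendicular to a material edge, spaced evenly over the interior of
the map (boundary lines of reconstructed maps carry the strongest
artifacts and are excluded when there is room). Edge presence is
validated: the range of per-position means must exceed 5× the robust noise
MAD, else an error reports the contrast statistic.

Each profile is interpolated with a cubic spline and differentiated
analytically on a 20× sub-sample grid; plain central differences smooth
the derivative over two samples and inflate the FWHM by ~15% at σ = 1 px.
The FWHM comes from the half-maximum crossings walked outward from the
derivative peak (through plateaus — the outermost crossing of the peak's
own lobe), linearly interpolated, and is floored at **two sampling steps**:
a perfect step differentiated on a grid already spans two samples, so
nothing below that is resolvable. Accuracy on noiseless Gaussian edges:
1.8% / 0.02% / 0.02% at σ = 1/2/4 px. The estimate is invariant to affine
intensity rescaling.

The confocal diffraction limit is computed as `0.46 λ/NA` (the prefactor
is exposed as an argument).

## Synthetic scenes — what they emulate, and what they do not

`make_bar_target` reproduces a lithography-style test chart: `n` bars of
width `w` separated by gaps of `w` (bounding box `(2n−1)w`, homothetic in
`w`); `make_edge_target` is the step marker used for metrology.
`make_mixture_scene` builds a multi-component particle field: pure spectra
are sums of Gaussian bands on a 900–1190 cm⁻¹ axis (default table loosely
shaped like sulfate/nitrate particle spectra, fully user-configurable),
concentration maps are unions of random disks with overlaps allowed, an
optional extra smooth background component emulates residual fluorescence.
Acquisition (`simulate_map_series`, `simulate_cube_series`) applies exactly
the forward operator above plus a separable fluorescence baseline
(spectral shape `exp(−Δν/600 cm⁻¹)` plus a linear term; per-pixel
amplitude log-normal, σ = 0.5) and additive Gaussian noise (a Poisson mode
exists, off by default). All generators are deterministic given their
seed.

Default study conditions mirror the instrument protocols the package
targets: 100 frames / 100 nm shifts / 1 μm pixels for the target-sample
workflow; 25 cubes / 200 nm shifts / 12×6 pixels / 0.59 μm PSF for the
aerosol workflow; SNR 40 noise where noise is on.

What passing these benchmarks does **not** show about real data: the
simulator's shifts are exact (real stages drift — the failure mode appears
only as solver divergence, not as simulated physics), its PSF is exactly
known and shift-invariant, its baseline is separable (rank-one), and there
are no cosmic rays, detector nonlinearity, or focus changes. Results on
real instruments depend on how well those assumptions hold; the 78% FWHM
gain in the README's worked example is a desk-scale analogue, not an
instrument claim.

## Problem sizes and runtime

The shipped benchmarks run the instrument-scale geometries directly: the
100-frame 8×8 → 80×80 reconstruction uses 15 descent iterations when only
geometry is measured (output size is fixed by `k` from the first
iteration), and 25–50 iterations where image quality matters; the full
aerosol chain (25 cubes × 12×6 × 146 channels → AsLS → rank-6 multiset
MCR → 6 super-resolved 60×30 maps) completes in well under a minute on
one CPU. The whole test suite runs in about half a minute.

## Known limitations

* Shifts must lie exactly on the HR grid; arbitrary sub-pixel shifts would
  need an interpolating `T` (not a permutation) and are out of scope.
* Only translations are modelled — no rotation, affine warps, or blind
  (unknown-PSF) reconstruction.
* MCR constraints are limited to non-negativity and normalization; no
  unimodality/closure/equality constraints and no rotational-ambiguity
  band computation. With no pure pixels the factorization is not unique
  and recovered spectra may mix.
* The L1 solver is a sub-gradient method: convergence is slow near the
  optimum, and the `converged` flag frequently stays `False` at tight
  tolerances even when the reconstruction is visually and metrologically
  stable.
* FWHM metrology is noise-sensitive through the spline derivative; very
  noisy profiles benefit from averaging maps before measuring.
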