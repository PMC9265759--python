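# Methods

## Problem and forward model

A lensless on-chip microscope records intensity only, on sensor pixels that
are coarser than the diffraction-limited detail of the optical field.  The
sample is described by its complex transmittance `x ∈ C^n` on a
high-resolution grid of pitch `p` (μm).  For each of `K` diversity
acquisitions the field is phase-modulated, propagated to the sensor, cropped
to the sensor area and binned into sensor pixels:

    y_k² = S |A_k x|²,    A_k = C · H · M_k,    k = 1..K

* `M_k` — phase-only modulation `exp(i φ_k)` applied on the sample grid (the
  modulator is optically conjugate to the sample; relay optics are abstracted
  away).  Unitary.
* `H` — free-space propagation over distance `z` by the angular-spectrum
  transfer function `exp(i2πz√(1/λ² − f_x² − f_y²))`, applied as a circular
  convolution (unpadded FFT multiply).  Evanescent frequencies
  (`f_x²+f_y² > 1/λ²`) are zeroed, so `‖H‖ ≤ 1` with equality on propagating
  modes.  Frequency convention: `f = j/(N·p)`, DC at index 0.
* `C` — restriction to the sensor window (centered by default; offset
  configurable).
* `S` — weighted sum of the `σ = σ₁·σ₂` subpixels under each sensor pixel.
  Default weights are all ones (plain block sum), so `s = Sᵀ1 ≡ 1`; a
  calibrated weight map with values in `[0, 1]` may be supplied but is not
  estimated here.

Every factor is linear and non-expansive, so `ρ(A_k) ≤ 1`.

## Objective and algorithm

Reconstruction minimizes the amplitude-based objective

    F(x) + λ‖Dx‖₁,
    F(x) = (1/2K) Σ_k ‖√(S|A_k x|²) − y_k‖²,

where `D` stacks horizontal and vertical forward differences (Neumann
boundary) and `‖·‖₁` sums complex moduli.  The amplitude residual (rather
than the intensity residual) is used because it converges faster in
practice; its Wirtinger gradient — the derivative with respect to `conj(x)`,
with the Wirtinger factor of two absorbed into the step size — is

    ∇F(x) = (1/2K) Σ_k A_kᴴ[(A_k x) ⊙ Sᵀ(1 − y_k ⊘ √(S|A_k x|²))].

At sensor pixels with zero model intensity the ratio is defined as 0 (a
bounded subgradient choice; the residual factor becomes 1).

The solver is a proximal-gradient loop with Nesterov extrapolation:

    v(t) = u(t−1) − γ ∇F(u(t−1))
    x(t) = prox_{γR}(v(t))
    u(t) = x(t) + β_t (x(t) − x(t−1)),    u(0) = x(0)

with `β_t = t/(t+3)` (accelerated Wirtinger flow, AWF) or `β_t ≡ 0` (plain
Wirtinger flow, WF).  No momentum restart is applied by default.  Plain WF
with a fixed step

    γ ≤ 2K / Σ_k ρ(A_kᴴ diag(s) A_k)

converges to a stationary point; with unit weights every radius equals 1
(`H` and `M_k` unitary, `CᵀC` a projection, so `A_kᴴ diag(s) A_k` is a
unitary conjugate of a projection), giving the prespecified step `γ = 2`.
The default step is `min(bound, 2)` with the radii estimated by power
iteration (the operator is Hermitian PSD, so the norm-ratio estimate
converges monotonically from below; 100 iterations are far more than needed
because the leading eigenvalue has large multiplicity).

### TV proximity operator

`prox_{γR}` is computed on the dual: one complex dual variable per
difference, clipped to the unit disk (magnitude clipping, which makes the
prox equivariant under global phase rotation — real/imaginary-separable
shrinkage would not be), dual step `1/(8γλ)` (8 bounds `‖D‖²` in 2-D).  The
default is a **single** inner iteration per outer step with the dual
variables warm-started across outer iterations; accuracy then accumulates
over the outer loop at negligible cost.  For stand-alone prox evaluation the
inner iteration count is configurable; a few hundred iterations reproduce
the two-pixel closed form (soft-shrinkage of the difference by `2γλ`) to
better than 1e−6.

### Initialization

The data fix the scale of `x` but phase retrieval has no canonical starting
point.  Options:

* `flat` (default): constant amplitude `√(mean_k Σ y_k² / m)` (the measured
  energy spread uniformly over the crop), zero phase.  Deterministic and
  scale-matched.
* `backprop`: the average over `k` of `A_kᴴ` applied to the up-sampled
  measured amplitude — the standard holographic back-propagation start.
* `random`: seeded complex Gaussian with the same RMS amplitude.

All runs are bitwise reproducible given the option set and seed.

## Synthetic data generator

The generator emulates a phase-modulation-diversity acquisition entirely in
software.  Defaults are the package's standard study conditions: 256×256 grid,
`σ = 4×4 = 16` under-sampling, `K = 8`, λ = 0.532 μm, pitch 1.27 μm,
`z = 500` μm; sample amplitude mapped to `[0.2, 1]` (passive sample) and
phase to `[0, π]`.  The built-in procedural sample (textured blobs,
resolution-target-like bar groups, smooth phase ramps) stands in for
copyrighted standard test images; any user-supplied grayscale pair can be
imported instead.  Modulation patterns are i.i.d. uniform phase fields
smoothed by a Gaussian (default 2 px, wrap boundary) and rescaled to span
`[0, 2π)` — smoothing limits modulator crosstalk at some cost in diversity.
Noise models: none (default, used for theorem-facing experiments), additive
Gaussian intensity noise at a stated SNR (40 dB for robustness studies;
clipped at zero), or scaled Poisson counts.

What the generator does **not** model: partial coherence, modulator
crosstalk and phase-response nonlinearity, sensor dark current and read
noise, lens aberrations, or model mismatch of any kind.  Simulated
reconstructions therefore commit an "inverse crime": passing tests show
algorithmic correctness and the relative merits of the variants under the
stated model, not end-to-end performance on experimental data, where
modeling errors dominate late-iteration behaviour.

## Metrics

Intensity data are invariant under `x → x·e^{iφ}`, so all errors are
computed after removing the optimal global phase
`φ* = −arg⟨x_true, x_hat⟩` (closed form).  `rmse_complex` is
`‖x̂e^{iφ*} − x‖/√n`; `rmse_amp` compares moduli; `rmse_phase` uses the
wrapped (−π, π] aligned phase difference (the targets of interest are less
than one wave deep, so no unwrapping).  A configurable border margin
(default: the binning factor) is excluded to avoid circular-convolution
wrap-around; amplitude scale is never re-fitted.

## Problem sizes and empirical behaviour of the experiments

The packaged experiments (test suite and reproduction scripts) use
dense-matrix oracles on grids up to 16×16, operator/step-size checks on
64×64, and full-scale studies on the default 256×256 grid; 1024×1024 runs
are possible but are opted into by the user.

Empirical notes from the packaged studies (all reproducible from the test
suite, which computes every quantity it asserts):

* Plain WF with `γ = 2` decreases the objective monotonically on noiseless
  data, as the step-size theorem predicts.
* AWF reaches a given fidelity level several times sooner than WF on the
  default K=8, σ=4×4 benchmark.  How large the speed-up is depends strongly
  on the conditioning of the instance, and hence on the diversity of the
  modulation patterns: with the default 2-px-smoothed patterns the
  iteration-count ratio is in the mid single digits; smoother (less
  diverse) patterns worsen the conditioning and widen the gap to an order
  of magnitude and beyond.  Since the pattern recipe leaves the smoothing
  bandwidth free, the packaged acceleration test states the benchmark it
  uses rather than claiming a universal factor.
* TV regularization (`λ = 5·10⁻⁴` for the unit-order-amplitude benchmark,
  selected by a sweep over {2, 5, 10, 20, 50}·10⁻⁴ at K=16 and frozen for
  the study) suppresses the artifacts of the severely under-determined K=8
  problem and lets 8 or 16 noisy measurements beat a non-regularized
  reconstruction from 32, once measurement noise (40 dB) is present.
* Noiseless recovery with K=32 keeps improving slowly past 500 iterations;
  the aligned relative error is still a little under 2·10⁻² at that budget
  on the default benchmark.

## Design choices where the design was open

* **Unit sensor weights.**  With uniform weights the step rule gives exactly
  `γ = 2`; weights are configurable but uncalibrated.
* **Zero-intensity gradient entries** take ratio 0 (bounded subgradient).
* **Crop placement** defaults to centered.
* **Stopping** is a fixed iteration budget `T`; an optional relative-change
  tolerance (1e−7) exists but is off by default.
* **Objective logging** (one extra forward pass per iteration) is on by
  default and can be disabled for large runs.
* **λ defaults**: λ is problem-scale dependent and left to the user; the
  packaged measurement-reduction study documents its swept values and the
  chosen one in the test itself.

## Known limitations

* Only modulation diversity is implemented; the operator interface admits
  defocus/wavelength/ptychographic diversity but no such operators ship.
* No BM3D or learned denoiser priors; the `Regularizer` interface is the
  extension point.
* No line search, momentum restart tuning, GPU path or multi-wavelength
  recovery.
* The TV prox with a single warm-started inner iteration is inexact early in
  a run; its error is absorbed by subsequent iterations but the packaged
  monotonicity guarantees are stated (and tested) for the non-regularized
  case.
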