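# psr-awf — accelerated Wirtinger flow for pixel-super-resolution phase retrieval

Lensless on-chip holographic microscopes record only intensity, on sensor
pixels that are larger than the optical detail they are meant to resolve.
Recovering the complex transmittance of a sample from such data is the
**pixel-super-resolution (PSR) phase retrieval** problem: given `K` diversity
measurements

    y_k² = S |A_k x|²,     A_k = C · H · M_k,     k = 1..K

(`M_k` a known phase-only modulation, `H` angular-spectrum free-space
propagation, `C` the sensor crop, `S` the `σ₁×σ₂` sub-pixel binning of the
sensor), estimate the high-resolution complex field `x`.  This package is for
computational-imaging researchers and microscopists who want a reference
implementation of the solver together with a complete simulator, so the
whole pipeline runs without any experimental data.

The reconstruction minimizes the regularized amplitude-based objective

    x̂ = argmin_x  (1/2K) Σ_k ‖√(S|A_k x|²) − y_k‖₂²  +  λ‖Dx‖₁

by **accelerated Wirtinger flow (AWF)** — proximal gradient steps on the
Wirtinger gradient of the fidelity term with Nesterov extrapolation
`β_t = t/(t+3)` and the anisotropic complex total-variation prox — using the
prespecified step size

    γ ≤ 2K / Σ_k ρ(A_kᴴ diag(s) A_k),    s = Sᵀ1,

which evaluates to `γ = 2` for this system (all spectral radii are exactly 1
with unit-weight binning).  `β_t ≡ 0` gives the plain Wirtinger flow (WF)
baseline.  See `docs/methods.md` for the model, the algorithm and all
numerical conventions.

## Worked example

```python
from psr_awf import SimulationConfig, simulate, reconstruct, aligned_rmse

config = SimulationConfig(grid=(128, 128), sigma=(4, 4), K=8, seed=0)
x_true, system, stack = simulate(config)

result = reconstruct(stack, system, lam=0.0, schedule="nesterov", T=300, truth=x_true)
metrics = aligned_rmse(result.x_hat, x_true, border=4)

tv = reconstruct(stack, system, lam=2e-3, schedule="nesterov", T=300, truth=x_true)
```

Output:

```
measured: K=8 images of (32, 32) pixels (sigma = 4x4 binning)
step size gamma = 2.000000
iteration 300: fidelity = 2.541e-06
aligned RMSE: complex = 0.1731, amplitude = 0.0931, phase = 0.4355 rad
with TV (lambda = 2e-3): complex RMSE 0.0330 (vs 0.1731 unregularized)
```

Reading this: eight 32×32 intensity images constrain a 128×128 complex field
— a 16-fold under-sampling, so the non-regularized problem is severely
ill-posed.  The automatic step size comes out at the theoretical value
`γ = 2`; the data fidelity is driven to ~1e−6, but the unregularized
estimate still carries ambiguity artifacts (complex RMSE 0.17 against the
known ground truth, after removing the global phase).  Adding the TV prior
with `λ = 2·10⁻³` suppresses those artifacts (RMSE 0.033) from the same
eight images.

The same pipeline is available from the shell:

```bash
psr-awf simulate   --config sim.yaml --out stack.h5 --truth truth.h5
psr-awf reconstruct --stack stack.h5 --lambda 2e-3 --iters 300 --out recon.h5
psr-awf evaluate   --recon recon.h5 --truth truth.h5 --out metrics.json
```

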