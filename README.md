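# laosfit

Fractional-viscoelastic torque simulation and material identification for
soft tissue tested under combined compression preload and large-amplitude
oscillatory shear (LAOS).

## The problem

Soft tissues such as liver are power-law viscoelastic: their complex shear
modulus scales with frequency as G\* ∝ ω^α (α ≈ 0.2–0.35), and at shear
strains of tens of percent their stress response is visibly non-sinusoidal.
Rotational rheometer studies probe this by compressing a cylindrical sample
(height H, radius R) between plates to an axial stretch λ = 1 − CS and
oscillating the top plate at angular displacement ψ(t) = sin(2πft)·hγ/r,
recording the torque. `laosfit` provides the forward model for that
experiment and the fitting machinery to identify constitutive parameters
from torque traces — for rheologists and biomechanics modellers who need a
3-D nonlinear viscoelastic law rather than a small-strain modulus.

## The model

The second Piola–Kirchhoff stress is split as S = S_e + D_t^α S_v + JPC⁻¹,
where D_t^α is the Caputo fractional derivative

    D_t^α S_v(t) = 1/Γ(1−α) ∫₀ᵗ (t−z)^{−α} ∂_z S_v(z) dz,

discretised with the L1 scheme. Three incompressible isotropic laws are
implemented:

| model | total stress (minus hydrostatic part) |
|-------|----------------------------------------|
| `vmr` (modified Mooney–Rivlin) | C·S_e² + δ·D_t^α(S_e¹), S_e¹ = J^{−2/3}(I − (I_C/3)C⁻¹), S_e² = J^{−4/3}(II_Ĉ−3)(C − (II_C/3)C⁻¹) |
| `vog` (viscoelastic Ogden) | δ·D_t^α(Σᵢ λᵢ^{b−1} vᵢ⊗vᵢ) over the spectral decomposition of C |
| `vexp` (viscoelastic exponential) | δ·Dev[D_t^α(e^{b(II_C−3)}·C)] |

The plate torque τ₃ = ∫ r₁σ₂₃ − r₂σ₁₃ dΓ is integrated over the deformed
top disc (Gauss–Legendre in radius by default; a 765-element triangulated
disc as cross-check). Because τ is linear in (C, δ) and nonlinear in
(α, b), fitting sweeps (α, b) on a grid and solves nonnegative least
squares at each node under one of three norms — plain L2, point-wise
(amplitude-normalised, shape-matching) or parameter-scaling, in which the
nonlinear parameters are shared across tests while per-test linear
amplitudes float via scalings β_i (x_i = x\*/β_i), absorbing strain
softening and sample variability. All norms read 0% on a perfect fit and
exactly 100% with the linear parameters zeroed.

## Worked example

```python
import numpy as np
from laosfit import (MaterialParameters, SampleGeometry, TestCondition,
                     simulate_test, sweep_fit, SyntheticStudyConfig,
                     generate_dataset)

# simulate one test: 10% compression, 50% shear, 1 Hz
params = MaterialParameters(model="vexp", delta=300.0, alpha=0.2, b=1.3)
cond = TestCondition(
    geometry=SampleGeometry(H=3e-3, R=10e-3, cs=0.10), gamma=0.50, freq=1.0)
trace = simulate_test(params, cond)
print(f"peak torque: {np.max(np.abs(trace.tau)):.3e} N·m")

# a full 18-test study with strain softening and 1% noise, then refit
study = SyntheticStudyConfig(true_params=params, softening="linear-in-gamma",
                             noise_sd=0.01, seed=42)
dataset = generate_dataset(study)
fit = sweep_fit(dataset.traces, "vexp", norm="scaling",
                alpha_grid=[0.18, 0.20, 0.22], b_grid=[1.2, 1.3, 1.4])
print(f"alpha = {fit.alpha:.2f}, b = {fit.b:.2f}, error = {fit.error:.2f}%")
delta = fit.scaling.x_per_test[:, 0]
print(f"per-test delta: {delta.min():.1f} ... {delta.max():.1f} Pa")
```

prints

```
peak torque: 1.267e-03 N·m
alpha = 0.20, b = 1.30, error = 1.54%
per-test delta: 149.9 ... 300.1 Pa
```

The recovered fractional order and exponential power land on the
generating values; the per-test δ span reproduces the imposed 2-fold
strain-softening schedule (300 Pa at 1% shear down to 150 Pa at 50%)
within a fraction of a percent despite 1% measurement noise.

The same pipeline is scriptable from the shell:

```sh
laosfit generate --model vexp --alpha 0.2 --b 1.3 --delta 300 \
        --softening linear-in-gamma --noise-sd 0.01 --seed 42 --out data/
laosfit fit --model vexp --norm scaling --data data/ --out fit.json
```

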