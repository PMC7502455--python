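# Methods

## Problem and model

`laosfit` simulates and identifies the torque response of a cylindrical
soft-tissue sample (liver is the motivating tissue) held at a static
compression preload and driven in large-amplitude oscillatory shear (LAOS)
between the plates of a rotational rheometer. At shear amplitudes of tens
of percent the torque is visibly non-sinusoidal and phase-delayed, and its
amplitude scales with frequency like ω^α with a fractional exponent α ≈
0.2–0.35 — the signature of power-law (fractional-order) viscoelasticity
in soft tissue.

### Kinematics

Ideal incompressible compression to axial stretch λ = 1 − CS deforms the
cylinder (height H, radius R) to h = λH, r = R/√λ. The plate oscillation
ψ(t) = sin(2πft)·hγ/r twists cross-sections by Ψ(t, X₃) = ψ(t)X₃/H. The
composed motion has deformation gradient

    F = [[cosΨ/√λ, −sinΨ/√λ, −(ψ/H) r_x sinθ],
         [sinΨ/√λ,  cosΨ/√λ,  (ψ/H) r_x cosθ],
         [0,         0,         λ]],

with θ = θ₀ + Ψ and r_x the deformed radial position; det F = 1
identically. We verified numerically (central differences, 1e-6 relative)
that this F is the exact Jacobian of the motion map everywhere in the
sample, not only on the top surface. Stress for torque is evaluated on the
top surface (Ψ → ψ), where the instrument measures.

### Constitutive models

The second Piola–Kirchhoff stress is S = S_e + D_t^α S_v + JPC⁻¹, with the
Caputo fractional derivative D_t^α interpolating between hyperelastic
(α = 0) and viscous (α = 1) response. Three laws are implemented:

* **vmr** (modified Mooney–Rivlin): S = C·S_e² + δ·D_t^α(S_e¹), with the
  neo-Hookean kernel S_e¹ = J^{−2/3}(I − (I_C/3)C⁻¹) and the quadratic
  second-invariant kernel S_e² = J^{−4/3}(II_Ĉ − 3)(C − (II_C/3)C⁻¹).
* **vog** (viscoelastic Ogden): S = δ·D_t^α(Σᵢ λᵢ^{b−1} vᵢ⊗vᵢ) over the
  principal stretches/eigenvectors of C. The λᵢ^{b−1} spectral weights are
  the model's *definition* here; they are not the literal C-derivative of
  the Ogden energy (Σλᵢ^b − 3)/(2b), which would give λᵢ^{b−2} weights.
  We keep the λᵢ^{b−1} form deliberately and therefore exclude this kernel
  from the energy-consistency tests. Stretches are the full ones; under
  this protocol J = 1 so isochoric and full stretches coincide.
* **vexp** (Fung-type exponential): S = δ·Dev[D_t^α(exp(b(II_C − 3))·C)],
  with the Lagrangian deviatoric projection Dev[A] = A − ((A:C)/3)C⁻¹
  applied *after* the time derivative, using C at the evaluation time, so
  deviatoric and hydrostatic parts remain separated.

The hydrostatic pressure never enters the torque (an isotropic Cauchy
stress has no 13/23 components); it is recoverable from the traction-free
lateral wall and exposed as `recover_wall_pressure` for completeness.

### Fractional derivative

The Caputo integral is discretised with the L1 scheme (piecewise-linear
history inside the kernel), giving convolution weights
w_ℓ = dt^{−α}/Γ(2−α)·((ℓ+1)^{1−α} − ℓ^{1−α}). The scheme is exact for
linear histories, O(dt^{2−α}) otherwise, and the full O(n²)-memory history
is kept (desk-scale n makes truncation unnecessary); the convolution is
evaluated by FFT. The memory origin t = 0 is the instant the compressed
preload state is in place — the compression ramp is not simulated, so a
held preload produces zero fractional stress. Edge orders: α = 0 maps a
history to itself (hyperelastic limit, chosen over the literal Caputo
limit f(t) − f(0), which would zero a static preload's elastic stress);
α = 1 is the backward difference.

### Torque integration

τ₃ = ∫ r₁σ₂₃ − r₂σ₁₃ dΓ over the deformed top disc. The default rule
exploits axisymmetry: the integrand depends only on deformed radius, so a
16-point Gauss–Legendre rule in ρ with weight 2πρ suffices (doubling the
order changes τ₃ by < 1e-6 relative). A 765-element triangulated disc
(153 sectors × 3 rings) is provided as an independent cross-check. Each
flat triangle is integrated with the three-edge-midpoint rule, which is
exact for quadratic integrands; centroid sampling was rejected because on
convex integrands such as the ρ² torsion field it biases the integral low
by ~0.7% at this element count, while the midpoint rule leaves only the
polygon-versus-disc geometry error (≈ 6e-4). The analytic torsion field
σ₁₃ = −cx₂, σ₂₃ = cx₁ (τ₃ = πr⁴c/2) is the quadrature oracle.

## Simulation protocol and defaults

* Sampling: T = 200 points per period (dt = 1/(fT)); 8 preconditioning
  (burn-in) cycles followed by 3 recorded cycles, with the fractional
  derivative applied across the full history so memory crosses the
  recording boundary. After 8 burn-in cycles the last two recorded cycles
  agree to < 0.5% RMS.
* Geometry defaults: H = 3 mm, R = 10 mm.
* The 18-test study protocol: CS ∈ {1, 10, 20}% × SS ∈ {1, 10, 25, 50}%
  at 1 Hz, plus CS 10% × SS ∈ {1, 10, 25}% at 0.5 and 2 Hz.
* A signed shear amplitude is accepted (sign = twist direction); protocol
  constructors emit nonnegative amplitudes. Reversing the sign flips the
  torque trace exactly, so even harmonics of the steady response vanish.

## Fitting

The torque model is linear in (C, δ) and nonlinear in (α, b), so fitting
sweeps (α, b) on a grid and solves a nonnegative least-squares problem at
each node. Default grids mirror standard practice for this protocol:
α from 0.05 to 1 in steps of 0.05, refined to 0.01 steps on [0.15, 0.4];
b on [1, 14] step 0.5 (vog) and [1, 1.5] step 0.1 (vexp). Grid ties
resolve to the smallest α, then smallest b.

Three norms, all reading 0% at a perfect fit and exactly 100% at zero
linear parameters:

* **l2** — ‖Ax − b‖₂/‖b‖₂; dominated by the large-amplitude tests.
* **pointwise** — residuals scaled per sample by max(tol, |b_k|); equal
  weight per point, matching curve shape irrespective of amplitude. The
  guard tol (unspecified in the norm's general form) defaults to
  1e-3 × each test's peak torque: small enough to leave genuine signal
  untouched, large enough that zero crossings cannot dominate.
* **scaling** — shared nonlinear parameters with per-test linear
  amplitudes x_i = x*/β_i; alternates a stacked nonnegative LSQ for x*
  (columns scaled by 1/β_i) with the closed-form update
  β_i = (b_i*ᵀA_i*x*)/(b_i*ᵀb_i*), from β_i = 1, until the relative error
  change is < 1e-10 or 200 sweeps. Blocks are pre-normalised by
  n_i·‖τ_i^d‖₂. A β update that would turn nonpositive (possible only for
  degenerate, anti-correlated data) is skipped. The (x*, β) pair is only
  defined up to a joint positive scale; for reporting, β is gauge-fixed to
  mean 1 (the absolute x_i are gauge-invariant).

## Synthetic data

The generator emulates the study's statistical structure: the 18-test
protocol, fractional phase lag and harmonic distortion (via the forward
model itself), shape-preserving per-test strain softening, and additive
Gaussian torque noise with s.d. a fraction (default choice 1%) of each
test's peak torque. Softening is modelled purely as amplitude scaling
x_i = x_true/β_i — the modelling assumption behind the scaling norm — with
the `linear-in-gamma` schedule spanning a 2-fold stiffness decrease from
the smallest to the largest shear amplitude (a deliberately mild,
qualitative emulation of the trend seen in tissue; real samples can
scatter far more, and the span is configurable).

What the generator does **not** emulate: barrelled (non-ideal) compression
and its normal-force consequences, inertia, sample inhomogeneity or
anisotropy, slip, multiplicative or drift-like instrument noise, and
biological covariates. Passing recovery tests therefore demonstrate the
identifiability machinery under the model's own assumptions, not
robustness to real-tissue artefacts.

Default ground-truth fixture: vexp with α = 0.2 (inside the range
typically identified for liver), b = 1.3, δ = 300 Pa; δ and b are
convenient positive choices recorded in dataset manifests, not measured
tissue values.

## Numerical and design choices

* Degenerate spectra (γ = 0, C ∝ I): the symmetric eigensolver's basis in
  a degenerate eigenspace is arbitrary, but all downstream quantities are
  spectral functions, which are basis-independent; tests assert
  reconstructed tensors, never eigenvectors.
* Linear parameters are constrained to the nonnegative orthant in every
  norm (scipy's NNLS).
* Problem sizes: recovery and self-consistency tests run the full 18-test
  protocol at T = 200 and radial order 16; cross-checks that only probe
  structure (symmetry, mesh agreement) use shortened cycle counts.
* Determinism: a fixed study seed makes generated datasets bit-identical;
  the fitting path contains no randomness.

## Limitations

* Only ideal compression is modelled; normal force under ideal kinematics
  is known to differ qualitatively from experiments, so the package does
  not expose normal-force predictions.
* The forward model is quasi-static (no inertia) and strictly
  incompressible.
* The L1 scheme's O(n²) memory cost is fine at desk scale but would need a
  sum-of-exponentials approximation for long records.
* The Ogden-kernel energy inconsistency noted above means vog stresses
  should be read as a spectral power-law model in their own right.
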