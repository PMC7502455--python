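"""Hyperelastic stress kernels and stress assembly for three viscoelastic laws.

Three incompressible, isotropic constitutive models are supported, each
built from a hyperelastic second Piola–Kirchhoff (PK2) kernel whose time
history is passed through a Caputo fractional derivative D_t^α:

``vmr``  (modified Mooney–Rivlin)
    S = C·S_e² + δ·D_t^α(S_e¹) + S_p, with S_e¹ the neo-Hookean kernel
    (linear in shear) and S_e² a quadratic second-invariant kernel
    (nonlinear in shear).

``vog``  (viscoelastic Ogden)
    S = δ·D_t^α(S_e^b) + S_p with the spectral kernel
    S_e^b = Σᵢ λᵢ^{b−1} vᵢ⊗vᵢ built from the principal stretches and
    eigenvectors of C.

``vexp`` (viscoelastic exponential / Fung-type)
    S = δ·Dev[D_t^α(S_e^b)] + S_p with S_e^b = exp(b·(II_C − 3))·C; the
    Lagrangian deviatoric projection is applied *after* the fractional
    derivative, using C at the evaluation time, so the deviatoric and
    hydrostatic parts stay separated.

S_p = J·P·C⁻¹ is the hydrostatic part. It never contributes to the plate
torque, but the pressure P can be recovered from the traction-free lateral
wall (see :func:`recover_wall_pressure`).

The Ogden kernel is implemented with λᵢ^{b−1} spectral weights. Note this
is not the literal C-derivative of the Ogden energy (Σλᵢ^b − 3)/(2b),
whose weights would scale as λᵢ^{b−2}; the λᵢ^{b−1} form is kept
deliberately as the model definition.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .kinematics import DeformationState, invariants

__all__ = [
    "MODELS",
    "MaterialParameters",
    "dev",
    "pk2_mr1",
    "pk2_mr2",
    "pk2_ogden",
    "pk2_exp",
    "viscoelastic_kernel",
    "elastic_kernel",
    "recover_wall_pressure",
]

MODELS = ("vmr", "vog", "vexp")

_I3 = np.eye(3)


@dataclass(frozen=True)
class MaterialParameters:
    """Material parameters of one constitutive law.

    Parameters
    ----------
    model : {"vmr", "vog", "vexp"}
    delta : float
        Linear viscoelastic scale δ (Pa), ≥ 0.
    alpha : float
        Fractional order α ∈ [0, 1]; α=0 is hyperelastic, α=1 purely viscous.
    C_lin : float
        Linear elastic scale C (Pa) of the quadratic Mooney–Rivlin term;
        only meaningful for ``vmr``.
    b : float
        Nonlinear power; Ogden exponent (``vog``) or exponential rate
        (``vexp``).
    """

    model: str
    delta: float
    alpha: float
    C_lin: float = 0.0
    b: float = 1.0

    def __post_init__(self) -> None:
        if self.model not in MODELS:
            raise ValueError(f"unknown model {self.model!r}; choose from {MODELS}")
        if self.delta < 0 or self.C_lin < 0:
            raise ValueError("linear parameters must be nonnegative")
        if not 0.0 <= self.alpha <= 1.0:
            raise ValueError("fractional order must lie in [0, 1]")

    @property
    def n_linear(self) -> int:
        """Number of linear parameters (2 for vmr: C and δ; otherwise 1)."""
        return 2 if self.model == "vmr" else 1


def dev(A: np.ndarray, C: np.ndarray) -> np.ndarray:
    """Lagrangian deviatoric projection Dev[A] = A − ((A:C)/3)·C⁻¹.

    The result double-contracts to zero with C.
    """
    A = np.asarray(A, dtype=float)
    C = np.asarray(C, dtype=float)
    Cinv = np.linalg.inv(C)
    return A - (np.sum(A * C) / 3.0) * Cinv


def pk2_mr1(state: DeformationState) -> np.ndarray:
    """Neo-Hookean PK2 kernel J^{−2/3}·(I − (I_C/3)·C⁻¹)."""
    I_C, _ = invariants(state.C)
    Cinv = np.linalg.inv(state.C)
    return state.J ** (-2.0 / 3.0) * (_I3 - (I_C / 3.0) * Cinv)


def pk2_mr2(state: DeformationState) -> np.ndarray:
    """Quadratic second-invariant kernel J^{−4/3}·(II_Ĉ−3)·(C − (II_C/3)·C⁻¹)."""
    _, II_C = invariants(state.C)
    _, II_Ciso = invariants(state.C_iso)
    Cinv = np.linalg.inv(state.C)
    return state.J ** (-4.0 / 3.0) * (II_Ciso - 3.0) * (
        state.C - (II_C / 3.0) * Cinv
    )


def pk2_ogden(state: DeformationState, b: float) -> np.ndarray:
    """Ogden spectral kernel Σᵢ λᵢ^{b−1} vᵢ⊗vᵢ."""
    lam = state.stretches
    V = state.eigvecs
    return (V * lam ** (b - 1.0)) @ V.T


def pk2_exp(state: DeformationState, b: float) -> np.ndarray:
    """Exponential (Fung-type) kernel exp(b·(II_C − 3))·C."""
    if b <= 0:
        raise ValueError("exponential rate b must be positive")
    _, II_C = invariants(state.C)
    return np.exp(b * (II_C - 3.0)) * state.C


def viscoelastic_kernel(model: str, state: DeformationState, b: float = 1.0) -> np.ndarray:
    """The PK2 kernel whose time history is fractionally differentiated.

    For ``vexp`` the deviatoric projection belongs *after* the fractional
    derivative and is therefore not applied here.
    """
    if model == "vmr":
        return pk2_mr1(state)
    if model == "vog":
        return pk2_ogden(state, b)
    if model == "vexp":
        return pk2_exp(state, b)
    raise ValueError(f"unknown model {model!r}; choose from {MODELS}")


def elastic_kernel(model: str, state: DeformationState) -> np.ndarray | None:
    """Purely elastic PK2 kernel, or None for models without one."""
    if model == "vmr":
        return pk2_mr2(state)
    if model in MODELS:
        return None
    raise ValueError(f"unknown model {model!r}; choose from {MODELS}")


def recover_wall_pressure(
    state: DeformationState, S_dev_total: np.ndarray, wall_normal: np.ndarray
) -> float:
    """Hydrostatic pressure from the traction-free lateral wall.

    With σ = F·(S_e + D_t^α S_v)·Fᵀ + J·P·I and zero normal traction on the
    wall, the normal-normal balance gives

        P = − nᵀ F (S_e + D_t^α S_v) Fᵀ n / J.

    Parameters
    ----------
    state : DeformationState on the wall.
    S_dev_total : combined elastic + fractionally differentiated
        viscoelastic PK2 (everything except the hydrostatic part).
    wall_normal : outward unit normal (any nonzero vector; normalised here).
    """
    n = np.asarray(wall_normal, dtype=float)
    nn = np.linalg.norm(n)
    if nn == 0:
        raise ValueError("wall normal must be nonzero")
    n = n / nn
    sig_dev = state.F @ np.asarray(S_dev_total, dtype=float) @ state.F.T
    return float(-(n @ sig_dev @ n) / state.J)
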