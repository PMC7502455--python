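"""Ideal compression + torsion kinematics of a cylindrical sample.

A cylindrical specimen of undeformed height ``H`` and radius ``R`` is
compressed between parallel plates to an axial stretch ``lam = 1 - cs``
(``cs`` is the compression strain) and then twisted sinusoidally about its
axis. Ideal, volume-preserving compression is assumed, so the deformed
height and radius are ``h = lam * H`` and ``r = R / sqrt(lam)``.

The top plate oscillates with angular displacement

    psi(t) = sin(2 pi f t) * h * gamma / r,

where ``gamma`` is the shear-strain amplitude (peak rotational displacement
of the top plate divided by the inter-plate gap). Interior cross-sections
rotate by ``Psi(t, X3) = psi(t) * X3 / H``, which makes the motion a
compression composed with a torsion whose deformation gradient has unit
determinant everywhere.

Conventions: the cylinder axis is the third coordinate axis; the reference
top surface sits at ``X3 = H`` and its image at ``x3 = h``. Material points
are parametrised by their *deformed* radial position ``r_x``, referential
azimuth ``theta0`` and referential height ``X3``. All quantities are SI.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

__all__ = [
    "SampleGeometry",
    "TestCondition",
    "MaterialPoint",
    "DeformationState",
    "angular_displacement",
    "motion_map",
    "deformation_gradient",
    "deformation_state",
    "invariants",
    "spectral",
]


@dataclass(frozen=True)
class SampleGeometry:
    """Cylinder dimensions and axial preload.

    Parameters
    ----------
    H, R : float
        Undeformed height and radius (m).
    cs : float
        Compression strain in [0, 1); the axial stretch is ``lam = 1 - cs``.
    """

    H: float
    R: float
    cs: float = 0.0

    def __post_init__(self) -> None:
        if self.H <= 0 or self.R <= 0:
            raise ValueError("sample dimensions must be positive")
        if not 0.0 <= self.cs < 1.0:
            raise ValueError(f"compression strain must lie in [0, 1), got {self.cs}")

    @property
    def lam(self) -> float:
        """Axial stretch λ = 1 − cs."""
        return 1.0 - self.cs

    @property
    def h(self) -> float:
        """Deformed height λ·H (m)."""
        return self.lam * self.H

    @property
    def r(self) -> float:
        """Deformed radius R/√λ (m); preserves the volume h·r² = H·R²."""
        return self.R / np.sqrt(self.lam)


@dataclass(frozen=True)
class TestCondition:
    """One loading cell of the oscillatory protocol.

    ``points_per_period`` fixes the time step ``dt = 1 / (freq *
    points_per_period)`` so simulated samples line up with rheometer
    readings. ``n_burnin`` oscillation cycles precede the ``n_record``
    cycles that are kept, mirroring experimental preconditioning.
    """

    geometry: SampleGeometry
    gamma: float
    freq: float
    points_per_period: int = 200
    n_burnin: int = 8
    n_record: int = 3

    def __post_init__(self) -> None:
        # gamma's sign encodes the twist direction; protocols use gamma >= 0
        if self.freq <= 0:
            raise ValueError("frequency must be positive")
        if self.points_per_period < 4:
            raise ValueError("need at least 4 points per period")
        if self.n_burnin < 0 or self.n_record < 1:
            raise ValueError("invalid cycle counts")

    @property
    def dt(self) -> float:
        return 1.0 / (self.freq * self.points_per_period)

    @property
    def n_samples(self) -> int:
        """Total samples over burn-in + recorded cycles (endpoint included)."""
        return (self.n_burnin + self.n_record) * self.points_per_period + 1

    @property
    def record_start(self) -> int:
        """Index of the first recorded sample."""
        return self.n_burnin * self.points_per_period

    def times(self) -> np.ndarray:
        return np.arange(self.n_samples) * self.dt


@dataclass(frozen=True)
class MaterialPoint:
    """A point of the sample, located by deformed radius, referential azimuth
    and referential height. The referential radius is ``r_x * sqrt(lam)``."""

    r_x: float
    theta0: float = 0.0
    X3: float = 0.0

    def referential_coords(self, geom: SampleGeometry) -> np.ndarray:
        R_x = self.r_x * np.sqrt(geom.lam)
        return np.array(
            [R_x * np.cos(self.theta0), R_x * np.sin(self.theta0), self.X3]
        )


def angular_displacement(cond: TestCondition, t):
    """Top-plate angular displacement ψ(t) = sin(2πft)·h·γ/r (rad).

    Accepts scalar or array times; the peak value is h·γ/r.
    """
    g = cond.geometry
    return np.sin(2.0 * np.pi * cond.freq * np.asarray(t)) * g.h * cond.gamma / g.r


def motion_map(X: np.ndarray, cond: TestCondition, t: float) -> np.ndarray:
    """Spatial position of referential point ``X`` at time ``t``.

    Compression scales the in-plane coordinates by 1/√λ and the axial one by
    λ; torsion rotates the cross-section at height X3 by Ψ(t, X3) = ψ(t)·X3/H.
    """
    g = cond.geometry
    lam = g.lam
    psi = angular_displacement(cond, t)
    Psi = psi * X[2] / g.H
    c, s = np.cos(Psi), np.sin(Psi)
    return np.array(
        [
            (X[0] * c - X[1] * s) / np.sqrt(lam),
            (X[0] * s + X[1] * c) / np.sqrt(lam),
            lam * X[2],
        ]
    )


def deformation_gradient(
    point: MaterialPoint, cond: TestCondition, t: float, top_surface: bool = False
) -> np.ndarray:
    """Deformation gradient F of the compression + torsion field.

    With θ(t) = θ0 + Ψ(t, X3) and ψ the top-plate angle,

        F = [[cosΨ/√λ, −sinΨ/√λ, −(ψ/H)·r_x·sinθ],
             [sinΨ/√λ,  cosΨ/√λ,  (ψ/H)·r_x·cosθ],
             [0,         0,        λ]]

    which has det F = 1 identically. ``top_surface=True`` evaluates the
    cross-section rotation at the top-plate angle (Ψ → ψ), the form used
    where torque is measured.
    """
    g = cond.geometry
    if point.r_x < 0 or point.r_x > g.r * (1 + 1e-12):
        raise ValueError(f"point at r_x={point.r_x} lies outside the sample (r={g.r})")
    lam = g.lam
    psi = angular_displacement(cond, t)
    Psi = psi if top_surface else psi * point.X3 / g.H
    theta = point.theta0 + Psi
    sq = np.sqrt(lam)
    cP, sP = np.cos(Psi), np.sin(Psi)
    ct, st = np.cos(theta), np.sin(theta)
    k = psi / g.H * point.r_x
    return np.array(
        [
            [cP / sq, -sP / sq, -k * st],
            [sP / sq, cP / sq, k * ct],
            [0.0, 0.0, lam],
        ]
    )


@dataclass(frozen=True)
class DeformationState:
    """Strain measures derived from a deformation gradient.

    Holds F, J = det F, the right/left Cauchy–Green tensors C = FᵀF and
    B = FFᵀ, their isochoric (J^{-2/3}-scaled) forms, and the spectral
    decomposition of C: principal stretches λᵢ (square roots of the
    eigenvalues of C) with orthonormal eigenvectors vᵢ.
    """

    F: np.ndarray
    J: float = field(init=False)
    C: np.ndarray = field(init=False)
    B: np.ndarray = field(init=False)
    C_iso: np.ndarray = field(init=False)
    B_iso: np.ndarray = field(init=False)
    stretches: np.ndarray = field(init=False)
    eigvecs: np.ndarray = field(init=False)

    def __post_init__(self) -> None:
        F = np.asarray(self.F, dtype=float)
        J = float(np.linalg.det(F))
        if J <= 0:
            raise ValueError("deformation gradient must have positive determinant")
        C = F.T @ F
        B = F @ F.T
        lam2, V = np.linalg.eigh(C)
        object.__setattr__(self, "F", F)
        object.__setattr__(self, "J", J)
        object.__setattr__(self, "C", C)
        object.__setattr__(self, "B", B)
        object.__setattr__(self, "C_iso", J ** (-2.0 / 3.0) * C)
        object.__setattr__(self, "B_iso", J ** (-2.0 / 3.0) * B)
        object.__setattr__(self, "stretches", np.sqrt(lam2))
        object.__setattr__(self, "eigvecs", V)


def deformation_state(F: np.ndarray) -> DeformationState:
    """Package a deformation gradient into the derived strain measures."""
    return DeformationState(F=F)


def invariants(A: np.ndarray) -> tuple[float, float]:
    """First and second invariants (trace, Frobenius double contraction A:A)."""
    A = np.asarray(A, dtype=float)
    if A.ndim != 2 or A.shape[0] != A.shape[1]:
        raise ValueError("invariants require a square tensor")
    return float(np.trace(A)), float(np.sum(A * A))


def spectral(C: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Principal stretches and eigenvectors of an SPD right Cauchy–Green C.

    Returns ``(stretches, V)`` with stretches λᵢ = √eigᵢ in ascending order
    and V[:, i] the corresponding orthonormal eigenvectors, so that
    ``sum_i stretches[i]**2 * outer(V[:,i], V[:,i])`` reconstructs C.
    """
    C = np.asarray(C, dtype=float)
    if C.ndim != 2 or C.shape[0] != C.shape[1]:
        raise ValueError("spectral decomposition requires a square tensor")
    if not np.allclose(C, C.T, rtol=1e-10, atol=1e-12):
        raise ValueError("tensor must be symmetric")
    eig, V = np.linalg.eigh(C)
    if eig[0] <= 0:
        raise ValueError("tensor must be positive definite")
    return np.sqrt(eig), V
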