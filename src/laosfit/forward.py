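"""Forward simulation of one LAOS test: stress assembly and plate torque.

A test is simulated on the deformed top surface of the sample (where the
rheometer measures torque): for every spatial integration point the
deformation history over burn-in + recorded cycles is built, the model's
PK2 kernels are evaluated along it, the viscoelastic kernel is passed
through the Caputo derivative over the *full* history (so fractional
memory crosses the recording boundary), stresses are pushed forward to
Cauchy form, and the axial torque

    τ₃ = ∫_{Γ_t} r₁σ₂₃ − r₂σ₁₃ dΓ

is integrated over the deformed top disc of radius r. The hydrostatic
part JP·I has no 13/23 components and never contributes to τ₃, so the
pressure is not needed here.

Two integration rules are provided. The default exploits axisymmetry —
the torque integrand depends only on the deformed radius — and reduces
τ₃ to a 1-D Gauss–Legendre quadrature, τ₃ = 2π ∫₀^r ρ² σ₂₃(ρ) dρ. A
765-element triangulated disc (85 sectors × 5 rings, centroid rule) is
provided as an independent cross-check.

Torque components are returned at *unit* linear parameters: ``tau_e`` is
the torque of the elastic kernel at C = 1 Pa (vmr only) and ``tau_v`` the
torque of the fractionally differentiated kernel at δ = 1 Pa, so the
measured torque model is τ = C·tau_e + δ·tau_v. This linearity is what
the fitting stage exploits.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .constitutive import MODELS, MaterialParameters
from .fractional import caputo_derivative
from .kinematics import TestCondition, angular_displacement

__all__ = [
    "SurfaceMesh",
    "TorqueTrace",
    "ForwardOperator",
    "cauchy_from_pk2",
    "torque_integrand",
    "integrate_torque",
    "simulate_test",
]


@dataclass(frozen=True)
class SurfaceMesh:
    """Integration rule over the deformed top disc of radius ``radius``.

    Nodes are material points of the top surface given by deformed radius
    ``r_x`` and referential azimuth ``theta0``; ``weights`` are their area
    weights and sum to the disc area πr².
    """

    mode: str
    radius: float
    r_x: np.ndarray
    theta0: np.ndarray
    weights: np.ndarray

    @classmethod
    def radial(cls, radius: float, order: int = 16) -> "SurfaceMesh":
        """Axisymmetric rule: Gauss–Legendre in radius, exact in azimuth."""
        nodes, w = np.polynomial.legendre.leggauss(order)
        rho = 0.5 * radius * (nodes + 1.0)
        w = 0.5 * radius * w
        return cls(
            mode="radial",
            radius=radius,
            r_x=rho,
            theta0=np.zeros(order),
            weights=2.0 * np.pi * rho * w,
        )

    @classmethod
    def triangulated(
        cls, radius: float, n_sectors: int = 153, n_rings: int = 3
    ) -> "SurfaceMesh":
        """Triangulated disc; 153 sectors × 3 rings gives 765 elements.

        Each flat triangle is integrated with the three-edge-midpoint rule
        (exact for quadratics), so the residual error is set by the
        polygon-versus-disc geometry alone.
        """
        ring_r = np.linspace(0.0, radius, n_rings + 1)
        thetas = np.linspace(0.0, 2.0 * np.pi, n_sectors + 1)
        px, py, wts = [], [], []

        def tri(p0, p1, p2):
            area = 0.5 * abs(
                (p1[0] - p0[0]) * (p2[1] - p0[1])
                - (p2[0] - p0[0]) * (p1[1] - p0[1])
            )
            for a, b in ((p0, p1), (p1, p2), (p0, p2)):
                px.append(0.5 * (a[0] + b[0]))
                py.append(0.5 * (a[1] + b[1]))
                wts.append(area / 3.0)

        def node(rho, th):
            return (rho * np.cos(th), rho * np.sin(th))

        for j in range(n_sectors):
            t0, t1 = thetas[j], thetas[j + 1]
            # inner fan
            tri((0.0, 0.0), node(ring_r[1], t0), node(ring_r[1], t1))
            # annular strips, two triangles per quad
            for i in range(1, n_rings):
                a, b = ring_r[i], ring_r[i + 1]
                p00, p01 = node(a, t0), node(a, t1)
                p10, p11 = node(b, t0), node(b, t1)
                tri(p00, p10, p11)
                tri(p00, p11, p01)

        px = np.asarray(px)
        py = np.asarray(py)
        return cls(
            mode="triangulated",
            radius=radius,
            r_x=np.hypot(px, py),
            theta0=np.arctan2(py, px),
            weights=np.asarray(wts),
        )

    @property
    def n_points(self) -> int:
        return self.r_x.size

    def positions(self, psi: float = 0.0) -> np.ndarray:
        """Deformed in-plane node positions (P, 2) at top-plate angle ψ."""
        th = self.theta0 + psi
        return np.stack([self.r_x * np.cos(th), self.r_x * np.sin(th)], axis=-1)


@dataclass
class TorqueTrace:
    """Recorded (post burn-in) time series of one test.

    ``tau_e``/``tau_v`` are the unit-parameter torque components where
    applicable; ``tau`` is the combined (or measured) torque in N·m.
    """

    cond: TestCondition
    t: np.ndarray
    angle: np.ndarray
    tau: np.ndarray
    tau_e: np.ndarray | None = None
    tau_v: np.ndarray | None = None

    def __post_init__(self) -> None:
        n = len(self.t)
        for name in ("angle", "tau", "tau_e", "tau_v"):
            v = getattr(self, name)
            if v is not None and len(v) != n:
                raise ValueError(f"{name} length {len(v)} != time length {n}")


def cauchy_from_pk2(F: np.ndarray, S: np.ndarray, J: float = 1.0) -> np.ndarray:
    """Push a PK2 tensor to Cauchy stress, σ = (1/J)·F·S·Fᵀ."""
    if J <= 0:
        raise ValueError("J must be positive")
    F = np.asarray(F, dtype=float)
    S = np.asarray(S, dtype=float)
    return np.einsum("...ik,...kl,...jl->...ij", F, S, F) / J


def torque_integrand(sigma: np.ndarray, position) -> float:
    """Axial torque density r₁σ₂₃ − r₂σ₁₃ at a point of the top surface."""
    sigma = np.asarray(sigma, dtype=float)
    r1, r2 = position[..., 0], position[..., 1]
    return r1 * sigma[..., 1, 2] - r2 * sigma[..., 0, 2]


def integrate_torque(mesh: SurfaceMesh, sigma: np.ndarray, psi: float = 0.0) -> float:
    """Integrate the torque density of Cauchy stresses sampled at mesh nodes.

    ``sigma`` has shape (P, 3, 3) with P = mesh.n_points, evaluated at the
    node positions for top-plate angle ``psi``.
    """
    if mesh.n_points == 0:
        raise ValueError("empty mesh")
    vals = torque_integrand(sigma, mesh.positions(psi))
    return float(mesh.weights @ vals)


class ForwardOperator:
    """Per-test forward simulator with cached deformation history.

    Builds the top-surface deformation gradients F(t_k, ρ_p) once and then
    serves unit-parameter torque columns for any (model, α, b) — the
    expensive kinematic and spectral quantities are shared across the
    fitting sweep.
    """

    def __init__(self, cond: TestCondition, mesh: SurfaceMesh | None = None):
        self.cond = cond
        self.mesh = mesh if mesh is not None else SurfaceMesh.radial(cond.geometry.r)
        if self.mesh.radius <= 0:
            raise ValueError("mesh radius must be positive")
        self._build_history()
        self._eig_cache: tuple[np.ndarray, np.ndarray] | None = None

    def _build_history(self) -> None:
        cond, mesh = self.cond, self.mesh
        g = cond.geometry
        lam, sq = g.lam, np.sqrt(g.lam)
        t = cond.times()
        psi = angular_displacement(cond, t)  # (n,)
        n, P = t.size, mesh.n_points

        th = psi[:, None] + mesh.theta0[None, :]  # deformed azimuth (n, P)
        k = psi[:, None] / g.H * mesh.r_x[None, :]

        F = np.zeros((n, P, 3, 3))
        F[..., 0, 0] = np.cos(psi)[:, None] / sq
        F[..., 0, 1] = -np.sin(psi)[:, None] / sq
        F[..., 1, 0] = np.sin(psi)[:, None] / sq
        F[..., 1, 1] = np.cos(psi)[:, None] / sq
        F[..., 0, 2] = -k * np.sin(th)
        F[..., 1, 2] = k * np.cos(th)
        F[..., 2, 2] = lam

        C = np.einsum("...ki,...kj->...ij", F, F)
        self.t = t
        self.psi = psi
        self.F = F
        self.C = C
        self.Cinv = np.linalg.inv(C)
        self.I_C = np.trace(C, axis1=-2, axis2=-1)
        self.II_C = np.sum(C * C, axis=(-2, -1))
        # deformed in-plane lever arms of each node over time
        self.x1 = mesh.r_x[None, :] * np.cos(th)
        self.x2 = mesh.r_x[None, :] * np.sin(th)
        # torque is linear in the PK2 history: tau(t) = sum_pij M_tpij S_tpij
        # with M folding the push-forward, lever arms and area weights
        a = self.x1[..., None] * F[..., 1, :] - self.x2[..., None] * F[..., 0, :]
        self._M = (
            mesh.weights[None, :, None, None]
            * a[..., :, None]
            * F[..., 2, :][..., None, :]
        )
        self._sl = slice(cond.record_start, None)

    # -- kernel histories ---------------------------------------------------

    def _eig(self) -> tuple[np.ndarray, np.ndarray]:
        if self._eig_cache is None:
            self._eig_cache = np.linalg.eigh(self.C)
        return self._eig_cache

    def _kernel_history(self, model: str, b: float) -> np.ndarray:
        if model == "vmr":
            I3 = np.broadcast_to(np.eye(3), self.C.shape)
            return I3 - (self.I_C / 3.0)[..., None, None] * self.Cinv
        if model == "vog":
            eig, V = self._eig()
            w = np.sqrt(eig) ** (b - 1.0)
            return np.einsum("...ik,...k,...jk->...ij", V, w, V)
        if model == "vexp":
            return np.exp(b * (self.II_C - 3.0))[..., None, None] * self.C
        raise ValueError(f"unknown model {model!r}; choose from {MODELS}")

    def _elastic_history(self, model: str) -> np.ndarray | None:
        if model != "vmr":
            return None
        pref = self.II_C - 3.0  # J = 1, so II of C and of its isochoric form agree
        return pref[..., None, None] * (
            self.C - (self.II_C / 3.0)[..., None, None] * self.Cinv
        )

    # -- torque assembly ----------------------------------------------------

    def _torque_of_pk2(self, S: np.ndarray) -> np.ndarray:
        """Torque time series of a PK2 history (precomputed linear map)."""
        return np.einsum("tpij,tpij->t", self._M, S, optimize=True)

    def unit_torque_columns(
        self, model: str, alpha: float, b: float = 1.0
    ) -> tuple[np.ndarray | None, np.ndarray]:
        """(tau_e, tau_v) at unit linear parameters over the recorded window."""
        Sv = self._kernel_history(model, b)
        DSv = caputo_derivative(Sv, alpha, self.cond.dt)
        if model == "vexp":
            # deviatoric split applied after the time derivative, with C at
            # the evaluation time
            contr = np.sum(DSv * self.C, axis=(-2, -1))
            DSv = DSv - (contr / 3.0)[..., None, None] * self.Cinv
        tau_v = self._torque_of_pk2(DSv)[self._sl]
        Se = self._elastic_history(model)
        tau_e = self._torque_of_pk2(Se)[self._sl] if Se is not None else None
        return tau_e, tau_v

    @property
    def recorded_times(self) -> np.ndarray:
        return self.t[self._sl]

    @property
    def recorded_angle(self) -> np.ndarray:
        return self.psi[self._sl]


def simulate_test(
    params: MaterialParameters,
    cond: TestCondition,
    mesh: SurfaceMesh | None = None,
) -> TorqueTrace:
    """Simulate one oscillatory test and return the recorded torque trace.

    Burn-in cycles are simulated (the fractional memory spans them) but
    excluded from the returned series.
    """
    op = ForwardOperator(cond, mesh)
    tau_e, tau_v = op.unit_torque_columns(params.model, params.alpha, params.b)
    tau = params.delta * tau_v
    if tau_e is not None:
        tau = tau + params.C_lin * tau_e
    return TorqueTrace(
        cond=cond,
        t=op.recorded_times,
        angle=op.recorded_angle,
        tau=tau,
        tau_e=tau_e,
        tau_v=tau_v,
    )
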