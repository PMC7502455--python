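"""Material identification: nonlinear-parameter sweep + nonnegative LSQ.

The torque model is linear in the material scales (C, δ) and nonlinear in
the fractional order α and the power b. Identification therefore sweeps
(α, b) over a grid and, at each node, solves for the linear parameters by
nonnegative least squares on the unit-parameter torque columns, scoring
the fit with one of three norms. All norms are calibrated to read 0% for
a perfect fit and exactly 100% when the linear parameters are zeroed.

L2 norm
    ‖Ax − b‖₂ / ‖b‖₂ over all tests stacked; dominated by the
    high-amplitude (large-strain) tests.

Point-wise norm
    Every residual sample is scaled by its own data amplitude
    max(tol, |b_k|) before the L2 reduction, so each point carries equal
    weight and curve *shape* is matched irrespective of amplitude. ``tol``
    guards near-zero crossings (default 1e-3 of each test's peak torque).

Parameter-scaling norm
    Nonlinear parameters are shared across the N tests while each test's
    linear amplitudes float through a positive per-test scaling β_i
    (x_i = x*/β_i) — accommodating sample-to-sample variability and
    strain softening without changing curve shape. Solved by alternating
    a stacked nonnegative LSQ for x* (β fixed) with the closed-form
    per-test update β_i = (b_i*ᵀ A_i* x*) / (b_i*ᵀ b_i*), iterated from
    β_i = 1 until the error stops changing. Blocks are pre-normalised by
    n_i·‖τ_i^d‖₂ so every test contributes comparably.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd
from scipy.optimize import nnls

from .forward import ForwardOperator, SurfaceMesh, TorqueTrace

__all__ = [
    "DesignSystem",
    "ScalingState",
    "FitResult",
    "solve_linear_nonneg",
    "norm_l2",
    "norm_pointwise",
    "norm_scaling",
    "fit_parameter_scaling",
    "sweep_fit",
    "default_alpha_grid",
    "default_b_grid",
]

NORMS = ("l2", "pointwise", "scaling")


@dataclass(frozen=True)
class DesignSystem:
    """Per-test unit-torque column blocks A_i and data vectors b_i."""

    A_blocks: list[np.ndarray]
    b_blocks: list[np.ndarray]

    def __post_init__(self) -> None:
        if len(self.A_blocks) != len(self.b_blocks) or not self.A_blocks:
            raise ValueError("need matching, nonempty A and b block lists")
        m = self.A_blocks[0].shape[1]
        for A, b in zip(self.A_blocks, self.b_blocks):
            if A.shape[0] != b.shape[0]:
                raise ValueError("row counts of A_i and b_i must match")
            if A.shape[1] != m:
                raise ValueError("all blocks must share the column count")

    @property
    def n_tests(self) -> int:
        return len(self.A_blocks)

    @property
    def n_linear(self) -> int:
        return self.A_blocks[0].shape[1]

    def stacked(self) -> tuple[np.ndarray, np.ndarray]:
        return np.vstack(self.A_blocks), np.concatenate(self.b_blocks)


@dataclass(frozen=True)
class ScalingState:
    """Converged parameter-scaling solution.

    ``x_star`` are the shared (gauge-fixed, mean(β) = 1) linear parameters;
    ``beta`` the per-test scalings; the reported absolute per-test
    parameters are x_i = x*/β_i.
    """

    x_star: np.ndarray
    beta: np.ndarray
    error: float  # percent
    n_iter: int

    @property
    def x_per_test(self) -> np.ndarray:
        return self.x_star[None, :] / self.beta[:, None]


def solve_linear_nonneg(A: np.ndarray, b: np.ndarray) -> np.ndarray:
    """argmin ‖Ax − b‖₂ subject to x ≥ 0."""
    A = np.atleast_2d(np.asarray(A, dtype=float))
    b = np.asarray(b, dtype=float).ravel()
    if A.size == 0 or b.size == 0:
        raise ValueError("empty linear system")
    x, _ = nnls(A, b)
    return x


def norm_l2(A: np.ndarray, x: np.ndarray, b: np.ndarray) -> float:
    """Relative L2 residual ‖Ax − b‖₂/‖b‖₂ in percent."""
    b = np.asarray(b, dtype=float).ravel()
    r = np.atleast_2d(A) @ np.asarray(x, dtype=float) - b
    return 100.0 * float(np.linalg.norm(r) / np.linalg.norm(b))


def _pw_scales(b_blocks: Sequence[np.ndarray], tol: float | Sequence[float]) -> list[np.ndarray]:
    tols = np.broadcast_to(np.asarray(tol, dtype=float), (len(b_blocks),))
    if np.any(tols <= 0):
        raise ValueError("point-wise tolerance must be positive")
    return [np.maximum(t, np.abs(b)) for b, t in zip(b_blocks, tols)]


def norm_pointwise(
    A_blocks: Sequence[np.ndarray],
    x: np.ndarray,
    b_blocks: Sequence[np.ndarray],
    tol: float | Sequence[float],
) -> float:
    """Amplitude-normalised residual norm in percent.

    Each sample's residual is divided by max(tol, |b_k|); the reduction is
    then a ratio of root-sum-squares, so zero linear parameters give
    exactly 100%.
    """
    scales = _pw_scales(b_blocks, tol)
    num = den = 0.0
    for A, b, s in zip(A_blocks, b_blocks, scales):
        r = np.atleast_2d(A) @ np.asarray(x, dtype=float) - b
        num += float(np.sum((r / s) ** 2))
        den += float(np.sum((b / s) ** 2))
    return 100.0 * np.sqrt(num / den)


def _normalise_blocks(
    A_blocks: Sequence[np.ndarray], b_blocks: Sequence[np.ndarray]
) -> tuple[list[np.ndarray], list[np.ndarray]]:
    A_star, b_star = [], []
    for A, b in zip(A_blocks, b_blocks):
        nrm = np.linalg.norm(b)
        if nrm == 0:
            raise ValueError("all-zero data block: per-test scaling undefined")
        s = b.size * nrm
        A_star.append(np.atleast_2d(A) / s)
        b_star.append(b / s)
    return A_star, b_star


def norm_scaling(
    A_blocks: Sequence[np.ndarray],
    x_star: np.ndarray,
    beta: np.ndarray,
    b_blocks: Sequence[np.ndarray],
) -> float:
    """Parameter-scaling error at a given (x*, β), in percent."""
    A_star, b_star = _normalise_blocks(A_blocks, b_blocks)
    x_star = np.asarray(x_star, dtype=float)
    num = sum(
        float(np.sum((A @ (x_star / be) - b) ** 2))
        for A, b, be in zip(A_star, b_star, beta)
    )
    den = sum(float(np.sum(b**2)) for b in b_star)
    return 100.0 * np.sqrt(num / den)


def fit_parameter_scaling(
    A_blocks: Sequence[np.ndarray],
    b_blocks: Sequence[np.ndarray],
    rtol: float = 1e-10,
    max_iter: int = 200,
) -> ScalingState:
    """Alternating solve for shared x* and per-test scalings β.

    Starts from β_i = 1 and alternates (i) a stacked nonnegative LSQ for
    x* with β fixed (test i's columns scaled by 1/β_i) and (ii) the
    closed-form β_i update, until the relative change of the error drops
    below ``rtol`` or ``max_iter`` sweeps. A β update that would turn
    nonpositive (degenerate, anti-correlated data) is skipped, freezing
    that test's previous scaling. On return β is gauge-fixed to mean 1.
    """
    A_star, b_star = _normalise_blocks(A_blocks, b_blocks)
    N = len(A_star)
    beta = np.ones(N)
    x_star = np.zeros(A_star[0].shape[1])
    err_prev = np.inf
    n_iter = 0
    for n_iter in range(1, max_iter + 1):
        A_sc = np.vstack([A / be for A, be in zip(A_star, beta)])
        x_star = solve_linear_nonneg(A_sc, np.concatenate(b_star))
        for i in range(N):
            num = float(b_star[i] @ (A_star[i] @ x_star))
            den = float(b_star[i] @ b_star[i])
            cand = num / den
            if cand > 0:
                beta[i] = cand
        err = norm_scaling(A_blocks, x_star, beta, b_blocks)
        if abs(err_prev - err) <= rtol * max(err_prev, 1e-300):
            err_prev = err
            break
        err_prev = err
    mean_beta = float(np.mean(beta))
    return ScalingState(
        x_star=x_star / mean_beta, beta=beta / mean_beta, error=err_prev, n_iter=n_iter
    )


@dataclass
class FitResult:
    """Outcome of a nonlinear-parameter sweep."""

    model: str
    norm: str
    alpha: float
    b: float
    x: np.ndarray | None  # global linear parameters (l2 / pointwise)
    scaling: ScalingState | None  # scaling norm solution
    error: float  # percent, at the argmin node
    surface: pd.DataFrame = field(repr=False)  # columns: alpha, b, error

    @property
    def linear_parameters(self) -> np.ndarray:
        if self.x is not None:
            return self.x
        assert self.scaling is not None
        return self.scaling.x_star


def default_alpha_grid() -> np.ndarray:
    """Coarse 0.05-step sweep of α over (0, 1] refined to 0.01 in [0.15, 0.4]."""
    coarse = np.arange(0.05, 1.0 + 1e-12, 0.05)
    fine = np.arange(0.15, 0.40 + 1e-12, 0.01)
    return np.unique(np.round(np.concatenate([coarse, fine]), 10))


def default_b_grid(model: str) -> np.ndarray:
    """Default power grids: [1, 14] step 0.5 (vog); [1, 1.5] step 0.1 (vexp)."""
    if model == "vog":
        return np.round(np.arange(1.0, 14.0 + 1e-12, 0.5), 10)
    if model == "vexp":
        return np.round(np.arange(1.0, 1.5 + 1e-12, 0.1), 10)
    return np.array([1.0])


def sweep_fit(
    traces: Sequence[TorqueTrace],
    model: str,
    norm: str = "l2",
    alpha_grid: Sequence[float] | None = None,
    b_grid: Sequence[float] | None = None,
    mesh_order: int = 16,
    pw_tol_frac: float = 1e-3,
) -> FitResult:
    """Fit one model to a set of torque traces by grid sweep.

    Per (α, b) node the unit-parameter torque columns are simulated for
    every test, the linear parameters solved under ``norm``, and the node
    error recorded; the argmin node is returned together with the full
    error surface. Grid ties resolve to the smallest α, then smallest b.
    """
    if norm not in NORMS:
        raise ValueError(f"unknown norm {norm!r}; choose from {NORMS}")
    if not traces:
        raise ValueError("no traces to fit")
    alphas = np.asarray(
        default_alpha_grid() if alpha_grid is None else alpha_grid, dtype=float
    )
    bs = np.asarray(default_b_grid(model) if b_grid is None else b_grid, dtype=float)
    if alphas.size == 0 or bs.size == 0:
        raise ValueError("empty sweep grid")
    alphas = np.sort(alphas)
    bs = np.sort(bs)

    ops = [
        ForwardOperator(tr.cond, SurfaceMesh.radial(tr.cond.geometry.r, mesh_order))
        for tr in traces
    ]
    b_blocks = [np.asarray(tr.tau, dtype=float) for tr in traces]
    pw_tol = [pw_tol_frac * np.max(np.abs(b)) for b in b_blocks]

    rows = []
    best = None
    for b_val in bs:
        for a_val in alphas:
            A_blocks = []
            for op in ops:
                tau_e, tau_v = op.unit_torque_columns(model, a_val, b_val)
                cols = [tau_v] if tau_e is None else [tau_e, tau_v]
                A_blocks.append(np.stack(cols, axis=1))
            x = scal = None
            if norm == "l2":
                A, b = np.vstack(A_blocks), np.concatenate(b_blocks)
                x = solve_linear_nonneg(A, b)
                err = norm_l2(A, x, b)
            elif norm == "pointwise":
                scales = _pw_scales(b_blocks, pw_tol)
                Aw = np.vstack([A / s[:, None] for A, s in zip(A_blocks, scales)])
                bw = np.concatenate([b / s for b, s in zip(b_blocks, scales)])
                x = solve_linear_nonneg(Aw, bw)
                err = norm_pointwise(A_blocks, x, b_blocks, pw_tol)
            else:
                scal = fit_parameter_scaling(A_blocks, b_blocks)
                err = scal.error
            rows.append((a_val, b_val, err))
            # lexicographic: ties in error resolve to smallest alpha, then b
            node = (err, a_val, b_val)
            if best is None or node < best[0]:
                best = (node, x, scal)
    assert best is not None
    (err, a_best, b_best), x_best, scal_best = best
    surface = pd.DataFrame(rows, columns=["alpha", "b", "error"])
    return FitResult(
        model=model,
        norm=norm,
        alpha=float(a_best),
        b=float(b_best),
        x=x_best,
        scaling=scal_best,
        error=float(err),
        surface=surface,
    )
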