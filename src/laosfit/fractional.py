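"""Caputo fractional derivative of sampled histories on a uniform grid.

The Caputo derivative of order α ∈ (0, 1),

    D^α f(t) = 1/Γ(1−α) ∫₀ᵗ (t−z)^{−α} f'(z) dz,

is discretised with the L1 scheme: ``f`` is taken piecewise linear between
samples, which turns the memory integral at t_k into a convolution of the
increments f_{j+1} − f_j with weights

    w_ℓ = dt^{−α} / Γ(2−α) · ((ℓ+1)^{1−α} − ℓ^{1−α}),   ℓ = k−1−j,

positive and decaying in lag. The scheme is exact for linear histories and
O(dt^{2−α}) accurate otherwise. The full history is retained (no
short-memory truncation); the convolution is evaluated by FFT, so a
history of n samples costs O(n log n) per tensor component.

Edge orders: α = 0 returns the history unchanged (a hyperelastic,
memory-free response — not the literal Caputo limit f(t) − f(0)); α = 1
returns the backward difference (f_k − f_{k−1})/dt (purely viscous).

The memory starts at t = 0, understood as the instant the static
compression preload is in place; the preload ramp itself is not part of
the history, so a history held at its initial value has zero derivative.
"""

from __future__ import annotations

import numpy as np
from scipy.signal import fftconvolve
from scipy.special import gamma as _gamma

__all__ = [
    "caputo_weights",
    "caputo_derivative",
    "steady_state_reference",
    "power_law_decay_time",
]


def caputo_weights(alpha: float, n: int, dt: float) -> np.ndarray:
    """L1 convolution weights w_0..w_{n-1} for order ``alpha`` on step ``dt``.

    ``D^α f(t_k) = Σ_{j<k} w_{k−1−j}·(f_{j+1} − f_j)``. The first weight is
    dt^{−α}/Γ(2−α); weights decay like (1−α)·ℓ^{−α}.
    """
    if not 0.0 < alpha < 1.0:
        raise ValueError("L1 weights are defined for 0 < alpha < 1")
    if dt <= 0:
        raise ValueError("time step must be positive")
    ell = np.arange(n, dtype=float)
    return dt ** (-alpha) / _gamma(2.0 - alpha) * (
        (ell + 1.0) ** (1.0 - alpha) - ell ** (1.0 - alpha)
    )


def caputo_derivative(values: np.ndarray, alpha: float, dt: float) -> np.ndarray:
    """Componentwise Caputo derivative of a sampled history.

    Parameters
    ----------
    values : ndarray
        History sampled at t_k = k·dt along axis 0; trailing axes are
        treated componentwise (scalars, vectors or tensors).
    alpha : float
        Fractional order in [0, 1] inclusive (see module notes on 0 and 1).
    dt : float
        Uniform time step.

    Returns
    -------
    ndarray of the same shape; the output at t_0 is zero (for 0 < α ≤ 1).
    """
    f = np.asarray(values, dtype=float)
    if f.shape[0] == 0:
        raise ValueError("history must be nonempty")
    if alpha == 0.0:
        return f.copy()
    out = np.zeros_like(f)
    if f.shape[0] == 1:
        return out
    incr = np.diff(f, axis=0)
    if alpha == 1.0:
        out[1:] = incr / dt
        return out
    w = caputo_weights(alpha, f.shape[0] - 1, dt)
    w = w.reshape((-1,) + (1,) * (f.ndim - 1))
    out[1:] = fftconvolve(incr, w, axes=0)[: f.shape[0] - 1]
    return out


def steady_state_reference(omega: float, alpha: float) -> tuple[float, float]:
    """Steady-state gain and phase of D^α acting on sin(ωt): (ω^α, απ/2).

    This is the fractional operator's harmonic response — the origin of the
    G* ∝ ω^α frequency scaling seen in soft-tissue rheometry.
    """
    if omega <= 0:
        raise ValueError("omega must be positive")
    return omega**alpha, alpha * np.pi / 2.0


def power_law_decay_time(alpha: float, fraction: float = 0.01) -> float:
    """Time for a t^{−α} power-law relaxation to decay to ``fraction`` of peak.

    Solves F_max·t^{−α} = fraction·F_max, i.e. t = fraction^{−1/α}. For
    α = 0.2 and a 1% threshold this is 1e10 s (~317 years) — the reason a
    single fractional viscoelastic term behaves as quasi-elastic on any
    experimental time scale.
    """
    if not 0.0 < alpha <= 1.0:
        raise ValueError("alpha must lie in (0, 1]")
    if not 0.0 < fraction < 1.0:
        raise ValueError("fraction must lie in (0, 1)")
    return fraction ** (-1.0 / alpha)
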