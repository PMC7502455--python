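"""Ground-truth-known synthetic rheometer datasets.

Emulates the statistical structure of a combined compression + LAOS study
on cylindrical liver samples (nominally 10 mm radius × 3 mm height):

* the 18-test protocol — compression strains {1, 10, 20}% crossed with
  shear strains {1, 10, 25, 50}% at 1 Hz, plus shear strains {1, 10, 25}%
  at 10% compression for 0.5 and 2 Hz;
* the fractional phase delay and non-sinusoidal (higher-harmonic) torque
  produced by the forward model;
* per-test strain softening, modelled as a shape-preserving amplitude
  scaling: test i is generated with linear parameters x_i = x_true/β_i,
  with β_i growing with shear-strain amplitude so the apparent stiffness
  falls as the tissue is sheared harder;
* additive Gaussian measurement noise, with standard deviation expressed
  as a fraction of each test's peak torque.

Datasets are deterministic given the seed; the manifest records
everything needed to regenerate them bit-exactly.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np

from .constitutive import MaterialParameters
from .forward import SurfaceMesh, TorqueTrace, simulate_test
from .kinematics import SampleGeometry, TestCondition

__all__ = [
    "SyntheticStudyConfig",
    "SyntheticDataset",
    "default_protocol",
    "softening_schedule",
    "generate_dataset",
]

DEFAULT_HEIGHT = 3e-3  # m
DEFAULT_RADIUS = 10e-3  # m


def default_protocol(
    H: float = DEFAULT_HEIGHT,
    R: float = DEFAULT_RADIUS,
    points_per_period: int = 200,
    n_burnin: int = 8,
    n_record: int = 3,
) -> list[TestCondition]:
    """The 18-test loading protocol.

    12 tests at 1 Hz (CS {1,10,20}% × SS {1,10,25,50}%) plus the
    CS 10% / SS {1,10,25}% cells repeated at 0.5 Hz and 2 Hz.
    """
    conds = []

    def add(cs, ss, f):
        conds.append(
            TestCondition(
                geometry=SampleGeometry(H=H, R=R, cs=cs),
                gamma=ss,
                freq=f,
                points_per_period=points_per_period,
                n_burnin=n_burnin,
                n_record=n_record,
            )
        )

    for cs in (0.01, 0.10, 0.20):
        for ss in (0.01, 0.10, 0.25, 0.50):
            add(cs, ss, 1.0)
    for f in (0.5, 2.0):
        for ss in (0.01, 0.10, 0.25):
            add(0.10, ss, f)
    return conds


def softening_schedule(
    kind: str,
    protocol: list[TestCondition],
    custom: dict[int, float] | None = None,
    span: float = 2.0,
) -> np.ndarray:
    """Per-test amplitude scalings β_i (> 0), indexed like ``protocol``.

    ``none``
        β_i = 1 everywhere (no softening).
    ``linear-in-gamma``
        β rises linearly with shear-strain amplitude from 1 at the
        smallest γ of the protocol to ``span`` at the largest, so the
        absolute linear parameters x_i = x_true/β_i fall ``span``-fold
        across the shear sweep — the qualitative strain-softening trend.
    ``custom``
        β taken from ``custom`` (mapping test index → β).
    """
    n = len(protocol)
    if kind == "none":
        return np.ones(n)
    if kind == "linear-in-gamma":
        gammas = np.array([c.gamma for c in protocol])
        lo, hi = gammas.min(), gammas.max()
        if hi == lo:
            return np.ones(n)
        return 1.0 + (span - 1.0) * (gammas - lo) / (hi - lo)
    if kind == "custom":
        if custom is None:
            raise ValueError("custom softening requires an explicit map")
        beta = np.array([custom[i] for i in range(n)], dtype=float)
        if np.any(beta <= 0):
            raise ValueError("softening scalings must be positive")
        return beta
    raise ValueError(f"unknown softening kind {kind!r}")


@dataclass(frozen=True)
class SyntheticStudyConfig:
    """Recipe for one synthetic study."""

    true_params: MaterialParameters
    protocol: list[TestCondition] = field(default_factory=default_protocol)
    softening: str = "none"
    softening_span: float = 2.0
    noise_sd: float = 0.0  # fraction of each test's peak torque
    seed: int = 0
    mesh_order: int = 16

    def __post_init__(self) -> None:
        if not self.protocol:
            raise ValueError("protocol must be nonempty")
        if self.noise_sd < 0:
            raise ValueError("noise level must be nonnegative")


@dataclass
class SyntheticDataset:
    """Generated traces plus the manifest that regenerates them."""

    traces: list[TorqueTrace]
    beta: np.ndarray
    manifest: dict

    @property
    def conditions(self) -> list[TestCondition]:
        return [tr.cond for tr in self.traces]


def generate_dataset(config: SyntheticStudyConfig) -> SyntheticDataset:
    """Simulate the configured protocol with softening and noise.

    Each test is simulated with the true parameters' linear scales divided
    by its softening factor β_i; i.i.d. Gaussian noise with standard
    deviation ``noise_sd × max|τ|`` of that test is then added. The result
    is bit-reproducible for a fixed config (the RNG is seeded per study).
    """
    p = config.true_params
    beta = softening_schedule(
        config.softening, config.protocol, span=config.softening_span
    )
    rng = np.random.default_rng(config.seed)
    traces = []
    for cond, b_i in zip(config.protocol, beta):
        params_i = replace(p, delta=p.delta / b_i, C_lin=p.C_lin / b_i)
        mesh = SurfaceMesh.radial(cond.geometry.r, config.mesh_order)
        tr = simulate_test(params_i, cond, mesh)
        if config.noise_sd > 0:
            amp = float(np.max(np.abs(tr.tau)))
            tr.tau = tr.tau + rng.normal(0.0, config.noise_sd * amp, size=tr.tau.shape)
        traces.append(tr)
    manifest = {
        "model": p.model,
        "alpha": p.alpha,
        "b": p.b,
        "delta_pa": p.delta,
        "C_lin_pa": p.C_lin,
        "softening": config.softening,
        "softening_span": config.softening_span,
        "beta": beta.tolist(),
        "noise_sd": config.noise_sd,
        "seed": config.seed,
        "mesh_order": config.mesh_order,
        "n_tests": len(config.protocol),
    }
    return SyntheticDataset(traces=traces, beta=beta, manifest=manifest)
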