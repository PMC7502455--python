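"""Trace files, fit reports and dataset directories.

A torque trace is stored as a CSV with columns ``time_s, angle_rad,
torque_Nm`` plus a JSON sidecar (same stem, ``.json``) carrying the test
metadata: ``cs_percent, shear_percent, freq_hz, height_m, radius_m,
points_per_period, n_burnin, n_record``. Values are written at full repr
precision so a write/read round trip is lossless and deterministic.

Fit reports are JSON documents describing the model, norm, grid, argmin
node, linear parameters and error; the error surface is exported
alongside as a CSV for plotting.
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import pandas as pd

from .fitting import FitResult
from .forward import TorqueTrace
from .kinematics import SampleGeometry, TestCondition
from .synthetic import SyntheticDataset

__all__ = [
    "write_trace",
    "read_trace",
    "write_dataset",
    "read_dataset",
    "write_fit_report",
]

_COLUMNS = ["time_s", "angle_rad", "torque_Nm"]
_META_KEYS = [
    "cs_percent",
    "shear_percent",
    "freq_hz",
    "height_m",
    "radius_m",
    "points_per_period",
    "n_burnin",
    "n_record",
]


def _sidecar(path: Path) -> Path:
    return path.with_suffix(".json")


def write_trace(trace: TorqueTrace, path) -> None:
    """Write one trace as CSV + JSON metadata sidecar."""
    path = Path(path)
    df = pd.DataFrame(
        {"time_s": trace.t, "angle_rad": trace.angle, "torque_Nm": trace.tau}
    )
    df.to_csv(path, index=False, float_format="%.17g")
    g = trace.cond.geometry
    meta = {
        "cs_percent": 100.0 * g.cs,
        "shear_percent": 100.0 * trace.cond.gamma,
        "freq_hz": trace.cond.freq,
        "height_m": g.H,
        "radius_m": g.R,
        "points_per_period": trace.cond.points_per_period,
        "n_burnin": trace.cond.n_burnin,
        "n_record": trace.cond.n_record,
    }
    _sidecar(path).write_text(json.dumps(meta, indent=1))


def read_trace(path) -> TorqueTrace:
    """Read a trace CSV + sidecar back into a :class:`TorqueTrace`."""
    path = Path(path)
    df = pd.read_csv(path, float_precision="round_trip")
    missing = [c for c in _COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(f"trace file {path} is missing column(s): {missing}")
    t = df["time_s"].to_numpy()
    if np.any(np.diff(t) <= 0):
        raise ValueError(f"trace file {path} has non-monotone time")
    side = _sidecar(path)
    if not side.exists():
        raise FileNotFoundError(f"metadata sidecar {side} not found")
    meta = json.loads(side.read_text())
    absent = [k for k in _META_KEYS if k not in meta]
    if absent:
        raise ValueError(f"sidecar {side} is missing key(s): {absent}")
    cond = TestCondition(
        geometry=SampleGeometry(
            H=meta["height_m"], R=meta["radius_m"], cs=meta["cs_percent"] / 100.0
        ),
        gamma=meta["shear_percent"] / 100.0,
        freq=meta["freq_hz"],
        points_per_period=int(meta["points_per_period"]),
        n_burnin=int(meta["n_burnin"]),
        n_record=int(meta["n_record"]),
    )
    return TorqueTrace(
        cond=cond,
        t=t,
        angle=df["angle_rad"].to_numpy(),
        tau=df["torque_Nm"].to_numpy(),
    )


def write_dataset(dataset: SyntheticDataset, outdir) -> None:
    """Write a synthetic dataset as one CSV per test + a manifest."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    for i, tr in enumerate(dataset.traces):
        write_trace(tr, outdir / f"test_{i:02d}.csv")
    (outdir / "manifest.json").write_text(json.dumps(dataset.manifest, indent=1))


def read_dataset(indir) -> list[TorqueTrace]:
    """Read all ``test_*.csv`` traces in a directory, in index order."""
    indir = Path(indir)
    paths = sorted(indir.glob("test_*.csv"))
    if not paths:
        raise FileNotFoundError(f"no test_*.csv traces found in {indir}")
    return [read_trace(p) for p in paths]


def write_fit_report(result: FitResult, path, grid_note: dict | None = None) -> None:
    """Write a fit report (JSON) and its error surface (CSV alongside)."""
    path = Path(path)
    doc = {
        "model": result.model,
        "norm": result.norm,
        "alpha": result.alpha,
        "b": result.b,
        "error_percent": result.error,
        "grid": grid_note or {},
    }
    if result.x is not None:
        doc["linear_parameters_pa"] = [float(v) for v in result.x]
    if result.scaling is not None:
        doc["x_star_pa"] = [float(v) for v in result.scaling.x_star]
        doc["beta"] = [float(v) for v in result.scaling.beta]
        doc["x_per_test_pa"] = [
            [float(v) for v in row] for row in result.scaling.x_per_test
        ]
        doc["n_iter"] = result.scaling.n_iter
    path.write_text(json.dumps(doc, indent=1))
    result.surface.to_csv(path.with_suffix(".surface.csv"), index=False)
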