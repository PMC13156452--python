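"""Readers and writers for the formats the package touches.

Complex time-series round-trip through a three-column CSV (TR index, real,
imaginary) with a unit-bearing header; velocity traces through one-column
CSV; image stacks through compressed ``.npz``; fit results through JSON.
Sequence/tissue configuration is flat YAML.
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import yaml

from .epg import SignalTimeseries
from .fitting import FitResult
from .params import InvalidParameterError, SequenceParams, TissueParams

__all__ = [
    "save_timeseries_csv",
    "load_timeseries_csv",
    "save_trace_csv",
    "load_trace_csv",
    "save_fit_json",
    "load_config",
    "save_image_stack",
    "load_image_stack",
    "save_bvecs",
    "load_bvecs",
]


def save_timeseries_csv(series: SignalTimeseries, path) -> None:
    header = f"# b_label={series.b_label}\ntr,real,imag"
    tr = np.arange(len(series))
    data = np.column_stack([tr, series.values.real, series.values.imag])
    np.savetxt(path, data, delimiter=",", header=header, comments="",
               fmt=["%d", "%.17g", "%.17g"])


def load_timeseries_csv(path, TR: float = 1.0) -> SignalTimeseries:
    b_label = ""
    with open(path) as fh:
        first = fh.readline()
        if first.startswith("#") and "b_label=" in first:
            b_label = first.split("b_label=", 1)[1].strip()
    data = np.loadtxt(path, delimiter=",", skiprows=2)
    data = np.atleast_2d(data)
    values = data[:, 1] + 1j * data[:, 2]
    times = TR * (data[:, 0] + 1)
    return SignalTimeseries(values=values, times=times, b_label=b_label)


def save_trace_csv(trace: np.ndarray, path) -> None:
    np.savetxt(path, np.asarray(trace), header="V_mm_per_s", comments="# ", fmt="%.17g")


def load_trace_csv(path) -> np.ndarray:
    return np.atleast_1d(np.loadtxt(path))


def save_fit_json(fit: FitResult, path) -> None:
    obj = dict(
        D_hat=fit.D_hat,
        S0_hat=fit.S0_hat,
        phi_hat=list(map(float, np.atleast_1d(fit.phi_hat))),
        V_hat=np.asarray(fit.V_hat).tolist(),
        D_var=None if np.isnan(fit.D_var) else fit.D_var,
        residual_norm=fit.residual_norm,
        converged=fit.converged,
        message=fit.message,
        n_iter=fit.n_iter,
    )
    Path(path).write_text(json.dumps(obj, indent=2))


_SEQ_KEYS = {"G", "delta", "TR", "alpha_deg", "phi_rf_deg", "g_hat", "n_tr"}
_TIS_KEYS = {"T1", "T2", "D", "B1"}


def load_config(path) -> dict:
    """Parse a flat YAML config into SequenceParams/TissueParams plus extras.

    Angles are given in degrees in the file (``alpha_deg``, ``phi_rf_deg``).
    Unknown keys inside the ``sequence`` and ``tissue`` blocks are rejected.
    """
    raw = yaml.safe_load(Path(path).read_text())
    if not isinstance(raw, dict):
        raise InvalidParameterError("config must be a mapping")
    out = dict(raw)
    if "sequence" in raw:
        s = dict(raw["sequence"])
        unknown = set(s) - _SEQ_KEYS
        if unknown:
            raise InvalidParameterError(f"unknown sequence key(s): {sorted(unknown)}")
        missing = {"G", "delta", "TR", "alpha_deg"} - set(s)
        if missing:
            raise InvalidParameterError(f"missing sequence key(s): {sorted(missing)}")
        out["sequence"] = SequenceParams(
            G=float(s["G"]),
            delta=float(s["delta"]),
            TR=float(s["TR"]),
            alpha=np.deg2rad(float(s["alpha_deg"])),
            phi_rf=np.deg2rad(float(s.get("phi_rf_deg", 0.0))),
            g_hat=np.asarray(s.get("g_hat", [0.0, 0.0, 1.0]), dtype=float),
            n_tr=int(s.get("n_tr", 200)),
        )
    if "tissue" in raw:
        t = dict(raw["tissue"])
        unknown = set(t) - _TIS_KEYS
        if unknown:
            raise InvalidParameterError(f"unknown tissue key(s): {sorted(unknown)}")
        missing = {"T1", "T2", "D"} - set(t)
        if missing:
            raise InvalidParameterError(f"missing tissue key(s): {sorted(missing)}")
        out["tissue"] = TissueParams(
            T1=float(t["T1"]), T2=float(t["T2"]), D=float(t["D"]),
            B1=float(t.get("B1", 1.0)),
        )
    return out


def save_image_stack(stack: np.ndarray, path) -> None:
    np.savez_compressed(path, stack=np.asarray(stack))


def load_image_stack(path) -> np.ndarray:
    with np.load(path) as z:
        return z["stack"]


def save_bvecs(directions: np.ndarray, path) -> None:
    np.savetxt(path, np.asarray(directions), fmt="%.17g")


def load_bvecs(path) -> np.ndarray:
    g = np.atleast_2d(np.loadtxt(path))
    return g / np.linalg.norm(g, axis=1, keepdims=True)
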