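"""Plain-text trace and parameter file handling.

A trace directory mirrors the layout of published patch-clamp source data:
a shared ``Time.txt`` (seconds, one column), one whitespace file per
observable (``current.txt``, ``fluorescence.txt``) with one column per
ligand concentration, and a ``metadata.json`` sidecar with sampling and
noise metadata.  Raw (unnormalized) signals are stored; display
normalization is a view, never stored.
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np

from .simulate import NoiseParams, TraceSet

__all__ = ["write_traceset", "read_traceset", "read_params", "write_params"]


def write_traceset(traces: TraceSet, path) -> Path:
    path = Path(path)
    path.mkdir(parents=True, exist_ok=True)
    np.savetxt(path / "Time.txt", traces.times)
    np.savetxt(path / "current.txt", traces.current)
    if traces.fluorescence is not None:
        np.savetxt(path / "fluorescence.txt", traces.fluorescence)
    meta = {
        "concentrations_uM": list(map(float, traces.concentrations)),
        "f_ana": traces.f_ana,
        "f_sim": traces.f_sim,
        "f_cut": traces.f_cut,
        "T_int": traces.T_int,
        "Nch": traces.Nch,
        "seed": traces.seed,
        "scheme": traces.scheme_name,
        "t_on": traces.t_on,
        "noise": vars(traces.noise).copy() if traces.noise else None,
    }
    (path / "metadata.json").write_text(json.dumps(meta, indent=1))
    return path


def read_traceset(path) -> TraceSet:
    """Load a trace directory; a missing fluorescence file gives PC-only data."""
    path = Path(path)
    times = np.loadtxt(path / "Time.txt")
    if np.any(np.diff(times) <= 0):
        raise ValueError("non-monotone time axis")
    current = np.atleast_2d(np.loadtxt(path / "current.txt"))
    if current.shape[0] == 1 and len(times) > 1:
        current = current.T
    flu_file = path / "fluorescence.txt"
    fluorescence = None
    if flu_file.exists():
        fluorescence = np.atleast_2d(np.loadtxt(flu_file))
        if fluorescence.shape[0] == 1 and len(times) > 1:
            fluorescence = fluorescence.T
    if current.shape[0] != len(times):
        raise ValueError("ragged columns: current rows do not match Time.txt")
    meta_file = path / "metadata.json"
    meta = json.loads(meta_file.read_text()) if meta_file.exists() else {}
    noise = NoiseParams(**meta["noise"]) if meta.get("noise") else NoiseParams()
    concentrations = meta.get(
        "concentrations_uM", list(range(1, current.shape[1] + 1))
    )
    f_ana = meta.get("f_ana") or 1.0 / (times[1] - times[0])
    return TraceSet(
        times=times,
        concentrations=concentrations,
        current=current,
        fluorescence=fluorescence,
        f_ana=f_ana,
        f_sim=meta.get("f_sim"),
        f_cut=meta.get("f_cut"),
        T_int=meta.get("T_int", 0.0),
        noise=noise,
        Nch=meta.get("Nch"),
        seed=meta.get("seed"),
        scheme_name=meta.get("scheme", ""),
        t_on=meta.get("t_on"),
    )


def read_params(path) -> dict:
    return json.loads(Path(path).read_text())


def write_params(params: dict, path) -> None:
    Path(path).write_text(json.dumps(params, indent=1))
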