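"""Deterministic reference outputs for regression testing.

``generate_fixtures`` runs a small standard batch — fixed-parameter reference
runs at 0.1 and 0.4 nA, a current sweep with the first fitted parameter set,
and a short synaptic-drive simulation — and writes traces (CSV), extracted
features (JSON) and a manifest with content hashes.  Identical seeds yield
byte-identical files.
"""

from __future__ import annotations

import hashlib
import json
from pathlib import Path

import numpy as np

from .analysis import extract_features, fi_and_dbl_curves
from .cell import RunResult, conventional_cell, default_cell, run
from .mechanism import CELL_203030003_R
from .protocols import LAB1_PROTOCOL, run_sweep, run_synaptic

__all__ = ["generate_fixtures", "write_trace_csv", "read_trace_csv"]

_TRACE_FMT = "%.6f"


def write_trace_csv(path, res: RunResult) -> None:
    """Write a run's compartment voltages as CSV (time_ms, v_soma_mV, ...)."""
    header = "time_ms,v_soma_mV,v_prox_mV,v_dist_mV"
    data = np.column_stack([res.t, res.v])
    np.savetxt(path, data, fmt=_TRACE_FMT, delimiter=",", header=header, comments="")


def write_shifts_csv(path, res: RunResult) -> None:
    cols = list(res.shifts)
    data = np.column_stack([res.t] + [res.shifts[c] for c in cols])
    np.savetxt(path, data, fmt=_TRACE_FMT, delimiter=",",
               header=",".join(["time_ms"] + cols), comments="")


def read_trace_csv(path):
    """Load a (time_ms, v_mV, ...) CSV; returns (t, v) with v as 2-D array."""
    data = np.loadtxt(path, delimiter=",", skiprows=1)
    return data[:, 0], data[:, 1:]


def _features_record(res: RunResult) -> dict:
    f = extract_features(res.soma_trace())
    return {
        "amplitude_nA": res.amplitude,
        "n_spikes": int(f.n_spikes),
        "spike_times_ms": [round(float(t), 4) for t in f.spike_times],
        "peaks_mV": [round(float(p), 4) for p in f.peaks],
        "dbl_mV": None if np.isnan(f.dbl) else round(float(f.dbl), 4),
        "mean_frequency_Hz": round(float(f.mean_frequency), 4),
        "block": bool(f.block),
    }


def generate_fixtures(outdir, seed: int = 0) -> dict:
    """Generate the reference batch under ``outdir``; returns the manifest."""
    out = Path(outdir)
    out.mkdir(parents=True, exist_ok=True)
    files: dict[str, dict] = {}
    features: dict[str, dict] = {}

    conv = conventional_cell()
    for amp in (0.1, 0.4):
        res = run(conv, t_total=550.0, inj={"soma": amp}, t_on=50.0, t_off=450.0,
                  amplitude=amp, rec_every=4)
        name = f"conventional_{amp:.1f}nA.csv"
        write_trace_csv(out / name, res)
        features[name] = _features_record(res)

    cell = default_cell()
    sweep = run_sweep(cell, LAB1_PROTOCOL, mechanism=CELL_203030003_R)
    curves = fi_and_dbl_curves(sweep)
    curves.to_csv(out / "dbl_sweep_curves.csv", index=False, float_format="%.6f")
    for res in sweep:
        name = f"dbl_{res.amplitude:.2f}nA.csv"
        write_trace_csv(out / name, res)
        features[name] = _features_record(res)

    syn = run_synaptic(cell, CELL_203030003_R, t_total_ms=2000.0, seed=seed, rec_every=4)
    write_trace_csv(out / "synaptic_2s.csv", syn)
    features["synaptic_2s.csv"] = _features_record(syn)

    with open(out / "features.json", "w") as fh:
        json.dump({"seed": seed, "records": features}, fh, indent=1, sort_keys=True)

    for p in sorted(out.iterdir()):
        if p.name == "manifest.json":
            continue
        files[p.name] = {
            "sha256": hashlib.sha256(p.read_bytes()).hexdigest(),
            "bytes": p.stat().st_size,
        }
    manifest = {"seed": seed, "files": files}
    with open(out / "manifest.json", "w") as fh:
        json.dump(manifest, fh, indent=1, sort_keys=True)
    return manifest
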