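"""Configuration files: schema, validation, and (de)serialization.

A run configuration is a YAML/JSON mapping with sections ``cell``, ``dbl``,
``protocol``, ``dt``, ``seed``, ``filter`` and ``output_dir``.  Every section
is optional except ``cell``; unknown keys anywhere are rejected with the full
key path, and so are type errors.  Channel kinetics are serialized as named
closed-form families plus coefficient lists, so a user can swap in different
kinetics without touching code.

``dbl`` is either the string ``"disabled"``, the name of a built-in fitted
parameter set (``"203030003_R"`` or ``"170518_4e"``), or an explicit mapping
with the published coefficient names (alpha_ENa, alpha_Na, B_Na, C_Na,
alpha_EK, alpha_K, B_K, C_K, alpha_Ca, B_Ca, C_Ca) plus optional EMA settings
(F, t_step, reference_dt, v_rest).
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import yaml

from .cell import CaPoolConfig, CellConfig, Compartment, conventional_cell, default_cell
from .channels import ChannelSpec, GateSpec
from .mechanism import DBLParams, EMAConfig, TABLE1
from .protocols import LAB1_PROTOCOL, LAB2_PROTOCOL, StepProtocol

__all__ = [
    "SchemaError",
    "RunConfig",
    "FilterSettings",
    "load_config",
    "parse_config",
    "config_to_dict",
    "save_config",
    "channel_to_dict",
    "channel_from_dict",
    "cell_to_dict",
    "cell_from_dict",
]


class SchemaError(ValueError):
    """Configuration violates the schema; ``path`` names the offending key."""

    def __init__(self, path: str, message: str):
        super().__init__(f"{path}: {message}")
        self.path = path


def _require_keys(d: dict, allowed: set, path: str) -> None:
    unknown = set(d) - allowed
    if unknown:
        raise SchemaError(f"{path}.{sorted(unknown)[0]}", "unknown key")


def _number(d: dict, key: str, path: str, default=None):
    if key not in d:
        if default is None:
            raise SchemaError(f"{path}.{key}", "missing required key")
        return default
    v = d[key]
    if isinstance(v, bool) or not isinstance(v, (int, float)):
        raise SchemaError(f"{path}.{key}", f"expected a number, got {v!r}")
    return float(v)


# ---------------------------------------------------------------------------
# channel / cell serialization
# ---------------------------------------------------------------------------

def _gate_to_dict(g: GateSpec) -> dict:
    d = {"name": g.name, "exponent": g.exponent, "shiftable": g.shiftable}
    if g.rate_based:
        d["alpha"] = [g.alpha[0], list(g.alpha[1])]
        d["beta"] = [g.beta[0], list(g.beta[1])]
    else:
        d["inf"] = [g.inf[0], list(g.inf[1])]
        d["tau"] = [g.tau[0], list(g.tau[1])]
    return d


def _gate_from_dict(d: dict, path: str) -> GateSpec:
    _require_keys(d, {"name", "exponent", "shiftable", "inf", "tau", "alpha", "beta"}, path)
    try:
        kw = {}
        for fam_key in ("inf", "tau", "alpha", "beta"):
            if fam_key in d:
                fam, coeff = d[fam_key]
                kw[fam_key] = (str(fam), tuple(float(c) for c in coeff))
        return GateSpec(name=d["name"], exponent=int(d["exponent"]),
                        shiftable=bool(d.get("shiftable", True)), **kw)
    except (ValueError, TypeError) as e:
        raise SchemaError(path, str(e)) from e


def channel_to_dict(c: ChannelSpec) -> dict:
    d = {
        "name": c.name,
        "g_max": c.g_max,
        "reversal_ref": c.reversal_ref,
        "shift_class": c.shift_class,
        "gates": [_gate_to_dict(g) for g in c.gates],
    }
    if c.E_fixed is not None:
        d["E_fixed"] = c.E_fixed
    if c.ca_dependent:
        d["ca_dependent"] = True
        d["ca_half"] = c.ca_half
    return d


def channel_from_dict(d: dict, path: str = "channel") -> ChannelSpec:
    _require_keys(d, {"name", "g_max", "reversal_ref", "shift_class", "gates",
                      "E_fixed", "ca_dependent", "ca_half"}, path)
    try:
        return ChannelSpec(
            name=d["name"],
            gates=tuple(_gate_from_dict(g, f"{path}.gates[{i}]")
                        for i, g in enumerate(d.get("gates", []))),
            g_max=_number(d, "g_max", path),
            reversal_ref=d.get("reversal_ref", "fixed"),
            shift_class=d.get("shift_class", "none"),
            E_fixed=d.get("E_fixed"),
            ca_dependent=bool(d.get("ca_dependent", False)),
            ca_half=d.get("ca_half"),
        )
    except ValueError as e:
        raise SchemaError(path, str(e)) from e


def cell_to_dict(c: CellConfig) -> dict:
    return {
        "compartments": [
            {"name": cp.name, "area": cp.area, "cm": cp.cm,
             "g_leak": cp.g_leak, "E_leak": cp.E_leak}
            for cp in c.compartments
        ],
        "axial_uS": list(c.axial_uS),
        "channels": [channel_to_dict(ch) for ch in c.channels],
        "densities": {k: list(v) for k, v in c.densities.items()},
        "E_Na0": c.E_Na0,
        "E_K0": c.E_K0,
        "v_rest": c.v_rest,
        "ca": {"depth_um": c.ca.depth_um, "tau_ms": c.ca.tau_ms,
               "rest_mM": c.ca.rest_mM, "out_mM": c.ca.out_mM},
    }


def cell_from_dict(d: dict, path: str = "cell") -> CellConfig:
    _require_keys(d, {"compartments", "axial_uS", "channels", "densities",
                      "E_Na0", "E_K0", "v_rest", "ca"}, path)
    try:
        comps = tuple(
            Compartment(name=cp["name"], area=float(cp["area"]), cm=float(cp.get("cm", 1.0)),
                        g_leak=float(cp["g_leak"]), E_leak=float(cp["E_leak"]))
            for cp in d["compartments"]
        )
        ca = d.get("ca", {})
        return CellConfig(
            compartments=comps,
            axial_uS=tuple(float(x) for x in d["axial_uS"]),
            channels=tuple(channel_from_dict(ch, f"{path}.channels[{i}]")
                           for i, ch in enumerate(d["channels"])),
            densities={k: tuple(float(x) for x in v) for k, v in d.get("densities", {}).items()},
            E_Na0=_number(d, "E_Na0", path, 55.0),
            E_K0=_number(d, "E_K0", path, -112.0),
            v_rest=_number(d, "v_rest", path, -70.0),
            ca=CaPoolConfig(**{k: float(v) for k, v in ca.items()}) if ca else CaPoolConfig(),
        )
    except SchemaError:
        raise
    except (KeyError, TypeError, ValueError) as e:
        raise SchemaError(path, str(e)) from e


# ---------------------------------------------------------------------------
# run config
# ---------------------------------------------------------------------------

_DBL_KEYS = ("alpha_ENa", "alpha_Na", "B_Na", "C_Na", "alpha_EK", "alpha_K",
             "B_K", "C_K", "alpha_Ca", "B_Ca", "C_Ca")


@dataclass(frozen=True)
class FilterSettings:
    cutoff_khz: float = 2.0
    sample_khz: float = 10.0


@dataclass
class RunConfig:
    """Fully resolved configuration of a simulation run."""

    cell: CellConfig
    cell_name: str = "default"
    dbl: DBLParams | None = None
    dbl_name: str = "disabled"
    protocol: StepProtocol = field(default_factory=lambda: LAB1_PROTOCOL)
    protocol_name: str = "lab1"
    dt: float = 0.025
    seed: int = 0
    filter: FilterSettings = field(default_factory=FilterSettings)
    output_dir: str = "."


_CELLS = {"default": default_cell, "conventional": conventional_cell}
_PROTOCOLS = {"lab1": LAB1_PROTOCOL, "lab2": LAB2_PROTOCOL}


def _parse_dbl(spec, path: str):
    if spec is None or spec == "disabled":
        return None, "disabled"
    if isinstance(spec, str):
        if spec not in TABLE1:
            raise SchemaError(path, f"unknown parameter set {spec!r}; "
                                    f"choose from {sorted(TABLE1)} or 'disabled'")
        return TABLE1[spec], spec
    if not isinstance(spec, dict):
        raise SchemaError(path, f"expected a name or mapping, got {spec!r}")
    _require_keys(spec, set(_DBL_KEYS) | {"F", "t_step", "reference_dt", "v_rest",
                                          "literal_eq1_signs"}, path)
    vals = [_number(spec, k, path) for k in _DBL_KEYS]
    ema = EMAConfig(
        F=_number(spec, "F", path, 2.0),
        t_step=int(_number(spec, "t_step", path, 1000.0)),
        reference_dt=_number(spec, "reference_dt", path, 0.025),
        v_rest=_number(spec, "v_rest", path, -70.0),
    )
    params = DBLParams.from_table(*vals, ema=ema)
    if spec.get("literal_eq1_signs"):
        params = dataclasses.replace(params, literal_eq1_signs=True)
    return params, "custom"


def _parse_protocol(spec, path: str):
    if spec is None:
        return LAB1_PROTOCOL, "lab1"
    if isinstance(spec, str):
        if spec not in _PROTOCOLS:
            raise SchemaError(path, f"unknown protocol {spec!r}; choose from {sorted(_PROTOCOLS)}")
        return _PROTOCOLS[spec], spec
    if not isinstance(spec, dict):
        raise SchemaError(path, f"expected a name or mapping, got {spec!r}")
    _require_keys(spec, {"delay_ms", "duration_ms", "amplitudes_nA", "post_ms"}, path)
    amps = spec.get("amplitudes_nA", list(LAB1_PROTOCOL.amplitudes_nA))
    if not isinstance(amps, (list, tuple)):
        raise SchemaError(f"{path}.amplitudes_nA", "expected a list of numbers")
    try:
        proto = StepProtocol(
            delay_ms=_number(spec, "delay_ms", path, 50.0),
            duration_ms=_number(spec, "duration_ms", path, 400.0),
            amplitudes_nA=tuple(float(a) for a in amps),
            post_ms=_number(spec, "post_ms", path, 100.0),
        )
    except (TypeError, ValueError) as e:
        raise SchemaError(path, str(e)) from e
    return proto, "custom"


def parse_config(raw: dict) -> RunConfig:
    """Validate a raw mapping and resolve it into a RunConfig with defaults."""
    if not isinstance(raw, dict):
        raise SchemaError("<root>", "configuration must be a mapping")
    _require_keys(raw, {"cell", "dbl", "protocol", "dt", "seed", "filter", "output_dir"},
                  "<root>")
    cell_spec = raw.get("cell")
    if cell_spec is None:
        raise SchemaError("cell", "missing required key")
    if isinstance(cell_spec, str):
        if cell_spec not in _CELLS:
            raise SchemaError("cell", f"unknown cell {cell_spec!r}; choose from {sorted(_CELLS)}")
        cell, cell_name = _CELLS[cell_spec](), cell_spec
    elif isinstance(cell_spec, dict):
        cell, cell_name = cell_from_dict(cell_spec, "cell"), "custom"
    else:
        raise SchemaError("cell", f"expected a name or mapping, got {cell_spec!r}")

    dbl, dbl_name = _parse_dbl(raw.get("dbl"), "dbl")
    protocol, protocol_name = _parse_protocol(raw.get("protocol"), "protocol")

    dt = _number(raw, "dt", "<root>", 0.025)
    if not 0.0 < dt <= 0.1:
        raise SchemaError("dt", f"dt must be in (0, 0.1] ms, got {dt}")
    seed = raw.get("seed", 0)
    if isinstance(seed, bool) or not isinstance(seed, int):
        raise SchemaError("seed", f"expected an integer, got {seed!r}")

    filt_spec = raw.get("filter", {})
    if not isinstance(filt_spec, dict):
        raise SchemaError("filter", "expected a mapping")
    _require_keys(filt_spec, {"cutoff_khz", "sample_khz"}, "filter")
    filt = FilterSettings(
        cutoff_khz=_number(filt_spec, "cutoff_khz", "filter", 2.0),
        sample_khz=_number(filt_spec, "sample_khz", "filter", 10.0),
    )
    out = raw.get("output_dir", ".")
    if not isinstance(out, str):
        raise SchemaError("output_dir", f"expected a string, got {out!r}")
    return RunConfig(cell=cell, cell_name=cell_name, dbl=dbl, dbl_name=dbl_name,
                     protocol=protocol, protocol_name=protocol_name, dt=dt, seed=seed,
                     filter=filt, output_dir=out)


def load_config(path) -> RunConfig:
    """Load and validate a YAML/JSON configuration file."""
    p = Path(path)
    if not p.exists():
        raise FileNotFoundError(f"configuration file not found: {p}")
    with open(p) as fh:
        raw = yaml.safe_load(fh)
    return parse_config(raw if raw is not None else {})


def config_to_dict(cfg: RunConfig) -> dict:
    """Serialize a RunConfig back to a plain mapping (inverse of parse_config)."""
    d: dict = {}
    d["cell"] = cfg.cell_name if cfg.cell_name != "custom" else cell_to_dict(cfg.cell)
    if cfg.dbl_name == "custom":
        p = cfg.dbl
        d["dbl"] = {
            "alpha_ENa": p.Na.alpha_E, "alpha_Na": p.Na.alpha_sh, "B_Na": p.Na.B, "C_Na": p.Na.C,
            "alpha_EK": p.K.alpha_E, "alpha_K": p.K.alpha_sh, "B_K": p.K.B, "C_K": p.K.C,
            "alpha_Ca": p.Ca.alpha_sh, "B_Ca": p.Ca.B, "C_Ca": p.Ca.C,
            "F": p.ema.F, "t_step": p.ema.t_step, "reference_dt": p.ema.reference_dt,
            "v_rest": p.ema.v_rest,
        }
        if p.literal_eq1_signs:
            d["dbl"]["literal_eq1_signs"] = True
    else:
        d["dbl"] = cfg.dbl_name
    if cfg.protocol_name == "custom":
        pr = cfg.protocol
        d["protocol"] = {"delay_ms": pr.delay_ms, "duration_ms": pr.duration_ms,
                         "amplitudes_nA": list(pr.amplitudes_nA), "post_ms": pr.post_ms}
    else:
        d["protocol"] = cfg.protocol_name
    d["dt"] = cfg.dt
    d["seed"] = cfg.seed
    d["filter"] = {"cutoff_khz": cfg.filter.cutoff_khz, "sample_khz": cfg.filter.sample_khz}
    d["output_dir"] = cfg.output_dir
    return d


def save_config(cfg: RunConfig, path) -> None:
    with open(path, "w") as fh:
        yaml.safe_dump(config_to_dict(cfg), fh, sort_keys=False)
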