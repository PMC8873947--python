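"""Reduced 3-compartment CA1 cell: configuration, state, and simulation driver.

The cell is a soma - proximal dendrite - distal dendrite chain.  Dendritic
detail exists to place the two synaptic pathways (entorhinal inputs distally,
Schaffer-collateral inputs proximally); the depolarization-baseline mechanism
is driven by the somatic voltage and applied globally.

Voltage integration is Crank-Nicolson (second-order, implicit in v), gates are
advanced by exponential Euler, and the internal Ca2+ pool relaxes toward an
influx-driven target; the hot loop lives in :mod:`dblsim._kernel`.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace

import numpy as np

from .channels import (
    ChannelSpec,
    default_channels,
    gate_steady_state,
)
from .mechanism import DBLParams, ShiftState
from . import _kernel

__all__ = [
    "Compartment",
    "CaPoolConfig",
    "CellConfig",
    "CompartmentState",
    "RunResult",
    "NumericalDivergenceError",
    "default_cell",
    "init_state",
    "step",
    "run",
    "conventional_cell",
    "ca_reversal",
    "RT2F_35C",
]

RT2F_35C = 13.277  # RT/2F at 308.15 K, mV (matches the kernel's Ca reversal)
COMPARTMENTS = ("soma", "prox", "dist")

SHIFT_CLASS_INDEX = {"Na": 0, "K": 1, "Ca": 2, "none": -1}
REV_KIND_INDEX = {"Na": 0, "K": 1, "Ca": 2, "fixed": 3}
_INF_CODE = {"sigmoid": 0}
_TAU_CODE = {"constant": 0, "sigmoid": 1, "bell": 2}
_RATE_CODE = {"exp": 0, "sigmoid": 1, "linoid": 2}


class NumericalDivergenceError(RuntimeError):
    """Membrane potential left the physically meaningful range (|v| > 200 mV)."""

    def __init__(self, t_ms: float):
        super().__init__(f"numerical divergence at t = {t_ms:.3f} ms")
        self.t_ms = t_ms


@dataclass(frozen=True)
class Compartment:
    """Passive properties of one compartment (densities, not totals)."""

    name: str
    area: float          # cm^2
    cm: float = 1.0      # uF/cm^2
    g_leak: float = 7.5e-5  # S/cm^2
    E_leak: float = -70.0   # mV

    def __post_init__(self) -> None:
        if self.area <= 0 or self.cm <= 0 or self.g_leak <= 0:
            raise ValueError(f"compartment {self.name!r}: area, cm, g_leak must be positive")


@dataclass(frozen=True)
class CaPoolConfig:
    """Submembrane Ca2+ pool: shell depth, decay, resting/extracellular levels."""

    depth_um: float = 1.0
    tau_ms: float = 80.0
    rest_mM: float = 5e-5
    out_mM: float = 2.0

    def __post_init__(self) -> None:
        if min(self.depth_um, self.tau_ms, self.rest_mM, self.out_mM) <= 0:
            raise ValueError("Ca pool parameters must be positive")


@dataclass(frozen=True)
class CellConfig:
    """Full specification of the reduced cell.

    ``densities`` maps channel name -> (soma, prox, dist) conductance density in
    S/cm^2, overriding each channel's reference ``g_max``.  Channels absent
    from the map use ``g_max`` uniformly.
    """

    compartments: tuple[Compartment, Compartment, Compartment]
    axial_uS: tuple[float, float]        # soma-prox, prox-dist coupling, uS
    channels: tuple[ChannelSpec, ...]
    densities: dict = field(default_factory=dict)
    E_Na0: float = 55.0
    E_K0: float = -105.0
    v_rest: float = -70.0
    ca: CaPoolConfig = field(default_factory=CaPoolConfig)

    def __post_init__(self) -> None:
        if len(self.compartments) != 3:
            raise ValueError("the reduced cell has exactly 3 compartments")
        if any(g <= 0 for g in self.axial_uS):
            raise ValueError("axial couplings must be positive")
        if not -90.0 <= self.v_rest <= -55.0:
            raise ValueError(f"v_rest {self.v_rest} outside plausible range [-90, -55] mV")
        names = [c.name for c in self.channels]
        if len(set(names)) != len(names):
            raise ValueError("duplicate channel names")
        for key in self.densities:
            if key not in names:
                raise ValueError(f"density entry for unknown channel {key!r}")

    def density(self, chan: ChannelSpec) -> np.ndarray:
        d = self.densities.get(chan.name)
        if d is None:
            return np.full(3, chan.g_max)
        return np.asarray(d, dtype=float)

    def with_channel(self, chan: ChannelSpec, density: tuple[float, float, float]) -> "CellConfig":
        """Copy of this config with an extra channel added (e.g. the Nap variant)."""
        dens = dict(self.densities)
        dens[chan.name] = density
        return replace(self, channels=self.channels + (chan,), densities=dens)

    def scaled_densities(self, factor: float) -> "CellConfig":
        """Copy with every channel density multiplied by ``factor``."""
        dens = {c.name: tuple(self.density(c) * factor) for c in self.channels}
        return replace(self, densities=dens)


@dataclass
class CompartmentState:
    """Dynamic state: voltages, gate open fractions, internal Ca2+."""

    v: np.ndarray          # (3,) mV
    gates: np.ndarray      # (ngate, 3) open fractions
    ca: np.ndarray         # (3,) mM

    def copy(self) -> "CompartmentState":
        return CompartmentState(self.v.copy(), self.gates.copy(), self.ca.copy())


def ca_reversal(ca_in: float, ca_out: float, T: float = 308.15) -> float:
    """Nernst potential (mV) for Ca2+ (z = 2)."""
    if ca_in <= 0 or ca_out <= 0:
        raise ValueError(f"concentrations must be positive, got {ca_in}, {ca_out}")
    return 1000.0 * 8.314462618 * T / (2.0 * 96485.33212) * math.log(ca_out / ca_in)


# ---------------------------------------------------------------------------
# compilation to kernel arrays
# ---------------------------------------------------------------------------

@dataclass
class _Compiled:
    cm: np.ndarray
    gl: np.ndarray
    el: np.ndarray
    ax: np.ndarray
    area: np.ndarray
    gmax: np.ndarray
    rev_kind: np.ndarray
    e_fixed: np.ndarray
    ca_dep: np.ndarray
    ca_kd: np.ndarray
    g_chan: np.ndarray
    g_mode: np.ndarray
    g_f1: np.ndarray
    g_p1: np.ndarray
    g_f2: np.ndarray
    g_p2: np.ndarray
    g_exp: np.ndarray
    g_shift: np.ndarray
    gate_names: list


def _compile(config: CellConfig) -> _Compiled:
    comps = config.compartments
    area = np.array([c.area for c in comps])
    cm = np.array([c.cm * c.area * 1e3 for c in comps])    # nF (nF*mV/ms = nA)
    gl = np.array([c.g_leak * c.area * 1e6 for c in comps])  # uS
    el = np.array([c.E_leak for c in comps])
    ax = np.asarray(config.axial_uS, dtype=float)

    nchan = len(config.channels)
    gmax = np.zeros((nchan, 3))
    rev_kind = np.zeros(nchan, dtype=np.int64)
    e_fixed = np.zeros(nchan)
    ca_dep = np.zeros(nchan, dtype=np.int64)
    ca_kd = np.ones(nchan)

    g_chan, g_mode, g_f1, g_p1, g_f2, g_p2, g_exp, g_shift = [], [], [], [], [], [], [], []
    gate_names = []
    for ci, chan in enumerate(config.channels):
        gmax[ci] = config.density(chan) * area * 1e6  # uS totals
        rev_kind[ci] = REV_KIND_INDEX[chan.reversal_ref]
        e_fixed[ci] = chan.E_fixed if chan.E_fixed is not None else 0.0
        ca_dep[ci] = 1 if chan.ca_dependent else 0
        ca_kd[ci] = chan.ca_half if chan.ca_half else 1.0
        for gate in chan.gates:
            g_chan.append(ci)
            if gate.rate_based:
                g_mode.append(1)
                g_f1.append(_RATE_CODE[gate.alpha[0]])
                g_p1.append(list(gate.alpha[1]) + [0.0] * (4 - len(gate.alpha[1])))
                g_f2.append(_RATE_CODE[gate.beta[0]])
                g_p2.append(list(gate.beta[1]) + [0.0] * (4 - len(gate.beta[1])))
            else:
                g_mode.append(0)
                g_f1.append(_INF_CODE[gate.inf[0]])
                g_p1.append(list(gate.inf[1]) + [0.0] * (4 - len(gate.inf[1])))
                g_f2.append(_TAU_CODE[gate.tau[0]])
                g_p2.append(list(gate.tau[1]) + [0.0] * (4 - len(gate.tau[1])))
            g_exp.append(gate.exponent)
            cls = SHIFT_CLASS_INDEX[chan.shift_class] if gate.shiftable else -1
            g_shift.append(cls)
            gate_names.append(f"{chan.name}.{gate.name}")

    ng = len(g_chan)
    return _Compiled(
        cm=cm, gl=gl, el=el, ax=ax, area=area,
        gmax=gmax, rev_kind=rev_kind, e_fixed=e_fixed, ca_dep=ca_dep, ca_kd=ca_kd,
        g_chan=np.array(g_chan, dtype=np.int64),
        g_mode=np.array(g_mode, dtype=np.int64),
        g_f1=np.array(g_f1, dtype=np.int64),
        g_p1=np.array(g_p1, dtype=float).reshape(ng, 4),
        g_f2=np.array(g_f2, dtype=np.int64),
        g_p2=np.array(g_p2, dtype=float).reshape(ng, 4),
        g_exp=np.array(g_exp, dtype=np.int64),
        g_shift=np.array(g_shift, dtype=np.int64),
        gate_names=gate_names,
    )


def _rest_gates(config: CellConfig) -> np.ndarray:
    ng = sum(len(c.gates) for c in config.channels)
    gates = np.empty((ng, 3))
    gi = 0
    for chan in config.channels:
        for gate in chan.gates:
            gates[gi, :] = gate_steady_state(gate, config.v_rest, 0.0)
            gi += 1
    return gates


def _rest_ca(config: CellConfig, cc: "_Compiled", gates: np.ndarray) -> np.ndarray:
    """Equilibrium Ca2+ per compartment at v_rest (resting influx balances decay)."""
    kca = 1.0e4 / (2.0 * 96485.33212 * config.ca.depth_um)
    ca = np.full(3, config.ca.rest_mM)
    for _ in range(100):
        ca_new = ca.copy()
        for k in range(3):
            gca = 0.0
            gi = 0
            for ci, chan in enumerate(config.channels):
                of = 1.0
                for gate in chan.gates:
                    of *= gates[gi, k] ** gate.exponent
                    gi += 1
                if chan.reversal_ref == "Ca":
                    gca += cc.gmax[ci, k] * of
            if gca > 0.0:
                e_ca = RT2F_35C * math.log(config.ca.out_mM / ca[k])
                ica = gca * (config.v_rest - e_ca) / (cc.area[k] * 1e6)
                ca_new[k] = config.ca.rest_mM - kca * ica * config.ca.tau_ms
        if np.max(np.abs(ca_new - ca)) < 1e-16:
            ca = ca_new
            break
        ca = ca_new
    return np.maximum(ca, 1e-9)


def init_state(config: CellConfig) -> CompartmentState:
    """Resting state: uniform v_rest, gates at steady state, Ca2+ pool equilibrated."""
    cc = _compile(config)
    v = np.full(3, config.v_rest)
    gates = _rest_gates(config)
    ca = _rest_ca(config, cc, gates)
    return CompartmentState(v=v, gates=gates, ca=ca)


def balance_leak(config: CellConfig) -> CellConfig:
    """Set each compartment's leak reversal so that v_rest is a true equilibrium.

    At v_rest with gates at steady state the sum of all channel currents is
    cancelled by the leak, making the resting state a fixed point of the
    dynamics (axial currents vanish at uniform voltage).
    """
    state = init_state(config)
    cc = _compile(config)
    new_comps = []
    for k, comp in enumerate(config.compartments):
        i_other = 0.0  # nA
        gi = 0
        for ci, chan in enumerate(config.channels):
            of = 1.0
            for gate in chan.gates:
                of *= state.gates[gi, k] ** gate.exponent
                gi += 1
            if chan.ca_dependent:
                of *= state.ca[k] / (state.ca[k] + chan.ca_half)
            if chan.reversal_ref == "Na":
                e_c = config.E_Na0
            elif chan.reversal_ref == "K":
                e_c = config.E_K0
            elif chan.reversal_ref == "Ca":
                e_c = RT2F_35C * math.log(config.ca.out_mM / state.ca[k])
            else:
                e_c = chan.E_fixed
            i_other += cc.gmax[ci, k] * of * (config.v_rest - e_c)
        gl = cc.gl[k]  # uS
        el = config.v_rest + i_other / gl
        new_comps.append(replace(comp, E_leak=float(el)))
    return replace(config, compartments=tuple(new_comps))


# ---------------------------------------------------------------------------
# simulation driver
# ---------------------------------------------------------------------------

_SHIFT_COLS = ("ema", "fvrun_Na", "fvrun_K", "fvrun_Ca", "dE_Na", "dE_K",
               "sh_Na", "sh_K", "sh_Ca")


@dataclass
class RunResult:
    """Sampled traces and mechanism time course from one simulation."""

    t: np.ndarray                 # (nrec,) ms
    v: np.ndarray                 # (nrec, 3) mV: soma, prox, dist
    shifts: dict                  # column -> (nrec,) array (see _SHIFT_COLS)
    dt: float                     # recording interval, ms
    final_state: CompartmentState
    stim_window: tuple[float, float]
    amplitude: float | None = None
    gate_traj: np.ndarray | None = None   # (nrec, ngate) somatic gate values
    gate_names: list | None = None
    seed: int | None = None

    def soma_trace(self):
        from .analysis import VoltageTrace

        return VoltageTrace(
            dt=self.dt, v=self.v[:, 0], stim_window=self.stim_window,
            meta={"amplitude_nA": self.amplitude, "seed": self.seed},
        )

    def gate(self, name: str) -> np.ndarray:
        if self.gate_traj is None:
            raise ValueError("run() was called without record_gates=True")
        return self.gate_traj[:, self.gate_names.index(name)]


_EMPTY_F = np.empty(0)
_EMPTY_I = np.empty(0, dtype=np.int64)


def _mech_vector(mechanism: DBLParams | None, config: CellConfig, dt: float) -> np.ndarray:
    m = np.zeros(16)
    if mechanism is None:
        return m
    m[0] = 1.0
    m[1] = mechanism.ema.F
    m[2] = mechanism.ema.effective_t_step(dt)
    m[3] = mechanism.ema.v_rest if mechanism.ema.v_rest is not None else config.v_rest
    m[4:8] = (mechanism.Na.alpha_E, mechanism.Na.B, mechanism.Na.C, mechanism.Na.alpha_sh)
    m[8:12] = (mechanism.K.alpha_E, mechanism.K.B, mechanism.K.C, mechanism.K.alpha_sh)
    m[12:15] = (mechanism.Ca.alpha_sh, mechanism.Ca.B, mechanism.Ca.C)
    m[15] = 1.0 if mechanism.literal_eq1_signs else 0.0
    return m


def run(
    config: CellConfig,
    *,
    t_total: float,
    dt: float = 0.025,
    mechanism: DBLParams | None = None,
    inj: dict | None = None,
    t_on: float = 0.0,
    t_off: float = 0.0,
    static_shift: tuple[float, float, float] = (0.0, 0.0, 0.0),
    synapses=(),
    initial: CompartmentState | None = None,
    record_gates: bool = False,
    rec_every: int = 1,
    amplitude: float | None = None,
    seed: int | None = None,
) -> RunResult:
    """Integrate the cell for ``t_total`` ms and return sampled traces.

    ``inj`` maps compartment name to a constant current (nA) applied during
    [t_on, t_off).  ``synapses`` is a sequence of event streams (see
    :mod:`dblsim.protocols`).  ``mechanism=None`` runs the conventional
    fixed-parameter model; passing mechanism parameters with all B = 0 is
    bit-identical to that.  Identical inputs yield bit-identical outputs.
    """
    if not 0.0 < dt <= 0.1:
        raise ValueError(f"dt must be in (0, 0.1] ms, got {dt}")
    cc = _compile(config)
    state = initial.copy() if initial is not None else init_state(config)
    nsteps = int(round(t_total / dt))

    inj_arr = np.zeros(3)
    if inj:
        for name, amp in inj.items():
            inj_arr[COMPARTMENTS.index(name)] = amp

    ns = len(synapses)
    if ns:
        syn_comp = np.array([COMPARTMENTS.index(s.compartment) for s in synapses], dtype=np.int64)
        syn_gpeak = np.array([s.g_peak_uS for s in synapses])
        syn_tr = np.array([s.tau_rise for s in synapses])
        syn_td = np.array([s.tau_decay for s in synapses])
        syn_e = np.array([s.E_rev for s in synapses])
        syn_nmda = np.array([1 if s.is_nmda else 0 for s in synapses], dtype=np.int64)
        ev_t = np.concatenate([np.asarray(s.times, dtype=float) for s in synapses]) \
            if any(len(s.times) for s in synapses) else _EMPTY_F
        ev_w = np.concatenate([np.asarray(s.weights, dtype=float) for s in synapses]) \
            if any(len(s.times) for s in synapses) else _EMPTY_F
        ev_start = np.zeros(ns + 1, dtype=np.int64)
        for i, s in enumerate(synapses):
            ev_start[i + 1] = ev_start[i] + len(s.times)
        mg0 = synapses[0].mg
        mg_par = np.array([mg0.conc_mM / mg0.K_mM, mg0.gamma, 0.0])
    else:
        syn_comp = _EMPTY_I
        syn_gpeak = syn_tr = syn_td = syn_e = ev_t = ev_w = _EMPTY_F
        syn_tr = np.empty(0)
        syn_td = np.empty(0)
        syn_nmda = _EMPTY_I
        ev_start = np.zeros(1, dtype=np.int64)
        mg_par = np.array([1.0 / 3.57, 0.062, 0.0])

    mech = _mech_vector(mechanism, config, dt)

    out = _kernel.simulate(
        cc.cm, cc.gl, cc.el, cc.ax, cc.area,
        cc.gmax, cc.rev_kind, cc.e_fixed, cc.ca_dep, cc.ca_kd,
        cc.g_chan, cc.g_mode, cc.g_f1, cc.g_p1, cc.g_f2, cc.g_p2, cc.g_exp, cc.g_shift,
        config.E_Na0, config.E_K0,
        config.ca.rest_mM, config.ca.out_mM, config.ca.tau_ms, config.ca.depth_um,
        mech, np.asarray(static_shift, dtype=float),
        inj_arr, t_on, t_off,
        syn_comp, syn_gpeak, syn_tr, syn_td, syn_e, syn_nmda, mg_par,
        ev_t, ev_w, ev_start,
        state.v, state.gates, state.ca,
        0.0, 0,
        nsteps, dt, rec_every, record_gates,
    )
    err, t_err, v_rec, shift_rec, gate_rec, vf, gf, caf, ema, cnt = out
    if err:
        raise NumericalDivergenceError(t_err)

    nrec = v_rec.shape[0]
    t = np.arange(nrec) * dt * rec_every
    shifts = {col: shift_rec[:, i].copy() for i, col in enumerate(_SHIFT_COLS)}
    return RunResult(
        t=t,
        v=v_rec,
        shifts=shifts,
        dt=dt * rec_every,
        final_state=CompartmentState(v=vf, gates=gf, ca=caf),
        stim_window=(t_on, t_off),
        amplitude=amplitude if amplitude is not None else (inj_arr[0] if inj else None),
        gate_traj=gate_rec if record_gates else None,
        gate_names=cc.gate_names,
        seed=seed,
    )


def step(
    state: CompartmentState,
    config: CellConfig,
    dt: float,
    injected: dict | None = None,
    shift: ShiftState | None = None,
) -> CompartmentState:
    """Advance the cell state by a single integration step.

    ``shift`` supplies externally computed reversal offsets and kinetic shifts
    (all zero when the mechanism is disabled).  This is the same update the
    full run performs; it is exposed for stepwise inspection and testing.
    """
    sh = shift or ShiftState()
    cfg = replace(config, E_Na0=config.E_Na0 + sh.dE_Na, E_K0=config.E_K0 + sh.dE_K)
    res = run(
        cfg,
        t_total=dt,
        dt=dt,
        inj=injected,
        t_on=0.0,
        t_off=dt,
        static_shift=(sh.sh_Na, sh.sh_K, sh.sh_Ca),
        initial=state,
    )
    return res.final_state


def default_cell(balanced: bool = True) -> CellConfig:
    """The reduced CA1 cell used throughout: geometry, passive load and densities.

    The soma carries the full spiking apparatus; dendrites have progressively
    less Na+/delayed-rectifier and more A-type K+ and h-current with distance,
    mirroring the known density gradients.  Leak reversals are balanced so the
    configured resting potential is an exact equilibrium.
    """
    comps = (
        Compartment("soma", area=1.3e-5, g_leak=3.0e-5),
        Compartment("prox", area=3.0e-5, g_leak=3.0e-5),
        Compartment("dist", area=5.0e-5, g_leak=3.0e-5),
    )
    config = CellConfig(
        compartments=comps,
        axial_uS=(0.05, 0.02),
        channels=tuple(default_channels()),
        densities={
            "Na": (0.28, 0.14, 0.07),
            "KDR": (0.02, 0.01, 0.005),
            "KA": (0.005, 0.006, 0.009),
            "KM": (0.0002, 0.0001, 0.0),
            "CaH": (0.0002, 0.0002, 0.0002),
            "KAHP": (0.0005, 0.00025, 0.0),
            "Ih": (0.00005, 0.0001, 0.00015),
        },
        E_K0=-112.0,
    )
    return balance_leak(config) if balanced else config


def conventional_cell(balanced: bool = True) -> CellConfig:
    """A minimal fixed-parameter reference cell (Na, K_DR, K_A only).

    This is the conventional-model counterpart used for the depolarization-block
    demonstration: densities are set so the cell fires full-amplitude action
    potentials at weak somatic steps (~0.1-0.2 nA) but cannot sustain firing
    under strong drive -- at 0.3-0.4 nA the spike train collapses into a
    depolarized plateau because Na+ inactivation cannot recover between spikes.
    The soma is nearly isolated electrically (small axial coupling), keeping
    the after-spike trajectory under somatic channel control.
    """
    from .channels import default_channels as _dc

    chans = tuple(c for c in _dc() if c.name in ("Na", "KDR", "KA"))
    comps = (
        Compartment("soma", area=1.3e-5, g_leak=1.2e-5),
        Compartment("prox", area=3.0e-5, g_leak=1.2e-5),
        Compartment("dist", area=5.0e-5, g_leak=1.2e-5),
    )
    config = CellConfig(
        compartments=comps,
        axial_uS=(0.005, 0.003),
        channels=chans,
        densities={
            "Na": (0.14, 0.042, 0.014),
            "KDR": (0.0013, 0.00065, 0.000325),
            "KA": (0.018, 0.0108, 0.0054),
        },
        E_K0=-105.0,
    )
    return balance_leak(config) if balanced else config
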