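"""Voltage- and calcium-gated membrane current definitions.

Gates are expressed as named closed-form families with numeric coefficients so
that a channel set is fully serializable: a user can swap in different kinetics
(e.g. ones transcribed from a published model database) through the config file
without touching code.  Two parameterizations are supported:

* ``(inf, tau)`` — steady state and time constant as functions of voltage;
* ``(alpha, beta)`` — forward/backward rate pair, from which
  inf = alpha/(alpha+beta) and tau = 1/(alpha+beta).

Every shiftable gate evaluates its curves at the *effective* voltage ``v - sh``
where ``sh`` is the instantaneous kinetic shift (mV) supplied by the
depolarization-baseline mechanism, i.e. the whole voltage dependence is
translated along the voltage axis, which is the standard way a kinetic shift is
defined in the experimental literature.

The default channel set is a deliberately compact surrogate for the much larger
published CA1 kinetics files: transient Na+ (m^3 h), delayed-rectifier K+ (n),
A-type K+ (a b), M-type K+ (slow n), a lumped high-threshold Ca2+ channel
(m^2), a Ca2+-gated AHP K+ channel, the h-current (fixed reversal -30 mV), and
a persistent Na+ channel (Nap) whose activation/deactivation time constants are
300 ms / 1 ms.  Coefficients are calibration parameters chosen so the
conventional model rests near -70 mV, spikes peak near +35 mV and the
first-spike threshold at 0.1 nA is near -55 mV.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np

__all__ = [
    "GateSpec",
    "ChannelSpec",
    "gate_steady_state",
    "gate_time_constant",
    "channel_current",
    "default_channels",
    "nap_channel",
    "INF_FAMILIES",
    "TAU_FAMILIES",
    "RATE_FAMILIES",
]

# ---------------------------------------------------------------------------
# closed-form families
# ---------------------------------------------------------------------------

def _sigmoid_inf(v, p):
    vhalf, k = p
    return 1.0 / (1.0 + np.exp((vhalf - v) / k))


def _constant_tau(v, p):
    return np.full_like(np.asarray(v, dtype=float), p[0])


def _sigmoid_tau(v, p):
    base, amp, vhalf, k = p
    return base + amp / (1.0 + np.exp((vhalf - v) / k))


def _bell_tau(v, p):
    base, amp, vhalf, width = p
    return base + amp * np.exp(-(((v - vhalf) / width) ** 2))


def _rate_exp(v, p):
    a, vhalf, k = p
    return a * np.exp((v - vhalf) / k)


def _rate_sigmoid(v, p):
    a, vhalf, k = p
    return a / (1.0 + np.exp((vhalf - v) / k))


def _rate_linoid(v, p):
    a, vhalf, k = p
    x = np.asarray((v - vhalf) / k, dtype=float)
    # removable singularity at x = 0: a*k*x/(1-exp(-x)) -> a*k
    with np.errstate(over="ignore", invalid="ignore", divide="ignore"):
        out = np.where(np.abs(x) < 1e-7, a * k * (1.0 + x / 2.0), a * k * x / -np.expm1(-x))
    return out


INF_FAMILIES = {"sigmoid": (_sigmoid_inf, 2)}
TAU_FAMILIES = {
    "constant": (_constant_tau, 1),
    "sigmoid": (_sigmoid_tau, 4),
    "bell": (_bell_tau, 4),
}
RATE_FAMILIES = {
    "exp": (_rate_exp, 3),
    "sigmoid": (_rate_sigmoid, 3),
    "linoid": (_rate_linoid, 3),
}


def _check_family(table, name, params, what):
    if name not in table:
        raise ValueError(f"unknown {what} family {name!r}; choose from {sorted(table)}")
    fn, nparam = table[name]
    if len(params) != nparam:
        raise ValueError(f"{what} family {name!r} takes {nparam} coefficients, got {len(params)}")
    return fn


@dataclass(frozen=True)
class GateSpec:
    """One gating variable of a channel.

    Exactly one parameterization must be given: either ``inf``+``tau`` or
    ``alpha``+``beta``, each as a ``(family_name, (coefficients...))`` pair.
    """

    name: str
    exponent: int
    shiftable: bool = True
    inf: tuple[str, tuple[float, ...]] | None = None
    tau: tuple[str, tuple[float, ...]] | None = None
    alpha: tuple[str, tuple[float, ...]] | None = None
    beta: tuple[str, tuple[float, ...]] | None = None

    def __post_init__(self) -> None:
        if self.exponent < 1:
            raise ValueError(f"gate exponent must be >= 1, got {self.exponent}")
        has_it = self.inf is not None and self.tau is not None
        has_ab = self.alpha is not None and self.beta is not None
        if has_it == has_ab:
            raise ValueError(
                f"gate {self.name!r}: give either (inf, tau) or (alpha, beta), not both/neither"
            )
        if has_it:
            _check_family(INF_FAMILIES, self.inf[0], self.inf[1], "inf")
            _check_family(TAU_FAMILIES, self.tau[0], self.tau[1], "tau")
        else:
            _check_family(RATE_FAMILIES, self.alpha[0], self.alpha[1], "rate")
            _check_family(RATE_FAMILIES, self.beta[0], self.beta[1], "rate")

    @property
    def rate_based(self) -> bool:
        return self.alpha is not None


def gate_steady_state(gate: GateSpec, v, sh: float = 0.0):
    """Steady-state open fraction of ``gate`` at voltage ``v`` under kinetic shift ``sh``.

    A nonzero ``sh`` translates the curve: the value at ``v`` equals the
    unshifted value at ``v - sh``.  ``sh`` should be 0 for non-shiftable gates.
    """
    veff = np.asarray(v, dtype=float) - sh
    if gate.rate_based:
        a = _check_family(RATE_FAMILIES, *gate.alpha, "rate")(veff, gate.alpha[1])
        b = _check_family(RATE_FAMILIES, *gate.beta, "rate")(veff, gate.beta[1])
        out = a / (a + b)
    else:
        out = _check_family(INF_FAMILIES, *gate.inf, "inf")(veff, gate.inf[1])
    return float(out) if np.isscalar(v) else out


def gate_time_constant(gate: GateSpec, v, sh: float = 0.0):
    """Time constant (ms) of ``gate`` at ``v`` under kinetic shift ``sh``; strictly positive."""
    veff = np.asarray(v, dtype=float) - sh
    if gate.rate_based:
        a = _check_family(RATE_FAMILIES, *gate.alpha, "rate")(veff, gate.alpha[1])
        b = _check_family(RATE_FAMILIES, *gate.beta, "rate")(veff, gate.beta[1])
        out = 1.0 / (a + b)
    else:
        out = _check_family(TAU_FAMILIES, *gate.tau, "tau")(veff, gate.tau[1])
    return float(out) if np.isscalar(v) else out


@dataclass(frozen=True)
class ChannelSpec:
    """A membrane current: a set of gates, a maximal conductance and a reversal.

    ``reversal_ref`` selects which reversal potential drives the current:
    "Na", "K" or "Ca" for the dynamically shifted reversals, or "fixed" with
    ``E_fixed`` for a constant one (e.g. the h-current at -30 mV).
    ``shift_class`` routes the dynamic kinetic shift: gates of this channel see
    sh_Na, sh_K or sh_Ca; "none" leaves them unshifted.
    """

    name: str
    gates: tuple[GateSpec, ...]
    g_max: float  # S/cm^2, reference density (may be overridden per compartment)
    reversal_ref: str
    shift_class: str = "none"
    E_fixed: float | None = None
    ca_dependent: bool = False
    ca_half: float | None = None  # mM, half-activation of the Ca-dependent factor

    def __post_init__(self) -> None:
        if self.g_max < 0:
            raise ValueError(f"g_max must be >= 0, got {self.g_max}")
        if self.reversal_ref not in ("Na", "K", "Ca", "fixed"):
            raise ValueError(f"bad reversal_ref {self.reversal_ref!r}")
        if self.reversal_ref == "fixed" and self.E_fixed is None:
            raise ValueError(f"channel {self.name!r}: fixed reversal requires E_fixed")
        if self.shift_class not in ("Na", "K", "Ca", "none"):
            raise ValueError(f"bad shift_class {self.shift_class!r}")
        if self.ca_dependent and (self.ca_half is None or self.ca_half <= 0):
            raise ValueError(f"channel {self.name!r}: ca_dependent requires ca_half > 0")


def channel_current(
    chan: ChannelSpec,
    gates,
    v: float,
    E_eff: float,
    ca_in: float = 5e-5,
    g_max: float | None = None,
) -> float:
    """Ohmic current density (mA/cm^2) of one channel at one point in state space.

    ``gates`` is a sequence of open fractions matching ``chan.gates``.  ``E_eff``
    is the (possibly dynamically shifted) reversal potential in mV.  For
    Ca-dependent channels the conductance is multiplied by ca/(ca + ca_half).
    """
    gates = np.asarray(gates, dtype=float)
    if gates.shape != (len(chan.gates),):
        raise ValueError(f"channel {chan.name!r} has {len(chan.gates)} gates, got {gates.shape}")
    if np.any(gates < -1e-9) or np.any(gates > 1.0 + 1e-9):
        raise ValueError(f"gate fraction outside [0, 1]: {gates}")
    g = chan.g_max if g_max is None else g_max
    open_frac = 1.0
    for spec, x in zip(chan.gates, gates):
        open_frac *= float(np.clip(x, 0.0, 1.0)) ** spec.exponent
    if chan.ca_dependent:
        open_frac *= ca_in / (ca_in + chan.ca_half)
    return g * open_frac * (v - E_eff)


# ---------------------------------------------------------------------------
# default surrogate channel set
# ---------------------------------------------------------------------------

def default_channels() -> list[ChannelSpec]:
    """The surrogate CA1 channel set used by the reduced model.

    Densities (``g_max``) here are soma reference values; the cell config may
    scale them per compartment.
    """
    na = ChannelSpec(
        name="Na",
        gates=(
            GateSpec("m", 3, True, inf=("sigmoid", (-38.0, 4.0)),
                     tau=("bell", (0.1, 0.15, -38.0, 25.0))),
            GateSpec("h", 1, True, inf=("sigmoid", (-55.0, -5.0)),
                     tau=("bell", (0.6, 2.5, -55.0, 18.0))),
        ),
        g_max=0.12,
        reversal_ref="Na",
        shift_class="Na",
    )
    kdr = ChannelSpec(
        name="KDR",
        gates=(
            GateSpec("n", 2, True, inf=("sigmoid", (-12.0, 8.0)),
                     tau=("bell", (0.8, 4.0, -40.0, 30.0))),
        ),
        g_max=0.02,
        reversal_ref="K",
        shift_class="K",
    )
    ka = ChannelSpec(
        name="KA",
        gates=(
            GateSpec("a", 1, True, inf=("sigmoid", (-28.0, 7.5)), tau=("constant", (0.6,))),
            GateSpec("b", 1, True, inf=("sigmoid", (-65.0, -6.0)), tau=("constant", (20.0,))),
        ),
        g_max=0.006,
        reversal_ref="K",
        shift_class="K",
    )
    km = ChannelSpec(
        name="KM",
        gates=(
            GateSpec("n", 1, True, inf=("sigmoid", (-35.0, 6.0)), tau=("constant", (60.0,))),
        ),
        g_max=0.0006,
        reversal_ref="K",
        shift_class="K",
    )
    cah = ChannelSpec(
        name="CaH",
        gates=(
            GateSpec("m", 2, True, inf=("sigmoid", (-18.0, 6.0)), tau=("constant", (1.5,))),
        ),
        g_max=0.0008,
        reversal_ref="Ca",
        shift_class="Ca",
    )
    kahp = ChannelSpec(
        name="KAHP",
        gates=(),
        g_max=0.0008,
        reversal_ref="K",
        shift_class="none",
        ca_dependent=True,
        ca_half=2e-3,
    )
    ih = ChannelSpec(
        name="Ih",
        gates=(
            GateSpec("r", 1, False, inf=("sigmoid", (-88.0, -8.0)), tau=("constant", (50.0,))),
        ),
        g_max=0.00005,
        reversal_ref="fixed",
        E_fixed=-30.0,
        shift_class="none",
    )
    return [na, kdr, ka, km, cah, kahp, ih]


def nap_channel(g_max: float = 0.001) -> ChannelSpec:
    """Persistent Na+ channel with slow activation (300 ms) and fast deactivation (1 ms).

    The time constant switches between the two values across the activation
    midpoint: in the depolarized (activating) regime tau -> 300 ms, in the
    hyperpolarized (deactivating) regime tau -> 1 ms.
    """
    return ChannelSpec(
        name="Nap",
        gates=(
            GateSpec("m", 1, True, inf=("sigmoid", (-52.0, 5.0)),
                     tau=("sigmoid", (1.0, 299.0, -85.0, 1.5))),
        ),
        g_max=g_max,
        reversal_ref="Na",
        shift_class="Na",
    )
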