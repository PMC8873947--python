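"""Activity-dependent reversal-potential and channel-kinetics shifts.

The mechanism tracks the somatic depolarization above rest, x = v - v_rest,
with an exponential moving average (EMA),

    EMA[n] = a * x[n] + (1 - a) * EMA[n-1],      a = F / (cnt + 1),

where ``cnt`` counts integration steps up to a cap ``t_step`` (so early in a
simulation the average is effectively cumulative, and after ``t_step`` samples
it becomes a fixed-window EMA with a = F/(t_step+1)).  The EMA then drives a
saturating Hill function per ion species i in {Na, K, Ca},

    f_vrun_i = B_i * C_i * EMA / (C_i + EMA),

which sets a dynamic offset of the Na+ and K+ reversal potentials and a
translation ("kinetic shift") of the channel gating curves:

    E_Na(t) = E_Na(0) - alpha_ENa * f_vrun_Na      (gradient magnitude shrinks)
    E_K(t)  = E_K(0)  + alpha_EK  * f_vrun_K       (gradient magnitude shrinks)
    sh_i(t) = alpha_i * f_vrun_i                   (depolarizing translation)

Both reversal shifts *reduce the magnitude* of the respective electrochemical
gradient, consistent with ions accumulating on the side they flow toward
during sustained activity (internal Na+ rises, external K+ rises).  A literal
uniform-minus variant (E_K also lowered) is available through
``literal_eq1_signs`` for comparison.  The Ca2+ reversal is not offset here:
it is recomputed each step from the internal Ca2+ pool via the Nernst
relation; Ca participates only through its kinetic shift.

Setting every B_i = 0 switches the mechanism off identically: all shifts are
zero and the model reduces to a conventional fixed-parameter HH-type model.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

__all__ = [
    "EMAConfig",
    "EMAState",
    "IonShiftParams",
    "DBLParams",
    "ShiftState",
    "ema_alpha",
    "ema_update",
    "fvrun",
    "compute_shifts",
    "shift_report",
    "CELL_203030003_R",
    "CELL_170518_4E",
    "TABLE1",
]


@dataclass(frozen=True)
class EMAConfig:
    """EMA weighting scheme.

    F is the dimensionless weight numerator (a = F/(cnt+1)); t_step is the
    window length in integration steps, defined at ``reference_dt``.  When the
    simulation runs at a different dt the effective window is rescaled so that
    the averaging *time* window (t_step * reference_dt, 25 ms by default) is
    preserved.
    """

    F: float = 2.0
    t_step: int = 1000
    reference_dt: float = 0.025  # ms
    v_rest: float = -70.0  # mV

    def __post_init__(self) -> None:
        if self.F <= 0:
            raise ValueError(f"F must be positive, got {self.F}")
        if self.t_step < 1:
            raise ValueError(f"t_step must be >= 1, got {self.t_step}")

    def effective_t_step(self, dt: float) -> int:
        """Window length in steps at integration step ``dt`` (ms)."""
        return max(1, round(self.t_step * self.reference_dt / dt))


@dataclass(frozen=True)
class EMAState:
    """Running EMA value (mV above rest, clamped at 0) and sample counter."""

    ema: float = 0.0
    cnt: int = 0


def ema_alpha(cnt: int, F: float = 2.0) -> float:
    return F / (cnt + 1.0)


def ema_update(state: EMAState, v: float, cfg: EMAConfig, dt: float | None = None) -> EMAState:
    """Advance the EMA by one sample of the somatic voltage ``v``.

    The depolarization x = v - v_rest is clamped at 0 from below (the Hill
    driver is only defined for depolarization; hyperpolarized excursions do
    not build up negative drive).
    """
    t_step = cfg.t_step if dt is None else cfg.effective_t_step(dt)
    cnt = min(state.cnt + 1, t_step)
    x = v - cfg.v_rest
    a = ema_alpha(cnt, cfg.F)
    ema = a * x + (1.0 - a) * state.ema
    return EMAState(ema=max(ema, 0.0), cnt=cnt)


@dataclass(frozen=True)
class IonShiftParams:
    """Hill and gain coefficients for one ion species.

    alpha_E is the reversal-shift gain (absent/ignored for Ca), alpha_sh the
    kinetic-shift gain; B (dimensionless) and C (mV) parameterize the Hill
    function B*C*ema/(C + ema), which saturates at B*C.
    """

    alpha_sh: float
    B: float
    C: float
    alpha_E: float = 0.0

    def __post_init__(self) -> None:
        if self.B < 0:
            raise ValueError(f"B must be >= 0, got {self.B}")
        if self.C <= 0:
            raise ValueError(f"C must be > 0, got {self.C}")
        if self.alpha_sh < 0 or self.alpha_E < 0:
            raise ValueError("gains must be >= 0")


@dataclass(frozen=True)
class DBLParams:
    """Full parameter set of the depolarization-baseline mechanism."""

    Na: IonShiftParams
    K: IonShiftParams
    Ca: IonShiftParams
    ema: EMAConfig = field(default_factory=EMAConfig)
    literal_eq1_signs: bool = False

    @property
    def disabled(self) -> bool:
        return self.Na.B == 0.0 and self.K.B == 0.0 and self.Ca.B == 0.0

    def switched_off(self) -> "DBLParams":
        """Copy with every Hill amplitude B set to 0 (conventional model)."""
        return replace(
            self,
            Na=replace(self.Na, B=0.0),
            K=replace(self.K, B=0.0),
            Ca=replace(self.Ca, B=0.0),
        )

    @classmethod
    def from_table(cls, alpha_ENa, alpha_Na, B_Na, C_Na, alpha_EK, alpha_K, B_K, C_K,
                   alpha_Ca, B_Ca, C_Ca, ema: EMAConfig | None = None) -> "DBLParams":
        """Build from the published per-cell coefficient table ordering."""
        return cls(
            Na=IonShiftParams(alpha_sh=alpha_Na, B=B_Na, C=C_Na, alpha_E=alpha_ENa),
            K=IonShiftParams(alpha_sh=alpha_K, B=B_K, C=C_K, alpha_E=alpha_EK),
            Ca=IonShiftParams(alpha_sh=alpha_Ca, B=B_Ca, C=C_Ca),
            ema=ema or EMAConfig(),
        )


@dataclass(frozen=True)
class ShiftState:
    """Instantaneous mechanism output: Hill drivers, reversal offsets, kinetic shifts (mV)."""

    fvrun_Na: float = 0.0
    fvrun_K: float = 0.0
    fvrun_Ca: float = 0.0
    dE_Na: float = 0.0
    dE_K: float = 0.0
    sh_Na: float = 0.0
    sh_K: float = 0.0
    sh_Ca: float = 0.0


def fvrun(ema: float, p: IonShiftParams) -> float:
    """Hill driver B*C*ema/(C + ema); monotone, concave, saturating at B*C."""
    if ema < 0:
        raise ValueError(f"ema must be >= 0, got {ema}")
    return p.B * p.C * ema / (p.C + ema)


def compute_shifts(ema: float, params: DBLParams) -> ShiftState:
    """Map an EMA level to the instantaneous reversal and kinetic shifts."""
    f_na = fvrun(ema, params.Na)
    f_k = fvrun(ema, params.K)
    f_ca = fvrun(ema, params.Ca)
    dE_K = -params.K.alpha_E * f_k if params.literal_eq1_signs else params.K.alpha_E * f_k
    return ShiftState(
        fvrun_Na=f_na,
        fvrun_K=f_k,
        fvrun_Ca=f_ca,
        dE_Na=-params.Na.alpha_E * f_na,
        dE_K=dE_K,
        sh_Na=params.Na.alpha_sh * f_na,
        sh_K=params.K.alpha_sh * f_k,
        sh_Ca=params.Ca.alpha_sh * f_ca,
    )


def shift_report(sweep_results) -> pd.DataFrame:
    """Per-current-step summary of the mechanism's excursions during a sweep.

    ``sweep_results`` is a sequence of run results (see ``dblsim.cell.RunResult``)
    carrying the shift time course.  Returns one row per injected amplitude
    with the maximum and final (steady) values of each driver and shift.
    """
    rows = []
    for res in sweep_results:
        sc = res.shifts
        row = {"amplitude_nA": res.amplitude}
        for col in ("fvrun_Na", "fvrun_K", "fvrun_Ca", "dE_Na", "dE_K",
                    "sh_Na", "sh_K", "sh_Ca"):
            series = sc[col]
            imax = int(np.argmax(np.abs(series)))
            row[f"max_{col}"] = float(series[imax])
            row[f"end_{col}"] = float(series[-1])
        rows.append(row)
    return pd.DataFrame(rows)


# Published per-cell coefficient sets (column order: alpha_ENa, alpha_Na, B_Na,
# C_Na, alpha_EK, alpha_K, B_K, C_K, alpha_Ca, B_Ca, C_Ca).
CELL_203030003_R = DBLParams.from_table(0.25, 0.13, 2.60, 60.0,
                                        1.06, 0.15, 2.11, 48.0,
                                        0.15, 2.0, 50.0)
CELL_170518_4E = DBLParams.from_table(0.30, 0.17, 2.50, 68.0,
                                      1.12, 0.12, 2.13, 68.0,
                                      0.10, 2.0, 70.0)
TABLE1 = {"203030003_R": CELL_203030003_R, "170518_4e": CELL_170518_4E}
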