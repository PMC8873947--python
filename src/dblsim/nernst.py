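"""Nernst-equation conversions between reversal potentials and ion concentrations.

Beyond the forward Nernst relation, this module inverts a *predicted* shift of a
reversal potential into the transmembrane ion transfer that would produce it:
given a baseline pool (c_in, c_out) and a shift ``dE``, find the amount Δ moved
across the membrane such that the new concentration ratio yields the shifted
potential.  The transfer conserves the total amount of ion: the intracellular
concentration changes by Δ and the extracellular one by Δ/ρ, where ρ is the
effective extracellular-to-intracellular volume ratio.

All potentials are in mV, concentrations in mM, temperatures in kelvin.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, replace

from scipy.optimize import brentq

__all__ = [
    "IonPool",
    "NoSolutionError",
    "nernst",
    "invert_shift",
    "fold_change",
    "GAS_CONSTANT",
    "FARADAY",
    "CELSIUS_35_K",
]

GAS_CONSTANT = 8.314462618  # J / (mol K)
FARADAY = 96485.33212  # C / mol
CELSIUS_35_K = 308.15  # recording temperature used throughout


class NoSolutionError(ValueError):
    """Requested reversal-potential shift is not achievable by a conservative transfer."""


@dataclass(frozen=True)
class IonPool:
    """Intra/extracellular concentrations of one ion species.

    Parameters
    ----------
    ion : str
        Species label ("Na", "K", "Ca", ...). Informational only.
    z : int
        Valence (signed; +1 for Na/K, +2 for Ca).
    c_in, c_out : float
        Intra- and extracellular concentrations, mM. Must be positive.
    T : float
        Absolute temperature, K. Defaults to 35 degC.
    rho : float
        Effective extracellular-to-intracellular volume ratio used when a
        transfer splits between the two sides. Default 1 (equal volumes).
    """

    ion: str
    z: int
    c_in: float
    c_out: float
    T: float = CELSIUS_35_K
    rho: float = 1.0

    def __post_init__(self) -> None:
        if self.c_in <= 0 or self.c_out <= 0:
            raise ValueError(
                f"concentrations must be positive, got c_in={self.c_in}, c_out={self.c_out}"
            )
        if self.T <= 0:
            raise ValueError(f"temperature must be positive, got {self.T}")
        if self.rho <= 0:
            raise ValueError(f"volume ratio must be positive, got {self.rho}")
        if self.z == 0:
            raise ValueError("valence must be nonzero")


# Reconstructed baseline pools consistent with a ~20 mM transfer roughly doubling
# internal Na+ and producing a ~10-fold rise of external K+; configurable, not printed
# constants of nature.
DEFAULT_POOLS = {
    "Na": IonPool("Na", 1, c_in=20.0, c_out=140.0),
    "K": IonPool("K", 1, c_in=133.0, c_out=2.2),
    "Ca": IonPool("Ca", 2, c_in=5e-5, c_out=2.0),
}


def nernst(pool: IonPool) -> float:
    """Nernst reversal potential (mV): (RT / zF) ln(c_out / c_in)."""
    kT = 1000.0 * GAS_CONSTANT * pool.T / (pool.z * FARADAY)
    return kT * math.log(pool.c_out / pool.c_in)


def _transferred(pool: IonPool, delta: float, direction: str) -> IonPool:
    if direction == "inward":
        c_in = pool.c_in + delta
        c_out = pool.c_out - delta / pool.rho
    elif direction == "outward":
        c_in = pool.c_in - delta
        c_out = pool.c_out + delta / pool.rho
    else:
        raise ValueError(f"direction must be 'inward' or 'outward', got {direction!r}")
    return replace(pool, c_in=c_in, c_out=c_out)


def invert_shift(
    pool: IonPool, dE: float, direction: str, tol: float = 1e-9
) -> tuple[float, float, float]:
    """Invert a reversal-potential shift into a conservative ion transfer.

    Finds the unique Δ >= 0 such that moving Δ mM across the membrane in the
    given direction ("inward" moves ion into the cell) changes the Nernst
    potential by exactly ``dE`` mV.  Returns ``(c_in', c_out', Δ)``.

    Raises
    ------
    NoSolutionError
        If ``dE`` has the wrong sign for the requested direction, or its
        magnitude exceeds what the transfer can produce before exhausting one
        side of the membrane.
    """
    if direction not in ("inward", "outward"):
        raise ValueError(f"direction must be 'inward' or 'outward', got {direction!r}")
    if dE == 0.0:
        return pool.c_in, pool.c_out, 0.0

    e0 = nernst(pool)

    def objective(delta: float) -> float:
        return nernst(_transferred(pool, delta, direction)) - e0 - dE

    # An inward transfer of a positive-z ion lowers c_out/c_in, hence lowers E
    # (and conversely); the objective is strictly monotone in delta.
    sign = -1.0 if (direction == "inward") == (pool.z > 0) else 1.0
    if dE * sign < 0:
        raise NoSolutionError(
            f"{direction} transfer of {pool.ion} (z={pool.z}) cannot shift E by {dE:+g} mV"
        )

    if direction == "inward":
        delta_max = pool.c_out * pool.rho
    else:
        delta_max = pool.c_in
    hi = delta_max * (1.0 - 1e-13)
    if objective(0.0) * objective(hi) > 0:
        raise NoSolutionError(
            f"|dE|={abs(dE):g} mV exceeds the achievable range for {pool.ion} "
            f"before one side of the membrane is exhausted"
        )
    delta = brentq(objective, 0.0, hi, xtol=1e-15, rtol=8.9e-16, maxiter=200)
    # polish to the requested potential tolerance
    assert abs(objective(delta)) < tol
    new = _transferred(pool, delta, direction)
    return new.c_in, new.c_out, delta


def fold_change(pool: IonPool, dE: float, direction: str, side: str) -> float:
    """Post/pre concentration ratio on one side after inverting a shift ``dE``.

    ``side`` is "in" or "out".
    """
    c_in, c_out, _ = invert_shift(pool, dE, direction)
    if side == "in":
        return c_in / pool.c_in
    if side == "out":
        return c_out / pool.c_out
    raise ValueError(f"side must be 'in' or 'out', got {side!r}")
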