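"""Chip/liquor mass balance and the two-phase energy balance.

Delignification (chip -> liquor) and redeposition (liquor -> chip) are
first-order in the lignin mass of the source phase, with Arrhenius rate
coefficients evaluated at the chip and liquor temperatures respectively:

    dL_c/dt = -k_D L_c + k_R L_d,     dL_d/dt = +k_D L_c - k_R L_d

The chip phase exchanges heat with the liquor (overall coefficient ``U``)
and carries the reaction enthalpy of delignification; the liquor is heated
by an external jacket stream at temperature ``T_ext`` and flow rate
``Mdot_ext``:

    C_Pc M_c dT_c/dt = dH_R r_D + U (T_f - T_c)
    C_Pf M_f dT_f/dt = -U (T_f - T_c) + C_Pext Mdot_ext (T_ext - T_f)

Both balances are integrated by explicit Euler at the fixed macroscopic step
``dt = 5e-4 min``.  Lignin masses are expressed on the same scale as chain
molar masses (one simulated chain of molar mass M contributes M mass units),
so the continuous balances couple directly to the discrete chain transfer
rule: dissolved/redeposited mass accumulates until it exceeds the mass of a
chain in the source phase, at which point that chain changes phase.

The rate and thermal parameters are not experimentally printed quantities;
the defaults are stand-ins calibrated to the qualitative behavior of acid
fractionation at 353-363 K (fast early delignification converging to a
plateau set by redeposition, faster and deeper at the higher temperature).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

from .chains import ConfigurationError
from .kinetics import R_GAS, rate_coefficient


@dataclass(frozen=True)
class JacketInput:
    """Manipulated external-jacket conditions."""

    t_ext: float = 353.0  # K
    mdot_ext: float = 70.0  # mL/min


@dataclass
class MacroParams:
    """Macroscopic rate, thermal and integration parameters.

    Heat capacities may be temperature-dependent polynomials: ``cp_*`` holds
    ascending polynomial coefficients in T (constant by default).  Units:
    kJ, K, min, mL; lignin mass on the chain molar-mass scale.
    """

    a_d: float = 8.3e10  # min^-1
    e_d: float = 80.0  # kJ/mol
    a_r: float = 550.0  # min^-1
    e_r: float = 30.0  # kJ/mol
    cp_c: tuple[float, ...] = (0.0015,)  # kJ g^-1 K^-1
    cp_f: tuple[float, ...] = (0.00418,)  # kJ g^-1 K^-1
    cp_ext: tuple[float, ...] = (0.00418,)  # kJ mL^-1 K^-1
    m_c: float = 10.0  # g
    m_f: float = 100.0  # g
    dh_r: float = -1.0e-8  # kJ per lignin mass unit (delignification)
    u: float = 0.03  # kJ min^-1 K^-1
    dt: float = 5.0e-4  # min

    def __post_init__(self):
        if self.dt <= 0:
            raise ConfigurationError("dt must be positive")
        if self.m_c <= 0 or self.m_f <= 0:
            raise ConfigurationError("phase masses must be positive")
        for name in ("cp_c", "cp_f", "cp_ext"):
            if _polyval(getattr(self, name), 353.0) <= 0:
                raise ConfigurationError(f"{name} must be positive near 353 K")

    def k_d(self, t_c: float) -> float:
        return rate_coefficient(self.a_d, self.e_d, t_c)

    def k_r(self, t_f: float) -> float:
        return rate_coefficient(self.a_r, self.e_r, t_f)

    def heat_capacity(self, which: str, temperature: float) -> float:
        return _polyval(getattr(self, f"cp_{which}"), temperature)


def _polyval(coeffs: tuple[float, ...], t: float) -> float:
    acc = 0.0
    for c in reversed(coeffs):
        acc = acc * t + c
    return acc


def mass_balance_step(l_c: float, l_d: float, t_c: float, t_f: float,
                      params: MacroParams,
                      dt: float | None = None) -> tuple[float, float, float, float]:
    """One explicit-Euler step of the delignification/redeposition balance.

    Returns ``(l_c', l_d', dissolved_increment, redeposit_increment)`` where
    the increments are the gross one-way mass flows of this step (used to
    charge the chain-transfer accumulators).  Total mass is conserved
    exactly; a step that would overdraw a phase is clamped to empty it.
    """
    if l_c < 0 or l_d < 0:
        raise ConfigurationError("phase lignin masses must be non-negative")
    h = params.dt if dt is None else dt
    dissolved = params.k_d(t_c) * l_c * h
    redeposited = params.k_r(t_f) * l_d * h
    if dissolved > l_c:  # stiff-parameter guard
        dissolved = l_c
    if redeposited > l_d:
        redeposited = l_d
    return (l_c - dissolved + redeposited, l_d + dissolved - redeposited,
            dissolved, redeposited)


def energy_balance_step(t_c: float, t_f: float, r_d: float,
                        jacket: JacketInput, params: MacroParams,
                        dt: float | None = None) -> tuple[float, float]:
    """One explicit-Euler step of the two-phase energy balance.

    ``r_d`` is the instantaneous delignification rate (mass/min) feeding the
    reaction-enthalpy term of the chip phase.
    """
    if t_c <= 0 or t_f <= 0:
        raise ConfigurationError("temperatures must be positive")
    h = params.dt if dt is None else dt
    exchange = params.u * (t_f - t_c)
    dtc = (params.dh_r * r_d + exchange) / (params.heat_capacity("c", t_c) * params.m_c)
    dtf = (-exchange
           + params.heat_capacity("ext", t_f) * jacket.mdot_ext
           * (jacket.t_ext - t_f)) / (params.heat_capacity("f", t_f) * params.m_f)
    t_c2 = t_c + h * dtc
    t_f2 = t_f + h * dtf
    if not (math.isfinite(t_c2) and math.isfinite(t_f2)):
        raise ArithmeticError(
            "energy balance diverged; use a smaller time step")
    return t_c2, t_f2


def mass_balance_exact(l_c0: float, l_d0: float, k_d: float, k_r: float,
                       t: float) -> tuple[float, float]:
    """Closed-form solution of the constant-coefficient two-state balance.

    The linear system relaxes to the equilibrium split with rate
    ``k_d + k_r``; used as the integrator oracle.
    """
    total = l_c0 + l_d0
    s = k_d + k_r
    if s == 0.0:
        return l_c0, l_d0
    l_c_eq = total * k_r / s
    l_c = l_c_eq + (l_c0 - l_c_eq) * math.exp(-s * t)
    return l_c, total - l_c
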