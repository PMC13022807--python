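"""Arrhenius rate laws for the three microscale lignin reactions.

Rate coefficients follow ``k = A exp(-E / R T)`` with ``A`` in min^-1 and
``E`` in kJ/mol (converted to J/mol at the single exponent evaluation point).
Three reaction classes are modeled for dissolved chains:

* depolymerization -- first order; per beta-O-4 bond, with the bond's
  activation energy looked up by its flanking S/G dyad and temperature;
* condensation -- second order in chain concentration, with an activation
  energy that is a V-shaped function of the *combined* molar mass of the two
  partners, minimized at 972 g/mol;
* demethoxylation -- first order, scaled by the chain's S-unit fraction,
  with a single constant barrier (764 kJ/mol) whose enormous pre-exponential
  factor makes the reaction extremely temperature sensitive.

Chain copy numbers are converted to concentrations through the control-volume
factor ``omega``: each chain copy contributes a concentration ``1/omega``.

The per-dyad depolymerization energies and the condensation energy offset are
not experimentally printed quantities; the defaults shipped here are
documented, configurable stand-ins (see ``docs/methods.md`` for the
calibration rationale).  The V-function's slopes default to the value that
anchors the 353 K condensation window at a combined molar mass of
1672.33 g/mol.
"""

from __future__ import annotations

import io
import math
from dataclasses import dataclass, field

import numpy as np

from .chains import ConfigurationError, DYAD_NAMES, LigninChain

#: Gas constant, J mol^-1 K^-1.
R_GAS = 8.314

#: Largest exponent magnitude before exp() underflows to zero.
_EXP_UNDERFLOW = 745.0


def compute_threshold(temperature: float, ratio_cutoff: float = 1000.0) -> float:
    """Activation-energy threshold ``R T ln(ratio_cutoff)`` in kJ/mol.

    Two Arrhenius reactions whose barriers differ by more than this amount
    have rate coefficients separated by more than ``ratio_cutoff`` at the
    given temperature.
    """
    if temperature <= 0:
        raise ConfigurationError("temperature must be positive")
    if ratio_cutoff <= 1:
        raise ConfigurationError("ratio_cutoff must exceed 1")
    return R_GAS * temperature * math.log(ratio_cutoff) / 1000.0


# Anchors of the default condensation-energy parameterization.
_VERTEX_MW_DEFAULT = 972.0
_WINDOW_HIGH_353 = 1672.33
#: Slope that reproduces the printed 353 K window bound: at 353 K the
#: threshold equals the energy rise from the vertex to 1672.33 g/mol.
DEFAULT_CON_SLOPE = compute_threshold(353.0) / (_WINDOW_HIGH_353 - _VERTEX_MW_DEFAULT)


@dataclass(frozen=True)
class ArrheniusParams:
    """Pre-exponential factors (min^-1) and the demethoxylation barrier."""

    a_dep: float = 4.8e22
    a_con: float = 2.5e20
    a_dem: float = 9.5e104
    e_dem: float = 764.0  # kJ/mol

    def __post_init__(self):
        if min(self.a_dep, self.a_con, self.a_dem) <= 0:
            raise ConfigurationError("pre-exponential factors must be positive")


def rate_coefficient(a: float, e_kj: float, temperature: float) -> float:
    """Arrhenius rate coefficient ``A exp(-E/RT)`` in min^-1.

    Energies are in kJ/mol; this is the single point where they are converted
    to J/mol.  Coefficients that underflow evaluate cleanly to 0.0.
    """
    if temperature <= 0:
        raise ConfigurationError("temperature must be positive")
    x = e_kj * 1000.0 / (R_GAS * temperature) - math.log(a)
    if x > _EXP_UNDERFLOW:
        return 0.0
    if x < -_EXP_UNDERFLOW:  # pathological A/E combination
        return math.inf
    return math.exp(-x)


class DepolymerizationEnergyTable:
    """Per-dyad beta-O-4 scission activation energies versus temperature.

    Energies (kJ/mol) are tabulated on a temperature grid for each of the
    four flanking dyads SS, SG, GS, GG and linearly interpolated in between
    (clamped at the grid ends).  Lookups are pure functions of (dyad, T).
    """

    def __init__(self, temperatures, energies: dict[str, list[float]]):
        self.temperatures = np.asarray(temperatures, dtype=float)
        if self.temperatures.ndim != 1 or len(self.temperatures) < 1:
            raise ConfigurationError("temperature grid must be a 1-D list")
        if np.any(np.diff(self.temperatures) <= 0):
            raise ConfigurationError("temperature grid must be increasing")
        rows = []
        for name in DYAD_NAMES:
            if name not in energies:
                raise ConfigurationError(f"missing dyad {name} in energy table")
            vals = np.asarray(energies[name], dtype=float)
            if vals.shape != self.temperatures.shape:
                raise ConfigurationError(
                    f"dyad {name}: {len(vals)} energies for "
                    f"{len(self.temperatures)} temperatures")
            if not np.all(np.isfinite(vals)) or np.any(vals <= 0):
                raise ConfigurationError(
                    f"dyad {name}: energies must be positive and finite")
            rows.append(vals)
        self._table = np.vstack(rows)  # (4, n_T)

    @classmethod
    def default(cls) -> "DepolymerizationEnergyTable":
        """Stand-in energy library (kJ/mol) at the 353/363 K study grid."""
        return cls([353.0, 363.0], {
            "SS": [187.5, 192.5],
            "SG": [190.0, 195.0],
            "GS": [192.0, 197.0],
            "GG": [195.0, 200.0],
        })

    def energies_at(self, temperature: float) -> np.ndarray:
        """The four dyad energies (kJ/mol) interpolated at ``temperature``."""
        t = np.clip(temperature, self.temperatures[0], self.temperatures[-1])
        return np.array([np.interp(t, self.temperatures, row)
                         for row in self._table])

    def energy(self, dyad: int | str, temperature: float) -> float:
        idx = DYAD_NAMES.index(dyad) if isinstance(dyad, str) else dyad
        return float(self.energies_at(temperature)[idx])

    # -- CSV provenance ----------------------------------------------------
    def to_csv(self, path_or_buf) -> None:
        buf = io.StringIO()
        buf.write("dyad,temperature_K,E_dep_kJ_mol\n")
        for d, name in enumerate(DYAD_NAMES):
            for j, t in enumerate(self.temperatures):
                buf.write(f"{name},{t:g},{self._table[d, j]:g}\n")
        text = buf.getvalue()
        if hasattr(path_or_buf, "write"):
            path_or_buf.write(text)
        else:
            with open(path_or_buf, "w") as fh:
                fh.write(text)

    @classmethod
    def from_csv(cls, path_or_buf) -> "DepolymerizationEnergyTable":
        if hasattr(path_or_buf, "read"):
            lines = path_or_buf.read().splitlines()
        else:
            with open(path_or_buf) as fh:
                lines = fh.read().splitlines()
        temps: list[float] = []
        data: dict[str, dict[float, float]] = {n: {} for n in DYAD_NAMES}
        for line in lines[1:]:
            if not line.strip():
                continue
            name, t_s, e_s = line.split(",")
            t = float(t_s)
            if t not in temps:
                temps.append(t)
            data[name][t] = float(e_s)
        temps.sort()
        energies = {}
        for name in DYAD_NAMES:
            try:
                energies[name] = [data[name][t] for t in temps]
            except KeyError as exc:
                raise ConfigurationError(
                    f"dyad {name} missing temperature {exc}") from exc
        return cls(temps, energies)


@dataclass(frozen=True)
class CondensationEnergyFunction:
    """V-shaped condensation barrier versus combined molar mass.

    ``E_con(mw) = e_min + slope_high * (mw - vertex_mw)`` above the vertex
    and ``e_min + slope_low * (vertex_mw - mw)`` below it; strictly minimized
    at ``vertex_mw`` (972 g/mol, a combined chain length of 4-5 units).
    The barrier is taken as temperature independent; temperature enters the
    kinetics only through the Boltzmann factor and the filtering threshold.
    """

    vertex_mw: float = _VERTEX_MW_DEFAULT
    e_min: float = 228.0  # kJ/mol, configurable stand-in
    slope_low: float = DEFAULT_CON_SLOPE
    slope_high: float = DEFAULT_CON_SLOPE

    def __post_init__(self):
        if self.vertex_mw <= 0 or self.e_min <= 0:
            raise ConfigurationError("vertex_mw and e_min must be positive")
        if self.slope_low <= 0 or self.slope_high <= 0:
            raise ConfigurationError("condensation slopes must be positive")

    def __call__(self, combined_mw):
        mw = np.asarray(combined_mw, dtype=float)
        dv = mw - self.vertex_mw
        e = self.e_min + np.where(dv >= 0, self.slope_high * dv,
                                  -self.slope_low * dv)
        return float(e) if np.isscalar(combined_mw) else e

    def window(self, delta_e_th: float) -> tuple[float, float]:
        """Combined-MW interval where ``E_con <= e_min + delta_e_th``."""
        low = self.vertex_mw - delta_e_th / self.slope_low
        high = self.vertex_mw + delta_e_th / self.slope_high
        return max(low, 0.0), high


@dataclass
class Kinetics:
    """Bundle of every microscale kinetic ingredient.

    ``omega`` is the control-volume normalization: a chain copy has
    concentration ``1/omega``, so first-order propensities scale as
    ``k/omega`` and second-order ones as ``k/omega**2``.
    """

    params: ArrheniusParams = field(default_factory=ArrheniusParams)
    dep_table: DepolymerizationEnergyTable = field(
        default_factory=DepolymerizationEnergyTable.default)
    con_energy: CondensationEnergyFunction = field(
        default_factory=CondensationEnergyFunction)
    omega: float = 3.5e-4

    def __post_init__(self):
        if self.omega <= 0:
            raise ConfigurationError("omega must be positive")

    # -- rate coefficients -------------------------------------------------
    def k_dep_dyads(self, temperature: float) -> np.ndarray:
        """Scission rate coefficients (min^-1) for the four dyads."""
        es = self.dep_table.energies_at(temperature)
        return np.array([rate_coefficient(self.params.a_dep, e, temperature)
                         for e in es])

    def k_con(self, combined_mw, temperature: float):
        """Condensation rate coefficient(s) for combined molar mass(es)."""
        e = self.con_energy(combined_mw)
        if np.isscalar(combined_mw):
            return rate_coefficient(self.params.a_con, e, temperature)
        x = np.asarray(e) * 1000.0 / (R_GAS * temperature) - math.log(self.params.a_con)
        out = np.zeros_like(x)
        ok = x <= _EXP_UNDERFLOW
        out[ok] = np.exp(-x[ok])
        return out

    def k_dem(self, temperature: float) -> float:
        return rate_coefficient(self.params.a_dem, self.params.e_dem, temperature)

    # -- propensities ------------------------------------------------------
    def depolymerization_rate(self, chain: LigninChain, bond_index: int,
                              temperature: float) -> float:
        """Propensity of cleaving one specific bond (min^-1)."""
        dyads = chain.bond_dyads()
        e = self.dep_table.energy(dyads[bond_index], temperature)
        return rate_coefficient(self.params.a_dep, e, temperature) / self.omega

    def condensation_rate(self, chain_i: LigninChain, chain_j: LigninChain,
                          temperature: float) -> float:
        """Propensity of merging two specific chains (min^-1); symmetric."""
        k = self.k_con(chain_i.mw + chain_j.mw, temperature)
        return k / (self.omega * self.omega)

    def demethoxylation_rate(self, chain: LigninChain,
                             temperature: float) -> float:
        """Propensity of converting one S unit of this chain (min^-1)."""
        return self.k_dem(temperature) * chain.f_s / self.omega
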