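"""Run configuration: validated parameters, YAML I/O and output writers.

Every parameter with a published value defaults to it exactly (monomer
masses 227.2/179.2 g/mol, pre-exponential factors 4.8e22 / 2.5e20 / 9.5e104
min^-1, demethoxylation barrier 764 kJ/mol, macroscopic step 5e-4 min,
filter ratio cutoff 1000, condensation vertex 972 g/mol, pristine targets
Mn 13,000 g/mol and S/G 1.76, operating temperatures 353/363 K, controller
horizon/bounds/ramp).  Everything else is a documented stand-in (see
``docs/methods.md``).  Configuration files are YAML; unknown keys are
rejected and validation errors name the offending key.
"""

from __future__ import annotations

import hashlib
import json
from pathlib import Path
from typing import Literal, Optional

import pandas as pd
import yaml
from pydantic import BaseModel, ConfigDict, Field, ValidationError, model_validator

from . import __version__
from .chains import ConfigurationError, MonomerMasses, initialize_system
from .kinetics import (ArrheniusParams, CondensationEnergyFunction,
                       DepolymerizationEnergyTable, Kinetics,
                       DEFAULT_CON_SLOPE)
from .macro import JacketInput, MacroParams


class _Model(BaseModel):
    model_config = ConfigDict(extra="forbid", validate_assignment=True)


class MonomerConfig(_Model):
    s_mass: float = Field(227.2, gt=0)
    g_mass: float = Field(179.2, gt=0)


class DepTableConfig(_Model):
    """Per-dyad scission energies (kJ/mol) on a temperature grid (K)."""

    temperatures: list[float] = [353.0, 363.0]
    SS: list[float] = [187.5, 192.5]
    SG: list[float] = [190.0, 195.0]
    GS: list[float] = [192.0, 197.0]
    GG: list[float] = [195.0, 200.0]


class CondensationConfig(_Model):
    vertex_mw: float = Field(972.0, gt=0)
    e_min: float = Field(228.0, gt=0)
    #: None picks the slope anchoring the 353 K window at 1672.33 g/mol.
    slope_low: Optional[float] = Field(None, gt=0)
    slope_high: Optional[float] = Field(None, gt=0)


class ArrheniusConfig(_Model):
    a_dep: float = Field(4.8e22, gt=0)
    a_con: float = Field(2.5e20, gt=0)
    a_dem: float = Field(9.5e104, gt=0)
    e_dem: float = Field(764.0, gt=0)


class KineticsConfig(_Model):
    arrhenius: ArrheniusConfig = ArrheniusConfig()
    dep_table: DepTableConfig = DepTableConfig()
    condensation: CondensationConfig = CondensationConfig()
    omega: float = Field(3.5e-4, gt=0)


class MacroConfig(_Model):
    a_d: float = Field(8.3e10, gt=0)
    e_d: float = Field(80.0, ge=0)
    a_r: float = Field(550.0, gt=0)
    e_r: float = Field(30.0, ge=0)
    cp_c: list[float] = [0.0015]
    cp_f: list[float] = [0.00418]
    cp_ext: list[float] = [0.00418]
    m_c: float = Field(10.0, gt=0)
    m_f: float = Field(100.0, gt=0)
    dh_r: float = -1.0e-8
    u: float = Field(0.03, ge=0)
    dt: float = Field(5.0e-4, gt=0)


class FilterConfig(_Model):
    ratio_cutoff: float = Field(1000.0, gt=1.0)


class InitConfig(_Model):
    n_chains: int = Field(500, ge=1)
    target_mn: float = Field(13000.0, gt=0)
    target_sg: float = Field(1.76, gt=0)
    temperature: float = Field(353.0, gt=0)


class MpcConfig(_Model):
    mw_setpoint: float = Field(1500.0, gt=0)
    sg_setpoint: float = Field(1.50, gt=0)
    #: None means 1/setpoint^2 (normalized outputs).
    weight_mw: Optional[float] = Field(None, gt=0)
    weight_sg: Optional[float] = Field(None, gt=0)
    horizon: int = Field(6, ge=1)
    interval_min: float = Field(5.0, gt=0)
    t_ext_min: float = Field(343.0, gt=0)
    t_ext_max: float = Field(363.0, gt=0)
    flow_min: float = Field(40.0, gt=0)
    flow_max: float = Field(100.0, gt=0)
    ramp_limit: float = Field(5.0, gt=0)
    t_grid_step: float = Field(0.3125, gt=0)
    flow_grid: list[float] = [40.0, 100.0]
    move_blocking: int = Field(2, ge=1)
    refine_top: int = Field(6, ge=1)
    replicates: int = Field(2, ge=1)
    internal_fraction: float = Field(0.4, gt=0, le=1.0)
    internal_dt_factor: float = Field(20.0, ge=1.0)
    tiebreak_band: float = Field(1.0e-3, ge=0.0)

    @model_validator(mode="after")
    def _check(self):
        if self.t_ext_max <= self.t_ext_min:
            raise ValueError("t_ext_max must exceed t_ext_min")
        n_steps = self.ramp_limit / self.t_grid_step
        if abs(n_steps - round(n_steps)) > 1e-9:
            raise ValueError("t_grid_step must divide ramp_limit")
        for f in self.flow_grid:
            if not self.flow_min <= f <= self.flow_max:
                raise ValueError(f"flow_grid value {f} outside bounds")
        return self


class RunConfig(_Model):
    """Top-level configuration; an empty file yields all defaults."""

    seed: int = 12345
    duration_min: float = Field(30.0, ge=0)
    engine: Literal["full", "filtered"] = "filtered"
    jacket_t_ext: float = Field(353.0, gt=0)
    jacket_mdot: float = Field(70.0, gt=0)
    record_every_min: float = Field(0.5, gt=0)
    event_log: bool = False
    monomers: MonomerConfig = MonomerConfig()
    kinetics: KineticsConfig = KineticsConfig()
    macro: MacroConfig = MacroConfig()
    filter: FilterConfig = FilterConfig()
    init: InitConfig = InitConfig()
    mpc: MpcConfig = MpcConfig()


def load_config(path) -> RunConfig:
    """Load and validate a YAML configuration file."""
    p = Path(path)
    if not p.exists():
        raise ConfigurationError(f"configuration file not found: {p}")
    data = yaml.safe_load(p.read_text())
    if data is None:
        data = {}
    try:
        return RunConfig(**data)
    except ValidationError as exc:
        raise ConfigurationError(f"invalid configuration: {exc}") from exc


def save_config(config: RunConfig, path) -> None:
    Path(path).write_text(yaml.safe_dump(config.model_dump(), sort_keys=False))


def config_hash(config: RunConfig) -> str:
    """Stable short hash of the full parameter set, for provenance."""
    blob = json.dumps(config.model_dump(), sort_keys=True).encode()
    return hashlib.sha256(blob).hexdigest()[:16]


# ---------------------------------------------------------------------------
# Builders: config -> domain objects
# ---------------------------------------------------------------------------

def build_masses(config: RunConfig) -> MonomerMasses:
    return MonomerMasses(config.monomers.s_mass, config.monomers.g_mass)


def build_kinetics(config: RunConfig) -> Kinetics:
    kc = config.kinetics
    table = DepolymerizationEnergyTable(
        kc.dep_table.temperatures,
        {n: getattr(kc.dep_table, n) for n in ("SS", "SG", "GS", "GG")})
    con = CondensationEnergyFunction(
        vertex_mw=kc.condensation.vertex_mw,
        e_min=kc.condensation.e_min,
        slope_low=kc.condensation.slope_low or DEFAULT_CON_SLOPE,
        slope_high=kc.condensation.slope_high or DEFAULT_CON_SLOPE)
    params = ArrheniusParams(kc.arrhenius.a_dep, kc.arrhenius.a_con,
                             kc.arrhenius.a_dem, kc.arrhenius.e_dem)
    return Kinetics(params=params, dep_table=table, con_energy=con,
                    omega=kc.omega)


def build_macro(config: RunConfig) -> MacroParams:
    mc = config.macro
    return MacroParams(a_d=mc.a_d, e_d=mc.e_d, a_r=mc.a_r, e_r=mc.e_r,
                       cp_c=tuple(mc.cp_c), cp_f=tuple(mc.cp_f),
                       cp_ext=tuple(mc.cp_ext), m_c=mc.m_c, m_f=mc.m_f,
                       dh_r=mc.dh_r, u=mc.u, dt=mc.dt)


def build_state(config: RunConfig, seed: int | None = None,
                n_chains: int | None = None):
    ic = config.init
    return initialize_system(
        n_chains=n_chains if n_chains is not None else ic.n_chains,
        target_mn=ic.target_mn, target_sg=ic.target_sg,
        temperature=ic.temperature,
        seed=config.seed if seed is None else seed,
        masses=build_masses(config))


def build_jacket(config: RunConfig) -> JacketInput:
    return JacketInput(config.jacket_t_ext, config.jacket_mdot)


# ---------------------------------------------------------------------------
# Output bundle
# ---------------------------------------------------------------------------

def run_simulation(config: RunConfig, out_dir) -> dict:
    """Open-loop simulation with the full output bundle.

    Writes ``timeseries.csv``, ``mwd_final.csv``, ``chains_final.jsonl`` and
    ``summary.json`` (with a provenance block) into ``out_dir`` and returns
    the summary dictionary.
    """
    from .chains import LIQUOR, compute_observables, EmptyPhaseError
    from .runner import simulate

    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)

    kin = build_kinetics(config)
    macro = build_macro(config)
    state = build_state(config)
    result = simulate(state, kin, macro, config.duration_min,
                      jacket=build_jacket(config),
                      filtered=config.engine == "filtered",
                      ratio_cutoff=config.filter.ratio_cutoff,
                      record_every=config.record_every_min)

    ts = result.timeseries
    ts.to_csv(out / "timeseries.csv", index=False, float_format="%.10g")

    reg = state.registry
    try:
        obs = compute_observables(reg, LIQUOR, bins=40)
        final = {"Mn": obs["Mn"], "Mw": obs["Mw"], "sg_ratio": obs["sg_ratio"],
                 "n_liquor_chains": obs["n_chains"]}
        mwd = pd.DataFrame({
            "mw_low": obs["mwd_edges"][:-1],
            "mw_high": obs["mwd_edges"][1:],
            "count": obs["mwd_counts"]})
    except EmptyPhaseError:
        final = {"Mn": None, "Mw": None, "sg_ratio": None,
                 "n_liquor_chains": 0}
        mwd = pd.DataFrame(columns=["mw_low", "mw_high", "count"])
    mwd.to_csv(out / "mwd_final.csv", index=False)

    e4 = kin.dep_table.energies_at(state.t_f)
    reg.to_jsonl(out / "chains_final.jsonl", energy_of_dyad=e4.__getitem__)

    summary = {
        "provenance": {
            "package": "ligfrac",
            "version": __version__,
            "seed": config.seed,
            "config_hash": config_hash(config),
            "engine": config.engine,
        },
        "final": {
            **final,
            "residual_chip_fraction": (
                reg.agg["chip"].sum_mw / reg.total_mass()
                if reg.total_mass() > 0 else None),
            "T_f": state.t_f,
            "T_c": state.t_c,
        },
        "event_counts": result.event_counts,
        "n_transfers": result.n_transfers,
        "candidate_stats": result.candidate_stats,
    }
    (out / "summary.json").write_text(json.dumps(summary, indent=2))
    return summary
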