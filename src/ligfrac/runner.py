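"""Coupled macro/micro simulation driver.

Each macroscopic step of length ``dt`` (default 5e-4 min):

1. advances the delignification/redeposition mass balance (explicit Euler)
   and charges the gross one-way flows to the transfer accumulators;
2. advances the two-phase energy balance under the current jacket input;
3. moves whole chains across the chip/liquor boundary while an accumulator
   covers the mass of an eligible chain (uniformly chosen among them);
4. refreshes the temperature-adaptive threshold/coefficient caches and runs
   the Gillespie loop for the remainder of the interval.

The loop body is deliberately flat scalar arithmetic: a 30-minute run is
60,000 macro steps and sits inside the predictive controller's inner
optimization, so per-step overhead dominates the cost of everything else.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Callable, Optional

import numpy as np
import pandas as pd

from .chains import (CHIP, LIQUOR, ChainRegistry, SystemState,
                     compute_observables, transfer_chain)
from .engine import LiveCatalog, run_micro_interval
from .kinetics import Kinetics
from .macro import JacketInput, MacroParams

_REC_COLUMNS = ["t_min", "L_c", "L_d", "T_c", "T_f", "T_ext", "Mdot_ext",
                "Mn", "Mw", "SG", "n_liquor_chains", "r_tot",
                "events_per_interval"]


@dataclass
class SimulationResult:
    timeseries: pd.DataFrame
    event_counts: dict
    n_transfers: dict
    final_state: SystemState
    candidate_stats: dict = field(default_factory=dict)


class Simulator:
    """Owns a system state, a kinetics bundle and a live event catalog."""

    def __init__(self, state: SystemState, kinetics: Kinetics,
                 macro: MacroParams, filtered: bool = True,
                 ratio_cutoff: float = 1000.0,
                 rng: np.random.Generator | None = None,
                 enable_micro: bool = True):
        self.state = state
        self.kin = kinetics
        self.macro = macro
        self.filtered = filtered
        self.rng = rng if rng is not None else state.rng
        self.enable_micro = enable_micro
        self.catalog = LiveCatalog(state.registry, kinetics, state.t_f,
                                   filtered, ratio_cutoff)
        self.event_counts: dict[str, int] = {}
        self.n_transfers = {"dissolve": 0, "redeposit": 0}
        self.jacket = JacketInput()

    # -- single macro step --------------------------------------------------
    def macro_step(self, jacket: JacketInput | None = None) -> None:
        """One coupled step: mass balance, energy balance, transfers, micro."""
        if jacket is not None:
            self.jacket = jacket
        state = self.state
        reg = state.registry
        macro = self.macro
        dt = macro.dt
        agg_c = reg.agg[CHIP]
        agg_f = reg.agg[LIQUOR]

        l_c = agg_c.sum_mw
        l_d = agg_f.sum_mw
        t_c = state.t_c
        t_f = state.t_f
        k_d = macro.k_d(t_c)
        k_r = macro.k_r(t_f)
        dissolved = k_d * l_c * dt
        redeposited = k_r * l_d * dt
        reg.dissolved_accumulator += dissolved
        reg.redeposit_accumulator += redeposited

        jk = self.jacket
        exchange = macro.u * (t_f - t_c)
        r_d = k_d * l_c
        state.t_c = t_c + dt * (macro.dh_r * r_d + exchange) / (
            macro.heat_capacity("c", t_c) * macro.m_c)
        state.t_f = t_f + dt * (
            -exchange + macro.heat_capacity("ext", t_f) * jk.mdot_ext
            * (jk.t_ext - t_f)) / (macro.heat_capacity("f", t_f) * macro.m_f)

        self._do_transfers(reg)

        if self.enable_micro:
            run_micro_interval(state, dt, self.catalog, self.rng,
                               event_counts=self.event_counts)
        state.clock += dt

    def _do_transfers(self, reg: ChainRegistry) -> None:
        while reg.dissolved_accumulator >= reg.min_mass_bound(CHIP):
            chain = transfer_chain(reg, "dissolve", self.rng)
            if chain is None:
                break
            self.n_transfers["dissolve"] += 1
        while reg.redeposit_accumulator >= reg.min_mass_bound(LIQUOR):
            chain = transfer_chain(reg, "redeposit", self.rng)
            if chain is None:
                break
            self.n_transfers["redeposit"] += 1

    # -- runs ---------------------------------------------------------------
    def run(self, duration: float,
            jacket: JacketInput | Callable[[float], JacketInput] | None = None,
            record_every: float | None = None,
            records: list | None = None) -> Optional[list]:
        """Advance the coupled simulation by ``duration`` minutes."""
        state = self.state
        dt = self.macro.dt
        n_steps = int(round(duration / dt))
        rec_stride = (max(1, int(round(record_every / dt)))
                      if record_every else None)
        jacket_fn = jacket if callable(jacket) else None
        if jacket is not None and jacket_fn is None:
            self.jacket = jacket
        events_before = sum(self.event_counts.values())

        for step in range(n_steps):
            if jacket_fn is not None:
                self.jacket = jacket_fn(state.clock)
            self.macro_step()
            if records is not None and rec_stride and (step + 1) % rec_stride == 0:
                events_now = sum(self.event_counts.values())
                records.append(self._record_row(events_now - events_before))
                events_before = events_now
        return records

    def _record_row(self, events_in_interval: int) -> dict:
        state = self.state
        reg = state.registry
        agg_f = reg.agg[LIQUOR]
        if agg_f.n > 0:
            obs = compute_observables(reg, LIQUOR)
            mn, mw, sg = obs["Mn"], obs["Mw"], obs["sg_ratio"]
        else:
            mn = mw = sg = float("nan")
        return {
            "t_min": state.clock,
            "L_c": reg.agg[CHIP].sum_mw,
            "L_d": agg_f.sum_mw,
            "T_c": state.t_c,
            "T_f": state.t_f,
            "T_ext": self.jacket.t_ext,
            "Mdot_ext": self.jacket.mdot_ext,
            "Mn": mn,
            "Mw": mw,
            "SG": sg,
            "n_liquor_chains": agg_f.n,
            "r_tot": self.catalog.total_rate(),
            "events_per_interval": events_in_interval,
        }

    def measure(self) -> dict:
        """Current liquor observables (NaN before anything dissolves)."""
        return self._record_row(0)


def simulate(state: SystemState, kinetics: Kinetics, macro: MacroParams,
             duration: float, jacket: JacketInput | None = None,
             filtered: bool = True, ratio_cutoff: float = 1000.0,
             record_every: float = 0.5,
             rng: np.random.Generator | None = None) -> SimulationResult:
    """Open-loop run under a fixed jacket input; returns a time series."""
    sim = Simulator(state, kinetics, macro, filtered=filtered,
                    ratio_cutoff=ratio_cutoff, rng=rng)
    records: list = [sim._record_row(0)]
    sim.run(duration, jacket=jacket or JacketInput(),
            record_every=record_every, records=records)
    ts = pd.DataFrame.from_records(records, columns=_REC_COLUMNS)
    return SimulationResult(ts, dict(sim.event_counts),
                            dict(sim.n_transfers), state,
                            sim.catalog.candidate_stats())
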