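"""Gillespie engine: catalog construction, sampling statistics and the
incremental live catalog against the explicit oracle."""

import math
from collections import Counter

import numpy as np
import pytest
from scipy import stats

from ligfrac.chains import G, LIQUOR, S, apply_scission
from ligfrac.engine import (CON, DEM, DEP, EventCatalog, LiveCatalog,
                            build_catalog_snapshot, build_full_catalog,
                            execute_event, gillespie_step,
                            run_micro_interval)
from ligfrac.kinetics import Kinetics

from conftest import make_registry, make_state


def catalog_key(cat: EventCatalog):
    """Order-insensitive comparable representation (positive events only)."""
    out = set()
    for e in cat.events:
        if e.propensity <= 0:
            continue
        if e.kind == CON:
            ident = frozenset((e.chain_id, e.partner_id))
        else:
            ident = (e.chain_id, e.site)
        out.add((e.kind, ident, round(math.log(e.propensity), 9)))
    return out


class TestFullCatalog:
    def test_combinatorial_event_counts(self, toy_liquor_registry, kinetics):
        cat = build_full_catalog(toy_liquor_registry, kinetics, 353.0)
        kinds = Counter(e.kind for e in cat.events)
        assert kinds[DEP] == 3  # 2 + 1 + 0 bonds
        assert kinds[CON] == 3  # C(3, 2) pairs
        assert kinds[DEM] == 2  # chains containing S
        assert cat.r_tot == pytest.approx(cat.recompute_r_tot())

    def test_empty_liquor_gives_zero_rate(self, kinetics):
        reg = make_registry([])
        cat = build_full_catalog(reg, kinetics, 353.0)
        assert cat.r_tot == 0.0
        assert cat.events == []


class TestGillespieStep:
    def test_waiting_time_closed_form(self, kinetics):
        cat = EventCatalog([], 2.0, "full")
        cat.events = [type("E", (), {})]  # placeholder, not selected

        class FixedRng:
            def __init__(self):
                self.calls = 0

            def random(self):
                self.calls += 1
                return math.exp(-1.0) if self.calls == 1 else 0.0

        reg = make_registry([[S, G]])
        real = build_full_catalog(reg, kinetics, 353.0)
        real.r_tot = 2.0  # force the printed example rate
        ev, dt = gillespie_step(real, FixedRng())
        assert dt == pytest.approx(0.5)

    def test_zero_rate_signals_no_activity(self, rng):
        ev, dt = gillespie_step(EventCatalog([], 0.0, "full"), rng)
        assert ev is None and math.isinf(dt)

    def test_selection_frequencies_match_propensities(self, rng):
        from ligfrac.engine import Event
        events = [Event(DEP, 0, site=0, propensity=3.0),
                  Event(DEP, 1, site=0, propensity=1.0)]
        cat = EventCatalog(events, 4.0, "full")
        counts = Counter()
        n = 10_000
        for _ in range(n):
            ev, _ = gillespie_step(cat, rng)
            counts[ev.chain_id] += 1
        # chi-square against the exact 0.75 / 0.25 multinomial
        chi2 = sum((counts[i] - p * n) ** 2 / (p * n)
                   for i, p in ((0, 0.75), (1, 0.25)))
        assert chi2 < stats.chi2.ppf(0.999, df=1)

    def test_mean_waiting_time_is_inverse_rate(self, rng):
        from ligfrac.engine import Event
        cat = EventCatalog([Event(DEP, 0, site=0, propensity=5.0)], 5.0, "full")
        dts = [gillespie_step(cat, rng)[1] for _ in range(10_000)]
        se = np.std(dts) / math.sqrt(len(dts))
        assert abs(np.mean(dts) - 0.2) < 3 * se


class TestLiveCatalog:
    @pytest.mark.parametrize("filtered", [False, True])
    def test_matches_snapshot_oracle_through_events(self, filtered, rng):
        kin = Kinetics()
        state = make_state(
            [(rng.random(2 + int(rng.random() * 10)) < 0.6).astype(int).tolist()
             for _ in range(12)])
        live = LiveCatalog(state.registry, kin, 353.0, filtered=filtered)
        for _ in range(60):
            oracle = build_catalog_snapshot(state.registry, kin, 353.0,
                                            filtered=filtered)
            assert catalog_key(live.snapshot()) == catalog_key(oracle)
            assert live.total_rate() == pytest.approx(oracle.r_tot, rel=1e-9)
            if oracle.r_tot == 0:
                break
            ev = live.sample(rng.random(), rng)
            execute_event(state.registry, ev, rng)

    def test_aggregate_rate_equals_per_event_sum(self, toy_liquor_registry,
                                                 kinetics):
        live = LiveCatalog(toy_liquor_registry, kinetics, 353.0, filtered=True)
        snap = live.snapshot()
        assert live.total_rate() == pytest.approx(snap.recompute_r_tot())

    def test_executed_events_change_the_state(self, rng):
        kin = Kinetics()
        state = make_state([[S, G, S, G], [G, S]])
        live = LiveCatalog(state.registry, kin, 353.0, filtered=True)
        for _ in range(5):
            before = {cid: list(c.units)
                      for cid, c in state.registry.chains.items()}
            ev = live.sample(rng.random(), rng)
            execute_event(state.registry, ev, rng)
            after = {cid: list(c.units)
                     for cid, c in state.registry.chains.items()}
            assert before != after

    def test_temperature_refresh_keeps_oracle_equality(self, rng):
        kin = Kinetics()
        state = make_state([[S, G, S], [G, G, S], [S, S]])
        live = LiveCatalog(state.registry, kin, 353.0, filtered=True)
        for t in (355.0, 359.0, 363.0):
            live.set_temperature(t)
            oracle = build_catalog_snapshot(state.registry, kin, t,
                                            filtered=True)
            assert catalog_key(live.snapshot()) == catalog_key(oracle)
            assert live.total_rate() == pytest.approx(oracle.r_tot, rel=1e-9)


class TestMicroInterval:
    def test_first_waiting_time_beyond_interval_executes_nothing(self):
        kin = Kinetics()
        state = make_state([[G, G]])  # single slow GG bond, no S
        live = LiveCatalog(state.registry, kin, 353.0, filtered=True)
        n = run_micro_interval(state, 1e-9, live, state.rng)
        assert n == 0

    def test_poisson_event_count_on_single_bond_toy(self):
        """One bond with propensity r: executed-event count over many short
        intervals follows the Poisson law with mean r*dt."""
        kin = Kinetics()
        total = 0
        n_trials = 400
        dt = 0.5
        rate = None
        for trial in range(n_trials):
            state = make_state([[G, G]], seed=trial)
            live = LiveCatalog(state.registry, kin, 353.0, filtered=True)
            if rate is None:
                rate = live.total_rate()
            # count only the first scission (chain has one bond)
            total += run_micro_interval(state, dt, live, state.rng)
        p_event = 1.0 - math.exp(-rate * dt)  # single bond, one event max
        expected = n_trials * p_event
        sd = math.sqrt(n_trials * p_event * (1 - p_event))
        assert abs(total - expected) < 4 * sd + 1

    def test_exponential_bond_survival(self):
        """First-order decay: the surviving fraction of identical bonds
        matches exp(-k t) within binomial error."""
        kin = Kinetics()
        n_bonds = 2000
        state = make_state([[G, G] for _ in range(n_bonds)], seed=9)
        live = LiveCatalog(state.registry, kin, 353.0, filtered=True)
        k_bond = kin.k_dep_dyads(353.0)[3] / kin.omega  # GG dyad
        t_run = 0.3 / k_bond
        n_steps = 60
        for _ in range(n_steps):
            run_micro_interval(state, t_run / n_steps, live, state.rng)
        # two-unit chains have no S units and cannot condense back to
        # dimers' masses influencing counts; surviving bonds = dimers left
        survivors = sum(1 for c in state.registry.chains.values()
                        if c.n_bonds == 1)
        p = math.exp(-k_bond * t_run)
        sd = math.sqrt(n_bonds * p * (1 - p))
        assert abs(survivors - n_bonds * p) < 4 * sd

    def test_event_counts_reproducible_under_fixed_seed(self):
        kin = Kinetics()

        def run(seed):
            state = make_state(
                [[S, G, S, G, G, S] for _ in range(20)], seed=seed)
            live = LiveCatalog(state.registry, kin, 363.0, filtered=True)
            counts = {}
            for _ in range(200):
                run_micro_interval(state, 0.01, live, state.rng,
                                   event_counts=counts)
            return counts, sorted(
                (c.sequence_string(), c.phase)
                for c in state.registry.chains.values())

        assert run(7) == run(7)
        assert run(7) != run(8)  # and the dynamics are not frozen
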