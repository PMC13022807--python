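"""Chain representation, registry aggregates and the event primitives."""

import math

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from ligfrac.chains import (CHIP, EmptyPhaseError, EventError, G, LIQUOR,
                            ChainRegistry, MonomerMasses, S,
                            apply_condensation, apply_demethoxylation,
                            apply_scission, compute_observables,
                            initialize_system, transfer_chain)

from conftest import make_registry


class TestInitializer:
    def test_recovers_pristine_averages(self):
        state = initialize_system(5000, target_mn=13000.0, target_sg=1.76,
                                  seed=42)
        obs = compute_observables(state.registry, CHIP)
        assert obs["Mn"] == pytest.approx(13000.0, rel=0.02)
        assert obs["sg_ratio"] == pytest.approx(1.76, rel=0.02)

    def test_mean_chain_length_matches_closed_form(self):
        # expected unit mass (1.76*227.2 + 179.2)/2.76 = 209.81 g/mol
        m = MonomerMasses().mean_unit_mass(1.76)
        assert m == pytest.approx(209.81, abs=0.01)
        state = initialize_system(4000, seed=3)
        agg = state.registry.agg[CHIP]
        assert agg.units / agg.n == pytest.approx(13000.0 / m, rel=0.03)

    def test_single_all_s_unit_limit(self):
        state = initialize_system(1, target_mn=227.2, target_sg=1e9, seed=0)
        (chain,) = state.registry.chains.values()
        assert chain.units == [S]
        assert chain.mw == pytest.approx(227.2)

    def test_sampling_error_shrinks_with_population(self):
        devs = []
        for n in (200, 20000):
            reps = [abs(compute_observables(
                initialize_system(n, seed=s).registry, CHIP)["Mn"] - 13000.0)
                for s in range(5)]
            devs.append(np.mean(reps))
        assert devs[1] < devs[0]

    @pytest.mark.parametrize("kwargs", [
        {"n_chains": 0}, {"n_chains": 5, "target_mn": 100.0},
        {"n_chains": 5, "target_sg": -1.0},
    ])
    def test_invalid_parameters_rejected(self, kwargs):
        with pytest.raises(ValueError):
            initialize_system(**{"target_mn": 13000.0, "seed": 0, **kwargs})


class TestScission:
    def test_fragment_masses_and_conservation(self):
        reg = make_registry([[S, G, S]])
        (cid,) = list(reg.chains)
        left, right = apply_scission(reg, cid, 0)
        assert left.mw == pytest.approx(227.2)
        assert right.mw == pytest.approx(406.4)
        assert left.mw + right.mw == pytest.approx(633.6)

    def test_bond_slice_semantics(self, kinetics):
        reg = make_registry([[S, G, S]])
        (cid,) = list(reg.chains)
        e4 = kinetics.dep_table.energies_at(353.0)
        parent = reg.chains[cid]
        parent_energies = parent.bond_energies(e4.__getitem__)
        left, right = apply_scission(reg, cid, 0)
        assert left.n_bonds == 0
        np.testing.assert_allclose(right.bond_energies(e4.__getitem__),
                                   parent_energies[1:])

    def test_preconditions(self):
        reg = make_registry([[S, G]], phase=CHIP)
        (cid,) = list(reg.chains)
        with pytest.raises(EventError):
            apply_scission(reg, cid, 0)  # chip phase
        reg2 = make_registry([[S, G]])
        (cid2,) = list(reg2.chains)
        with pytest.raises(EventError):
            apply_scission(reg2, cid2, 5)


class TestCondensation:
    def test_merge_mass_and_bond_count(self):
        reg = make_registry([[G], [G]])
        i, j = sorted(reg.chains)
        merged = apply_condensation(reg, i, j)
        assert merged.mw == pytest.approx(358.4)
        assert merged.n_bonds == 1
        assert reg.agg[LIQUOR].n == 1

    def test_merge_then_cleave_roundtrip(self):
        reg = make_registry([[S, G], [G, S, S]])
        i, j = sorted(reg.chains)
        mw_i, mw_j = reg.chains[i].mw, reg.chains[j].mw
        merged = apply_condensation(reg, i, j)
        left, right = apply_scission(reg, merged.id, 1)  # junction bond
        assert left.mw == pytest.approx(mw_i)
        assert right.mw == pytest.approx(mw_j)

    def test_self_merge_rejected(self):
        reg = make_registry([[G, G]])
        (cid,) = list(reg.chains)
        with pytest.raises(EventError):
            apply_condensation(reg, cid, cid)


class TestDemethoxylation:
    def test_mass_drop_is_one_methoxy_group(self):
        reg = make_registry([[S]])
        (cid,) = list(reg.chains)
        chain = apply_demethoxylation(reg, cid, 0)
        assert chain.units == [G]
        assert chain.mw == pytest.approx(179.2)
        assert 227.2 - chain.mw == pytest.approx(48.0)

    def test_sg_ratio_strictly_decreases(self):
        reg = make_registry([[S, S, G], [S, G]])
        prev = compute_observables(reg, LIQUOR)["sg_ratio"]
        for cid in sorted(reg.chains):
            chain = reg.chains[cid]
            while chain.s_count:
                site = chain.units.index(S)
                chain = apply_demethoxylation(reg, cid, site)
                sg = compute_observables(reg, LIQUOR)["sg_ratio"]
                assert sg < prev
                prev = sg

    def test_g_unit_rejected(self):
        reg = make_registry([[G, S]])
        (cid,) = list(reg.chains)
        with pytest.raises(EventError):
            apply_demethoxylation(reg, cid, 0)


class TestObservables:
    def test_two_chain_toy_averages(self):
        reg = make_registry([[G, S], [S]])  # 406.4 and 227.2 g/mol
        obs = compute_observables(reg, LIQUOR)
        assert obs["Mn"] == pytest.approx(316.8)
        assert obs["Mw"] == pytest.approx(216780.8 / 633.6)

    def test_single_chain_degenerate(self):
        reg = make_registry([[S, G, G]])
        obs = compute_observables(reg, LIQUOR)
        assert obs["Mn"] == pytest.approx(obs["Mw"])

    def test_sg_count_ratio(self):
        reg = make_registry([[S, S, G]])
        assert compute_observables(reg, LIQUOR)["sg_ratio"] == pytest.approx(2.0)

    def test_empty_phase_raises_and_all_s_flagged_infinite(self):
        reg = make_registry([[S, S]])
        with pytest.raises(EmptyPhaseError):
            compute_observables(reg, CHIP)
        assert math.isinf(compute_observables(reg, LIQUOR)["sg_ratio"])

    def test_histogram_covers_population(self):
        reg = make_registry([[S], [G], [S, G, S, G]])
        obs = compute_observables(reg, LIQUOR, bins=5)
        assert obs["mwd_counts"].sum() == 3


class TestTransfers:
    def test_mass_eligibility_rule(self, rng):
        reg = make_registry([[G] * 2, [G] * 3], phase=CHIP)  # 358.4, 537.6
        reg.dissolved_accumulator = 500.0
        chain = transfer_chain(reg, "dissolve", rng)
        assert chain.mw == pytest.approx(358.4)  # only the light one fits
        assert reg.dissolved_accumulator == pytest.approx(500.0 - 358.4)
        assert chain.phase == LIQUOR

    def test_no_transfer_below_every_mass(self, rng):
        reg = make_registry([[G] * 4], phase=CHIP)
        reg.dissolved_accumulator = 100.0
        assert transfer_chain(reg, "dissolve", rng) is None

    def test_total_mass_conserved(self, rng):
        reg = make_registry([[G, S, G], [S, S]], phase=CHIP)
        total = reg.total_mass()
        reg.dissolved_accumulator = 1e4
        transfer_chain(reg, "dissolve", rng)
        assert reg.total_mass() == pytest.approx(total)

    def test_empty_source_is_noop(self, rng):
        reg = make_registry([[G]], phase=CHIP)
        assert transfer_chain(reg, "redeposit", rng) is None


class TestRegistryInvariants:
    def test_unique_ids_across_phases(self):
        reg = make_registry([[S], [G]], phase=CHIP)
        reg.add_chain([S, G], LIQUOR)
        ids = list(reg.chains)
        assert len(ids) == len(set(ids))

    def test_aggregates_match_bruteforce_after_mixed_events(self, rng):
        reg = make_registry([[S, G, S, G, S, S, G, G] * 3 for _ in range(30)])
        for _ in range(1000):
            cids = sorted(reg.chains)
            u = rng.random()
            cid = cids[int(rng.random() * len(cids))]
            chain = reg.chains[cid]
            if u < 0.5 and chain.n_bonds > 0:
                apply_scission(reg, cid, int(rng.random() * chain.n_bonds))
            elif u < 0.7 and len(cids) > 1:
                other = cids[int(rng.random() * len(cids))]
                if other != cid:
                    apply_condensation(reg, cid, other)
            elif chain.s_count:
                site = chain.units.index(S)
                apply_demethoxylation(reg, cid, site)
        oracle = reg.recompute_aggregates()
        for phase in (CHIP, LIQUOR):
            live = reg.agg[phase].as_dict()
            for key, val in oracle[phase].items():
                assert live[key] == pytest.approx(val, rel=1e-9, abs=1e-6)

    def test_mass_ledger_only_demethoxylation_changes_total(self, rng):
        reg = make_registry([[S, G, S, S, G] for _ in range(10)])
        total = reg.total_mass()
        n_dem = 0
        for _ in range(300):
            liq = sorted(reg.phase_ids[LIQUOR])
            u = rng.random()
            if u < 0.6 and liq:
                cid = liq[int(rng.random() * len(liq))]
                chain = reg.chains[cid]
                if u < 0.45 and chain.n_bonds:
                    apply_scission(reg, cid,
                                   int(rng.random() * chain.n_bonds))
                elif len(liq) > 1:
                    other = liq[int(rng.random() * len(liq))]
                    if other != cid:
                        apply_condensation(reg, cid, other)
            elif u < 0.8:
                reg.dissolved_accumulator += 1e4
                reg.redeposit_accumulator += 1e4
                transfer_chain(reg, "redeposit" if rng.random() < 0.5
                               else "dissolve", rng)
            elif liq:
                cid = liq[int(rng.random() * len(liq))]
                chain = reg.chains[cid]
                if chain.s_count:
                    apply_demethoxylation(reg, cid, chain.units.index(S))
                    n_dem += 1
        expected = total - 48.0 * n_dem
        assert reg.total_mass() == pytest.approx(expected, abs=1e-6 * total)
        assert n_dem > 0

    def test_e_low_is_min_bond_energy(self, kinetics):
        reg = make_registry([[S, G, G, S, S]])
        (cid,) = list(reg.chains)
        e4 = kinetics.dep_table.energies_at(353.0)
        chain = reg.chains[cid]
        e_low, idx = chain.e_low(e4.__getitem__)
        energies = chain.bond_energies(e4.__getitem__)
        assert e_low == energies.min()
        assert energies[idx] == e_low


class TestSerialization:
    def test_jsonl_roundtrip(self, tmp_path, kinetics):
        reg = make_registry([[S, G, S], [G]], phase=LIQUOR)
        reg.add_chain([S, S], CHIP)
        e4 = kinetics.dep_table.energies_at(353.0)
        path = tmp_path / "chains.jsonl"
        reg.to_jsonl(path, energy_of_dyad=e4.__getitem__)
        back = ChainRegistry.from_jsonl(path)
        assert sorted(back.chains) == sorted(reg.chains)
        for cid, chain in reg.chains.items():
            other = back.chains[cid]
            assert other.units == chain.units
            assert other.phase == chain.phase
            assert other.mw == pytest.approx(chain.mw)


@settings(max_examples=30, deadline=None, derandomize=True)
@given(st.lists(st.integers(0, 1), min_size=2, max_size=40),
       st.integers(0, 10 ** 6))
def test_scission_conserves_mass_property(units, raw_bond):
    """Any scission splits the sequence and conserves total molar mass."""
    reg = make_registry([units])
    (cid,) = list(reg.chains)
    parent_mw = reg.chains[cid].mw
    bond = raw_bond % (len(units) - 1)
    left, right = apply_scission(reg, cid, bond)
    assert left.n_units + right.n_units == len(units)
    assert left.mw + right.mw == pytest.approx(parent_mw)
    assert left.units + right.units == units
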