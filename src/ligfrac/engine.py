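"""Gillespie direct-method engine over an incrementally maintained catalog.

The microscale simulation advances by drawing an exponential waiting time
``delta_t = -ln(xi) / r_tot`` and selecting the next event proportionally to
its propensity (cumulative-sum inversion with a second uniform).  Within one
macroscopic interval the draw/execute loop repeats until the next waiting
time would cross the interval boundary; the straddling event is discarded
and redrawn in the next interval, which is statistically equivalent by the
memorylessness of the exponential waiting time.

Two catalog realizations share one canonical event ordering so that the full
baseline and the threshold-filtered engine are interchangeable (and
bit-identical whenever the filter provably excludes nothing):

* :func:`build_catalog_snapshot` -- explicit per-event enumeration, the
  small-system oracle and the ``EventCatalog`` surface;
* :class:`LiveCatalog` -- the production structure, subscribed to the chain
  registry so that an event only touches the entries of affected chains.

Canonical order: depolymerization events grouped by bond dyad (SS, SG, GS,
GG; members in insertion order), condensation grouped by unordered pairs of
composition classes (chains bucketed by exact (S count, G count); class
pairs in lexicographic order) -- exact because every pair in a class pair
shares the same combined molar mass and hence the same rate coefficient --
and demethoxylation events per chain in insertion order.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass
from typing import Optional

import numpy as np

from . import chains as ch
from .chains import ChainRegistry, LigninChain, LIQUOR, SystemState
from .kinetics import Kinetics, compute_threshold, rate_coefficient

logger = logging.getLogger(__name__)

DEP = "depolymerization"
CON = "condensation"
DEM = "demethoxylation"

#: Temperature drift (K) tolerated before cached coefficients are refreshed.
T_REFRESH_TOL = 0.005


@dataclass(frozen=True)
class Event:
    """One candidate microscale event with its propensity in min^-1."""

    kind: str
    chain_id: int
    site: int = -1  # bond index (DEP); ignored otherwise
    partner_id: int = -1  # second chain (CON)
    propensity: float = 0.0


@dataclass
class EventCatalog:
    """Explicit event list in canonical order with its total rate."""

    events: list[Event]
    r_tot: float
    provenance: str  # "full" or "filtered"

    def recompute_r_tot(self) -> float:
        """Independent summation oracle."""
        return float(sum(e.propensity for e in self.events))


# ---------------------------------------------------------------------------
# Explicit snapshot builder (oracle; quadratic in the chain count)
# ---------------------------------------------------------------------------

def build_catalog_snapshot(registry: ChainRegistry, kinetics: Kinetics,
                           temperature: float, filtered: bool,
                           ratio_cutoff: float = 1000.0) -> EventCatalog:
    """Enumerate every candidate liquor-phase event explicitly.

    With ``filtered=True`` the depolymerization per-chain energy threshold
    and the condensation combined-MW window are applied; otherwise every
    bond, every unordered chain pair and every S-containing chain yields an
    event.
    """
    omega = kinetics.omega
    e4 = kinetics.dep_table.energies_at(temperature)
    k4 = kinetics.k_dep_dyads(temperature) / omega
    de_th = compute_threshold(temperature, ratio_cutoff) if filtered else math.inf
    if filtered:
        mw_low, mw_high = kinetics.con_energy.window(
            compute_threshold(temperature, ratio_cutoff))
    else:
        mw_low, mw_high = 0.0, math.inf

    liquor = [registry.chains[cid] for cid in registry.phase_ids[LIQUOR]]
    events: list[Event] = []

    # Depolymerization, grouped by dyad in canonical order.
    by_dyad: list[list[Event]] = [[], [], [], []]
    for chain in liquor:
        dyads = chain.bond_dyads()
        if not dyads:
            continue
        e_low = min(e4[d] for d in set(dyads))
        for m, d in enumerate(dyads):
            if e4[d] <= e_low + de_th:
                by_dyad[d].append(Event(DEP, chain.id, site=m,
                                        propensity=float(k4[d])))
    for group in by_dyad:
        events.extend(group)

    # Condensation: all (or window-retained) unordered pairs, ordered by
    # composition-class pair then member order.
    key_members: dict[tuple[int, int], list[LigninChain]] = {}
    for chain in liquor:
        key_members.setdefault((chain.s_count, chain.g_count), []).append(chain)
    keys = sorted(key_members)
    inv_om2 = 1.0 / (omega * omega)
    for a, ka in enumerate(keys):
        for kb in keys[a:]:
            mems_a, mems_b = key_members[ka], key_members[kb]
            mw_sum = mems_a[0].mw + mems_b[0].mw
            if not (mw_low <= mw_sum <= mw_high):
                continue
            k = kinetics.k_con(mw_sum, temperature) * inv_om2
            if ka == kb:
                for i in range(len(mems_a)):
                    for j in range(i + 1, len(mems_a)):
                        events.append(Event(CON, mems_a[i].id,
                                            partner_id=mems_a[j].id,
                                            propensity=k))
            else:
                for ca in mems_a:
                    for cb in mems_b:
                        events.append(Event(CON, ca.id, partner_id=cb.id,
                                            propensity=k))

    # Demethoxylation: one event per S-containing chain; never filtered.
    k_dem = kinetics.k_dem(temperature) / omega
    for chain in liquor:
        if chain.s_count > 0:
            events.append(Event(DEM, chain.id,
                                propensity=k_dem * chain.f_s))

    r_tot = float(sum(e.propensity for e in events))
    return EventCatalog(events, r_tot,
                        "filtered" if filtered else "full")


def build_full_catalog(registry: ChainRegistry, kinetics: Kinetics,
                       temperature: float) -> EventCatalog:
    """Unfiltered baseline catalog (one event per bond/pair/chain)."""
    return build_catalog_snapshot(registry, kinetics, temperature,
                                  filtered=False)


def gillespie_step(catalog: EventCatalog,
                   rng: np.random.Generator) -> tuple[Optional[Event], float]:
    """One direct-method draw from an explicit catalog.

    Returns the chosen event and the waiting time; ``(None, inf)`` signals no
    microscale activity (zero total rate).  Ties in the cumulative inversion
    resolve to the first index.
    """
    if catalog.r_tot <= 0.0:
        return None, math.inf
    dt = -math.log(rng.random()) / catalog.r_tot
    target = rng.random() * catalog.r_tot
    acc = 0.0
    chosen = None
    for ev in catalog.events:
        if ev.propensity <= 0.0:
            continue
        acc += ev.propensity
        chosen = ev
        if target < acc:
            break
    return chosen, dt


# ---------------------------------------------------------------------------
# Production catalog with incremental maintenance
# ---------------------------------------------------------------------------

class LiveCatalog:
    """Candidate-event catalog maintained incrementally from the registry.

    Subscribes to a :class:`ChainRegistry`; any chain entering, leaving or
    changing in the liquor phase updates only that chain's entries.
    Temperature-dependent coefficients are cached and refreshed when the
    liquor temperature drifts beyond ``T_REFRESH_TOL``; the retention
    structure (which dyads a chain may cleave given its most labile present
    dyad, and the condensation window mask) is re-derived at each refresh
    and triggers a full rebuild only when it actually changes.
    """

    def __init__(self, registry: ChainRegistry, kinetics: Kinetics,
                 temperature: float, filtered: bool,
                 ratio_cutoff: float = 1000.0):
        self.registry = registry
        self.kin = kinetics
        self.filtered = filtered
        self.ratio_cutoff = ratio_cutoff
        self._ms = registry.masses.s
        self._mg = registry.masses.g

        # depolymerization: four dyad groups of (chain_id, bond_idx)
        self._dep_members: list[list[tuple[int, int]]] = [[], [], [], []]
        self._dep_pos: dict[tuple[int, int], int] = {}
        self._chain_entries: dict[int, list[tuple[int, int]]] = {}

        # condensation composition classes
        self._class_members: dict[tuple[int, int], list[int]] = {}
        self._class_pos: dict[int, tuple[tuple[int, int], int]] = {}
        # Max unit count eligible for condensation classes (filtered engine
        # only; anything longer cannot reach the window even with a monomer).
        self._member_cap: float = math.inf if not filtered else -1.0
        self._keys: list[tuple[int, int]] = []
        self._K: np.ndarray | None = None
        self._counts: np.ndarray | None = None
        self._con_keys_dirty = True
        self._con_counts_dirty = True
        self._con_tot = 0.0

        # demethoxylation
        self._dem_members: list[int] = []
        self._dem_fs: list[float] = []
        self._dem_pos: dict[int, int] = {}
        self._sum_fs = 0.0

        # temperature caches
        self.temperature = None
        self._k4: np.ndarray | None = None
        self._e4: np.ndarray | None = None
        self._retain_mask: np.ndarray | None = None  # (4, 4) bool
        self._k_dem_eff = 0.0
        self.delta_e_th = math.inf
        self._window = (0.0, math.inf)

        self.n_underflow = 0
        self.set_temperature(temperature, force=True)
        registry.add_listener(self)
        self.rebuild()

    # -- temperature-dependent caches -------------------------------------
    def set_temperature(self, temperature: float, force: bool = False) -> None:
        if (not force and self.temperature is not None
                and abs(temperature - self.temperature) <= T_REFRESH_TOL):
            return
        kin = self.kin
        self.temperature = temperature
        e4 = kin.dep_table.energies_at(temperature)
        k4 = kin.k_dep_dyads(temperature) / kin.omega
        self.n_underflow += int(np.count_nonzero(k4 == 0.0))
        if self.filtered:
            de = compute_threshold(temperature, self.ratio_cutoff)
            window = kin.con_energy.window(de)
        else:
            de = math.inf
            window = (0.0, math.inf)
        # Retention mask: row d0 = chain's lowest-energy present dyad,
        # column d = bond dyad; True when the bond survives the filter.
        mask = e4[None, :] <= e4[:, None] + de
        structure_changed = (
            force
            or self._retain_mask is None
            or not np.array_equal(mask, self._retain_mask)
            or np.any(np.argsort(e4, kind="stable")
                      != np.argsort(self._e4, kind="stable"))
        )
        self._e4, self._k4 = e4, k4
        self.delta_e_th = de
        self._window = window
        self._retain_mask = mask
        self._k_dem_eff = kin.k_dem(temperature) / kin.omega
        self._con_keys_dirty = True  # K depends on T and the window

        if self.filtered:
            cap = int(math.floor(window[1] / self._mg)) - 1
            if cap > self._member_cap:  # never shrink: superset is exact
                self._member_cap = cap  # (the window mask zeroes excess pairs)
                structure_changed = True
        if structure_changed and self._chain_entries:
            self.rebuild()

    # -- membership maintenance --------------------------------------------
    def rebuild(self) -> None:
        """Recreate every membership from the registry (also the oracle path)."""
        self._dep_members = [[], [], [], []]
        self._dep_pos.clear()
        self._chain_entries.clear()
        self._class_members.clear()
        self._class_pos.clear()
        self._dem_members = []
        self._dem_fs = []
        self._dem_pos.clear()
        self._sum_fs = 0.0
        for cid in self.registry.phase_ids[LIQUOR]:
            self._add_chain(self.registry.chains[cid])
        self._con_keys_dirty = True
        self._con_counts_dirty = True

    def on_added(self, chain: LigninChain) -> None:
        if chain.phase == LIQUOR:
            self._add_chain(chain)

    def on_removed(self, chain: LigninChain) -> None:
        if chain.phase == LIQUOR:
            self._remove_chain(chain)

    def _add_chain(self, chain: LigninChain) -> None:
        cid = chain.id
        entries: list[tuple[int, int]] = []
        units = chain.units
        n = len(units)
        if n > 1:
            e4 = self._e4
            dyads = [(1 - units[m]) * 2 + (1 - units[m + 1])
                     for m in range(n - 1)]
            d_star = min(set(dyads), key=e4.__getitem__)
            mask = self._retain_mask[d_star]
            for m, d in enumerate(dyads):
                if mask[d]:
                    group = self._dep_members[d]
                    self._dep_pos[(cid, m)] = len(group)
                    group.append((cid, m))
                    entries.append((d, m))
        self._chain_entries[cid] = entries

        if n <= self._member_cap:
            key = (chain.s_count, n - chain.s_count)
            members = self._class_members.get(key)
            if members is None:
                self._class_members[key] = members = []
                self._con_keys_dirty = True
            self._class_pos[cid] = (key, len(members))
            members.append(cid)
            self._con_counts_dirty = True

        if chain.s_count > 0:
            self._dem_pos[cid] = len(self._dem_members)
            self._dem_members.append(cid)
            fs = chain.s_count / n
            self._dem_fs.append(fs)
            self._sum_fs += fs

    def _remove_chain(self, chain: LigninChain) -> None:
        cid = chain.id
        for d, m in self._chain_entries.pop(cid):
            group = self._dep_members[d]
            pos = self._dep_pos.pop((cid, m))
            last = group.pop()
            if last != (cid, m):
                group[pos] = last
                self._dep_pos[last] = pos

        cp = self._class_pos.pop(cid, None)
        if cp is not None:
            key, pos = cp
            members = self._class_members[key]
            last = members.pop()
            if last != cid:
                members[pos] = last
                self._class_pos[last] = (key, pos)
            if not members:
                del self._class_members[key]
                self._con_keys_dirty = True
            self._con_counts_dirty = True

        pos = self._dem_pos.pop(cid, None)
        if pos is not None:
            last_id = self._dem_members.pop()
            last_fs = self._dem_fs.pop()
            self._sum_fs -= self._dem_fs[pos] if last_id != cid else last_fs
            if last_id != cid:
                self._dem_members[pos] = last_id
                self._dem_fs[pos] = last_fs
                self._dem_pos[last_id] = pos

    # -- totals ------------------------------------------------------------
    def _refresh_con(self) -> None:
        if self._con_keys_dirty:
            self._keys = sorted(self._class_members)
            mw = np.array([k[0] * self._ms + k[1] * self._mg
                           for k in self._keys])
            if mw.size:
                combined = mw[:, None] + mw[None, :]
                kk = self.kin.k_con(combined.ravel(), self.temperature)
                K = kk.reshape(combined.shape) / (self.kin.omega ** 2)
                lo, hi = self._window
                K[(combined < lo) | (combined > hi)] = 0.0
            else:
                K = np.zeros((0, 0))
            self._K = K
            self._con_keys_dirty = False
            self._con_counts_dirty = True
        if self._con_counts_dirty:
            n = np.array([float(len(self._class_members[k]))
                          for k in self._keys])
            self._counts = n
            if n.size:
                K = self._K
                self._con_tot = 0.5 * (n @ K @ n - float(np.diag(K) @ n))
            else:
                self._con_tot = 0.0
            self._con_counts_dirty = False

    def dep_total(self) -> float:
        k4 = self._k4
        g = self._dep_members
        return (len(g[0]) * k4[0] + len(g[1]) * k4[1]
                + len(g[2]) * k4[2] + len(g[3]) * k4[3])

    def con_total(self) -> float:
        if self._con_keys_dirty or self._con_counts_dirty:
            self._refresh_con()
        return self._con_tot

    def dem_total(self) -> float:
        return self._k_dem_eff * self._sum_fs

    def total_rate(self) -> float:
        return self.dep_total() + self.con_total() + self.dem_total()

    def candidate_stats(self) -> dict:
        """Retained counts versus unfiltered candidate counts."""
        agg = self.registry.agg[LIQUOR]
        n = agg.n
        retained_con = 0.0
        self._refresh_con()
        cnt = self._counts
        if cnt.size:
            mask = self._K > 0
            retained_con = 0.5 * ((cnt @ mask @ cnt)
                                  - float(np.diag(mask) @ cnt))
        return {
            "dep_retained": sum(len(g) for g in self._dep_members),
            "dep_candidates": agg.units - n,
            "con_retained_pairs": int(round(retained_con)),
            "con_candidate_pairs": n * (n - 1) // 2,
            "dem_events": len(self._dem_members),
        }

    # -- sampling ----------------------------------------------------------
    def sample(self, u: float, rng: np.random.Generator) -> Optional[Event]:
        """Invert the canonical cumulative sum at ``u * r_tot``.

        Within a dyad group or a condensation class pair all propensities are
        equal, so the fractional remainder of the inversion selects the
        member deterministically; no additional uniforms are consumed here.
        """
        dep_tot = self.dep_total()
        con_tot = self.con_total()
        dem_tot = self.dem_total()
        r_tot = dep_tot + con_tot + dem_tot
        if r_tot <= 0.0:
            return None
        x = u * r_tot

        if x < dep_tot:
            for d in range(4):
                group = self._dep_members[d]
                rate = len(group) * self._k4[d]
                if x < rate and rate > 0.0:
                    frac = x / rate
                    cid, m = group[min(int(frac * len(group)), len(group) - 1)]
                    return Event(DEP, cid, site=m, propensity=self._k4[d])
                x -= rate
            x = 0.0  # rounding spill-over: fall through to condensation
        else:
            x -= dep_tot

        if x < con_tot:
            return self._sample_con(x)
        x -= con_tot

        if dem_tot > 0.0:
            target = min(x, dem_tot * (1.0 - 1e-16))
            acc = 0.0
            k = self._k_dem_eff
            for pos, cid in enumerate(self._dem_members):
                acc += k * self._dem_fs[pos]
                if target < acc:
                    return Event(DEM, cid, propensity=k * self._dem_fs[pos])
            cid = self._dem_members[-1]
            return Event(DEM, cid, propensity=k * self._dem_fs[-1])
        return None

    def _sample_con(self, x: float) -> Event:
        self._refresh_con()
        keys, K, cnt = self._keys, self._K, self._counts
        C = len(keys)
        for a in range(C):
            for b in range(a, C):
                if a == b:
                    npairs = cnt[a] * (cnt[a] - 1.0) / 2.0
                else:
                    npairs = cnt[a] * cnt[b]
                rate = K[a, b] * npairs
                if rate <= 0.0:
                    continue
                if x < rate:
                    frac = x / rate
                    m = min(int(frac * npairs), int(npairs) - 1)
                    mem_a = self._class_members[keys[a]]
                    if a == b:
                        i, j = _unrank_pair(m)
                        return Event(CON, mem_a[i], partner_id=mem_a[j],
                                     propensity=K[a, b])
                    mem_b = self._class_members[keys[b]]
                    nb = len(mem_b)
                    return Event(CON, mem_a[m // nb], partner_id=mem_b[m % nb],
                                 propensity=K[a, b])
                x -= rate
        # Rounding spill-over: return the last positive-rate pair.
        for a in range(C - 1, -1, -1):
            for b in range(C - 1, a - 1, -1):
                npairs = (cnt[a] * (cnt[a] - 1.0) / 2.0 if a == b
                          else cnt[a] * cnt[b])
                if K[a, b] * npairs > 0.0:
                    mem_a = self._class_members[keys[a]]
                    if a == b:
                        i, j = _unrank_pair(int(npairs) - 1)
                        return Event(CON, mem_a[i], partner_id=mem_a[j],
                                     propensity=K[a, b])
                    mem_b = self._class_members[keys[b]]
                    return Event(CON, mem_a[-1], partner_id=mem_b[-1],
                                 propensity=K[a, b])
        raise RuntimeError("condensation sampling with zero total rate")

    # -- snapshot for oracle comparison ------------------------------------
    def snapshot(self) -> EventCatalog:
        """Explicit expansion of the current incremental state."""
        events: list[Event] = []
        for d in range(4):
            for cid, m in self._dep_members[d]:
                events.append(Event(DEP, cid, site=m,
                                    propensity=float(self._k4[d])))
        self._refresh_con()
        keys, K = self._keys, self._K
        for a in range(len(keys)):
            mem_a = self._class_members[keys[a]]
            for b in range(a, len(keys)):
                if K[a, b] <= 0.0:
                    continue
                if a == b:
                    for i in range(len(mem_a)):
                        for j in range(i + 1, len(mem_a)):
                            events.append(Event(CON, mem_a[i],
                                                partner_id=mem_a[j],
                                                propensity=float(K[a, b])))
                else:
                    for ca in mem_a:
                        for cb in self._class_members[keys[b]]:
                            events.append(Event(CON, ca, partner_id=cb,
                                                propensity=float(K[a, b])))
        k = self._k_dem_eff
        for pos, cid in enumerate(self._dem_members):
            events.append(Event(DEM, cid, propensity=k * self._dem_fs[pos]))
        return EventCatalog(events, float(sum(e.propensity for e in events)),
                            "filtered" if self.filtered else "full")


def _unrank_pair(m: int) -> tuple[int, int]:
    """m-th unordered pair (i < j) in the order (0,1),(0,2),(1,2),(0,3)..."""
    j = int((1.0 + math.sqrt(1.0 + 8.0 * m)) / 2.0)
    while j * (j - 1) // 2 > m:
        j -= 1
    while (j + 1) * j // 2 <= m:
        j += 1
    return m - j * (j - 1) // 2, j


# ---------------------------------------------------------------------------
# Event execution and the micro interval
# ---------------------------------------------------------------------------

def execute_event(registry: ChainRegistry, event: Event,
                  rng: np.random.Generator) -> None:
    """Apply one sampled event to the registry (listeners update catalogs)."""
    if event.kind == DEP:
        ch.apply_scission(registry, event.chain_id, event.site)
    elif event.kind == CON:
        ch.apply_condensation(registry, event.chain_id, event.partner_id)
    elif event.kind == DEM:
        chain = registry.chains[event.chain_id]
        s_sites = [i for i, u in enumerate(chain.units) if u == ch.S]
        site = s_sites[int(rng.random() * len(s_sites))]
        ch.apply_demethoxylation(registry, event.chain_id, site)
    else:  # pragma: no cover
        raise ValueError(f"unknown event kind {event.kind!r}")


def run_micro_interval(state: SystemState, dt: float, catalog: LiveCatalog,
                       rng: np.random.Generator,
                       event_counts: dict | None = None,
                       event_log: list | None = None) -> int:
    """Run the Gillespie loop for one macroscopic interval of length ``dt``.

    Executes events while the accumulated stochastic time stays inside the
    interval; the partial final step is not executed.  Returns the number of
    executed events.
    """
    catalog.set_temperature(state.t_f)
    t_used = 0.0
    n_exec = 0
    while True:
        r_tot = catalog.total_rate()
        if r_tot <= 0.0:
            break
        dt_next = -math.log(rng.random()) / r_tot
        if t_used + dt_next > dt:
            break
        t_used += dt_next
        event = catalog.sample(rng.random(), rng)
        if event is None:  # pragma: no cover - r_tot>0 guarantees an event
            break
        execute_event(state.registry, event, rng)
        n_exec += 1
        if event_counts is not None:
            event_counts[event.kind] = event_counts.get(event.kind, 0) + 1
        if event_log is not None:
            event_log.append((state.clock + t_used, event.kind,
                              event.chain_id, event.partner_id, event.site,
                              dt_next, r_tot))
    return n_exec
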