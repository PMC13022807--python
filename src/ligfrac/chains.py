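"""Explicit lignin chains and the chip/liquor registry.

Lignin is represented as a population of linear chains of syringyl (S) and
guaiacyl (G) monolignols.  Chains live in one of two phases: the solid *chip*
phase (unreactive at the molecular scale) or the dissolved *liquor* phase,
where depolymerization (random scission of beta-O-4 linkages), condensation
(chain merging) and demethoxylation (S -> G conversion, -48.0 g/mol) act on
them.  The :class:`ChainRegistry` keeps both populations together with
incrementally maintained aggregates (chain counts, sum of molar masses, sum
of squared molar masses, unit and S-unit counts) so that number- and
weight-average molar masses and the S/G ratio are available in constant time
at any instant.

Monolignol codes: ``1`` is S, ``0`` is G.  Dyad codes (ordered pairs of
adjacent units, used to key bond activation energies): SS=0, SG=1, GS=2,
GG=3.
"""

from __future__ import annotations

import json
import logging
import math
from dataclasses import dataclass, field
from typing import Optional

import numpy as np

logger = logging.getLogger(__name__)

S = 1
G = 0

CHIP = "chip"
LIQUOR = "liquor"

DYAD_NAMES = ("SS", "SG", "GS", "GG")


class EventError(ValueError):
    """A microscale event was requested on an invalid chain/site."""


class ConfigurationError(ValueError):
    """Invalid configuration or initialization parameters."""


class EmptyPhaseError(ValueError):
    """An observable was requested for an empty phase."""


@dataclass(frozen=True)
class MonomerMasses:
    """Molar masses of the two monolignols in g/mol."""

    s: float = 227.2
    g: float = 179.2

    @property
    def demethoxylation_delta(self) -> float:
        """Mass lost when an S unit loses its methoxy group (48.0 g/mol)."""
        return self.s - self.g

    def unit_mass(self, code: int) -> float:
        return self.s if code == S else self.g

    def mean_unit_mass(self, sg_ratio: float) -> float:
        """Expected unit mass when S units occur with odds ``sg_ratio`` : 1."""
        p = sg_ratio / (1.0 + sg_ratio)
        return p * self.s + (1.0 - p) * self.g


def dyad_code(left: int, right: int) -> int:
    """Dyad index of the ordered unit pair flanking a bond (SS=0 .. GG=3)."""
    return (1 - left) * 2 + (1 - right)


class LigninChain:
    """A single linear lignin chain.

    ``units`` is the ordered monolignol sequence (1=S, 0=G).  Bond *m*
    connects units *m* and *m+1*; its activation energy for scission is keyed
    by the flanking dyad and looked up in the kinetics library at the current
    liquor temperature (see :meth:`bond_energies`).  Molar mass and S count
    are cached and maintained by the registry operations.
    """

    __slots__ = ("id", "units", "phase", "mw", "s_count")

    def __init__(self, chain_id: int, units: list[int], phase: str,
                 masses: MonomerMasses):
        self.id = chain_id
        self.units = units
        self.phase = phase
        self.s_count = sum(units)
        self.mw = self.s_count * masses.s + (len(units) - self.s_count) * masses.g

    # -- structure ---------------------------------------------------------
    @property
    def n_units(self) -> int:
        return len(self.units)

    @property
    def n_bonds(self) -> int:
        return len(self.units) - 1

    @property
    def g_count(self) -> int:
        return len(self.units) - self.s_count

    @property
    def f_s(self) -> float:
        """S-unit fraction, the chain-level demethoxylation factor."""
        return self.s_count / len(self.units)

    def bond_dyads(self) -> list[int]:
        u = self.units
        return [dyad_code(u[m], u[m + 1]) for m in range(len(u) - 1)]

    def bond_energies(self, energy_of_dyad) -> np.ndarray:
        """Per-bond scission activation energies in kJ/mol.

        ``energy_of_dyad`` maps a dyad code to an energy (typically
        ``DepolymerizationEnergyTable.energies_at(T).__getitem__``).
        """
        return np.asarray([energy_of_dyad(d) for d in self.bond_dyads()], dtype=float)

    def e_low(self, energy_of_dyad) -> tuple[float, int]:
        """Minimum bond activation energy and its site index.

        Raises :class:`EventError` on a single-unit chain (no bonds).
        """
        if self.n_bonds == 0:
            raise EventError(f"chain {self.id} has no bonds")
        energies = self.bond_energies(energy_of_dyad)
        idx = int(np.argmin(energies))
        return float(energies[idx]), idx

    def sequence_string(self) -> str:
        return "".join("S" if u == S else "G" for u in self.units)

    def __repr__(self) -> str:  # pragma: no cover - debugging aid
        return f"LigninChain(id={self.id}, n={self.n_units}, phase={self.phase})"


class PhaseAggregates:
    """Running totals for one phase, maintained incrementally."""

    __slots__ = ("n", "sum_mw", "sum_mw2", "units", "s_count")

    def __init__(self):
        self.n = 0
        self.sum_mw = 0.0
        self.sum_mw2 = 0.0
        self.units = 0
        self.s_count = 0

    def add(self, chain: LigninChain) -> None:
        self.n += 1
        self.sum_mw += chain.mw
        self.sum_mw2 += chain.mw * chain.mw
        self.units += chain.n_units
        self.s_count += chain.s_count

    def remove(self, chain: LigninChain) -> None:
        self.n -= 1
        self.sum_mw -= chain.mw
        self.sum_mw2 -= chain.mw * chain.mw
        self.units -= chain.n_units
        self.s_count -= chain.s_count

    def as_dict(self) -> dict:
        return {"n": self.n, "sum_mw": self.sum_mw, "sum_mw2": self.sum_mw2,
                "units": self.units, "s_count": self.s_count}


class ChainRegistry:
    """Integrated chip/liquor chain store with incremental aggregates.

    Every chain-level property needed by the rate laws (sequence, molar mass,
    S fraction, bond dyads) is kept on the chain objects; phase-level totals
    are maintained on every mutation so observables never require a scan.
    Listeners (e.g. a live event catalog) are notified of structural changes
    through ``on_added`` / ``on_removed`` / ``on_changed`` callbacks.
    """

    def __init__(self, masses: MonomerMasses | None = None):
        self.masses = masses or MonomerMasses()
        self.chains: dict[int, LigninChain] = {}
        # Ordered membership lists with O(1) swap-remove, for uniform draws.
        self.phase_ids: dict[str, list[int]] = {CHIP: [], LIQUOR: []}
        self._pos: dict[int, int] = {}
        # Mass-bucket index per phase (bucket width = one G-unit mass) so
        # that "uniform among chains lighter than the transfer budget" never
        # needs a full scan.
        self._bucket_w = (masses or MonomerMasses()).g
        self._buckets: dict[str, dict[int, list[int]]] = {CHIP: {}, LIQUOR: {}}
        self._bucket_pos: dict[int, int] = {}
        self._min_bucket: dict[str, int] = {CHIP: 0, LIQUOR: 0}
        self.agg: dict[str, PhaseAggregates] = {CHIP: PhaseAggregates(),
                                                LIQUOR: PhaseAggregates()}
        self.dissolved_accumulator = 0.0
        self.redeposit_accumulator = 0.0
        self._next_id = 0
        self._listeners: list = []

    # -- listener plumbing -------------------------------------------------
    def add_listener(self, listener) -> None:
        self._listeners.append(listener)

    def remove_listener(self, listener) -> None:
        self._listeners.remove(listener)

    def _notify_added(self, chain: LigninChain) -> None:
        for lis in self._listeners:
            lis.on_added(chain)

    def _notify_removed(self, chain: LigninChain) -> None:
        for lis in self._listeners:
            lis.on_removed(chain)

    # -- chain bookkeeping -------------------------------------------------
    def new_id(self) -> int:
        i = self._next_id
        self._next_id += 1
        return i

    def _list_add(self, phase: str, chain: "LigninChain") -> None:
        cid = chain.id
        lst = self.phase_ids[phase]
        self._pos[cid] = len(lst)
        lst.append(cid)
        b = int(chain.mw // self._bucket_w)
        bucket = self._buckets[phase].setdefault(b, [])
        self._bucket_pos[cid] = len(bucket)
        bucket.append(cid)
        if b < self._min_bucket[phase]:
            self._min_bucket[phase] = b

    def _list_remove(self, phase: str, chain: "LigninChain") -> None:
        cid = chain.id
        lst = self.phase_ids[phase]
        pos = self._pos.pop(cid)
        last = lst.pop()
        if last != cid:
            lst[pos] = last
            self._pos[last] = pos
        b = int(chain.mw // self._bucket_w)
        bucket = self._buckets[phase][b]
        bpos = self._bucket_pos.pop(cid)
        blast = bucket.pop()
        if blast != cid:
            bucket[bpos] = blast
            self._bucket_pos[blast] = bpos
        if not bucket:
            del self._buckets[phase][b]

    def min_mass_bound(self, phase: str) -> float:
        """Lower bound on the lightest chain mass in ``phase`` (cheap)."""
        if not self.phase_ids[phase]:
            return math.inf
        return self._min_bucket[phase] * self._bucket_w

    def _tighten_min_bucket(self, phase: str) -> None:
        buckets = self._buckets[phase]
        self._min_bucket[phase] = min(buckets) if buckets else 0

    def add_chain(self, units: list[int], phase: str,
                  chain_id: int | None = None) -> LigninChain:
        cid = self.new_id() if chain_id is None else chain_id
        if cid in self.chains:
            raise ConfigurationError(f"duplicate chain id {cid}")
        self._next_id = max(self._next_id, cid + 1)
        chain = LigninChain(cid, units, phase, self.masses)
        self.chains[cid] = chain
        self._list_add(phase, chain)
        self.agg[phase].add(chain)
        self._notify_added(chain)
        return chain

    def remove_chain(self, chain_id: int) -> LigninChain:
        chain = self.chains.pop(chain_id)
        self._list_remove(chain.phase, chain)
        self.agg[chain.phase].remove(chain)
        self._notify_removed(chain)
        return chain

    def move_phase(self, chain_id: int, phase: str) -> LigninChain:
        chain = self.chains[chain_id]
        if chain.phase == phase:
            return chain
        self._notify_removed(chain)
        self._list_remove(chain.phase, chain)
        self.agg[chain.phase].remove(chain)
        chain.phase = phase
        self._list_add(phase, chain)
        self.agg[phase].add(chain)
        self._notify_added(chain)
        return chain

    # -- oracles -----------------------------------------------------------
    def recompute_aggregates(self) -> dict[str, dict]:
        """Brute-force recomputation of every aggregate (test oracle)."""
        out = {}
        for phase in (CHIP, LIQUOR):
            agg = PhaseAggregates()
            for cid in self.phase_ids[phase]:
                agg.add(self.chains[cid])
            out[phase] = agg.as_dict()
        return out

    def total_mass(self) -> float:
        return self.agg[CHIP].sum_mw + self.agg[LIQUOR].sum_mw

    # -- serialization -----------------------------------------------------
    def to_jsonl(self, path, energy_of_dyad=None) -> None:
        """Write one JSON record per chain (id, phase, sequence, energies)."""
        with open(path, "w") as fh:
            for cid in sorted(self.chains):
                chain = self.chains[cid]
                rec = {"id": cid, "phase": chain.phase,
                       "sequence": chain.sequence_string()}
                if energy_of_dyad is not None:
                    rec["bond_energies"] = [
                        round(float(e), 6)
                        for e in chain.bond_energies(energy_of_dyad)]
                fh.write(json.dumps(rec) + "\n")

    @classmethod
    def from_jsonl(cls, path, masses: MonomerMasses | None = None) -> "ChainRegistry":
        reg = cls(masses)
        with open(path) as fh:
            for line in fh:
                if not line.strip():
                    continue
                rec = json.loads(line)
                units = [S if c == "S" else G for c in rec["sequence"]]
                reg.add_chain(units, rec["phase"], chain_id=rec["id"])
        return reg


@dataclass
class SystemState:
    """Full simulation state: chain registry, temperatures and clock."""

    registry: ChainRegistry
    t_c: float
    t_f: float
    clock: float = 0.0
    rng: np.random.Generator = field(default_factory=np.random.default_rng)

    def __post_init__(self):
        if self.t_c <= 0 or self.t_f <= 0:
            raise ConfigurationError("temperatures must be positive")


# ---------------------------------------------------------------------------
# Operations
# ---------------------------------------------------------------------------

def initialize_system(n_chains: int, target_mn: float = 13000.0,
                      target_sg: float = 1.76, temperature: float = 353.0,
                      seed: int | None = None,
                      masses: MonomerMasses | None = None,
                      rng: np.random.Generator | None = None) -> SystemState:
    """Generate a pristine chip-phase lignin population.

    Chain lengths are drawn as ``1 + Poisson(mu - 1)`` where ``mu`` is the
    target number-average molar mass divided by the expected unit mass at the
    target S/G ratio, and each unit is S with probability
    ``target_sg / (1 + target_sg)``.  As the population grows the sample
    number-average molar mass converges to ``target_mn`` and the S/G count
    ratio to ``target_sg``.
    """
    masses = masses or MonomerMasses()
    if n_chains < 1:
        raise ConfigurationError("n_chains must be >= 1")
    if target_mn < masses.g:
        raise ConfigurationError(
            f"target_mn={target_mn} below a single G unit ({masses.g})")
    if target_sg <= 0:
        raise ConfigurationError("target_sg must be positive")
    if rng is None:
        rng = np.random.default_rng(seed)

    mean_units = target_mn / masses.mean_unit_mass(target_sg)
    p_s = target_sg / (1.0 + target_sg)
    lengths = 1 + rng.poisson(max(mean_units - 1.0, 0.0), size=n_chains)

    registry = ChainRegistry(masses)
    for length in lengths:
        units = (rng.random(length) < p_s).astype(int).tolist()
        registry.add_chain(units, CHIP)
    return SystemState(registry=registry, t_c=temperature, t_f=temperature,
                       rng=rng)


def apply_scission(registry: ChainRegistry, chain_id: int,
                   bond_index: int) -> tuple[LigninChain, LigninChain]:
    """Cleave bond ``bond_index`` of a liquor chain into two fragments.

    The fragments inherit contiguous slices of the parent sequence (and hence
    of its dyad/energy structure); total molar mass is conserved.
    """
    chain = registry.chains[chain_id]
    if chain.phase != LIQUOR:
        raise EventError(f"scission on chip-phase chain {chain_id}")
    if not 0 <= bond_index < chain.n_bonds:
        raise EventError(
            f"bond index {bond_index} out of range for chain {chain_id} "
            f"({chain.n_bonds} bonds)")
    registry.remove_chain(chain_id)
    left = registry.add_chain(chain.units[:bond_index + 1], LIQUOR)
    right = registry.add_chain(chain.units[bond_index + 1:], LIQUOR)
    return left, right


def apply_condensation(registry: ChainRegistry, chain_id_i: int,
                       chain_id_j: int) -> LigninChain:
    """Merge two distinct liquor chains into one (sequence i then j).

    The junction bond is keyed, like every other bond, by its flanking dyad.
    """
    if chain_id_i == chain_id_j:
        raise EventError("condensation requires two distinct chains (j != i)")
    ci = registry.chains[chain_id_i]
    cj = registry.chains[chain_id_j]
    if ci.phase != LIQUOR or cj.phase != LIQUOR:
        raise EventError("condensation requires both chains in the liquor phase")
    registry.remove_chain(chain_id_i)
    registry.remove_chain(chain_id_j)
    return registry.add_chain(ci.units + cj.units, LIQUOR)


def apply_demethoxylation(registry: ChainRegistry, chain_id: int,
                          unit_index: int) -> LigninChain:
    """Convert the S unit at ``unit_index`` of a liquor chain to G.

    Molar mass decreases by exactly one methoxy-group mass (48.0 g/mol for
    the default monomer masses); the dyads of the adjacent bonds change.
    """
    chain = registry.chains[chain_id]
    if chain.phase != LIQUOR:
        raise EventError(f"demethoxylation on chip-phase chain {chain_id}")
    if chain.units[unit_index] != S:
        raise EventError(
            f"unit {unit_index} of chain {chain_id} is G, not S")
    # Re-add through the registry so aggregates and listeners stay coherent.
    registry.remove_chain(chain_id)
    units = list(chain.units)
    units[unit_index] = G
    return registry.add_chain(units, LIQUOR, chain_id=chain_id)


def compute_observables(registry: ChainRegistry, phase: str,
                        bins: np.ndarray | int | None = None) -> dict:
    """Molecular observables of one phase from the cached aggregates.

    Returns Mn, Mw (g/mol), the S/G count ratio (``inf`` flags a G-free
    phase) and, when ``bins`` is given, a molar-mass histogram.
    """
    agg = registry.agg[phase]
    if agg.n == 0:
        raise EmptyPhaseError(f"no chains in phase {phase!r}")
    g_count = agg.units - agg.s_count
    sg = agg.s_count / g_count if g_count > 0 else math.inf
    out = {
        "Mn": agg.sum_mw / agg.n,
        "Mw": agg.sum_mw2 / agg.sum_mw,
        "sg_ratio": sg,
        "n_chains": agg.n,
    }
    if bins is not None:
        mws = [registry.chains[cid].mw for cid in registry.phase_ids[phase]]
        counts, edges = np.histogram(mws, bins=bins)
        out["mwd_counts"] = counts
        out["mwd_edges"] = edges
    return out


def transfer_chain(registry: ChainRegistry, direction: str,
                   rng: np.random.Generator) -> Optional[LigninChain]:
    """Move one chain across the chip/liquor boundary if the budget allows.

    ``direction`` is ``"dissolve"`` (chip -> liquor, charged against the
    dissolved-mass accumulator) or ``"redeposit"`` (liquor -> chip).  The
    chain is picked uniformly at random among chains whose mass does not
    exceed the accumulator; the accumulator is decremented by its mass.
    Returns the moved chain, or None when nothing is eligible.
    """
    if direction == "dissolve":
        source, target = CHIP, LIQUOR
        acc = registry.dissolved_accumulator
    elif direction == "redeposit":
        source, target = LIQUOR, CHIP
        acc = registry.redeposit_accumulator
    else:
        raise ConfigurationError(f"unknown transfer direction {direction!r}")

    if not registry.phase_ids[source]:
        logger.warning("transfer %s requested but %s phase is empty",
                       direction, source)
        return None

    chosen = _sample_eligible(registry, source, acc, rng)
    if chosen is None:
        return None
    chain = registry.move_phase(chosen, target)
    if direction == "dissolve":
        registry.dissolved_accumulator -= chain.mw
    else:
        registry.redeposit_accumulator -= chain.mw
    return chain


def _sample_eligible(registry: ChainRegistry, phase: str, budget: float,
                     rng: np.random.Generator) -> Optional[int]:
    """Uniform draw among chains of ``phase`` with mass <= budget.

    Uses the registry's mass-bucket index: buckets strictly below the budget
    are fully eligible; the boundary bucket is resolved by rejection, with
    an exact boundary scan as the fallback.  Cost is proportional to the
    number of touched buckets, never to the phase population.
    """
    w = registry._bucket_w
    buckets = registry._buckets[phase]
    b_edge = int(budget // w)
    full: list[list[int]] = []
    n_full = 0
    for b, members in buckets.items():
        if (b + 1) * w <= budget:
            full.append(members)
            n_full += len(members)
    boundary = buckets.get(b_edge, [])
    if (b_edge + 1) * w <= budget:
        boundary = []  # already counted as full
    chains = registry.chains
    total = n_full + len(boundary)
    if total == 0:
        registry._tighten_min_bucket(phase)
        return None
    for _ in range(8):
        r = int(rng.random() * total)
        if r < n_full:
            for members in full:
                if r < len(members):
                    return members[r]
                r -= len(members)
        else:
            cid = boundary[r - n_full]
            if chains[cid].mw <= budget:
                return cid
    eligible = [cid for cid in boundary if chains[cid].mw <= budget]
    if n_full == 0 and not eligible:
        registry._tighten_min_bucket(phase)
        return None
    k = int(rng.random() * (n_full + len(eligible)))
    if k < n_full:
        for members in full:
            if k < len(members):
                return members[k]
            k -= len(members)
    return eligible[k - n_full]
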