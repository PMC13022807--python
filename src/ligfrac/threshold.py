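"""Arrhenius activation-energy threshold filtering of the event catalog.

Events whose rate coefficients are more than a factor ``ratio_cutoff``
(default 1000) slower than the fastest competing event of the same type
contribute negligibly to the total rate, and the Arrhenius form turns that
rate ratio into an energy margin:

    dE_th = R * T_f * ln(ratio_cutoff)        (20.27 kJ/mol at 353 K)

The filter is applied before any rate evaluation and adapts to the liquor
temperature:

* depolymerization: within each chain, only scission sites with
  ``E_dep <= E_dep_low + dE_th`` (relative to that chain's most labile site)
  are retained;
* condensation: the V-shaped barrier versus combined molar mass turns the
  energy margin into a combined-MW window ``[mw_low, mw_high]``
  (at 353 K with default slopes: up to 1672.33 g/mol, i.e. an all-G combined
  degree of polymerization of at most 9); candidate pairs are enumerated
  from a mass-bucketed index, never by a full pairwise scan;
* demethoxylation: never filtered -- all chains share one barrier, so no
  within-type activation-energy ratio exists to filter on.

Stochastic event selection among the retained events is untouched; every
excluded event's coefficient is provably below (fastest retained
coefficient)/ratio_cutoff.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Iterable

import numpy as np

from .chains import ChainRegistry, LigninChain, LIQUOR
from .kinetics import Kinetics, compute_threshold  # noqa: F401  (re-export)


@dataclass(frozen=True)
class Threshold:
    """The adaptive energy threshold and the temperature it was computed at."""

    delta_e_th: float  # kJ/mol
    ratio_cutoff: float
    t_ref: float  # K

    @classmethod
    def at(cls, temperature: float, ratio_cutoff: float = 1000.0) -> "Threshold":
        return cls(compute_threshold(temperature, ratio_cutoff),
                   ratio_cutoff, temperature)


@dataclass(frozen=True)
class CondensationWindow:
    """Combined-MW window retained by the condensation filter."""

    mw_low: float
    mw_high: float
    dp_low: int
    dp_high: int


def condensation_window(kinetics: Kinetics, temperature: float,
                        ratio_cutoff: float = 1000.0,
                        g_mass: float = 179.2) -> CondensationWindow:
    """Solve the retained combined-MW window at ``temperature``.

    ``dp_high`` is the largest combined degree of polymerization an all-G
    (lightest-unit) pair can have inside the window.
    """
    de = compute_threshold(temperature, ratio_cutoff)
    low, high = kinetics.con_energy.window(de)
    return CondensationWindow(low, high, 2, int(math.floor(high / g_mass)))


def filter_depolymerization(bond_energies, delta_e_th: float) -> np.ndarray:
    """Indices of scission sites within ``delta_e_th`` of the chain minimum.

    The reference energy is per chain (its most labile site), so the
    minimum-energy bond is always retained.
    """
    e = np.asarray(bond_energies, dtype=float)
    if e.size == 0:
        return np.empty(0, dtype=int)
    return np.flatnonzero(e <= e.min() + delta_e_th)


def filter_condensation(chains: Iterable[LigninChain], delta_e_th: float,
                        temperature: float,
                        kinetics: Kinetics) -> list[tuple[int, int]]:
    """Retained unordered chain pairs whose combined MW lies in the window.

    Pairs are generated through a mass-bucketed index (bucket width = one
    G-unit mass): each chain is only tested against buckets that can still
    land inside the window, so enumeration is proportional to the retained
    set rather than to all pairs.
    """
    low, high = kinetics.con_energy.window(delta_e_th)
    bucket_w = 179.2
    buckets: dict[int, list[LigninChain]] = {}
    order: list[LigninChain] = []
    for ch in chains:
        buckets.setdefault(int(ch.mw // bucket_w), []).append(ch)
        order.append(ch)

    pairs: list[tuple[int, int]] = []
    seen: set[int] = set()
    for ch in order:
        seen.add(ch.id)
        b_lo = int((low - ch.mw) // bucket_w) - 1
        b_hi = int((high - ch.mw) // bucket_w) + 1
        for b in range(b_lo, b_hi + 1):
            for other in buckets.get(b, ()):
                if other.id in seen:
                    continue
                if low <= ch.mw + other.mw <= high:
                    pairs.append((min(ch.id, other.id), max(ch.id, other.id)))
    return pairs


def build_filtered_catalog(registry: ChainRegistry, kinetics: Kinetics,
                           temperature: float, ratio_cutoff: float = 1000.0):
    """Threshold-filtered snapshot of the liquor-phase event catalog.

    Intended for inspection and as the small-system oracle; the production
    engine maintains the same retained set incrementally
    (:class:`ligfrac.engine.LiveCatalog` with ``filtered=True``).
    """
    from .engine import build_catalog_snapshot

    return build_catalog_snapshot(registry, kinetics, temperature,
                                  filtered=True, ratio_cutoff=ratio_cutoff)
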