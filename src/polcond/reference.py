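"""Rejection-free lattice kinetic Monte Carlo: reference implementation.

One iteration draws a transition from the rate catalog by tower sampling
(probability proportional to its Arrhenius rate), applies it, advances the
system clock by an exponential waiting time, and locally refreshes the
catalog in a window around the moved entities. Transition rates follow
k = k_coeff * exp(-(E2 - E1)) with energies in kBT, so forward and backward
rates of any move satisfy detailed balance with respect to exp(-2 E).

This module favors clarity and exactness over speed; long production runs go
through the compiled kernel in :mod:`polcond.engine`, which is cross-checked
against this implementation transition-for-transition.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np

from .config import KineticParams
from .lattice import (
    MOORE_OFFSETS,
    AffinityMatrix,
    LatticeState,
    Species,
    delta_energy,
    energy_offsets,
)

__all__ = [
    "Transition",
    "RateCatalog",
    "JammedSystemError",
    "arrhenius_rate",
    "enumerate_particle_transitions",
    "enumerate_polymer_transitions",
    "build_rate_catalog",
    "select_transition",
    "apply_transition",
    "advance_time",
    "local_update",
]

LOCAL_UPDATE_RADIUS = 4  # the crankshaft displaces by two sites: [x±4, y±4]


class JammedSystemError(RuntimeError):
    """No transition has positive rate; the system cannot evolve."""


def arrhenius_rate(e1: float, e2: float, k_coeff: float) -> float:
    """Arrhenius transition rate k = k_coeff * exp(-(E2 - E1))."""
    if k_coeff <= 0:
        raise ValueError("rate coefficient must be positive")
    return k_coeff * math.exp(-(e2 - e1))


@dataclass(frozen=True)
class Transition:
    """One elementary move: sources -> targets with an Arrhenius rate."""

    kind: str                                   # particle_move | end_flip | kink_jump | crankshaft
    sources: tuple[tuple[int, int], ...]
    targets: tuple[tuple[int, int], ...]
    rate: float
    chain: int | None = None
    monomers: tuple[int, ...] = ()

    @property
    def displacements(self):
        return tuple(zip(self.sources, self.targets))

    def key(self):
        """Identity ignoring the floating rate, for set comparisons."""
        return (self.kind, self.sources, self.targets, self.chain, self.monomers)


def enumerate_particle_transitions(
    state: LatticeState,
    site: tuple[int, int],
    w: AffinityMatrix,
    kinetics: KineticParams,
    neighborhood: str = "moore",
) -> list[Transition]:
    """All hops of the particle at ``site`` to empty Moore neighbors."""
    y, x = site
    if state.grid[y, x] != Species.S5P:
        raise ValueError(f"site {site} does not hold a particle")
    out = []
    for dy, dx in MOORE_OFFSETS:
        ny, nx = y + dy, x + dx
        if not state.in_bounds(ny, nx):
            continue
        if state.grid[ny, nx] != Species.EMPTY:
            continue
        de = delta_energy(state, [((y, x), (ny, nx))], w, neighborhood)
        out.append(Transition(
            kind="particle_move",
            sources=((y, x),),
            targets=((ny, nx),),
            rate=arrhenius_rate(0.0, de, kinetics.k_p),
        ))
    return out


def _monomer_transitions(
    state: LatticeState,
    cid: int,
    i: int,
    w: AffinityMatrix,
    kinetics: KineticParams,
    neighborhood: str,
) -> list[Transition]:
    """Moves stored under monomer (cid, i), in canonical slot order:
    [end-flip candidate A, end-flip candidate B, kink jump, crankshaft]."""
    chain = state.chains[cid]
    L = chain.length
    coords = chain.coords
    out: list[Transition] = []

    def empty(y: int, x: int) -> bool:
        return state.in_bounds(y, x) and state.grid[y, x] == Species.EMPTY

    # end flip: rotate the end monomer 90 degrees about its bonded neighbor
    if L >= 2 and (i == 0 or i == L - 1):
        pivot = coords[1] if i == 0 else coords[L - 2]
        end = coords[i]
        d = (int(end[0] - pivot[0]), int(end[1] - pivot[1]))
        if d[0] != 0:      # vertical bond -> horizontal candidates
            cands = [(int(pivot[0]), int(pivot[1]) - 1),
                     (int(pivot[0]), int(pivot[1]) + 1)]
        else:              # horizontal bond -> vertical candidates
            cands = [(int(pivot[0]) - 1, int(pivot[1])),
                     (int(pivot[0]) + 1, int(pivot[1]))]
        for ty, tx in cands:
            if not empty(ty, tx):
                continue
            de = delta_energy(state, [((int(end[0]), int(end[1])), (ty, tx))],
                              w, neighborhood)
            out.append(Transition(
                kind="end_flip",
                sources=((int(end[0]), int(end[1])),),
                targets=((ty, tx),),
                rate=arrhenius_rate(0.0, de, kinetics.k_kink),
                chain=cid, monomers=(i,),
            ))

    # kink jump: move a corner monomer to the opposite side of the corner
    if 0 < i < L - 1:
        a, p, b = coords[i - 1], coords[i], coords[i + 1]
        if a[0] != b[0] and a[1] != b[1]:
            ty, tx = int(a[0] + b[0] - p[0]), int(a[1] + b[1] - p[1])
            if empty(ty, tx):
                de = delta_energy(state, [((int(p[0]), int(p[1])), (ty, tx))],
                                  w, neighborhood)
                out.append(Transition(
                    kind="kink_jump",
                    sources=((int(p[0]), int(p[1])),),
                    targets=((ty, tx),),
                    rate=arrhenius_rate(0.0, de, kinetics.k_kink),
                    chain=cid, monomers=(i,),
                ))

    # crankshaft: reflect the two monomers of a U across its base
    if 1 <= i <= L - 3:
        e1, p1, p2, e2 = coords[i - 1], coords[i], coords[i + 1], coords[i + 2]
        base = (int(e2[0] - e1[0]), int(e2[1] - e1[1]))
        if abs(base[0]) + abs(base[1]) == 1:
            n1 = (int(p1[0] - e1[0]), int(p1[1] - e1[1]))
            n2 = (int(p2[0] - e2[0]), int(p2[1] - e2[1]))
            if n1 == n2 and abs(n1[0]) + abs(n1[1]) == 1:
                t1 = (int(e1[0] - n1[0]), int(e1[1] - n1[1]))
                t2 = (int(e2[0] - n1[0]), int(e2[1] - n1[1]))
                if empty(*t1) and empty(*t2):
                    de = delta_energy(
                        state,
                        [((int(p1[0]), int(p1[1])), t1),
                         ((int(p2[0]), int(p2[1])), t2)],
                        w, neighborhood)
                    out.append(Transition(
                        kind="crankshaft",
                        sources=((int(p1[0]), int(p1[1])),
                                 (int(p2[0]), int(p2[1]))),
                        targets=(t1, t2),
                        rate=arrhenius_rate(0.0, de, kinetics.k_crank),
                        chain=cid, monomers=(i, i + 1),
                    ))
    return out


def enumerate_polymer_transitions(
    state: LatticeState,
    cid: int,
    w: AffinityMatrix,
    kinetics: KineticParams,
    neighborhood: str = "moore",
) -> list[Transition]:
    """All Verdier-Stockmayer moves of chain ``cid``, monomer-ordered."""
    out: list[Transition] = []
    for i in range(state.chains[cid].length):
        out.extend(_monomer_transitions(state, cid, i, w, kinetics, neighborhood))
    return out


class RateCatalog:
    """Indexed collection of transitions keyed by source entity.

    Particle entries are keyed ``('p', y, x)`` by current site; polymer
    entries ``('m', chain, monomer)``. Canonical flat order — particles in
    row-major site order (neighbor order fixed), then chains and monomers in
    index order — defines the tower-sampling sequence.
    """

    def __init__(self, width: int, height: int, n_chains: int,
                 chain_lengths: list[int]):
        self.width = width
        self.height = height
        self.chain_lengths = list(chain_lengths)
        self.particle: dict[tuple[int, int], list[Transition]] = {}
        self.monomer: dict[tuple[int, int], list[Transition]] = {}

    def flat(self) -> list[Transition]:
        out: list[Transition] = []
        for (y, x) in sorted(self.particle):
            out.extend(self.particle[(y, x)])
        for cid, L in enumerate(self.chain_lengths):
            for i in range(L):
                out.extend(self.monomer.get((cid, i), ()))
        return out

    @property
    def transitions(self) -> list[Transition]:
        return self.flat()

    @property
    def k_total(self) -> float:
        total = 0.0
        for t in self.flat():
            total += t.rate
        return total

    def __len__(self) -> int:
        return sum(len(v) for v in self.particle.values()) + \
            sum(len(v) for v in self.monomer.values())


def build_rate_catalog(
    state: LatticeState,
    w: AffinityMatrix,
    kinetics: KineticParams,
    neighborhood: str = "moore",
) -> RateCatalog:
    """Full enumeration of every possible transition on ``state``."""
    cat = RateCatalog(state.width, state.height, len(state.chains),
                      [c.length for c in state.chains])
    for site in state.particle_sites():
        trs = enumerate_particle_transitions(state, site, w, kinetics,
                                             neighborhood)
        if trs:
            cat.particle[site] = trs
    for cid in range(len(state.chains)):
        for i in range(state.chains[cid].length):
            trs = _monomer_transitions(state, cid, i, w, kinetics, neighborhood)
            if trs:
                cat.monomer[(cid, i)] = trs
    return cat


def select_transition(catalog: RateCatalog, r1: float) -> Transition:
    """Tower sampling: the transition j with sum_{i<j} k_i < r1*k_total <= sum_{i<=j} k_i."""
    flat = catalog.flat()
    if not flat:
        raise JammedSystemError("empty rate catalog")
    k_total = 0.0
    for t in flat:
        k_total += t.rate
    if k_total <= 0:
        raise JammedSystemError("total rate is zero")
    k_star = r1 * k_total
    cum = 0.0
    for t in flat:
        cum += t.rate
        if cum >= k_star:
            return t
    return flat[-1]   # guard against terminal rounding


def advance_time(k_total: float, r2: float) -> float:
    """Exponential waiting time dt = -log(r2) / k_total."""
    if k_total <= 0:
        raise JammedSystemError("cannot advance time with zero total rate")
    return -math.log(r2) / k_total


def apply_transition(state: LatticeState, t: Transition) -> list[tuple[int, int]]:
    """Execute a transition in place; returns every site whose occupancy changed."""
    for (ty, tx) in t.targets:
        if state.grid[ty, tx] != Species.EMPTY and (ty, tx) not in t.sources:
            raise RuntimeError(f"stale transition: target ({ty},{tx}) occupied")
    if t.kind == "particle_move":
        (sy, sx), (ty, tx) = t.sources[0], t.targets[0]
        if state.grid[sy, sx] != Species.S5P:
            raise RuntimeError("stale transition: source is not a particle")
        state.grid[sy, sx] = Species.EMPTY
        state.grid[ty, tx] = Species.S5P
    else:
        chain = state.chains[t.chain]
        for mi, (sy, sx), (ty, tx) in zip(t.monomers, t.sources, t.targets):
            sp = int(state.grid[sy, sx])
            state.grid[sy, sx] = Species.EMPTY
            state.chain_id[sy, sx] = -1
            state.mono_ix[sy, sx] = -1
            state.grid[ty, tx] = sp
            state.chain_id[ty, tx] = t.chain
            state.mono_ix[ty, tx] = mi
            chain.coords[mi] = (ty, tx)
    return list(dict.fromkeys(list(t.sources) + list(t.targets)))


def local_update(
    catalog: RateCatalog,
    state: LatticeState,
    moved_sites: list[tuple[int, int]],
    w: AffinityMatrix,
    kinetics: KineticParams,
    neighborhood: str = "moore",
) -> RateCatalog:
    """Refresh the catalog in the [x±4, y±4] windows around moved sites.

    Every transition originating in or targeting the union of windows is
    recomputed; the result is identical to a full rebuild. The catalog is
    modified in place and returned.
    """
    r = LOCAL_UPDATE_RADIUS
    window: set[tuple[int, int]] = set()
    for (y, x) in moved_sites:
        for ny in range(max(0, y - r), min(state.height, y + r + 1)):
            for nx in range(max(0, x - r), min(state.width, x + r + 1)):
                window.add((ny, nx))
    monomers: set[tuple[int, int]] = set()
    for (y, x) in window:
        if state.grid[y, x] == Species.S5P:
            catalog.particle[(y, x)] = enumerate_particle_transitions(
                state, (y, x), w, kinetics, neighborhood)
        else:
            catalog.particle.pop((y, x), None)
        cid = int(state.chain_id[y, x])
        if cid >= 0:
            mi = int(state.mono_ix[y, x])
            L = state.chains[cid].length
            # slots of nearby monomers depend on this monomer's position
            for j in range(max(0, mi - 2), min(L, mi + 3)):
                monomers.add((cid, j))
    for (cid, mi) in monomers:
        trs = _monomer_transitions(state, cid, mi, w, kinetics, neighborhood)
        if trs:
            catalog.monomer[(cid, mi)] = trs
        else:
            catalog.monomer.pop((cid, mi), None)
    return catalog


def run_steps(
    state: LatticeState,
    w: AffinityMatrix,
    kinetics: KineticParams,
    draws: np.ndarray,
    neighborhood: str = "moore",
    catalog: RateCatalog | None = None,
    collect_dt: bool = False,
):
    """Drive ``len(draws)`` iterations on ``state`` (mutated in place).

    ``draws`` is an (n, 2) array of uniforms in [0, 1); per step the first is
    mapped to r1 (selection) and the second to r2 (waiting time), both on
    (0, 1]. Returns (elapsed simulated time, catalog, list of k_total*dt if
    requested).
    """
    if catalog is None:
        catalog = build_rate_catalog(state, w, kinetics, neighborhood)
    t_elapsed = 0.0
    scaled_dts: list[float] = []
    for u1, u2 in np.asarray(draws, dtype=float):
        r1 = 1.0 - u1
        r2 = 1.0 - u2
        k_total = catalog.k_total
        if k_total <= 0:
            raise JammedSystemError("system is jammed")
        tr = select_transition(catalog, r1)
        dt = advance_time(k_total, r2)
        t_elapsed += dt
        if collect_dt:
            scaled_dts.append(k_total * dt)
        moved = apply_transition(state, tr)
        local_update(catalog, state, moved, w, kinetics, neighborhood)
    return t_elapsed, catalog, scaled_dts
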