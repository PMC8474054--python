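"""Lattice world: species, affinities, polymer chains, state, and energies.

The model world is a 2-D square lattice with hard-wall boundaries. Each site
is either empty (solvent), holds one mobile Pol II Ser5P particle, or holds
one monomer of a chromatin chain. Chain monomers carry one of three chromatin
states: regulatory (RC, particle-attracting), inactive (IC, self-attracting),
or active/elongating (AC, particle-repelling). Interactions are pairwise
contact energies, in units of kBT, between entities in each other's
interaction neighborhood (Moore 8-neighborhood by default, switchable to the
4-site von Neumann shell).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from enum import IntEnum
from typing import Iterable, Sequence

import numpy as np

__all__ = [
    "Species",
    "AffinityMatrix",
    "PolymerChain",
    "LatticeState",
    "CapacityError",
    "PlacementError",
    "MOORE_OFFSETS",
    "VON_NEUMANN_OFFSETS",
    "energy_offsets",
    "pair_energy",
    "total_energy",
    "delta_energy",
    "initialize_state",
]


class Species(IntEnum):
    """Site contents. EMPTY is inert solvent and never contributes energy."""

    EMPTY = 0
    S5P = 1   # mobile "red" Pol II Ser5P particle
    RC = 2    # regulatory chromatin ("blue" monomer)
    IC = 3    # inactive chromatin ("black" monomer)
    AC = 4    # active / elongating chromatin ("gray" monomer)


# Canonical neighbor orders; fixed because the rate catalog enumerates
# transitions in this order and reproducibility depends on it.
MOORE_OFFSETS: tuple[tuple[int, int], ...] = (
    (-1, -1), (-1, 0), (-1, 1),
    (0, -1), (0, 1),
    (1, -1), (1, 0), (1, 1),
)
VON_NEUMANN_OFFSETS: tuple[tuple[int, int], ...] = (
    (-1, 0), (0, -1), (0, 1), (1, 0),
)


def energy_offsets(neighborhood: str) -> tuple[tuple[int, int], ...]:
    if neighborhood == "moore":
        return MOORE_OFFSETS
    if neighborhood == "von_neumann":
        return VON_NEUMANN_OFFSETS
    raise ValueError(f"unknown neighborhood {neighborhood!r}")


class CapacityError(ValueError):
    """Requested contents do not fit on the lattice."""


class PlacementError(RuntimeError):
    """A chain layout could not be realized on the lattice."""


class AffinityMatrix:
    """Symmetric pairwise contact energies w[a][b] in units of kBT.

    Negative values are attractive, positive repulsive. All pairs involving
    EMPTY are zero by construction. Defaults follow the adjusted model
    parameters: w(S5P,S5P) = -0.35, w(RC,S5P) = -0.5, w(IC,IC) = -0.5,
    w(AC,S5P) = +0.5, everything else 0.
    """

    N_SPECIES = 5

    def __init__(self, pairs: dict[tuple[Species, Species], float] | None = None):
        w = np.zeros((self.N_SPECIES, self.N_SPECIES), dtype=float)
        if pairs is None:
            pairs = self.default_pairs()
        for (a, b), val in pairs.items():
            a, b = Species(a), Species(b)
            if Species.EMPTY in (a, b):
                if val != 0.0:
                    raise ValueError("pairs with EMPTY must have zero energy")
                continue
            w[a, b] = val
            w[b, a] = val
        self._w = w
        self._w.setflags(write=False)

    @staticmethod
    def default_pairs() -> dict[tuple[Species, Species], float]:
        return {
            (Species.S5P, Species.S5P): -0.35,
            (Species.RC, Species.S5P): -0.5,
            (Species.IC, Species.IC): -0.5,
            (Species.AC, Species.S5P): +0.5,
        }

    @classmethod
    def from_updates(cls, **named: float) -> "AffinityMatrix":
        """Default matrix with named overrides like ``s5p_s5p=-0.15``."""
        pairs = cls.default_pairs()
        for key, val in named.items():
            a_name, b_name = key.split("_")
            a = Species[a_name.upper()]
            b = Species[b_name.upper()]
            if a != b:
                pairs.pop((a, b), None)
                pairs.pop((b, a), None)
            pairs[(min(a, b), max(a, b))] = float(val)
        return cls(pairs)

    @property
    def matrix(self) -> np.ndarray:
        return self._w

    def __getitem__(self, ab: tuple[Species, Species]) -> float:
        a, b = ab
        return float(self._w[Species(a), Species(b)])

    def to_dict(self) -> dict[str, float]:
        out: dict[str, float] = {}
        for a in Species:
            for b in Species:
                if a is Species.EMPTY or b is Species.EMPTY or b < a:
                    continue
                if self._w[a, b] != 0.0:
                    out[f"{a.name}_{b.name}"] = float(self._w[a, b])
        return out

    @classmethod
    def from_dict(cls, d: dict[str, float]) -> "AffinityMatrix":
        pairs = {}
        for key, val in d.items():
            a_name, b_name = key.split("_")
            pairs[(Species[a_name], Species[b_name])] = float(val)
        return cls(pairs)

    def __eq__(self, other: object) -> bool:
        return isinstance(other, AffinityMatrix) and np.array_equal(self._w, other._w)


@dataclass
class PolymerChain:
    """Self-avoiding chain of monomers with axis-aligned unit bonds.

    ``coords`` has shape (L, 2) in (row, col) order; ``species`` holds one
    of {RC, IC, AC} per monomer.
    """

    coords: np.ndarray
    species: np.ndarray

    def __post_init__(self) -> None:
        self.coords = np.asarray(self.coords, dtype=np.int64).reshape(-1, 2)
        self.species = np.asarray(self.species, dtype=np.int64).reshape(-1)
        if len(self.coords) != len(self.species):
            raise ValueError("coords and species length mismatch")

    @property
    def length(self) -> int:
        return len(self.coords)

    def validate(self) -> None:
        diffs = np.abs(np.diff(self.coords, axis=0)).sum(axis=1)
        if not np.all(diffs == 1):
            raise ValueError("consecutive monomers must be axis-adjacent")
        if len({tuple(p) for p in self.coords}) != self.length:
            raise ValueError("chain is not self-avoiding")
        if not np.all(np.isin(self.species, [Species.RC, Species.IC, Species.AC])):
            raise ValueError("monomer species must be RC, IC, or AC")

    def copy(self) -> "PolymerChain":
        return PolymerChain(self.coords.copy(), self.species.copy())


class LatticeState:
    """Single-occupancy lattice of particles and chains.

    Attributes
    ----------
    grid : (H, W) int array of Species values.
    chain_id, mono_ix : (H, W) int arrays; -1 where no monomer sits.
    chains : list of PolymerChain, kept consistent with the grids.
    """

    def __init__(self, width: int, height: int):
        self.width = int(width)
        self.height = int(height)
        self.grid = np.zeros((self.height, self.width), dtype=np.int64)
        self.chain_id = np.full((self.height, self.width), -1, dtype=np.int64)
        self.mono_ix = np.full((self.height, self.width), -1, dtype=np.int64)
        self.chains: list[PolymerChain] = []

    # -- construction -----------------------------------------------------
    def add_chain(self, chain: PolymerChain) -> None:
        chain.validate()
        for (y, x), sp in zip(chain.coords, chain.species):
            if not self.in_bounds(y, x):
                raise PlacementError(f"monomer ({y},{x}) outside lattice")
            if self.grid[y, x] != Species.EMPTY:
                raise PlacementError(f"site ({y},{x}) already occupied")
        cid = len(self.chains)
        self.chains.append(chain)
        for i, ((y, x), sp) in enumerate(zip(chain.coords, chain.species)):
            self.grid[y, x] = sp
            self.chain_id[y, x] = cid
            self.mono_ix[y, x] = i

    def add_particle(self, y: int, x: int) -> None:
        if not self.in_bounds(y, x):
            raise PlacementError(f"site ({y},{x}) outside lattice")
        if self.grid[y, x] != Species.EMPTY:
            raise PlacementError(f"site ({y},{x}) already occupied")
        self.grid[y, x] = Species.S5P

    # -- queries ----------------------------------------------------------
    def in_bounds(self, y: int, x: int) -> bool:
        return 0 <= y < self.height and 0 <= x < self.width

    @property
    def n_s5p(self) -> int:
        return int(np.count_nonzero(self.grid == Species.S5P))

    def particle_sites(self) -> list[tuple[int, int]]:
        ys, xs = np.nonzero(self.grid == Species.S5P)
        return list(zip(ys.tolist(), xs.tolist()))

    def empty_sites(self) -> list[tuple[int, int]]:
        ys, xs = np.nonzero(self.grid == Species.EMPTY)
        return list(zip(ys.tolist(), xs.tolist()))

    def species_mask(self, sp: Species) -> np.ndarray:
        return self.grid == sp

    def copy(self) -> "LatticeState":
        out = LatticeState(self.width, self.height)
        out.grid = self.grid.copy()
        out.chain_id = self.chain_id.copy()
        out.mono_ix = self.mono_ix.copy()
        out.chains = [c.copy() for c in self.chains]
        return out

    def audit(self) -> None:
        """Full consistency check of grids against chain coordinate lists."""
        seen: set[tuple[int, int]] = set()
        for cid, chain in enumerate(self.chains):
            chain.validate()
            for i, ((y, x), sp) in enumerate(zip(chain.coords, chain.species)):
                pos = (int(y), int(x))
                if pos in seen:
                    raise AssertionError(f"double occupancy at {pos}")
                seen.add(pos)
                assert self.grid[y, x] == sp, f"grid species mismatch at {pos}"
                assert self.chain_id[y, x] == cid
                assert self.mono_ix[y, x] == i
        n_mono = sum(c.length for c in self.chains)
        assert np.count_nonzero(self.chain_id >= 0) == n_mono
        mono_mask = self.chain_id >= 0
        assert np.all(np.isin(self.grid[mono_mask],
                              [Species.RC, Species.IC, Species.AC]))
        assert np.all(self.grid[~mono_mask] != Species.RC)
        assert np.all((self.grid[~mono_mask] == Species.EMPTY)
                      | (self.grid[~mono_mask] == Species.S5P))


# -- energies -------------------------------------------------------------

def pair_energy(a: Species, b: Species, w: AffinityMatrix) -> float:
    """Contact energy of a species pair; zero whenever either is EMPTY."""
    return w[Species(a), Species(b)]


def total_energy(
    state: LatticeState,
    w: AffinityMatrix,
    neighborhood: str = "moore",
    include_bonded: bool = True,
) -> float:
    """Sum of pair energies over unique adjacent occupied site pairs.

    Each pair is counted once; sites outside the lattice contribute nothing.
    ``include_bonded=False`` omits pairs of chain-bonded monomers; since bond
    adjacency never changes under the move set, the two conventions give
    identical energy differences.
    """
    offs = energy_offsets(neighborhood)
    # half-shell so each unordered pair is visited once
    half = [(dy, dx) for dy, dx in offs if (dy, dx) > (0, -1)]
    bonded: set[frozenset[tuple[int, int]]] = set()
    if not include_bonded:
        for chain in state.chains:
            for p, q in zip(chain.coords[:-1], chain.coords[1:]):
                bonded.add(frozenset({tuple(p), tuple(q)}))
    wmat = w.matrix
    grid = state.grid
    e = 0.0
    ys, xs = np.nonzero(grid != Species.EMPTY)
    for y, x in zip(ys.tolist(), xs.tolist()):
        a = grid[y, x]
        for dy, dx in half:
            ny, nx = y + dy, x + dx
            if not state.in_bounds(ny, nx):
                continue
            b = grid[ny, nx]
            if b == Species.EMPTY:
                continue
            if not include_bonded and frozenset({(y, x), (ny, nx)}) in bonded:
                continue
            e += wmat[a, b]
    return float(e)


def delta_energy(
    state: LatticeState,
    move,
    w: AffinityMatrix,
    neighborhood: str = "moore",
) -> float:
    """Energy change E2 - E1 of a move, computed from local contacts only.

    ``move`` is either a sequence of ((y, x), (ty, tx)) displacement pairs or
    an object exposing a ``displacements`` attribute of that form (as the
    engine's Transition does). Agrees exactly with the global total-energy
    difference.
    """
    displacements = getattr(move, "displacements", move)
    displacements = [((int(sy), int(sx)), (int(ty), int(tx)))
                     for (sy, sx), (ty, tx) in displacements]
    old_pos = [s for s, _ in displacements]
    new_pos = [t for _, t in displacements]
    species = []
    for (y, x) in old_pos:
        sp = Species(int(state.grid[y, x]))
        if sp == Species.EMPTY:
            raise ValueError(f"move source ({y},{x}) is empty")
        species.append(sp)
    for (y, x) in new_pos:
        if not state.in_bounds(y, x):
            raise ValueError(f"move target ({y},{x}) outside lattice")
        if state.grid[y, x] != Species.EMPTY and (y, x) not in old_pos:
            raise ValueError(f"move target ({y},{x}) occupied")

    offs = energy_offsets(neighborhood)
    wmat = w.matrix
    moved = set(old_pos)

    def static_species(y: int, x: int) -> int:
        if (y, x) in moved:
            return Species.EMPTY
        return int(state.grid[y, x])

    def shell_energy(positions: Sequence[tuple[int, int]]) -> float:
        e = 0.0
        for sp, (y, x) in zip(species, positions):
            for dy, dx in offs:
                ny, nx = y + dy, x + dx
                if not state.in_bounds(ny, nx):
                    continue
                e += wmat[sp, static_species(ny, nx)]
        # pairs among the moved entities themselves, each counted once
        for i in range(len(positions)):
            for j in range(i + 1, len(positions)):
                dy = positions[i][0] - positions[j][0]
                dx = positions[i][1] - positions[j][1]
                if (dy, dx) in offs:
                    e += wmat[species[i], species[j]]
        return e

    return float(shell_energy(new_pos) - shell_energy(old_pos))


# -- initialization -------------------------------------------------------

def _chain_species_blocks(n_rc: int, n_ac: int, length: int) -> np.ndarray:
    """Contiguous blocks in the order RC, AC, IC (IC fills to length)."""
    n_ic = length - n_rc - n_ac
    if min(n_rc, n_ac, n_ic) < 0:
        raise ValueError("species counts exceed chain length")
    return np.array(
        [Species.RC] * n_rc + [Species.AC] * n_ac + [Species.IC] * n_ic,
        dtype=np.int64,
    )


def _snake_path(
    start: tuple[int, int],
    direction: tuple[int, int],
    length: int,
    occupied: set[tuple[int, int]],
    height: int,
    width: int,
) -> list[tuple[int, int]]:
    """Deterministic path marching in ``direction``, folding at obstacles."""
    path = [start]
    pos = start
    d = direction
    turn = 1
    for _ in range(length - 1):
        placed = False
        candidates = [d]
        # rotate 90 degrees, alternating handedness to produce a snake
        perp = (d[1] * turn, -d[0] * turn)
        candidates += [perp, (-perp[0], -perp[1]), (-d[0], -d[1])]
        for cand in candidates:
            ny, nx = pos[0] + cand[0], pos[1] + cand[1]
            if 0 <= ny < height and 0 <= nx < width and (ny, nx) not in occupied \
                    and (ny, nx) not in path:
                if cand != d:
                    turn = -turn
                d = cand
                pos = (ny, nx)
                path.append(pos)
                placed = True
                break
        if not placed:
            raise PlacementError("snake path blocked before reaching length")
    return path


def _layout_paths(
    layout: str,
    n_chains: int,
    length: int,
    height: int,
    width: int,
    rng: np.random.Generator,
) -> list[list[tuple[int, int]]]:
    occupied: set[tuple[int, int]] = set()
    paths: list[list[tuple[int, int]]] = []

    def commit(path: list[tuple[int, int]]) -> None:
        occupied.update(path)
        paths.append(path)

    if layout == "single":
        if n_chains != 1:
            raise PlacementError("'single' layout requires exactly one chain")
        y = height // 2
        x0 = max(0, (width - length) // 2)
        commit(_snake_path((y, x0), (0, 1), length, occupied, height, width))
    elif layout in ("parallel", "four_parallel"):
        rows = [height * (i + 1) // (n_chains + 1) for i in range(n_chains)]
        for y in rows:
            x0 = max(0, (width - length) // 2)
            commit(_snake_path((y, x0), (0, 1), length, occupied, height, width))
    elif layout == "cross_of_four":
        if n_chains != 4:
            raise PlacementError("'cross_of_four' requires exactly four chains")
        cy, cx = height // 2, width // 2
        arms = [((cy, cx + 1), (0, 1)), ((cy, cx - 1), (0, -1)),
                ((cy + 1, cx), (1, 0)), ((cy - 1, cx), (-1, 0))]
        for start, d in arms:
            commit(_snake_path(start, d, length, occupied, height, width))
    elif layout == "random_walks":
        for _ in range(n_chains):
            for _attempt in range(200):
                y0 = int(rng.integers(height))
                x0 = int(rng.integers(width))
                if (y0, x0) in occupied:
                    continue
                path = _self_avoiding_walk((y0, x0), length, occupied,
                                           height, width, rng)
                if path is not None:
                    commit(path)
                    break
            else:
                raise PlacementError("could not place random-walk chain")
    else:
        raise PlacementError(f"unknown chain layout {layout!r}")
    return paths


def _self_avoiding_walk(start, length, occupied, height, width, rng):
    path = [start]
    taken = set(occupied)
    taken.add(start)
    pos = start
    for _ in range(length - 1):
        options = []
        for dy, dx in VON_NEUMANN_OFFSETS:
            ny, nx = pos[0] + dy, pos[1] + dx
            if 0 <= ny < height and 0 <= nx < width and (ny, nx) not in taken:
                options.append((ny, nx))
        if not options:
            return None
        pos = options[int(rng.integers(len(options)))]
        path.append(pos)
        taken.add(pos)
    return path


def initialize_state(config, rng: np.random.Generator) -> LatticeState:
    """Build the starting configuration: chains first, then random particles.

    Chains are placed according to ``config.layout`` with contiguous species
    blocks (RC, then AC, then IC filling to the chain length). Particles are
    then distributed uniformly at random over the remaining empty sites,
    without replacement.
    """
    state = LatticeState(config.width, config.height)
    chain_specs = list(config.chains)
    n_sites = config.width * config.height
    n_mono = sum(cs.length for cs in chain_specs)
    if config.n_s5p + n_mono > n_sites:
        raise CapacityError(
            f"{config.n_s5p} particles + {n_mono} monomers exceed "
            f"{n_sites} lattice sites"
        )
    if chain_specs:
        paths = _layout_paths(config.layout, len(chain_specs),
                              chain_specs[0].length, config.height,
                              config.width, rng)
        for cs, path in zip(chain_specs, paths):
            if len(path) != cs.length:
                raise PlacementError("layout path length mismatch")
            species = _chain_species_blocks(cs.n_rc, cs.n_ac, cs.length)
            state.add_chain(PolymerChain(np.array(path), species))
    empties = state.empty_sites()
    if config.n_s5p > len(empties):
        raise CapacityError("not enough free sites for particles")
    idx = rng.choice(len(empties), size=config.n_s5p, replace=False)
    for i in np.sort(idx):
        y, x = empties[int(i)]
        state.add_particle(y, x)
    return state
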