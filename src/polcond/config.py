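"""Scenario configuration: kinetic coefficients, chain specs, serialization."""

from __future__ import annotations

import math
from dataclasses import dataclass, field, asdict
from pathlib import Path

import yaml

from .lattice import AffinityMatrix

__all__ = ["KineticParams", "ChainSpec", "ScenarioConfig"]


@dataclass(frozen=True)
class KineticParams:
    """Rate coefficients (per unit time) for the elementary moves.

    ``k_p`` scales particle hops, ``k_kink`` single-monomer chain moves
    (end flip and kink jump), and ``k_crank`` the two-monomer crankshaft.
    The crankshaft coefficient is k_kink * log(4/3); the logarithm is natural
    by default (``crank_log_base='e'``), base-10 selectable.
    """

    k_p: float = 0.1
    k_kink: float = 0.1
    crank_log_base: str = "e"

    @property
    def k_crank(self) -> float:
        if self.crank_log_base == "e":
            return self.k_kink * math.log(4.0 / 3.0)
        if self.crank_log_base == "10":
            return self.k_kink * math.log10(4.0 / 3.0)
        raise ValueError(f"unknown crank_log_base {self.crank_log_base!r}")

    def __post_init__(self) -> None:
        if self.k_p <= 0 or self.k_kink <= 0:
            raise ValueError("rate coefficients must be positive")


@dataclass(frozen=True)
class ChainSpec:
    """Composition of one chain: monomer counts per chromatin state."""

    n_rc: int = 0
    n_ac: int = 0
    length: int = 20

    @property
    def n_ic(self) -> int:
        return self.length - self.n_rc - self.n_ac

    def __post_init__(self) -> None:
        if self.n_rc < 0 or self.n_ac < 0 or self.n_ic < 0:
            raise ValueError("chain species counts must be non-negative "
                             "and sum to at most the chain length")


@dataclass
class ScenarioConfig:
    """Complete description of one simulation run."""

    width: int = 25
    height: int = 25
    n_s5p: int = 100
    chains: list[ChainSpec] = field(default_factory=list)
    layout: str = "single"
    affinity: AffinityMatrix = field(default_factory=AffinityMatrix)
    kinetics: KineticParams = field(default_factory=KineticParams)
    n_steps: int = 10_000_000
    burn_in: int | None = None          # default: 10% of n_steps
    sample_every: int = 10_000
    seed: int = 0
    energy_neighborhood: str = "moore"

    def __post_init__(self) -> None:
        if self.width <= 0 or self.height <= 0:
            raise ValueError("lattice dimensions must be positive")
        if self.n_s5p < 0:
            raise ValueError("particle count must be non-negative")
        if self.n_steps < 0:
            raise ValueError("step count must be non-negative")
        if self.burn_in is not None and self.n_steps < self.burn_in:
            raise ValueError("n_steps must be at least burn_in")

    @property
    def effective_burn_in(self) -> int:
        return self.n_steps // 10 if self.burn_in is None else self.burn_in

    @property
    def bulk_concentration(self) -> float:
        return self.n_s5p / (self.width * self.height)

    # -- serialization ----------------------------------------------------
    def to_dict(self) -> dict:
        return {
            "width": self.width,
            "height": self.height,
            "n_s5p": self.n_s5p,
            "chains": [{"n_rc": c.n_rc, "n_ac": c.n_ac, "length": c.length}
                       for c in self.chains],
            "layout": self.layout,
            "affinity": self.affinity.to_dict(),
            "kinetics": {"k_p": self.kinetics.k_p,
                         "k_kink": self.kinetics.k_kink,
                         "crank_log_base": self.kinetics.crank_log_base},
            "n_steps": self.n_steps,
            "burn_in": self.burn_in,
            "sample_every": self.sample_every,
            "seed": self.seed,
            "energy_neighborhood": self.energy_neighborhood,
        }

    @classmethod
    def from_dict(cls, d: dict) -> "ScenarioConfig":
        d = dict(d)
        chains = [ChainSpec(**c) for c in d.pop("chains", [])]
        affinity = AffinityMatrix.from_dict(d.pop("affinity", {}))
        kinetics = KineticParams(**d.pop("kinetics", {}))
        return cls(chains=chains, affinity=affinity, kinetics=kinetics, **d)

    def to_yaml(self, path: str | Path) -> None:
        Path(path).write_text(yaml.safe_dump(self.to_dict(), sort_keys=False))

    @classmethod
    def from_yaml(cls, path: str | Path) -> "ScenarioConfig":
        return cls.from_dict(yaml.safe_load(Path(path).read_text()))

    def replace(self, **changes) -> "ScenarioConfig":
        d = {
            "width": self.width, "height": self.height, "n_s5p": self.n_s5p,
            "chains": list(self.chains), "layout": self.layout,
            "affinity": self.affinity, "kinetics": self.kinetics,
            "n_steps": self.n_steps, "burn_in": self.burn_in,
            "sample_every": self.sample_every, "seed": self.seed,
            "energy_neighborhood": self.energy_neighborhood,
        }
        d.update(changes)
        return ScenarioConfig(**d)
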