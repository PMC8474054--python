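"""Trajectory generation: seeded runs, ergodic sampling, trajectory I/O."""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from . import reference
from .config import ScenarioConfig
from .engine import KernelState
from .lattice import LatticeState, PolymerChain, initialize_state

__all__ = ["TrajectorySample", "Trajectory", "run_simulation",
           "save_trajectory", "load_trajectory"]


@dataclass
class TrajectorySample:
    """One recorded snapshot: simulated time, iteration index, lattice state."""

    t: float
    step: int
    state: LatticeState


@dataclass
class Trajectory:
    config: ScenarioConfig
    samples: list[TrajectorySample] = field(default_factory=list)
    jammed: bool = False
    final_state: LatticeState | None = None
    dwell: np.ndarray | None = None    # time-weighted occupancy histogram

    @property
    def times(self) -> np.ndarray:
        return np.array([s.t for s in self.samples])


def run_simulation(
    config: ScenarioConfig,
    engine: str = "fast",
    record_dwell: bool = False,
) -> Trajectory:
    """Run a full seeded simulation: select -> apply -> local update -> clock.

    Snapshots are recorded after the burn-in at the configured sampling
    interval (ergodic sampling). Trajectories are bit-identical across runs
    with the same seed and engine; the ``fast`` (compiled) and ``reference``
    engines consume the same uniform stream and agree transition-for-
    transition.

    ``record_dwell`` accumulates the time-weighted occupancy histogram over
    particle bitmask configurations (particle-only lattices of at most 24
    sites), which is how equilibrium sampling is validated.
    """
    rng = np.random.default_rng(config.seed)
    state = initialize_state(config, rng)
    traj = Trajectory(config=config)
    burn_in = config.effective_burn_in
    chunk = max(1, int(config.sample_every))
    n_steps = int(config.n_steps)

    if engine == "fast":
        kern = KernelState(state, config.affinity, config.kinetics,
                           config.energy_neighborhood,
                           record_dwell=record_dwell)
        done = 0
        while done < n_steps:
            take = min(chunk, n_steps - done)
            draws = rng.random((take, 2))
            jammed = kern.run(take, draws)
            done = kern.step
            if jammed:
                traj.jammed = True
                break
            if done >= burn_in:
                traj.samples.append(
                    TrajectorySample(kern.time, done, kern.snapshot()))
        traj.final_state = kern.snapshot()
        if record_dwell:
            traj.dwell = kern.dwell.copy()
    elif engine == "reference":
        catalog = None
        t_now = 0.0
        done = 0
        while done < n_steps:
            take = min(chunk, n_steps - done)
            draws = rng.random((take, 2))
            try:
                dt, catalog, _ = reference.run_steps(
                    state, config.affinity, config.kinetics, draws,
                    config.energy_neighborhood, catalog=catalog)
            except reference.JammedSystemError:
                traj.jammed = True
                break
            t_now += dt
            done += take
            if done >= burn_in:
                traj.samples.append(
                    TrajectorySample(t_now, done, state.copy()))
        traj.final_state = state.copy()
    else:
        raise ValueError(f"unknown engine {engine!r}")
    return traj


# -- persistence ----------------------------------------------------------

def save_trajectory(traj: Trajectory, outdir: str | Path) -> Path:
    """Write snapshots (integer label grids) plus a JSON provenance sidecar."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    grids = np.stack([s.state.grid for s in traj.samples]) \
        if traj.samples else np.zeros((0, traj.config.height,
                                       traj.config.width), dtype=np.int64)
    np.save(outdir / "snapshots.npy", grids)
    chains_meta = []
    for s in traj.samples:
        chains_meta.append([
            {"coords": c.coords.tolist(), "species": c.species.tolist()}
            for c in s.state.chains
        ])
    meta = {
        "config": traj.config.to_dict(),
        "times": [s.t for s in traj.samples],
        "steps": [s.step for s in traj.samples],
        "chains": chains_meta,
        "jammed": traj.jammed,
    }
    (outdir / "trajectory.json").write_text(json.dumps(meta))
    return outdir


def load_trajectory(outdir: str | Path) -> Trajectory:
    outdir = Path(outdir)
    meta = json.loads((outdir / "trajectory.json").read_text())
    config = ScenarioConfig.from_dict(meta["config"])
    grids = np.load(outdir / "snapshots.npy")
    traj = Trajectory(config=config, jammed=meta["jammed"])
    for t, step, grid, chains in zip(meta["times"], meta["steps"], grids,
                                     meta["chains"]):
        state = LatticeState(config.width, config.height)
        state.grid = np.asarray(grid, dtype=np.int64)
        for cid, c in enumerate(chains):
            chain = PolymerChain(np.asarray(c["coords"]),
                                 np.asarray(c["species"]))
            state.chains.append(chain)
            for i, (y, x) in enumerate(chain.coords):
                state.chain_id[y, x] = cid
                state.mono_ix[y, x] = i
        traj.samples.append(TrajectorySample(float(t), int(step), state))
    if traj.samples:
        traj.final_state = traj.samples[-1].state
    return traj
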