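"""Preset experiment configurations and phase-behavior scans.

Presets reproduce the published simulation conditions: the single-chain
baseline, long-time behavior on a 30x30 lattice, cluster merging with four
chains, the hexanediol variant with weakened interactions, randomized chain
compositions, the transcription-inhibitor variants (flavopiridol removes
active gene bodies; triptolide additionally weakens recruitment and raises
the particle count), and the binding-only appendix variants. ``phase_scan``
sweeps bulk particle concentration against self-affinity with and without a
polymer surface to separate canonical liquid-liquid phase separation from
surface condensation.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from .config import ChainSpec, KineticParams, ScenarioConfig
from .lattice import AffinityMatrix
from .morphology import phase_concentrations, segment_clusters
from .render import RenderParams, render_channel
from .simulate import run_simulation

__all__ = ["SCENARIO_NAMES", "make_scenario", "random_chain_composition",
           "phase_scan"]

RC_LENGTH_CHOICES = (0, 2, 4, 6, 8)
AC_LENGTH_CHOICES = (0, 3, 6)

SCENARIO_NAMES = (
    "baseline_fig5b", "longtime_fig5d", "merging_fig5e", "hexanediol_fig5f",
    "hexanediol_control", "randomized_fig6", "control_fig7",
    "flavopiridol_fig7", "triptolide_fig7", "llps_scan", "binding_only",
    "binding_only_strong", "phase_scan",
)


def random_chain_composition(rng: np.random.Generator) -> tuple[int, int]:
    """Draw (N_RC, N_AC) independently and uniformly from the preset sets."""
    n_rc = int(rng.choice(RC_LENGTH_CHOICES))
    n_ac = int(rng.choice(AC_LENGTH_CHOICES))
    return n_rc, n_ac


def _random_chains(rng: np.random.Generator, n_chains: int,
                   no_gray: bool = False) -> list[ChainSpec]:
    chains = []
    for _ in range(n_chains):
        n_rc, n_ac = random_chain_composition(rng)
        chains.append(ChainSpec(n_rc=n_rc, n_ac=0 if no_gray else n_ac))
    return chains


def make_scenario(name: str, seed: int = 0,
                  triptolide_literal_rc_rc: bool = False) -> ScenarioConfig:
    """Build the full configuration of a named preset.

    ``seed`` drives both the composition draws of randomized presets and the
    simulation itself. The triptolide preset reduces the particle-RC
    affinity by default; ``triptolide_literal_rc_rc`` instead applies the
    reduction to the RC-RC pair.
    """
    rng = np.random.default_rng(seed)
    if name == "baseline_fig5b":
        return ScenarioConfig(
            chains=[ChainSpec(n_rc=8, n_ac=0)], layout="single",
            n_steps=1_000_000, seed=seed)
    if name == "longtime_fig5d":
        return ScenarioConfig(
            width=30, height=30, n_s5p=140,
            chains=_random_chains(rng, 9), layout="parallel",
            n_steps=10_000_000, seed=seed)
    if name == "merging_fig5e":
        return ScenarioConfig(
            chains=[ChainSpec(n_rc=8, n_ac=0)] * 4, layout="four_parallel",
            n_steps=1_000_000, seed=seed)
    if name == "hexanediol_fig5f":
        return ScenarioConfig(
            chains=[ChainSpec(n_rc=8, n_ac=6)] * 3, layout="parallel",
            affinity=AffinityMatrix.from_updates(s5p_s5p=-0.15, rc_s5p=-0.25),
            n_steps=1_000_000, seed=seed)
    if name == "hexanediol_control":
        return ScenarioConfig(
            chains=[ChainSpec(n_rc=8, n_ac=6)] * 3, layout="parallel",
            n_steps=1_000_000, seed=seed)
    if name in ("randomized_fig6", "control_fig7"):
        return ScenarioConfig(
            chains=_random_chains(rng, 4), layout="cross_of_four",
            n_steps=1_000_000, seed=seed)
    if name == "flavopiridol_fig7":
        # pause-release inhibition: no active gene bodies are assigned
        return ScenarioConfig(
            chains=_random_chains(rng, 4, no_gray=True),
            layout="cross_of_four", n_steps=1_000_000, seed=seed)
    if name == "triptolide_fig7":
        # recruitment inhibition: no active regions, weakened self- and
        # RC-affinity, particle count raised from 100 to 120
        if triptolide_literal_rc_rc:
            aff = AffinityMatrix.from_updates(s5p_s5p=-0.25, rc_rc=-0.25)
        else:
            aff = AffinityMatrix.from_updates(s5p_s5p=-0.25, rc_s5p=-0.25)
        return ScenarioConfig(
            n_s5p=120, chains=_random_chains(rng, 4, no_gray=True),
            layout="cross_of_four", affinity=aff,
            n_steps=1_000_000, seed=seed)
    if name in ("llps_scan", "phase_scan"):
        return ScenarioConfig(chains=[], n_steps=300_000, seed=seed)
    if name == "binding_only":
        return ScenarioConfig(
            chains=[ChainSpec(n_rc=8, n_ac=0)], layout="single",
            affinity=AffinityMatrix.from_updates(s5p_s5p=0.0),
            n_steps=1_000_000, seed=seed)
    if name == "binding_only_strong":
        return ScenarioConfig(
            chains=[ChainSpec(n_rc=8, n_ac=0)], layout="single",
            affinity=AffinityMatrix.from_updates(s5p_s5p=0.0, rc_s5p=-5.0),
            n_steps=1_000_000, seed=seed)
    raise ValueError(
        f"unknown scenario {name!r}; valid names: {', '.join(SCENARIO_NAMES)}")


def phase_scan(
    bulk_values,
    w_values,
    with_polymer: bool = False,
    reps: int = 3,
    seed: int = 0,
    n_steps: int = 300_000,
    width: int = 25,
    height: int = 25,
    w_rc_s5p: float = -0.5,
    persistence_fraction: float = 0.5,
) -> pd.DataFrame:
    """Dilute/dense concentration scan over (bulk concentration, affinity).

    For every grid cell, replicate simulations are run, the dense phase is
    segmented on rendered Ser5P images, and the mean particle occupancy
    inside (dense) and outside (dilute) the segmented footprint is recorded.
    A dense phase counts as detected when a segmented object (area >= 10 px
    by segmentation) is present in at least ``persistence_fraction`` of the
    post-burn-in samples AND the largest object persists in place: its mask
    overlaps the previous sample's largest mask in at least that fraction of
    consecutive sample pairs. A standing droplet barely moves between
    samples, while super-threshold density fluctuations of a homogeneous
    (supercritical) gas decorrelate completely between samples, so the
    overlap requirement separates true coexistence from gas fluctuations.
    One row per (bulk, w, rep).
    """
    rows = []
    seed_rng = np.random.default_rng(seed)
    params = RenderParams()
    for w in w_values:
        for bulk in bulk_values:
            n_particles = int(round(bulk * width * height))
            for rep in range(reps):
                run_seed = int(seed_rng.integers(2**31 - 1))
                chains = [ChainSpec(n_rc=8, n_ac=0)] if with_polymer else []
                cfg = ScenarioConfig(
                    width=width, height=height, n_s5p=n_particles,
                    chains=chains, layout="single",
                    affinity=AffinityMatrix.from_updates(
                        s5p_s5p=w, rc_s5p=w_rc_s5p),
                    n_steps=n_steps, sample_every=max(1, n_steps // 20),
                    seed=run_seed)
                dilutes, denses, largest = [], [], []
                if n_particles > 0:
                    traj = run_simulation(cfg)
                    render_rng = np.random.default_rng(run_seed + 1)
                    for s in traj.samples:
                        ser5p = render_channel(s.state, "ser5p", params,
                                               render_rng)
                        masks = segment_clusters(ser5p)
                        dilute, dense = phase_concentrations(s.state, masks)
                        dilutes.append(dilute)
                        if masks:
                            areas = [int(m.sum()) for m in masks]
                            largest.append(masks[int(np.argmax(areas))])
                            denses.append(dense)
                        else:
                            largest.append(None)
                n_samples = max(1, len(largest))
                hits = sum(m is not None for m in largest)
                overlaps = [
                    bool((m1 & m2).any())
                    for m1, m2 in zip(largest[:-1], largest[1:])
                    if m1 is not None and m2 is not None
                ]
                presence = hits / n_samples
                overlap_frac = (np.mean(overlaps) * len(overlaps)
                                / max(1, n_samples - 1)) if overlaps else 0.0
                detected = (presence >= persistence_fraction
                            and overlap_frac >= persistence_fraction)
                rows.append({
                    "bulk": bulk, "w_s5p_s5p": w,
                    "with_polymer": with_polymer, "rep": rep,
                    "dilute": float(np.mean(dilutes)) if dilutes else 0.0,
                    "dense": float(np.mean(denses)) if denses else np.nan,
                    "presence_frac": float(presence),
                    "overlap_frac": float(overlap_frac),
                    "dense_detected": bool(detected),
                    "seed": run_seed,
                })
    return pd.DataFrame(rows)
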