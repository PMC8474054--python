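"""Trajectory-level analysis: rendering + quantification pipelines.

Bridges the simulator and the morphometry operators: every recorded snapshot
is rendered to a synthetic micrograph, clusters are segmented on the Ser5P
channel, and per-cluster descriptors are pooled into one table per
trajectory (with the sample index kept, so per-image summaries such as
cluster counts remain available).
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from .lattice import MOORE_OFFSETS, LatticeState, Species
from .morphology import (
    normalize_records,
    quantify_clusters,
    records_to_frame,
    segment_clusters,
)
from .render import RenderParams, render_image
from .simulate import Trajectory

__all__ = ["quantify_trajectory", "largest_cluster_stats",
           "rc_coating_fraction"]


def quantify_trajectory(
    traj: Trajectory,
    rng: np.random.Generator | None = None,
    params: RenderParams = RenderParams(),
    threshold: float = 0.35,
    normalize: bool = False,
) -> pd.DataFrame:
    """Render and quantify every snapshot; one row per cluster.

    ``normalize`` rescales intensities by the pooled population median
    across the whole trajectory (not per image). The returned frame carries
    a ``sample`` column so per-image counts can be recovered; samples
    without clusters contribute no rows.
    """
    all_records = []
    sample_col = []
    for k, s in enumerate(traj.samples):
        image = render_image(s.state, params, rng)
        masks = segment_clusters(image.ser5p, threshold=threshold)
        recs = quantify_clusters(image, s.state, masks, normalize=False)
        all_records.extend(recs)
        sample_col.extend([k] * len(recs))
    if normalize and all_records:
        all_records = normalize_records(all_records)
    frame = records_to_frame(all_records)
    frame["sample"] = sample_col
    return frame


def largest_cluster_stats(
    traj: Trajectory,
    rng: np.random.Generator | None = None,
    params: RenderParams = RenderParams(),
) -> pd.DataFrame:
    """Per-sample area and RC overlap of the largest segmented cluster."""
    rows = []
    for k, s in enumerate(traj.samples):
        image = render_image(s.state, params, rng)
        masks = segment_clusters(image.ser5p)
        if masks:
            areas = [int(m.sum()) for m in masks]
            imax = int(np.argmax(areas))
            rc_mask = s.state.species_mask(Species.RC)
            rows.append({"sample": k, "area": areas[imax],
                         "n_clusters": len(masks),
                         "rc_overlap": int(rc_mask[masks[imax]].sum())})
        else:
            rows.append({"sample": k, "area": 0, "n_clusters": 0,
                         "rc_overlap": 0})
    return pd.DataFrame(rows)


def rc_coating_fraction(state: LatticeState) -> float:
    """Fraction of RC monomers with at least one Moore-adjacent particle."""
    rc_sites = np.argwhere(state.species_mask(Species.RC))
    if len(rc_sites) == 0:
        return float("nan")
    coated = 0
    for y, x in rc_sites:
        for dy, dx in MOORE_OFFSETS:
            ny, nx = y + dy, x + dx
            if state.in_bounds(ny, nx) and state.grid[ny, nx] == Species.S5P:
                coated += 1
                break
    return coated / len(rc_sites)
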