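"""polcond: lattice kinetic Monte Carlo of Pol II surface condensation.

A simulator and analysis toolkit for the formation of RNA polymerase II
clusters by condensation of a particle liquid on polymer (chromatin)
surfaces: rejection-free lattice KMC with a Verdier-Stockmayer chain move
set, synthetic microscopy rendering, cluster morphometry with type i-iii
gating, phase-behavior diagnostics, and resampling statistics.
"""

from .config import ChainSpec, KineticParams, ScenarioConfig
from .lattice import (
    AffinityMatrix,
    LatticeState,
    PolymerChain,
    Species,
    delta_energy,
    initialize_state,
    pair_energy,
    total_energy,
)
from .render import RenderParams, SyntheticImage, render_channel, render_image
from .resampling import bonferroni_adjust, bootstrap_ci, permutation_test
from .scenarios import make_scenario, phase_scan, random_chain_composition
from .simulate import Trajectory, TrajectorySample, run_simulation

__version__ = "0.1.0"

LATTICE_CONSTANT_NM = 65.0   # one lattice site edge, instant-SIM pixel size


def lattice_area_um2(n_sites: float, lattice_constant_nm: float = LATTICE_CONSTANT_NM) -> float:
    """Physical area of ``n_sites`` lattice cells in square micrometers."""
    return n_sites * (lattice_constant_nm / 1000.0) ** 2
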