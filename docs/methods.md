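# Model and methods

## The lattice model

`polcond` simulates the formation of RNA polymerase II (Pol II) clusters as
condensation of a particle liquid on polymer surfaces. The world is a 2-D
square lattice (default 25×25) with hard-wall boundaries and single
occupancy. Two kinds of entities live on it:

- **Mobile particles (S5P)** representing the Pol II Ser5P–rich material
  that forms clusters. Default count N_S5P = 100.
- **Self-avoiding polymer chains** representing chromatin, with axis-aligned
  unit bonds and per-monomer states: regulatory chromatin (**RC**,
  particle-attracting; the condensation surface), inactive chromatin
  (**IC**, self-attracting), and active/elongating chromatin (**AC**,
  particle-repelling). Default chain length L = 20, with contiguous blocks
  in the order RC, AC, IC.

Energies are pairwise contact energies in units of kBT between entities in
each other's interaction neighborhood. The neighborhood is the Moore
8-neighborhood by default, matching the 8-direction particle move set; a
von Neumann (4-site) energy shell is selectable. Defaults:

| pair        | w (kBT) | meaning                               |
|-------------|---------|---------------------------------------|
| S5P–S5P     | −0.35   | liquid cohesion (self-affinity)        |
| RC–S5P      | −0.5    | recruitment to regulatory chromatin    |
| IC–IC       | −0.5    | heterochromatin-like self-attraction   |
| AC–S5P      | +0.5    | exclusion from elongating gene bodies  |

All other pairs are 0 and fully configurable. The AC–S5P repulsion
magnitude is the one value not fixed numerically by the source material
(only its sign); +0.5 is this package's default and everything downstream
treats it as configurable.

## Dynamics: rejection-free kinetic Monte Carlo

Each iteration enumerates every possible elementary move in a rate catalog:
particle hops to any of the 8 empty Moore neighbors, and the
Verdier–Stockmayer chain moves — end-bond flip (end monomer rotates 90°
about its bonded neighbor; the straight-through 180° position is excluded),
kink jump (a corner monomer moves to the opposite side of its corner), and
crankshaft (the two middle monomers of a U-shaped quadruple reflect across
the line through its endpoints). Rates follow the Arrhenius form

    k = k_coeff · exp(−(E2 − E1)),

with E2 − E1 the total contact-energy change of the move. Coefficients:
k_p = 0.1 (particles), k_kink = 0.1 (end flip and kink jump), and
k_crank = k_kink·ln(4/3) ≈ 0.0288 for the two-monomer crankshaft. The
logarithm is natural by default (base-10 selectable by configuration).

One step selects a transition by tower sampling (r1·k_total against the
running cumulative rate, with the boundary resolved by the ≤ rule), applies
it, advances the clock by Δt = −ln(r2)/k_total (exponential waiting time),
and refreshes the catalog locally. Per iteration exactly two uniforms are
consumed in the fixed order (selection, time), which makes trajectories
bit-reproducible for a given seed.

Because forward and backward rates of every move satisfy
k_f/k_b = e^(−2ΔE), the stationary distribution is π ∝ exp(−2E): the
dynamics effectively sample the contact Hamiltonian at twice the nominal
coupling. This is a property of the published rate rule, and all phase
behavior below should be read with the effective couplings (e.g. the
−0.35 self-affinity acts like −0.7 per contact). The test suite verifies
equilibrium sampling directly on a fully enumerable system (3×3 lattice,
two particles, all 36 configurations; total-variation distance < 0.02
against exp(−2E)).

Chain bonds never change their adjacency under this move set (an end stays
at unit distance from its pivot; a kink stays bonded to both neighbors; the
crankshaft's reflection preserves all distances within the moved quadruple),
so bonded-pair contact energies are constants of motion and ΔE is identical
whether or not they are included in the Hamiltonian. The implementation
includes them; a test verifies the equivalence.

### Local catalog update

Only transitions near the moved entities can change. The reference
implementation refreshes the published window of [x±4, y±4] around every
site whose occupancy changed; the compiled kernel uses the tightest window
that is provably identical to a full rebuild (Chebyshev radius 3 with
chains, 2 for particle-only systems: targets reach at most 2 sites, plus a
1-site energy shell), rebuilding per-entity subtotals exactly and re-summing
the total rate every 1e5 steps to bound floating-point drift. Tests compare
the locally updated catalog against a full rebuild after every step of long
randomized runs, and the two engines — pure-Python reference and numba
kernel — are cross-checked for bit-identical trajectories on a shared
uniform stream.

## Initialization and scenarios

Chains are placed first according to a layout — `single`, `parallel` /
`four_parallel` (evenly spaced rows, folding at walls), `cross_of_four`
(four arms radiating from the lattice center), or `random_walks` — and
particles are then scattered uniformly over the remaining empty sites.
Scenario presets encode the published simulation conditions: the
single-chain baseline (N_RC = 8, N_IC = 12), long-time behavior (30×30,
N_S5P = 140, nine chains, 1e7 steps), the hexanediol variant (three chains
with N_RC = 8, N_AC = 6; w_S5P-S5P = −0.15, w_RC-S5P = −0.25), randomized
compositions (four chains, N_RC uniform on {0,2,4,6,8}, N_AC uniform on
{0,3,6}), flavopiridol (no AC regions assigned), triptolide (no AC,
w_S5P-S5P = −0.25, particle–RC affinity −0.25, N_S5P raised to 120; a
literal RC–RC interpretation of the printed symbol is selectable), and the
binding-only variants (no self-affinity; the strong variant raises the
particle–RC affinity tenfold to −5.0).

The four-chain randomized scenarios default to the `cross_of_four` layout.
This was a deliberate choice among the published initial configurations:
with straight parallel chains all RC blocks align in the same columns, so
RC-rich clusters are elongated multi-chain bridges and the correlation
between regulatory-chromatin content and solidity inverts; with the cross
layout the RC blocks meet at the center and both reported correlation signs
(RC vs area, and RC vs solidity among large clusters) reproduce.

Defaults for trajectory sampling: burn-in = 10% of the step count,
snapshots every 1e4 iterations (ergodic sampling). Both are configuration
fields; analyses in this package state the values they use.

## Synthetic microscopy and morphometry

Snapshots are rendered to three channels (Ser5P from particles, Ser2P from
AC monomers, RC from RC monomers): binary occupancy → normalized Gaussian
blur (σ = 1 px, truncated at 4σ, zero padding outside the lattice; the dark
background outside the simulated region motivates zero padding, and reflect
mode is selectable) → per-pixel Poisson(λ = 5) noise divided by 100, drawn
independently per channel. One lattice site corresponds to one image pixel
at 65 nm, so 100 lattice sites ≈ 0.43 µm².

Clusters are segmented on the Ser5P channel at threshold 0.35 with
8-connected components, discarding objects under 10 px. Per cluster the
package reports area, solidity (pixel count over the rasterized filled
convex hull of pixel centers, boundary pixels counting as inside; collinear
sets have solidity 1), centroid, mean channel intensities inside the Ser5P
mask scaled by the population median, and the number of RC monomers under
the mask.

Morphology types are gated on (area, solidity): type i small
(area < 50 px), type ii large and compact, type iii large and unfolded.
The default `GateSpec` uses solidity cuts 0.8/0.6. The published gates are
hand-drawn polygons around the observed population, and under this model's
blur and threshold the large-cluster solidity distribution is concentrated
near 0.7–1.0, so fixed extreme cuts can leave gates nearly empty. Analyses
that need population extremes therefore derive cuts from the large-cluster
solidity quartiles (`gates_from_population`), which isolates "extreme
examples" of whatever population is analyzed; the 50 px size cut is always
kept.

Generic operators for real micrographs: Otsu thresholding (256-bin
inter-class variance), robust background thresholding (5% two-sided trim,
then trimmed mean + k·SD; trim fraction configurable), Gaussian background
subtraction (raster minus its σ-blur, clipped at zero), and surface-distance
enrichment profiles (Euclidean distance to the nearest reference-mask
boundary pixel, histogram of target pixels divided bin-wise by the
all-nucleus histogram and scaled by its own mean; a centroid-distance mode
would be the natural alternative for spot-like references).

## Phase-behavior diagnostics

`phase_scan` sweeps bulk particle concentration φ = N/(W·H) against
self-affinity, with and without a single chain carrying an 8-monomer RC
block. Per cell it runs replicate simulations, segments the rendered Ser5P
channel, and reports the particle occupancy outside (dilute) and inside
(dense) the segmented footprint. A dense phase counts as detected when a
segmented object is present in ≥ 50% of post-burn-in samples **and** the
largest object persists in place (its mask overlaps the previous sample's
in ≥ 50% of consecutive pairs). The second condition is essential: a
homogeneous near-critical gas produces super-threshold density fluctuations
of ≥ 10 px in most samples, but they decorrelate completely between samples
(1e4 steps apart a free particle has diffused across the lattice), whereas
a standing droplet barely moves. Presence alone misclassifies the
supercritical gas as phase-separated.

The diagnostics separate the two condensation modes: without polymer, a
dense phase appears only above a saturation concentration, the dilute
branch is approximately flat across the coexistence interval, and the
interval widens as the self-affinity strengthens; with polymer, dense
clusters appear at sub-saturated bulk concentrations and the dilute
concentration keeps rising with bulk while the dense phase is present — the
surface-condensation signature. Flatness regressions exclude the onset
(boundary) cell of the interval, where the droplet is smallest and
finite-size/curvature (Gibbs–Thomson) corrections on a 25×25 lattice are
largest.

## Resampling statistics

Two-sample comparisons use a two-tailed permutation test with the add-one
convention p = (1 + #{|T*| ≥ |T|})/(1 + R), so p never reaches 0 and at
R = 10,000 the resolution is 1e-4. Exhaustive enumeration replaces Monte
Carlo automatically when the number of distinct splits is ≤ 1e5 (the
p-value is then exact). The Monte Carlo two-tailed path permutes the sorted
pool into (smaller group, rest); since |mean_S − mean_Sc| is invariant
under complementation this is the same null and makes the p-value exactly
symmetric under label exchange. When observations share a sampling unit
(a nucleus, a simulation), aggregate per unit before testing. Confidence
intervals are percentile bootstrap (10,000 resamples, 95% default), with
BCa available. Bonferroni correction is a plain α/m. Calibration is
tested: type-I error within the binomial 99% CI of α = 0.05 over 2,000
null repetitions, and ~95% coverage of the true median over 1,000
repetitions.

## Problem sizes used in the test suite

The shipped analyses run at desk scale, chosen to give stable statistics:
equilibrium check at 1e6 steps on the enumerable system; surface
condensation at the published 10 seeds × 1e6 steps; phase scans at
6 bulk levels × 3 affinities × 3 replicates × 4e5 steps; morphology
populations from 30 randomized simulations of 6e5 steps; inhibitor
comparisons at 100 synthetic images per condition. The acceptance script
uses slightly smaller versions of the same computations.

## Known limitations

- The model is 2-D with hard walls; no hydrodynamics, no off-lattice or
  bead-spring polymers, no 3-D segmentation.
- The synthetic-data path emulates ideal microscopy (isotropic Gaussian
  PSF, Poisson detector noise, one z-plane, no bleaching or gain
  structure); passing tests say nothing about nucleus detection or
  aberrations in real embryo images.
- At the default self-affinity the particle gas is itself weakly
  supersaturated under π ∝ exp(−2E): on long runs a droplet eventually
  coarsens even without a polymer surface, so with/without-polymer
  contrasts at N_S5P = 100 are kinetic as much as thermodynamic, and the
  no-polymer largest cluster is not negligible at 1e6 steps.
- On a 25×25 lattice the dilute branch inside coexistence is only
  approximately constant: near the onset the droplet is small and the
  coexisting dilute concentration is elevated (Gibbs–Thomson), giving a
  small but real downward drift with bulk (~10% relative across the
  interval, versus slope 1 below saturation). With enough replication a
  zero-slope test will always reject; "flat" should be read as this
  approximate statement.
- Removing AC regions (the flavopiridol scenario) changes cluster counts
  and solidity only weakly at the default AC–S5P repulsion: repulsion
  pushes gray regions away from clusters, so they rarely touch. The
  triptolide and hexanediol perturbations reproduce their expected
  directions robustly.
- The morphology-type gates are operational definitions over this model's
  cluster population, not the published polygons, and per-gate counts are
  not comparable to the published ones.
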