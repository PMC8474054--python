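# polcond

Lattice kinetic Monte Carlo simulation and image-based morphometry of RNA
polymerase II cluster formation by **surface condensation on chromatin**.

In early embryos, recruited Pol II (Ser5-phosphorylated) forms nuclear
clusters with morphologies ranging from small dots to large compact blobs
to large unfolded shapes. `polcond` implements a minimal physical model of
this process for simulation studies: mobile particles (the Pol II
Ser5P-rich material) diffuse on a 2-D lattice among self-avoiding polymer
chains (chromatin) whose segments are regulatory (RC, particle-attracting),
inactive (IC, self-attracting), or actively transcribed (AC,
particle-repelling). Clusters arise as a particle liquid condensing on the
regulatory segments — a surface-condensation scenario distinct from bulk
liquid–liquid phase separation (LLPS). The package is aimed at
condensate-biophysics researchers who want a tested, seeded, reusable
implementation of the model, its synthetic-microscopy rendering, the
cluster morphometry (area/solidity gating into types i–iii), the
phase-behavior diagnostics, and the resampling statistics.

## The model in brief

Rejection-free (Gillespie-like) kinetic Monte Carlo on a single-occupancy
square lattice. Every possible elementary move — particle hops to the 8
Moore neighbors, and the Verdier–Stockmayer chain moves (end-bond flip,
kink jump, crankshaft) — enters a rate catalog with Arrhenius rates

    k = k_p · exp(−(E2 − E1)),      k_p = 0.1,  k_crank = k_kink·ln(4/3)

where E2 − E1 is the contact-energy change in kBT. Default affinities:
w(S5P,S5P) = −0.35, w(RC,S5P) = −0.5, w(IC,IC) = −0.5, w(AC,S5P) = +0.5.
Each step draws a transition by tower sampling, applies it, advances the
clock by an exponential waiting time Δt = −ln(r2)/k_total, and refreshes
the catalog locally. Forward/backward rates obey k_f/k_b = e^(−2ΔE), so the
chain samples π ∝ exp(−2E) — verified in the tests against exact
enumeration. Snapshots are rendered to synthetic micrographs (σ = 1 px
Gaussian blur + Poisson λ = 5 noise / 100), segmented at threshold 0.35
(8-connectivity, ≥ 10 px), and quantified per cluster (area, solidity,
median-scaled intensities, RC overlap). One lattice site is 65 nm, so 100
sites ≈ 0.43 µm². See `docs/methods.md` for the full account.

## Worked example

Simulate the single-chain baseline (25×25 lattice, 100 particles, one
20-mer chain with an 8-monomer regulatory block), render, and quantify:

```python
import numpy as np
from polcond import make_scenario, run_simulation, render_image
from polcond.morphology import segment_clusters, quantify_clusters

cfg = make_scenario("baseline_fig5b", seed=1)      # 1e6 KMC steps
traj = run_simulation(cfg)
rng = np.random.default_rng(501)

last = traj.samples[-1]
img = render_image(last.state, rng=rng)
masks = segment_clusters(img.ser5p)
for r in quantify_clusters(img, last.state, masks):
    print(f"cluster {r.id}: area={r.area} px, solidity={r.solidity:.2f}, "
          f"RC overlap={r.rc_overlap}")
```

Output:

```
cluster 0: area=82 px, solidity=0.86, RC overlap=8
cluster 1: area=22 px, solidity=1.00, RC overlap=0
```

One dominant cluster of 82 px (≈ 0.35 µm² at the 65 nm pixel mapping),
fairly compact (solidity 0.86), anchored on all 8 regulatory monomers of
the chain, plus one small free cluster (type i, no chromatin contact). Running the same configuration without the chain
(`cfg.replace(chains=[])`) leaves only smaller, wandering clusters — the
chain is the condensation surface. The same workflow is available from the
shell:

```bash
polcond simulate baseline_fig5b --seed 1 --out runs/baseline
polcond render runs/baseline --seed 501 --out runs/baseline_imgs
polcond quantify runs/baseline --seed 501 --out runs/baseline.csv
polcond gate runs/baseline.csv --out runs/baseline_gated.csv
```

Other subcommands: `phase-scan` (dilute/dense concentration scans),
`compare` (permutation test between two cluster tables), `fixtures`
(ground-truthed test images).

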