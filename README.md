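# poregate

Trajectory analysis for G protein-gated inwardly rectifying K⁺ (GIRK / Kir3)
channel simulations: gate geometry, ion-permeation counting, PIP₂ salt-bridge
statistics, helix bend and axis angles, typed interaction distances, and
correlation-network suboptimal-path analysis — plus a synthetic-trajectory
generator suite with exactly known ground truth, so every stage is testable
without molecular-dynamics data.

## Who this is for

Computational biophysicists analysing MD simulations of GIRK1/2 or GIRK1/4
heterotetramers (or similar two-gate K⁺ channels) who want the standard
collective variables that classify channel states as reusable, tested
library functions rather than one-off scripts.

## What it computes

- **Gate apertures.** The helix bundle crossing (HBC, four pore-lining Phe:
  GIRK1 F181 / GIRK2 F192) and the cytosolic G-loop (girdle Met, GIRK2
  M313/M319) are summarised per frame as the minimum sidechain heavy-atom
  distance across diagonal subunit pairs. Frames with aperture ≥ 5.7 Å — the
  minimal diameter that passes a partially solvated K⁺ ion — count as open.
- **Conduction events.** One event is a single ion traversing both gate
  planes in sequence, detected by a per-ion hysteresis state machine
  (ABOVE → IN_PORE → BELOW) that is robust to thermal recrossings, lateral
  exits and periodic-image jumps.
- **PIP₂ salt bridges.** A lysine NZ is engaged when within 4.0 Å of any
  PIP₂ phosphate atom (O11–O16, P2, P3). Normalized formation is the mean
  engaged fraction per candidate lysine; condition-vs-reference fold changes
  quantify activation (≈1.1–1.2×) or inhibition (≈0.8×).
- **Helix geometry.** TM2 bending about the conserved hinge glycine (GIRK1
  G169) as the angle at the pivot backbone centroid between vectors to the
  outer (G158–F162) and inner (A174–G178) turn centroids, with 180° =
  straight; TM1/slide-helix coupling as the angle between principal axes;
  backbone φ/ψ tracking with a rectangular Ramachandran classifier.
- **Interaction classes.** π–π (ring centroid, ≤ 4 Å), Van der Waals
  (≤ 3.0 Å, twice the smallest heavy-atom VdW radius), dipole/H-bond and
  charge–charge (≤ 4 Å), as per-frame series, histograms and engaged
  fractions.
- **Correlation networks.** The dynamic cross-correlation matrix over Cα
  motion, c_ij = ⟨Δr_i·Δr_j⟩ / √(⟨|Δr_i|²⟩⟨|Δr_j|²⟩), thresholded at
  |c_ij| ≥ 0.4 into a residue network with edge length −log|c_ij|; the k
  lowest-cost simple paths (default 250) between a source (GIRK1 F97 ligand
  site) and a sink (CD loop / PIP₂ site) via a deterministic Yen's
  algorithm, with per-edge path-usage counts.
- **Replicate statistics.** One-way ANOVA over per-replicate windowed gate
  distances and normal-approximation power sizing of the required replicate
  count.

## Worked example

Run a synthetic "activator-like" condition end to end (open pore under a
−0.06 V/nm field, programmed salt-bridge engagement 0.6 against an apo
reference of 0.5, TM2 bent to 165°):

```yaml
# activator.yaml
condition: activator-like
seed: 11
reference_normalized: 0.5
input:
  synthetic:
    pore: {n_ions: 20, n_frames: 2000}
    engagement: {prob: 0.6, n_frames: 5000, n_pairs: 3}
    helix: {bend_deg: 165.0, noise_sigma: 0.3, n_frames: 80}
```

```bash
poregate run --config activator.yaml --out out
```

prints

```json
{
  "condition": "activator-like",
  "fold_change": 1.200267,
  "mean_bend_deg": 164.868256,
  "mean_tm1_sh_deg": 45.0,
  "n_conductions": 91,
  "n_conductions_ground_truth": 91,
  "network": {
    "n_edges": 7,
    "n_nodes": 8,
    "n_paths": 1,
    "optimal_path_weight": 4.832987
  },
  "normalized_salt_bridge": 0.600133,
  "open_fraction": {
    "G-loop": 1.0,
    "HBC": 1.0
  }
}
```

Reading the numbers: both gates stay open (aperture ≥ 5.7 Å in every frame),
the conduction detector recovers exactly the 91 traversals the generator
programmed, the salt-bridge fold change recovers the programmed 0.6/0.5 =
1.2× increase, and the mean TM2 bend reproduces the programmed 165° within
the noise. Per-frame series land in `out/` as CSV next to `report.json`.

The same subcommands run on real data: `poregate gates|conduct|bridges|
contacts|bend|axes|rama|network` accept a PDB structure plus a DCD/XTC (or
plain-text fixture) trajectory; `poregate simulate` writes synthetic
fixtures with a ground-truth sidecar; `poregate stats` runs the replicate
ANOVA on a CSV of (condition, replicate, value).

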