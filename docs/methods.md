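# Methods

This note documents the models, conventions and numerical choices behind
`poregate`, in the order an analysis flows through the package. It states no
empirical result that the test suite or `scripts/acceptance.py` does not
itself compute.

## Coordinates, numbering and conventions

Coordinates are in ångströms, times in nanoseconds. The z axis is the
membrane normal with the extracellular side at +z, so a negative
membrane-normal electric field drives cations inward (+z → −z); the
transmembrane potential of a constant field is `field × thickness`
(0.06 V/nm across a 35 Å membrane ≈ 210 mV). Residues use canonical 1-based
UniProt numbering (GIRK1 P48549, GIRK2 P48542, GIRK4 P48544) with no
per-chain offsets. Chain→subunit assignment is user-supplied; the default is
alternating GIRK1/partner around the pore, since the physical arrangement of
a 2:2 heteromer is not fixed by sequence. Periodic imaging is minimum-image
on a per-frame orthorhombic box; fixture trajectories without a box header
disable imaging. All distance analyses use heavy atoms only unless a scope
explicitly includes hydrogens, because the packaged cutoffs refer to
heavy-atom centers.

The packaged role map records the functional residues the analyses address:
HBC gate Phe (GIRK1 F181, GIRK2 F192, and GIRK4 F187 by the conserved
hinge+12 register), G-loop girdle Met (GIRK2 M313/M319; catalogued for GIRK2
only — other subunits need explicit gate residues), hinge glycines
(G169/G180/G175), PIP₂ lysine triplets (K183/K188/K189, K194/K199/K200,
K189/K194/K195), the TM1 hydrophobic wire (F87/Y91/W95), pore-helix pair
(E141/F137), TM2 acid D173, pre-gate M180, slide-helix acids D70/D77,
CD-loop R230/H233, the G-loop trio R313/E315/K188, the ligand-site source
F97, and the segments TM1 (82–105), SH (67–76), PH (130–142) and the three
TM2 turns (158–162, 167–169, 174–178).

## Gate aperture and occlusion

A gate is four residues in ring order, paired diagonally (A–C, B–D). The
aperture is the per-frame minimum over the two diagonal pairs of the minimum
sidechain heavy-atom center-to-center distance. Diagonal pairing matches the
"diameter" reading of the 5.7 Å occlusion threshold — the minimal diameter
that still permits a partially solvated K⁺ ion — which is the default but
configurable. The open fraction is the fraction of windowed frames with
aperture ≥ threshold. Glycine (no sidechain heavy atoms) is rejected as a
gate residue with an explicit error.

## Conduction detection

Each ion runs a three-state hysteresis machine against two gate planes
(z_HBC > z_Gloop): ABOVE requires z > z_HBC + δ; entry into the pore
requires crossing below z_HBC while within `pore_radius` of the pore axis;
an inward event is emitted on reaching z < z_Gloop − δ; the mirror sequence
emits an outward event. Leaving the pore laterally or returning above resets
the machine. Defaults δ = 2 Å and pore_radius = 10 Å are larger than thermal
jitter and smaller than the inter-gate spacing; both are exposed. Gate
planes may be given directly or derived from the gate residues' Cα z
centroid (static, or per-frame to track drift).

Periodic images: a z jump larger than half the box between consecutive
frames is treated as an image jump (e.g. an ion recycled from the
intracellular floor back to the reservoir). The machine resets to the region
of the re-entry position and never emits an event across a jump. This
wrap-aware reset replaces naive unwrapping, which would let a recycled ion's
unwrapped coordinate descend forever and miss later traversals.

## Salt bridges, contacts and typed distances

A basic atom (lysine NZ) is engaged when its minimum-image distance to any
acceptor atom (PIP₂ phosphate names O11–O16, P2, P3) is ≤ 4.0 Å — the
standard salt-bridge criterion, config-exposed. Normalized formation is
defined here as the mean per-frame engaged count divided by the number of
candidate lysines: a bounded [0, 1] quantity whose condition/reference ratio
gives the reported fold change. (Alternative normalizations — per frame, per
pair, or against an apo baseline — are not distinguishable from the headline
fold-change numbers alone; this choice makes the quantity bounded and the
fold changes reproducible.)

Inter-segment contact totals count unordered heavy-atom pairs within 4.0 Å
per frame, summed over the frame, between two disjoint selections (e.g. TM1
vs TM2). Typed pair distances use one rule per class: π–π is six-membered
ring centroid to ring centroid (His uses its five-membered ring — one
unambiguous centroid per residue), all other classes are the minimum
sidechain heavy-atom distance. Cutoffs: π–π 4.0 Å, VdW 3.0 Å (twice the
smallest C/N/O VdW radius of 1.5 Å), dipole/H-bond and charge–charge 4.0 Å.
Histograms default to 0.25 Å bins over [0, 12] Å.

## Helix geometry

The TM2 bend angle is measured at the pivot-segment backbone centroid
between vectors to the outer-turn and inner-turn centroids; 180° is
straight. Centroids are unweighted backbone-atom (N, CA, C, O) means — mass
weighting changes these atoms' centroid negligibly and a flag provides it.
The TM1/slide-helix angle uses each segment's principal direction (largest
variance of backbone atoms), oriented N→C so frames are comparable, folded
to [0, 180); a first-to-last vector method is available as a flag since the
axis construction admits more than one reading. φ/ψ are the standard
C(i−1)–N–CA–C and N–CA–C–N(i+1) torsions (praxeolitic atan2 form).

Ramachandran classification uses fixed rectangles so the classifier is
deterministic and testable: favored α (φ ∈ [−100, −30], ψ ∈ [−67, −7]) and
β (φ ∈ [−180, −100], ψ ∈ [90, 180]); allowed is a 20° dilation of each plus
the left-handed box (φ ∈ [40, 80], ψ ∈ [20, 80]); anything else is an
outlier. These are coarse boxes, not a probability-density classifier; they
are meant for tracking hinge-residue shifts of ≥ 20°, not for validation
scoring.

## Correlation networks and suboptimal paths

The DCCM is computed on Cα coordinates over the analysis window, by default
after iterative least-squares superposition onto the running mean (Kabsch,
unweighted, iterated to 1e-8 or 10 rounds) to remove rigid-body drift;
whether to superpose is exposed because forced-correlation fixtures need raw
coordinates. A residue with zero positional variance raises a degeneracy
error naming it.

Edges exist exactly where |c_ij| ≥ cutoff (default 0.4) with length
−log|c_ij|, the standard correlation-to-length map under which perfect
coupling is free. Absolute correlation is used so anticorrelation counts as
coupling; a flag restricts to positive correlations. Suboptimal paths are
the k lowest-total-weight distinct simple paths (default k = 250), via Yen's
algorithm with every priority queue keyed by (weight, node sequence), so
equal-weight ties break lexicographically and ensembles are bit-stable.
Community detection is deliberately not implemented. Edge usage counts each
undirected edge once per path containing it.

## Replicate statistics

The replicate summary is one number per replicate (default: the mean gate
distance over the trailing 5 ns window), avoiding frame-level
pseudo-replication; pooling frames is possible but inflates the effective n.
One-way fixed-effects ANOVA (scipy) reports F, its degrees of freedom and p;
Bonferroni correction is available when several gates or conditions are
tested in one run. Replicate sizing uses the two-sample normal
approximation n = ⌈2((z₁₋α/₂ + z_power)·σ/δ)²⌉ floored at 2, with an
optional iterated t-quantile refinement.

## Synthetic generators: what they emulate, and what they do not

Each generator is a pure function of its spec, including the seed (one
counter-based Philox stream per spec), so reruns are byte-identical.

**Pore walk.** Ions follow an overdamped Euler scheme Δz = μ·E·Δt + noise
with μ = 25 Å·nm/(V·ns), frozen once so the default field (−0.06 V/nm at
0.1 ns/frame) drifts 0.15 Å per frame and an open 5 Å pore yields at least
one traversal per 1000 frames — events at desk scale. Gate blocking is
geometric (a crossing proposal is rejected while that gate's radius is below
2 Å), not energetic, so ground truth is unambiguous. The lower gate is a
one-way valve and crossing it flushes the ion 4 Å below the plane; this
enforces a ≥ 3 Å overshoot margin so the generator's logged traversals agree
*exactly* with any detector hysteresis δ ≤ 3 Å. Ions reaching the
intracellular floor are recycled to the reservoir (an image jump for the
detector). Not emulated: force fields, electrostatics beyond the constant
field, ion–ion interaction, solvent, lipids, or knock-on permeation — tests
passing on this generator show detector correctness, not permeation physics.

**Bent helix.** Backbone atoms are placed symmetrically about a
piecewise-linear axis kinked at a single vertex residue, so every
per-residue backbone centroid lies exactly on the axis and the noise-free
bend measured with a single-residue pivot at the vertex equals the
programmed angle to machine precision. The production-style three-residue
pivot introduces a sub-degree geometric bias, absorbed by the ±2° tolerance
used for noisy recovery. This construction is deliberately not
stereochemically ideal; the separate ideal α-helix builder (NeRF from
standard internal coordinates, φ = −57°, ψ = −47°, rise ≈ 1.5 Å/residue)
serves dihedral and axis tests.

**Correlated walk.** Per-frame pseudo-Cα displacements are drawn i.i.d.
across frames and Cartesian dimensions from N(0, σ²C) about fixed rest
positions, via the symmetric eigendecomposition square root (valid for
singular targets such as a perfectly correlated pair). Sample correlations
converge to the target at the Monte-Carlo rate; there is no time
correlation, so DCCM windowing effects are not exercised.

**Bridge engagement.** Each candidate pair sits at 3.5 Å (engaged) or 6.0 Å
(disengaged) by an independent per-frame Bernoulli draw, so the emitted
coordinates reproduce the engagement table exactly under the 4.0 Å cutoff
and fold-change recovery is limited only by binomial sampling error.

## Problem sizes and defaults used in checks

The packaged checks run at sizes chosen for tight statistical bounds on a
single CPU: 2000-frame, 10–20-ion pore runs for conduction; 80-frame noisy
helices (σ = 0.3 Å) for bend recovery; 5000-frame correlated walks (c = 0.5
recovered within ±0.05); 10 000-frame engagement runs (fold changes within
±0.03); 1000 resamples for the ANOVA type-I error (±0.02); exhaustive path
enumeration on ≤ 8-node graphs over 50 seeds. The headline MD observables of
full-scale channel simulations (≈10⁵ atoms, hundreds of ns) are represented
by these programmed ground truths, not re-simulated.

## Known limitations

- The gate "distance" is heavy-atom center-to-center; no solvent-accessible
  radius or HOLE-style profile is computed.
- Conduction counting uses plane crossings with hysteresis, not per-residue
  ring passage; strict ring ordering would require tracking each gate's
  residue geometry per frame.
- The fixture trajectory format carries one box for all frames; NPT-style
  fluctuating boxes are only supported through DCD/XTC.
- The suboptimal-path ensemble orders equal-weight paths lexicographically;
  at an ensemble boundary falling inside a tie class, which tie members are
  included is algorithm-defined (deterministic, but not meaningful).
- The ANOVA treats replicates as exchangeable; no time-series-aware or
  mixed-effects inference is provided.
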