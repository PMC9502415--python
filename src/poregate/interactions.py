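"""Salt bridges, inter-segment contacts and typed interaction distances.

The mechanistically loaded residue pairs of the GIRK gating pathway (PIP2
lysines against the lipid phosphates, the TM1 hydrophobic wire, the pore-helix
dipole pairs, the slide-helix / CD-loop switches) are measured here as
per-frame distances, engagement fractions and distance histograms.

Distance classes and cutoffs:

* ``pi_pi`` 4.0 A, six-membered-ring centroid to ring centroid (His uses its
  five-membered ring — the single unambiguous centroid per residue);
* ``vdw`` 3.0 A, minimum sidechain heavy-atom distance (twice the smallest
  C/N/O Van der Waals radius of 1.5 A);
* ``dipole_hbond`` and ``charge_charge`` 4.0 A, minimum sidechain heavy-atom
  distance.

All distances are minimum-image on the per-frame orthorhombic box and use
heavy atoms only.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from ._geometry import min_pair_distance, mic_displacements, pairwise_distances
from .errors import ValidationError
from .series import Histogram, TimeSeries
from .structure_io import (
    AnalysisWindow,
    Selection,
    Trajectory,
    select_atoms,
    window_frames,
)

SALT_BRIDGE_CUTOFF_A = 4.0
CONTACT_CUTOFF_A = 4.0

#: PIP2 phosphate-group atom names defining the salt-bridge acceptors.
PIP2_PHOSPHATE_ATOMS = ("O11", "O12", "O13", "O14", "O15", "O16", "P2", "P3")
#: Lysine terminal nitrogen.
LYSINE_BASIC_ATOM = "NZ"

# six-membered aromatic rings (His: five-membered)
_RING_ATOMS = {
    "PHE": ("CG", "CD1", "CD2", "CE1", "CE2", "CZ"),
    "TYR": ("CG", "CD1", "CD2", "CE1", "CE2", "CZ"),
    "TRP": ("CD2", "CE2", "CE3", "CZ2", "CZ3", "CH2"),
    "HIS": ("CG", "ND1", "CD2", "CE1", "NE2"),
    "HIE": ("CG", "ND1", "CD2", "CE1", "NE2"),
    "HID": ("CG", "ND1", "CD2", "CE1", "NE2"),
}


def vdw_contact_cutoff(min_radius_A: float = 1.5) -> float:
    """Upper cutoff for Van der Waals contacts between atom centers: twice the
    smallest heavy-atom VdW radius (C/N/O radii span 1.5-1.7 A)."""
    if min_radius_A <= 0:
        raise ValidationError("radius must be positive")
    return 2.0 * min_radius_A


@dataclass(frozen=True)
class InteractionClass:
    """A typed interaction: one cutoff, one measurement rule."""

    name: str
    cutoff: float
    rule: str  # "ring-centroid" or "min-heavy"

    def __post_init__(self):
        if self.rule not in ("ring-centroid", "min-heavy"):
            raise ValidationError(f"unknown measurement rule {self.rule!r}")
        if self.cutoff <= 0:
            raise ValidationError("cutoff must be positive")


PI_PI = InteractionClass("pi_pi", 4.0, "ring-centroid")
VDW = InteractionClass("vdw", vdw_contact_cutoff(), "min-heavy")
DIPOLE_HBOND = InteractionClass("dipole_hbond", 4.0, "min-heavy")
CHARGE_CHARGE = InteractionClass("charge_charge", 4.0, "min-heavy")

INTERACTION_CLASSES = {c.name: c for c in (PI_PI, VDW, DIPOLE_HBOND, CHARGE_CHARGE)}

DEFAULT_HISTOGRAM_EDGES = np.arange(0.0, 12.0 + 0.25, 0.25)


@dataclass(frozen=True)
class SaltBridgeSpec:
    """Basic (lysine NZ) and acceptor (PIP2 phosphate) atom selections."""

    basic: Selection
    acceptors: Selection
    cutoff: float = SALT_BRIDGE_CUTOFF_A

    def __post_init__(self):
        if len(self.basic) == 0 or len(self.acceptors) == 0:
            raise ValidationError("salt-bridge selections must be nonempty")
        if self.cutoff <= 0:
            raise ValidationError("cutoff must be positive")


def salt_bridge_series(
    traj: Trajectory,
    spec: SaltBridgeSpec,
    window: AnalysisWindow | None = None,
) -> TimeSeries:
    """Engaged basic atoms per frame: a basic atom counts as engaged when its
    minimum-image distance to any acceptor atom is <= cutoff."""
    fidx = window_frames(traj, window)
    b = spec.basic.indices
    a = spec.acceptors.indices
    values = np.empty(fidx.size)
    for k, f in enumerate(fidx):
        dmat = pairwise_distances(traj.frames[f, b], traj.frames[f, a],
                                  traj.box_at(f))
        values[k] = int(np.sum(dmat.min(axis=1) <= spec.cutoff))
    return TimeSeries(traj.times[fidx], values, units="count")


def normalized_salt_bridge(
    series: TimeSeries,
    n_candidates: int,
    reference: float | None = None,
) -> tuple[float, float | None]:
    """Normalized salt-bridge formation and (optionally) its fold change.

    Normalized formation = mean per-frame engaged count divided by the number
    of candidate basic atoms, a bounded [0, 1] quantity; fold change is
    normalized / reference (e.g. an apo-condition mean).
    """
    if n_candidates < 1:
        raise ValidationError("n_candidates must be >= 1")
    if len(series) == 0:
        raise ValidationError("empty series")
    normalized = series.mean() / n_candidates
    if not 0.0 <= normalized <= 1.0 + 1e-12:
        raise ValidationError(
            f"normalized formation {normalized:.3f} outside [0, 1]; is "
            f"n_candidates correct?"
        )
    fold = None
    if reference is not None:
        if reference <= 0:
            raise ValidationError("reference mean must be positive")
        fold = normalized / reference
    return float(min(normalized, 1.0)), fold


def intersegment_contact_series(
    traj: Trajectory,
    sel_a: Selection,
    sel_b: Selection,
    cutoff: float = CONTACT_CUTOFF_A,
    window: AnalysisWindow | None = None,
) -> TimeSeries:
    """Total atomic contacts per frame between two disjoint selections:
    the number of unordered atom pairs (a in A, b in B) within the cutoff,
    summed over the frame."""
    if len(sel_a) == 0 or len(sel_b) == 0:
        raise ValidationError("contact selections must be nonempty")
    if set(sel_a.atom_indices) & set(sel_b.atom_indices):
        raise ValidationError("contact selections must be disjoint")
    fidx = window_frames(traj, window)
    a = sel_a.indices
    b = sel_b.indices
    values = np.empty(fidx.size)
    for k, f in enumerate(fidx):
        dmat = pairwise_distances(traj.frames[f, a], traj.frames[f, b],
                                  traj.box_at(f))
        values[k] = int(np.sum(dmat <= cutoff))
    return TimeSeries(traj.times[fidx], values, units="contacts")


def _residue_measure_atoms(traj: Trajectory, chain: str, resid: int,
                           iclass: InteractionClass) -> np.ndarray:
    top = traj.topology
    if iclass.rule == "ring-centroid":
        all_idx = top.atom_indices(chain_id=chain, residue_index=resid)
        if all_idx.size == 0:
            raise ValidationError(f"no atoms for (chain {chain}, resid {resid})")
        resname = top.atoms[all_idx[0]].residue_name
        ring = _RING_ATOMS.get(resname)
        if ring is None:
            raise ValidationError(
                f"pi_pi requested on residue {resname} (chain {chain}, resid "
                f"{resid}) which has no aromatic ring"
            )
        idx = top.atom_indices(chain_id=chain, residue_index=resid, names=ring)
        if idx.size != len(ring):
            raise ValidationError(
                f"residue {resname} (chain {chain}, resid {resid}) is missing "
                f"ring atoms"
            )
        return idx
    idx = select_atoms(top, chain, resid, scope="sidechain-heavy")
    if idx.size == 0:
        raise ValidationError(
            f"residue (chain {chain}, resid {resid}) has no sidechain-heavy atoms"
        )
    return idx


def pair_distance_series(
    traj: Trajectory,
    res_a: tuple[str, int],
    res_b: tuple[str, int],
    iclass: InteractionClass,
    window: AnalysisWindow | None = None,
) -> TimeSeries:
    """Per-frame distance between two residues under the class rule."""
    ia = _residue_measure_atoms(traj, *res_a, iclass)
    ib = _residue_measure_atoms(traj, *res_b, iclass)
    fidx = window_frames(traj, window)
    values = np.empty(fidx.size)
    for k, f in enumerate(fidx):
        box = traj.box_at(f)
        if iclass.rule == "ring-centroid":
            ca = traj.frames[f, ia].mean(axis=0)
            cb = traj.frames[f, ib].mean(axis=0)
            d = mic_displacements(cb - ca, box)
            values[k] = float(np.linalg.norm(d))
        else:
            values[k] = min_pair_distance(traj.frames[f, ia],
                                          traj.frames[f, ib], box)
    return TimeSeries(traj.times[fidx], values, units="A")


def pair_distance_distribution(
    traj: Trajectory,
    res_a: tuple[str, int],
    res_b: tuple[str, int],
    iclass: InteractionClass,
    window: AnalysisWindow | None = None,
    edges: np.ndarray = DEFAULT_HISTOGRAM_EDGES,
) -> tuple[Histogram, float]:
    """Distance histogram plus engaged fraction (distance <= class cutoff)."""
    series = pair_distance_series(traj, res_a, res_b, iclass, window)
    hist = Histogram.from_values(series.values, edges)
    engaged = float(np.mean(series.values <= iclass.cutoff))
    return hist, engaged
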