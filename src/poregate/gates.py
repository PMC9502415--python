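"""Channel-gate geometry and ion-conduction counting.

The two functional gates of a GIRK channel are the helix bundle crossing
(HBC; four pore-lining Phe) and the cytosolic G-loop (girdle Met pair). Gate
state is summarised as the per-frame minimum sidechain heavy-atom distance
across the pore between diagonal subunit pairs; distances at or above the
occlusion threshold (default 5.7 A, the minimal diameter that still passes a
partially solvated K+ ion) count as open. A conduction event is one ion
traversing both gate planes in sequence.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from ._geometry import min_pair_distance
from .errors import ValidationError
from .series import TimeSeries
from .structure_io import (
    AnalysisWindow,
    ResidueRoleMap,
    Selection,
    SubunitAssignment,
    Topology,
    Trajectory,
    select_atoms,
    window_frames,
)

OCCLUSION_THRESHOLD_A = 5.7
DEFAULT_HYSTERESIS_A = 2.0
DEFAULT_PORE_RADIUS_A = 10.0

_GATE_ROLES = {"HBC": "HBC-gate", "G-loop": "G-loop-gate"}


@dataclass(frozen=True)
class GateSpec:
    """One gate: four residues in ring order, paired diagonally (0-2, 1-3)."""

    name: str
    residues: tuple[tuple[str, int], ...]  # four (chain_id, resid) in ring order
    occlusion_threshold: float = OCCLUSION_THRESHOLD_A
    atom_scope: str = "sidechain-heavy"

    def __post_init__(self):
        if len(self.residues) != 4:
            raise ValidationError(
                f"gate {self.name!r} needs exactly 4 residues, got "
                f"{len(self.residues)}"
            )
        if self.occlusion_threshold <= 0:
            raise ValidationError("occlusion threshold must be positive")

    @property
    def diagonal_pairs(self) -> tuple[tuple[int, int], tuple[int, int]]:
        return ((0, 2), (1, 3))

    @classmethod
    def from_roles(
        cls,
        topology: Topology,
        assignment: SubunitAssignment,
        roles: ResidueRoleMap,
        name: str,
        occlusion_threshold: float = OCCLUSION_THRESHOLD_A,
    ) -> "GateSpec":
        """Resolve the gate residues chain by chain from the role map.

        Chains are taken in sorted order (ring order A, B, C, D); each chain
        contributes the first role residue of its subunit type.
        """
        assignment.validate_channel()
        role = _GATE_ROLES.get(name)
        if role is None:
            raise ValidationError(f"unknown gate name {name!r}; expected HBC or G-loop")
        residues = []
        for chain in sorted(assignment.mapping):
            sub = assignment.subunit_of(chain)
            resid = roles.lookup(role, sub)[0]
            residues.append((chain, resid))
        return cls(name=name, residues=tuple(residues),
                   occlusion_threshold=occlusion_threshold)


@dataclass(frozen=True)
class ConductionEvent:
    """One ion passing both gates; direction is inward (+z to -z) or outward."""

    ion_id: int          # atom index of the ion in the topology
    entry_frame: int
    exit_frame: int
    direction: str

    def __post_init__(self):
        if self.entry_frame >= self.exit_frame:
            raise ValidationError("entry frame must precede exit frame")
        if self.direction not in ("inward", "outward"):
            raise ValidationError(f"unknown direction {self.direction!r}")


def _gate_atom_sets(traj: Trajectory, gate: GateSpec) -> list[np.ndarray]:
    sets = []
    for chain, resid in gate.residues:
        idx = select_atoms(traj.topology, chain, resid, scope=gate.atom_scope)
        if idx.size == 0:
            raise ValidationError(
                f"gate {gate.name!r}: residue (chain {chain}, resid {resid}) has "
                f"no {gate.atom_scope} atoms"
            )
        sets.append(idx)
    return sets


def gate_min_distance(
    traj: Trajectory,
    gate: GateSpec,
    window: AnalysisWindow | None = None,
) -> TimeSeries:
    """Per-frame gate aperture: min over the two diagonal residue pairs of the
    minimum heavy-atom center-to-center distance (minimum-image)."""
    atom_sets = _gate_atom_sets(traj, gate)
    fidx = window_frames(traj, window)
    values = np.empty(fidx.size)
    for k, f in enumerate(fidx):
        box = traj.box_at(f)
        best = np.inf
        for i, j in gate.diagonal_pairs:
            d = min_pair_distance(traj.frames[f, atom_sets[i]],
                                  traj.frames[f, atom_sets[j]], box)
            best = min(best, d)
        values[k] = best
    return TimeSeries(traj.times[fidx], values, units="A")


def classify_occlusion(series: TimeSeries,
                       threshold: float = OCCLUSION_THRESHOLD_A) -> float:
    """Fraction of frames in which the gate aperture permits permeation
    (value >= threshold)."""
    if len(series) == 0:
        raise ValidationError("cannot classify an empty series")
    return float(np.mean(series.values >= threshold))


def derive_gate_planes(
    traj: Trajectory,
    hbc: GateSpec,
    gloop: GateSpec,
    per_frame: bool = False,
) -> tuple[np.ndarray, np.ndarray] | tuple[float, float]:
    """Gate plane z positions from the C-alpha centroids of the gate residues.

    ``per_frame`` tracks channel drift; the static variant (default) averages
    over all frames, which is exact for the synthetic fixtures.
    """
    out = []
    for gate in (hbc, gloop):
        idx = np.concatenate([
            select_atoms(traj.topology, c, r, scope="backbone")
            for c, r in gate.residues
        ])
        ca = [i for i in idx if traj.topology.atoms[i].name == "CA"]
        if not ca:
            raise ValidationError(f"gate {gate.name!r} has no C-alpha atoms")
        z = traj.frames[:, ca, 2].mean(axis=1)
        out.append(z if per_frame else float(z.mean()))
    z_hbc, z_gloop = out
    return z_hbc, z_gloop


def count_conductions(
    traj: Trajectory,
    ions: Selection,
    gate_planes: tuple[float, float],
    window: AnalysisWindow | None = None,
    hysteresis: float = DEFAULT_HYSTERESIS_A,
    pore_radius: float = DEFAULT_PORE_RADIUS_A,
    axis_xy: tuple[float, float] = (0.0, 0.0),
) -> tuple[int, list[ConductionEvent]]:
    """Count complete two-gate ion traversals.

    Per-ion three-state machine: ABOVE (z > z_HBC + hysteresis) -> IN_PORE
    (between the planes and within ``pore_radius`` of the pore axis) -> BELOW
    (z < z_Gloop - hysteresis) emits one inward event; the mirror sequence
    emits an outward event. Leaving the pore laterally or returning ABOVE
    resets the machine. Jumps of more than half the box in z are treated as
    periodic-image jumps (ion recycling) and reset the machine to the region
    of the re-entry position without emitting an event.

    The returned count is the number of *inward* events whose exit frame falls
    inside the window; the event list carries both directions.
    """
    if len(ions) == 0:
        raise ValidationError("empty ion selection")
    z_hbc, z_gloop = gate_planes
    if not z_hbc > z_gloop:
        raise ValidationError("gate planes require z_HBC > z_Gloop")
    if hysteresis < 0:
        raise ValidationError("hysteresis must be >= 0")
    d = hysteresis
    box_z = None if traj.box is None else float(traj.box[0, 2])
    events: list[ConductionEvent] = []
    for ion in ions.indices:
        z = traj.frames[:, ion, 2]
        xy = traj.frames[:, ion, :2] - np.asarray(axis_xy)
        lat = np.linalg.norm(xy, axis=1)

        def region(f: int) -> str:
            if z[f] > z_hbc + d:
                return "ABOVE"
            if z[f] < z_gloop - d:
                return "BELOW"
            return "MID"

        state = region(0)
        if state == "MID":
            state = "UNARMED"
        entry = 0
        for f in range(1, traj.n_frames):
            if box_z is not None and abs(z[f] - z[f - 1]) > box_z / 2.0:
                state = region(f)
                if state == "MID":
                    state = "UNARMED"
                continue
            if state == "ABOVE":
                if z[f] < z_hbc:
                    if lat[f] <= pore_radius:
                        state, entry = "IN_PORE_DOWN", f
                    else:
                        state = "UNARMED"
            elif state == "BELOW":
                if z[f] > z_gloop:
                    if lat[f] <= pore_radius:
                        state, entry = "IN_PORE_UP", f
                    else:
                        state = "UNARMED"
            elif state == "IN_PORE_DOWN":
                if lat[f] > pore_radius:
                    state = "UNARMED"
                elif z[f] > z_hbc + d:
                    state = "ABOVE"
                elif z[f] < z_gloop - d:
                    events.append(ConductionEvent(int(ion), entry, f, "inward"))
                    state = "BELOW"
            elif state == "IN_PORE_UP":
                if lat[f] > pore_radius:
                    state = "UNARMED"
                elif z[f] < z_gloop - d:
                    state = "BELOW"
                elif z[f] > z_hbc + d:
                    events.append(ConductionEvent(int(ion), entry, f, "outward"))
                    state = "ABOVE"
            else:  # UNARMED
                if z[f] > z_hbc + d:
                    state = "ABOVE"
                elif z[f] < z_gloop - d:
                    state = "BELOW"
    if window is None:
        in_window = lambda f: True
    else:
        in_window = lambda f: bool(window.frame_mask(traj.times[f:f + 1])[0])
    count = sum(1 for e in events
                if e.direction == "inward" and in_window(e.exit_frame))
    return count, events
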