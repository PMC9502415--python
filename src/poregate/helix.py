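"""Helix bend angles, inter-helix axis angles, and backbone dihedrals.

TM2 bending about the conserved hinge glycine is quantified as the angle at
the pivot-segment backbone centroid between vectors to the outer-turn and
inner-turn centroids (180 deg = straight helix; activation bends TM2 toward
~165 deg, inhibition straightens it toward ~177 deg). The TM1/slide-helix
coupling is the angle between the two segments' principal axes, oriented
N->C. Backbone phi/psi tracking and a rectangular Ramachandran classifier
support hinge-residue dihedral-shift analysis.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from ._geometry import angle_deg, dihedral_deg, principal_axis
from .errors import DegeneracyError, ValidationError
from .series import TimeSeries
from .structure_io import (
    AnalysisWindow,
    ResidueRoleMap,
    SubunitAssignment,
    Topology,
    Trajectory,
    select_atoms,
    window_frames,
)

_BACKBONE_MASSES = {"N": 14.007, "CA": 12.011, "C": 12.011, "O": 15.999}


@dataclass(frozen=True)
class SegmentSpec:
    """A contiguous residue range on one chain, backbone-atom scope."""

    chain_id: str
    first_resid: int
    last_resid: int

    def __post_init__(self):
        if self.last_resid < self.first_resid:
            raise ValidationError(
                f"segment range {self.first_resid}-{self.last_resid} is empty"
            )

    @classmethod
    def from_role(
        cls,
        roles: ResidueRoleMap,
        role_name: str,
        chain_id: str,
    ) -> "SegmentSpec":
        _, (lo, hi) = roles.segment(role_name)
        return cls(chain_id, lo, hi)

    def atom_indices(self, topology: Topology, scope: str = "backbone") -> np.ndarray:
        idx = []
        for resid in range(self.first_resid, self.last_resid + 1):
            idx.extend(select_atoms(topology, self.chain_id, resid, scope=scope))
        if not idx:
            raise ValidationError(
                f"segment chain {self.chain_id} {self.first_resid}-"
                f"{self.last_resid} resolves to no {scope} atoms"
            )
        return np.asarray(sorted(idx), dtype=int)


@dataclass(frozen=True)
class BendAngleDef:
    """Outer turn / pivot / inner turn segments of a bending helix.

    Defaults follow the TM2 construction: outer one turn above the pivot
    (G158-F162), pivot I167-G169 around the hinge glycine, inner one turn
    below (A174-G178), all on a GIRK1 chain.
    """

    outer: SegmentSpec
    pivot: SegmentSpec
    inner: SegmentSpec

    def __post_init__(self):
        segs = (self.outer, self.pivot, self.inner)
        if len({s.chain_id for s in segs}) != 1:
            raise ValidationError("bend segments must share one chain")
        ranges = [(s.first_resid, s.last_resid) for s in segs]
        if not (ranges[0][1] < ranges[1][0] and ranges[1][1] < ranges[2][0]):
            raise ValidationError(
                "bend segments must be disjoint and in ascending sequence order"
            )

    @classmethod
    def tm2_default(cls, chain_id: str, roles: ResidueRoleMap | None = None
                    ) -> "BendAngleDef":
        roles = roles or ResidueRoleMap.default()
        return cls(
            outer=SegmentSpec.from_role(roles, "TM2-outer", chain_id),
            pivot=SegmentSpec.from_role(roles, "TM2-pivot", chain_id),
            inner=SegmentSpec.from_role(roles, "TM2-inner", chain_id),
        )


@dataclass
class DihedralSeries:
    """phi(t), psi(t) of one residue, degrees in (-180, 180]."""

    chain_id: str
    residue_index: int
    times: np.ndarray
    phi: np.ndarray
    psi: np.ndarray

    def max_abs_shift(self) -> tuple[float, float]:
        """Largest |change| of phi and psi relative to the first frame,
        on the circle."""
        def span(a):
            delta = (a - a[0] + 180.0) % 360.0 - 180.0
            return float(np.max(np.abs(delta)))
        return span(self.phi), span(self.psi)


def _segment_centroids(traj: Trajectory, seg: SegmentSpec, fidx: np.ndarray,
                       mass_weighted: bool) -> np.ndarray:
    idx = seg.atom_indices(traj.topology, scope="backbone")
    coords = traj.frames[np.ix_(fidx, idx)]
    if not mass_weighted:
        return coords.mean(axis=1)
    w = np.array([
        _BACKBONE_MASSES.get(traj.topology.atoms[i].name, 12.011) for i in idx
    ])
    w = w / w.sum()
    return np.einsum("fij,i->fj", coords, w)


def bend_angle_series(
    traj: Trajectory,
    bend_def: BendAngleDef,
    window: AnalysisWindow | None = None,
    mass_weighted: bool = False,
) -> TimeSeries:
    """Per-frame bend angle (degrees) at the pivot centroid between vectors to
    the outer and inner segment centroids; 180 = straight."""
    fidx = window_frames(traj, window)
    outer = _segment_centroids(traj, bend_def.outer, fidx, mass_weighted)
    pivot = _segment_centroids(traj, bend_def.pivot, fidx, mass_weighted)
    inner = _segment_centroids(traj, bend_def.inner, fidx, mass_weighted)
    values = np.array([
        angle_deg(o - p, i - p) for o, p, i in zip(outer, pivot, inner)
    ])
    return TimeSeries(traj.times[fidx], values, units="deg")


def _oriented_axis(coords: np.ndarray) -> np.ndarray:
    try:
        axis = principal_axis(coords)
    except ValueError as exc:
        raise DegeneracyError(str(exc))
    # orient N -> C: along the first-to-last atom displacement
    direction = coords[-1] - coords[0]
    if np.linalg.norm(direction) < 1e-9:
        raise DegeneracyError("segment endpoints coincide; axis orientation "
                              "undefined")
    if np.dot(axis, direction) < 0:
        axis = -axis
    return axis


def axis_angle_series(
    traj: Trajectory,
    seg_a: SegmentSpec,
    seg_b: SegmentSpec,
    window: AnalysisWindow | None = None,
    method: str = "principal",
) -> TimeSeries:
    """Per-frame angle (degrees, [0, 180)) between two helix axes.

    ``method`` is ``"principal"`` (largest-variance direction of the backbone
    atoms, oriented N->C) or ``"end-to-end"`` (first-to-last C-alpha vector).
    """
    if method not in ("principal", "end-to-end"):
        raise ValidationError(f"unknown axis method {method!r}")
    for seg, label in ((seg_a, "A"), (seg_b, "B")):
        if seg.last_resid - seg.first_resid + 1 < 4:
            raise ValidationError(
                f"segment {label} must span at least 4 residues for a stable axis"
            )
    ia = seg_a.atom_indices(traj.topology, scope="backbone")
    ib = seg_b.atom_indices(traj.topology, scope="backbone")
    fidx = window_frames(traj, window)
    values = np.empty(fidx.size)
    for k, f in enumerate(fidx):
        if method == "principal":
            axis_a = _oriented_axis(traj.frames[f, ia])
            axis_b = _oriented_axis(traj.frames[f, ib])
        else:
            axis_a = traj.frames[f, ia[-1]] - traj.frames[f, ia[0]]
            axis_b = traj.frames[f, ib[-1]] - traj.frames[f, ib[0]]
        ang = angle_deg(axis_a, axis_b)
        values[k] = ang if ang < 180.0 else 0.0
    return TimeSeries(traj.times[fidx], values, units="deg")


def backbone_dihedrals(
    traj: Trajectory,
    chain_id: str,
    residue_index: int,
    window: AnalysisWindow | None = None,
) -> DihedralSeries:
    """Standard phi (C(i-1)-N-CA-C) and psi (N-CA-C-N(i+1)) per frame."""
    top = traj.topology

    def one(resid: int, name: str) -> int:
        idx = top.atom_indices(chain_id=chain_id, residue_index=resid,
                               names=[name])
        if idx.size != 1:
            raise ValidationError(
                f"residue (chain {chain_id}, resid {resid}) lacks atom {name}; "
                f"terminal residues have no defined phi/psi"
            )
        return int(idx[0])

    c_prev = one(residue_index - 1, "C")
    n = one(residue_index, "N")
    ca = one(residue_index, "CA")
    c = one(residue_index, "C")
    n_next = one(residue_index + 1, "N")
    fidx = window_frames(traj, window)
    phi = np.array([
        dihedral_deg(traj.frames[f, c_prev], traj.frames[f, n],
                     traj.frames[f, ca], traj.frames[f, c]) for f in fidx
    ])
    psi = np.array([
        dihedral_deg(traj.frames[f, n], traj.frames[f, ca],
                     traj.frames[f, c], traj.frames[f, n_next]) for f in fidx
    ])
    return DihedralSeries(chain_id, residue_index, traj.times[fidx], phi, psi)


# rectangular Ramachandran regions (degrees); the allowed band dilates each
# favored rectangle by 20 deg and adds the left-handed-helix box
_FAVORED = (
    ((-100.0, -30.0), (-67.0, -7.0)),    # alpha
    ((-180.0, -100.0), (90.0, 180.0)),   # beta
)
_ALLOWED_EXTRA = (((40.0, 80.0), (20.0, 80.0)),)  # left-handed box
_DILATION = 20.0


def _in_box(phi: float, psi: float, box) -> bool:
    (plo, phi_hi), (slo, shi) = box
    return plo <= phi <= phi_hi and slo <= psi <= shi


def ramachandran_region(phi: float, psi: float) -> str:
    """Classify (phi, psi) as favored, allowed or outlier.

    Fixed rectangular regions: favored alpha phi in [-100, -30] / psi in
    [-67, -7]; favored beta phi in [-180, -100] / psi in [90, 180]; allowed is
    a 20 deg dilation of each plus the left-handed box phi in [40, 80] / psi
    in [20, 80]; anything else is an outlier.
    """
    if not (-180.0 < phi <= 180.0 and -180.0 < psi <= 180.0):
        raise ValidationError("phi/psi must lie in (-180, 180]")
    for box in _FAVORED:
        if _in_box(phi, psi, box):
            return "favored"
    for ((plo, phi_hi), (slo, shi)) in _FAVORED:
        dil = ((plo - _DILATION, phi_hi + _DILATION),
               (slo - _DILATION, shi + _DILATION))
        if _in_box(phi, psi, dil):
            return "allowed"
    for box in _ALLOWED_EXTRA:
        if _in_box(phi, psi, box):
            return "allowed"
    return "outlier"


def region_fractions(series: DihedralSeries) -> dict[str, float]:
    """Fraction of frames in each Ramachandran region."""
    labels = [ramachandran_region(p, s) for p, s in zip(series.phi, series.psi)]
    n = len(labels)
    return {r: labels.count(r) / n for r in ("favored", "allowed", "outlier")}
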