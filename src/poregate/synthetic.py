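"""Synthetic trajectories with exactly known ground truth.

Every downstream analysis stage in this package is exercised against data
produced here, so each generator is built for an *unambiguous* answer rather
than for physical realism:

* :func:`simulate_pore_trajectory` — K+ ions drifting through a two-gate pore
  under a constant membrane-normal field, with geometric gate blocking and a
  logged list of completed two-gate traversals;
* :func:`simulate_bent_helix` — a helix whose per-residue backbone centroid
  lies exactly on a piecewise-linear axis kinked at a pivot residue, so the
  segment-centroid bend angle is exact by construction;
* :func:`build_alpha_helix` — a stereochemically ideal alpha-helix backbone
  from standard internal coordinates (NeRF chain extension), for dihedral and
  helix-axis tests;
* :func:`simulate_correlated_walk` — pseudo-C-alpha displacements with a
  prescribed cross-correlation matrix;
* :func:`simulate_bridge_engagement` — Bernoulli lysine-phosphate engagement
  at programmed per-frame probability, emitted both as a table and as
  coordinates that reproduce it under the 4 A salt-bridge cutoff.

All randomness flows from one counter-based generator (Philox) per spec; the
same spec always reproduces identical bytes.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np

from .errors import ValidationError
from .structure_io import AtomRecord, Topology, Trajectory

__all__ = [
    "SyntheticPoreSpec",
    "GroundTruth",
    "HelixSpec",
    "CorrelatedWalkSpec",
    "simulate_pore_trajectory",
    "simulate_bent_helix",
    "build_alpha_helix",
    "simulate_correlated_walk",
    "simulate_bridge_engagement",
    "field_to_voltage",
    "ION_MOBILITY_A_PER_VNM_NS",
    "MIN_PASS_RADIUS_A",
]

# Ion drift mobility, angstrom displacement per (V/nm) of field per ns.
# Calibrated once so the production default (-0.06 V/nm, 0.1 ns/frame) drifts
# 0.15 A/frame: >= 1 expected traversal per 1000 frames through a 5 A open
# pore. Frozen; not a tuning knob.
ION_MOBILITY_A_PER_VNM_NS = 25.0

# An ion may pass a gate plane only while that gate's radius is at least this.
MIN_PASS_RADIUS_A = 2.0

_EXIT_FLUSH_A = 4.0          # ions crossing the lower gate land this far below it
_GT_HYSTERESIS_A = 3.0       # ground-truth machine margin (> any detector delta)
_BACKBONE_RING_RADIUS_A = 9.0


def _rng(seed: int) -> np.random.Generator:
    return np.random.Generator(np.random.Philox(seed))


# --------------------------------------------------------------------------- #
# pore + permeation
# --------------------------------------------------------------------------- #

@dataclass(frozen=True)
class SyntheticPoreSpec:
    """Parameters of the two-gate pore walk.

    ``field`` is the membrane-normal electric field in V/nm; a negative field
    drives cations from the extracellular side (+z) toward the intracellular
    side (-z), matching the production-simulation convention.
    """

    n_ions: int = 20
    gate_z: tuple[float, float] = (8.0, -8.0)       # (z_HBC, z_Gloop), A
    gate_radii: tuple[object, object] = (5.0, 5.0)  # per-gate: scalar or per-frame
    field: float = -0.06                            # V/nm
    noise_scale: float = 0.5                        # per-step Gaussian sigma, A
    box: tuple[float, float, float] = (40.0, 40.0, 80.0)
    n_frames: int = 2000
    dt_ns: float = 0.1
    seed: int = 0

    def __post_init__(self):
        z_hbc, z_gloop = self.gate_z
        if z_hbc - z_gloop < 5.0:
            raise ValidationError("gate planes must be >= 5 A apart (z_HBC > z_Gloop)")
        if self.n_frames < 2:
            raise ValidationError("n_frames must be >= 2")
        if self.n_ions < 1:
            raise ValidationError("need at least one ion")
        for r in self.gate_radii:
            if np.any(np.asarray(r, dtype=float) < 0):
                raise ValidationError("gate radii must be >= 0")

    def radius_schedule(self, which: int) -> np.ndarray:
        r = np.asarray(self.gate_radii[which], dtype=float)
        if r.ndim == 0:
            return np.full(self.n_frames, float(r))
        if r.shape != (self.n_frames,):
            raise ValidationError("per-frame radius schedule must have n_frames entries")
        return r


@dataclass
class GroundTruth:
    """The programmed truth emitted alongside a synthetic trajectory."""

    traversal_events: dict[int, list[tuple[int, int, str]]] = field(default_factory=dict)
    gate_planes: tuple[float, float] | None = None
    gate_residues: dict[str, tuple[tuple[str, int], ...]] | None = None
    ion_atom_indices: tuple[int, ...] = ()
    programmed_bend_deg: float | None = None
    programmed_correlation: np.ndarray | None = None
    programmed_engagement: float | None = None

    @property
    def n_traversals(self) -> int:
        return sum(len(v) for v in self.traversal_events.values())

    def to_json_dict(self) -> dict:
        return {
            "n_traversals": self.n_traversals,
            "traversal_events": {
                str(k): [list(e) for e in v] for k, v in self.traversal_events.items()
            },
            "gate_planes": list(self.gate_planes) if self.gate_planes else None,
            "programmed_bend_deg": self.programmed_bend_deg,
            "programmed_engagement": self.programmed_engagement,
        }


def _gate_residue_atoms(chain: str, resname: str, resid: int, tip_name: str,
                        serial_start: int, angle_rad: float,
                        z: float) -> list[AtomRecord]:
    """Backbone anchor plus a two-atom sidechain pointing at the pore axis.

    Positions here are placeholders; per-frame tip radii are written by the
    walk. Element of the tip follows its name."""
    c, s = np.cos(angle_rad), np.sin(angle_rad)
    mk = lambda serial, name, element, r: AtomRecord(
        serial, name, element, resname, resid, chain, (r * c, r * s, z))
    tip_elem = "S" if tip_name.startswith("S") else "C"
    return [
        mk(serial_start, "CA", "C", _BACKBONE_RING_RADIUS_A),
        mk(serial_start + 1, "CB", "C", _BACKBONE_RING_RADIUS_A - 2.0),
        mk(serial_start + 2, tip_name, tip_elem, _BACKBONE_RING_RADIUS_A - 4.0),
    ]


def simulate_pore_trajectory(spec: SyntheticPoreSpec) -> tuple[Trajectory, GroundTruth]:
    """Biased random walk of ions through a four-fold pseudo-symmetric pore.

    The topology carries four chains (A-D, alternating GIRK1/GIRK2 numbering)
    each contributing one HBC Phe and one G-loop Met whose sidechain tip sits
    at the programmed gate radius, plus ``n_ions`` K+ ions on chain I.

    Walk rules (overdamped Euler, Delta-z = mobility * field * dt + noise):

    * an ion may cross a gate plane only while that gate's radius is at least
      ``MIN_PASS_RADIUS_A``; blocked proposals are rejected at the plane;
    * the lower (G-loop) plane is a one-way valve and crossing it flushes the
      ion 4 A below the plane, guaranteeing the >= 3 A overshoot margin that
      makes ground truth and any detector with hysteresis <= 3 A agree
      exactly;
    * ions are confined laterally to a 5 A pore radius (reflective);
    * ions reaching the intracellular floor are recycled to the extracellular
      reservoir; the resulting z jump exceeds half the box and is treated as a
      periodic-image jump by the conduction detector.
    """
    rng = _rng(spec.seed)
    z_hbc, z_gloop = spec.gate_z
    box_z = spec.box[2]
    z_ceil = box_z / 2.0 - 2.0
    z_floor = -box_z / 2.0 + 5.0
    z_respawn = box_z / 2.0 - 5.0
    confine = 5.0
    r_hbc = spec.radius_schedule(0)
    r_gloop = spec.radius_schedule(1)

    # --- topology -----------------------------------------------------------
    atoms: list[AtomRecord] = []
    serial = 1
    hbc_res: list[tuple[str, int]] = []
    gloop_res: list[tuple[str, int]] = []
    for ci, chain in enumerate("ABCD"):
        angle = ci * np.pi / 2.0
        hbc_resid = 181 if ci % 2 == 0 else 192   # GIRK1 / GIRK2 numbering
        atoms += _gate_residue_atoms(chain, "PHE", hbc_resid, "CZ", serial,
                                     angle, z_hbc)
        serial += 3
        atoms += _gate_residue_atoms(chain, "MET", 313, "CE", serial,
                                     angle, z_gloop)
        serial += 3
        hbc_res.append((chain, hbc_resid))
        gloop_res.append((chain, 313))
    ion_first = len(atoms)
    for j in range(spec.n_ions):
        atoms.append(AtomRecord(serial, "K", "K", "K", j + 1, "I",
                                (0.0, 0.0, 0.0)))
        serial += 1
    top = Topology(atoms)

    # --- ion walk ------------------------------------------------------------
    n, nf = spec.n_ions, spec.n_frames
    drift = ION_MOBILITY_A_PER_VNM_NS * spec.field * spec.dt_ns
    z = z_respawn - rng.uniform(0.0, 10.0, size=n)
    xy = rng.uniform(-2.0, 2.0, size=(n, 2))
    ion_z = np.empty((nf, n))
    ion_xy = np.empty((nf, n, 2))
    ion_z[0] = z
    ion_xy[0] = xy
    for f in range(1, nf):
        zp = z + drift + rng.normal(0.0, spec.noise_scale, size=n)
        # gate blocking: reject crossings while the gate is narrower than an ion
        for z_g, r_g in ((z_hbc, r_hbc[f]), (z_gloop, r_gloop[f])):
            if r_g < MIN_PASS_RADIUS_A:
                crossing = (z - z_g) * (zp - z_g) <= 0.0
                zp = np.where(crossing, z, zp)
        # one-way valve + flush at the lower gate
        up_cross = (z < z_gloop) & (zp >= z_gloop)
        zp = np.where(up_cross, z, zp)
        down_cross = (z >= z_gloop) & (zp < z_gloop)
        zp = np.where(down_cross, z_gloop - _EXIT_FLUSH_A - 0.1, zp)
        # ceiling reflection, floor recycling
        zp = np.where(zp > z_ceil, 2.0 * z_ceil - zp, zp)
        recycled = zp < z_floor
        zp = np.where(recycled, z_respawn, zp)
        # lateral diffusion within the pore radius
        xyp = xy + rng.normal(0.0, spec.noise_scale, size=(n, 2))
        rad = np.linalg.norm(xyp, axis=1)
        over = rad > confine
        xyp[over] *= (confine / rad[over])[:, None]
        xyp[recycled] = rng.uniform(-2.0, 2.0, size=(int(recycled.sum()), 2))
        z, xy = zp, xyp
        ion_z[f] = z
        ion_xy[f] = xy

    # --- frames --------------------------------------------------------------
    frames = np.zeros((nf, top.n_atoms, 3))
    for ci in range(4):
        angle = ci * np.pi / 2.0
        c, s = np.cos(angle), np.sin(angle)
        base = ci * 6
        for gi, (z_g, sched) in enumerate(((z_hbc, r_hbc), (z_gloop, r_gloop))):
            off = base + 3 * gi
            frames[:, off + 0] = [_BACKBONE_RING_RADIUS_A * c,
                                  _BACKBONE_RING_RADIUS_A * s, z_g]
            mid = (sched + _BACKBONE_RING_RADIUS_A) / 2.0
            frames[:, off + 1, 0] = mid * c
            frames[:, off + 1, 1] = mid * s
            frames[:, off + 1, 2] = z_g
            frames[:, off + 2, 0] = sched * c
            frames[:, off + 2, 1] = sched * s
            frames[:, off + 2, 2] = z_g
    frames[:, ion_first:, 0] = ion_xy[:, :, 0]
    frames[:, ion_first:, 1] = ion_xy[:, :, 1]
    frames[:, ion_first:, 2] = ion_z

    times = np.arange(nf) * spec.dt_ns
    box = np.tile(np.asarray(spec.box, dtype=float), (nf, 1))
    traj = Trajectory(top, frames, times, box)

    # --- ground truth (generator-internal state machine) ----------------------
    events: dict[int, list[tuple[int, int, str]]] = {j: [] for j in range(n)}
    d = _GT_HYSTERESIS_A
    for j in range(n):
        zs = ion_z[:, j]
        state = "ABOVE" if zs[0] > z_hbc + d else "UNARMED"
        entry = -1
        for f in range(1, nf):
            if abs(zs[f] - zs[f - 1]) > box_z / 2.0:  # image jump (recycling)
                state = "ABOVE" if zs[f] > z_hbc + d else (
                    "BELOW" if zs[f] < z_gloop - d else "UNARMED")
                continue
            if state == "ABOVE":
                if zs[f] < z_hbc:
                    state, entry = "IN_PORE", f
            elif state == "IN_PORE":
                if zs[f] > z_hbc + d:
                    state = "ABOVE"
                elif zs[f] < z_gloop - d:
                    events[j].append((entry, f, "inward"))
                    state = "BELOW"
            else:  # BELOW or UNARMED
                if zs[f] > z_hbc + d:
                    state = "ABOVE"

    truth = GroundTruth(
        traversal_events=events,
        gate_planes=(z_hbc, z_gloop),
        gate_residues={"HBC": tuple(hbc_res), "G-loop": tuple(gloop_res)},
        ion_atom_indices=tuple(range(ion_first, ion_first + n)),
    )
    return traj, truth


# --------------------------------------------------------------------------- #
# helices
# --------------------------------------------------------------------------- #

@dataclass(frozen=True)
class HelixSpec:
    """A kinked helix with exact per-residue backbone centroids on its axis.

    ``bend_deg`` is the angle recovered by the segment-centroid bend analysis
    (180 = straight) for a pivot range equal to the single vertex residue.
    """

    bend_deg: float
    n_residues: int = 21
    rise: float = 1.5           # A per residue
    twist_deg: float = 100.0
    noise_sigma: float = 0.0    # isotropic per-atom Gaussian noise, A
    n_frames: int = 1
    seed: int = 0
    first_resid: int = 158      # mirrors the TM2 numbering used downstream
    pivot_resid: int | None = None  # default: middle residue
    dt_ns: float = 0.1

    def __post_init__(self):
        if not (0.0 < self.bend_deg <= 180.0):
            raise ValidationError("bend_deg must be in (0, 180]")
        if self.n_residues < 5:
            raise ValidationError("need at least 5 residues")

    @property
    def vertex_resid(self) -> int:
        if self.pivot_resid is not None:
            return self.pivot_resid
        return self.first_resid + self.n_residues // 2


def simulate_bent_helix(spec: HelixSpec) -> Trajectory:
    """Backbone (N, CA, C, O) of a helix kinked by (180 - bend_deg) at the pivot.

    The four backbone atoms of each residue are placed symmetrically about the
    residue's axis point, so every per-residue backbone centroid lies exactly
    on the piecewise-linear axis; the noise-free bend angle measured with a
    single-residue pivot at the vertex equals ``bend_deg`` to machine
    precision.
    """
    rng = _rng(spec.seed)
    theta = np.radians(spec.bend_deg)
    u1 = np.array([0.0, 0.0, 1.0])                      # vertex -> outer arm
    u2 = np.array([np.sin(theta), 0.0, np.cos(theta)])  # vertex -> inner arm
    q = spec.vertex_resid
    resids = np.arange(spec.first_resid, spec.first_resid + spec.n_residues)
    if not (resids[0] < q < resids[-1]):
        raise ValidationError("pivot residue must be interior to the helix")

    r_b = 1.2  # backbone offset radius, A
    atoms: list[AtomRecord] = []
    base = np.empty((spec.n_residues * 4, 3))
    serial = 1
    for k, rid in enumerate(resids):
        if rid < q:
            p = (q - rid) * spec.rise * u1
            d = -u1
        elif rid > q:
            p = (rid - q) * spec.rise * u2
            d = u2
        else:
            p = np.zeros(3)
            d = u2 - u1
            d = d / np.linalg.norm(d) if np.linalg.norm(d) > 1e-12 else np.array(
                [1.0, 0.0, 0.0])
        # perpendicular frame for the helical phase
        ref = np.array([1.0, 0.0, 0.0])
        if abs(np.dot(ref, d)) > 0.9:
            ref = np.array([0.0, 1.0, 0.0])
        e1 = ref - np.dot(ref, d) * d
        e1 /= np.linalg.norm(e1)
        e2 = np.cross(d, e1)
        phi = np.radians(k * spec.twist_deg)
        u_a = np.cos(phi) * e1 + np.sin(phi) * e2
        u_b = np.cos(phi + np.pi / 2) * e1 + np.sin(phi + np.pi / 2) * e2
        offsets = {"N": r_b * u_a, "CA": -r_b * u_a, "C": r_b * u_b, "O": -r_b * u_b}
        for name, off in offsets.items():
            pos = p + off
            base[serial - 1] = pos
            atoms.append(AtomRecord(serial, name, name[0], "ALA", int(rid), "A",
                                    tuple(pos)))
            serial += 1
    top = Topology(atoms)
    frames = np.tile(base, (spec.n_frames, 1, 1))
    if spec.noise_sigma > 0:
        frames = frames + rng.normal(0.0, spec.noise_sigma, size=frames.shape)
    times = np.arange(spec.n_frames) * spec.dt_ns
    return Trajectory(top, frames, times, None)


# standard backbone internal coordinates (A, degrees)
_B_N_CA, _B_CA_C, _B_C_N, _B_C_O = 1.458, 1.525, 1.329, 1.231
_A_C_N_CA, _A_N_CA_C, _A_CA_C_N, _A_CA_C_O = 121.7, 111.2, 116.2, 120.5


def _nerf(a: np.ndarray, b: np.ndarray, c: np.ndarray,
          bond: float, angle_deg: float, torsion_deg: float) -> np.ndarray:
    """Place atom d with |cd| = bond, angle(b,c,d) and torsion(a,b,c,d)."""
    ang = np.radians(angle_deg)
    tor = np.radians(torsion_deg)
    bc = c - b
    bc /= np.linalg.norm(bc)
    ab = b - a
    n = np.cross(ab, bc)
    n /= np.linalg.norm(n)
    m = np.cross(n, bc)
    d2 = bond * np.array([
        -np.cos(ang),
        np.sin(ang) * np.cos(tor),
        np.sin(ang) * np.sin(tor),
    ])
    return c + d2[0] * bc + d2[1] * m + d2[2] * n


def build_alpha_helix(n_residues: int, phi: float = -57.0, psi: float = -47.0,
                      omega: float = 180.0, chain: str = "A",
                      first_resid: int = 1, resname: str = "ALA",
                      n_frames: int = 1, dt_ns: float = 0.1) -> Trajectory:
    """Ideal alpha-helix backbone from internal coordinates (NeRF extension).

    Measured backbone dihedrals reproduce the requested phi/psi exactly, and
    the principal axis of the backbone is the helix axis (along which a
    canonical helix rises ~1.5 A per residue).
    """
    if n_residues < 2:
        raise ValidationError("need at least 2 residues")
    N = [np.array([0.0, 0.0, 0.0])]
    CA = [np.array([_B_N_CA, 0.0, 0.0])]
    ang = np.radians(_A_N_CA_C)
    C = [CA[0] + _B_CA_C * np.array([-np.cos(ang), np.sin(ang), 0.0])]
    for i in range(1, n_residues):
        N.append(_nerf(N[i - 1], CA[i - 1], C[i - 1], _B_C_N, _A_CA_C_N, psi))
        CA.append(_nerf(CA[i - 1], C[i - 1], N[i], _B_N_CA, _A_C_N_CA, omega))
        C.append(_nerf(C[i - 1], N[i], CA[i], _B_CA_C, _A_N_CA_C, phi))
    atoms: list[AtomRecord] = []
    coords: list[np.ndarray] = []
    serial = 1
    for i in range(n_residues):
        O = _nerf(N[i], CA[i], C[i], _B_C_O, _A_CA_C_O, psi + 180.0)
        for name, pos in (("N", N[i]), ("CA", CA[i]), ("C", C[i]), ("O", O)):
            atoms.append(AtomRecord(serial, name, name[0], resname,
                                    first_resid + i, chain, tuple(pos)))
            coords.append(pos)
            serial += 1
    top = Topology(atoms)
    base = np.array(coords)
    frames = np.tile(base, (n_frames, 1, 1))
    times = np.arange(n_frames) * dt_ns
    return Trajectory(top, frames, times, None)


# --------------------------------------------------------------------------- #
# correlated walks
# --------------------------------------------------------------------------- #

@dataclass(frozen=True)
class CorrelatedWalkSpec:
    """Pseudo-C-alpha ensemble with a prescribed displacement correlation."""

    n_residues: int
    target: object          # (n, n) symmetric PSD matrix, unit diagonal
    n_frames: int
    seed: int = 0
    step_sigma: float = 1.0  # displacement scale, A
    spacing: float = 3.8     # rest-position spacing along x, A
    dt_ns: float = 0.1

    def target_matrix(self) -> np.ndarray:
        t = np.asarray(self.target, dtype=float)
        if t.shape != (self.n_residues, self.n_residues):
            raise ValidationError("target matrix shape must be (n_residues, n_residues)")
        if not np.allclose(t, t.T, atol=1e-8):
            raise ValidationError("target correlation matrix must be symmetric")
        if not np.allclose(np.diag(t), 1.0, atol=1e-8):
            raise ValidationError("target correlation matrix must have unit diagonal")
        w = np.linalg.eigvalsh(t)
        if w.min() < -1e-8:
            raise ValidationError(
                f"target correlation matrix must be PSD (min eigenvalue {w.min():.2e})"
            )
        return t


def simulate_correlated_walk(spec: CorrelatedWalkSpec) -> Trajectory:
    """Per-frame displacements ~ N(0, sigma^2 C), i.i.d. across frames and
    across the three Cartesian dimensions, about fixed rest positions."""
    t = spec.target_matrix()
    rng = _rng(spec.seed)
    w, v = np.linalg.eigh(t)
    L = v @ np.diag(np.sqrt(np.clip(w, 0.0, None)))
    g = rng.normal(size=(spec.n_frames, 3, spec.n_residues))
    disp = spec.step_sigma * (g @ L.T)          # (n_frames, 3, n)
    base = np.zeros((spec.n_residues, 3))
    base[:, 0] = np.arange(spec.n_residues) * spec.spacing
    frames = base[None, :, :] + disp.transpose(0, 2, 1)
    atoms = [
        AtomRecord(i + 1, "CA", "C", "GLY", i + 1, "A", tuple(base[i]))
        for i in range(spec.n_residues)
    ]
    top = Topology(atoms)
    times = np.arange(spec.n_frames) * spec.dt_ns
    return Trajectory(top, frames, times, None)


# --------------------------------------------------------------------------- #
# salt-bridge engagement
# --------------------------------------------------------------------------- #

def simulate_bridge_engagement(
    n_frames: int,
    engagement_prob: float,
    n_pairs: int = 1,
    seed: int = 0,
    engaged_distance: float = 3.5,
    disengaged_distance: float = 6.0,
    dt_ns: float = 0.1,
) -> tuple[Trajectory, np.ndarray]:
    """Bernoulli lysine NZ / phosphate engagement at programmed probability.

    Each candidate pair sits at 3.5 A (engaged) or 6.0 A (disengaged) per an
    independent per-frame draw. Returns the trajectory and the boolean
    engagement table (n_frames, n_pairs); the coordinates reproduce the table
    under the standard 4.0 A salt-bridge cutoff.
    """
    if not (0.0 <= engagement_prob <= 1.0):
        raise ValidationError("engagement_prob must lie in [0, 1]")
    if n_frames < 1 or n_pairs < 1:
        raise ValidationError("n_frames and n_pairs must be >= 1")
    rng = _rng(seed)
    engaged = rng.random(size=(n_frames, n_pairs)) < engagement_prob
    atoms: list[AtomRecord] = []
    serial = 1
    for j in range(n_pairs):
        x0 = 20.0 * j
        atoms.append(AtomRecord(serial, "NZ", "N", "LYS", j + 1, "A",
                                (x0, 0.0, 0.0)))
        serial += 1
        atoms.append(AtomRecord(serial, "P2", "P", "PIP", j + 1, "P",
                                (x0 + disengaged_distance, 0.0, 0.0)))
        serial += 1
    top = Topology(atoms)
    frames = np.tile(top.positions, (n_frames, 1, 1))
    dist = np.where(engaged, engaged_distance, disengaged_distance)
    for j in range(n_pairs):
        frames[:, 2 * j + 1, 0] = 20.0 * j + dist[:, j]
    times = np.arange(n_frames) * dt_ns
    return Trajectory(top, frames, times, None), engaged


# --------------------------------------------------------------------------- #
# unit conversion
# --------------------------------------------------------------------------- #

def field_to_voltage(field_v_per_nm: float, thickness_angstrom: float) -> float:
    """Transmembrane potential (mV) of a constant field across a slab.

    ``field_v_per_nm`` in V/nm, ``thickness_angstrom`` in A; a 0.06 V/nm field
    across a 35 A membrane gives 210 mV.
    """
    if thickness_angstrom <= 0:
        raise ValidationError("membrane thickness must be positive")
    return field_v_per_nm * (thickness_angstrom / 10.0) * 1000.0
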