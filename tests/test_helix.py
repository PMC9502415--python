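"""Bend angles, inter-axis angles, dihedrals and Ramachandran regions."""

import numpy as np
import pytest

from poregate import (
    BendAngleDef,
    HelixSpec,
    SegmentSpec,
    Trajectory,
    axis_angle_series,
    backbone_dihedrals,
    bend_angle_series,
    build_alpha_helix,
    ramachandran_region,
    simulate_bent_helix,
)
from poregate.errors import ValidationError
from poregate.pipeline import _axis_pair_trajectory

from conftest import make_topology, single_frame


def _centroid_traj(outer, pivot, inner):
    """Three one-atom 'segments' whose backbone centroids are the given points."""
    records = [
        ("CA", "C", "ALA", 1, "A", outer),
        ("CA", "C", "ALA", 5, "A", pivot),
        ("CA", "C", "ALA", 9, "A", inner),
    ]
    top = make_topology(records)
    bend_def = BendAngleDef(SegmentSpec("A", 1, 1), SegmentSpec("A", 5, 5),
                            SegmentSpec("A", 9, 9))
    return single_frame(top), bend_def


def test_collinear_centroids_give_straight_angle():
    traj, bd = _centroid_traj((0, 0, 2), (0, 0, 1), (0, 0, 0))
    assert bend_angle_series(traj, bd).values[0] == pytest.approx(180.0)


def test_right_angle_centroids():
    traj, bd = _centroid_traj((0, 0, 0), (0, 0, 1), (1, 0, 1))
    assert bend_angle_series(traj, bd).values[0] == pytest.approx(90.0)


def _vertex_bend_def(spec: HelixSpec) -> BendAngleDef:
    q = spec.vertex_resid
    last = spec.first_resid + spec.n_residues - 1
    return BendAngleDef(
        SegmentSpec("A", spec.first_resid, spec.first_resid + 4),
        SegmentSpec("A", q, q),
        SegmentSpec("A", last - 4, last),
    )


@pytest.mark.parametrize("theta", [90.0, 120.0, 150.0, 165.0, 170.0, 177.0,
                                   180.0])
def test_noise_free_bend_recovered_exactly(theta):
    spec = HelixSpec(bend_deg=theta, noise_sigma=0.0)
    traj = simulate_bent_helix(spec)
    got = bend_angle_series(traj, _vertex_bend_def(spec)).values[0]
    assert got == pytest.approx(theta, abs=1e-8)


@pytest.mark.parametrize("theta", [165.0, 177.0])
def test_noisy_bend_within_two_degrees(theta):
    spec = HelixSpec(bend_deg=theta, noise_sigma=0.3, n_frames=60, seed=2)
    traj = simulate_bent_helix(spec)
    mean = bend_angle_series(traj, _vertex_bend_def(spec)).mean()
    assert mean == pytest.approx(theta, abs=2.0)


def test_bend_ordering_of_gating_states_preserved():
    """Activator-bent < apo < inhibitor-straightened."""
    means = []
    for theta in (165.0, 170.0, 177.0):
        spec = HelixSpec(bend_deg=theta, noise_sigma=0.3, n_frames=60, seed=6)
        traj = simulate_bent_helix(spec)
        means.append(bend_angle_series(traj, _vertex_bend_def(spec)).mean())
    assert means[0] < means[1] < means[2]


def test_three_residue_pivot_stays_within_tolerance():
    """The production-style pivot range (hinge +- 1 residue) introduces only a
    sub-degree geometric bias."""
    spec = HelixSpec(bend_deg=170.0, noise_sigma=0.0)
    q = spec.vertex_resid
    last = spec.first_resid + spec.n_residues - 1
    bd = BendAngleDef(
        SegmentSpec("A", spec.first_resid, spec.first_resid + 4),
        SegmentSpec("A", q - 1, q + 1),
        SegmentSpec("A", last - 4, last),
    )
    got = bend_angle_series(simulate_bent_helix(spec), bd).values[0]
    assert got == pytest.approx(170.0, abs=2.0)


def test_bend_invariant_under_rigid_motion_and_scaling():
    spec = HelixSpec(bend_deg=150.0, noise_sigma=0.0)
    traj = simulate_bent_helix(spec)
    bd = _vertex_bend_def(spec)
    ref = bend_angle_series(traj, bd).values[0]
    from scipy.spatial.transform import Rotation

    R = Rotation.from_euler("xyz", [0.5, 1.0, -0.7]).as_matrix()
    moved = Trajectory(traj.topology, (traj.frames @ R.T) * 2.5 + 7.0,
                       traj.times)
    assert bend_angle_series(moved, bd).values[0] == pytest.approx(ref,
                                                                   abs=1e-9)


def test_bend_def_requires_ordered_disjoint_segments():
    with pytest.raises(ValidationError):
        BendAngleDef(SegmentSpec("A", 1, 5), SegmentSpec("A", 4, 6),
                     SegmentSpec("A", 8, 9))


# --------------------------------------------------------------------------- #
# inter-axis angles
# --------------------------------------------------------------------------- #

@pytest.mark.parametrize("angle,tol", [(0.0, 0.5), (90.0, 0.5), (45.0, 1.0),
                                       (35.0, 1.0), (50.0, 1.0)])
def test_constructed_inter_axis_angle_recovered(angle, tol):
    traj = _axis_pair_trajectory(angle)
    series = axis_angle_series(traj, SegmentSpec("A", 1, 15),
                               SegmentSpec("B", 1, 15))
    assert series.values[0] == pytest.approx(angle, abs=tol)


def test_end_to_end_axis_method_agrees_for_parallel_helices():
    traj = _axis_pair_trajectory(0.0)
    series = axis_angle_series(traj, SegmentSpec("A", 1, 15),
                               SegmentSpec("B", 1, 15), method="end-to-end")
    assert series.values[0] == pytest.approx(0.0, abs=0.5)


def test_axis_angle_rejects_short_segments():
    traj = _axis_pair_trajectory(45.0)
    with pytest.raises(ValidationError):
        axis_angle_series(traj, SegmentSpec("A", 1, 3),
                          SegmentSpec("B", 1, 15))


# --------------------------------------------------------------------------- #
# dihedrals
# --------------------------------------------------------------------------- #

def test_ideal_helix_dihedrals_match_construction():
    traj = build_alpha_helix(10)
    for resid in (3, 5, 8):
        ds = backbone_dihedrals(traj, "A", resid)
        assert ds.phi[0] == pytest.approx(-57.0, abs=1.0)
        assert ds.psi[0] == pytest.approx(-47.0, abs=1.0)


def test_dihedral_agrees_with_mdanalysis_reference():
    """Cross-check the torsion computation against an independent library."""
    from MDAnalysis.lib.distances import calc_dihedrals

    traj = build_alpha_helix(8, phi=-64.0, psi=-41.0)
    top = traj.topology
    resid = 4
    c_prev = top.atom_indices(residue_index=resid - 1, names=["C"])[0]
    n = top.atom_indices(residue_index=resid, names=["N"])[0]
    ca = top.atom_indices(residue_index=resid, names=["CA"])[0]
    c = top.atom_indices(residue_index=resid, names=["C"])[0]
    ref = np.degrees(calc_dihedrals(
        traj.frames[0, c_prev][None], traj.frames[0, n][None],
        traj.frames[0, ca][None], traj.frames[0, c][None]))[0]
    ds = backbone_dihedrals(traj, "A", resid)
    # MDAnalysis computes in single precision
    assert ds.phi[0] == pytest.approx(ref, abs=1e-4)

    def torsion_reference(p0, p1, p2, p3):
        """Independent double-precision reference: signed angle between the
        two bond-plane normals."""
        b1, b2, b3 = p1 - p0, p2 - p1, p3 - p2
        n1 = np.cross(b1, b2)
        n2 = np.cross(b2, b3)
        cosang = n1 @ n2 / (np.linalg.norm(n1) * np.linalg.norm(n2))
        ang = np.degrees(np.arccos(np.clip(cosang, -1, 1)))
        if n1 @ b3 < 0:
            ang = -ang
        return ang

    ref64 = torsion_reference(traj.frames[0, c_prev], traj.frames[0, n],
                              traj.frames[0, ca], traj.frames[0, c])
    assert ds.phi[0] == pytest.approx(ref64, abs=1e-9)


def test_planar_trans_torsion_is_180():
    records = [
        ("C", "C", "ALA", 1, "A", (0.0, 1.0, 0.0)),
        ("N", "N", "ALA", 2, "A", (0.0, 0.0, 0.0)),
        ("CA", "C", "ALA", 2, "A", (1.0, 0.0, 0.0)),
        ("C", "C", "ALA", 2, "A", (1.0, -1.0, 0.0)),
        ("N", "N", "ALA", 3, "A", (2.0, -1.0, 0.0)),
    ]
    top = make_topology(records)
    traj = single_frame(top)
    ds = backbone_dihedrals(traj, "A", 2)
    assert abs(ds.phi[0]) == pytest.approx(180.0, abs=1e-9)


def test_terminal_residue_rejected():
    traj = build_alpha_helix(5)
    with pytest.raises(ValidationError):
        backbone_dihedrals(traj, "A", 1)


def test_psi_rotation_flagged_above_twenty_degrees():
    """A mid-run +25 degree psi shift at the hinge is detected."""
    a = build_alpha_helix(8, psi=-47.0, n_frames=3)
    b = build_alpha_helix(8, psi=-22.0, n_frames=3)
    frames = np.concatenate([a.frames, b.frames])
    traj = Trajectory(a.topology, frames, np.arange(6) * 0.1)
    ds = backbone_dihedrals(traj, "A", 4)
    dphi, dpsi = ds.max_abs_shift()
    assert dpsi >= 20.0
    assert dphi < 5.0


# --------------------------------------------------------------------------- #
# Ramachandran
# --------------------------------------------------------------------------- #

@pytest.mark.parametrize("phi,psi,expected", [
    (-60.0, -45.0, "favored"),    # canonical alpha helix
    (-120.0, 130.0, "favored"),   # canonical beta sheet
    (60.0, 60.0, "allowed"),      # left-handed helix box
    (-110.0, -75.0, "allowed"),   # dilated alpha margin
    (60.0, -120.0, "outlier"),
    (0.0, 0.0, "outlier"),
])
def test_ramachandran_rectangles(phi, psi, expected):
    assert ramachandran_region(phi, psi) == expected


def test_ramachandran_range_validation():
    with pytest.raises(ValidationError):
        ramachandran_region(-200.0, 0.0)
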