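"""Salt bridges, contacts and typed interaction distances."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from poregate import (
    CHARGE_CHARGE,
    DIPOLE_HBOND,
    PI_PI,
    Histogram,
    SaltBridgeSpec,
    Selection,
    TimeSeries,
    Trajectory,
    intersegment_contact_series,
    normalized_salt_bridge,
    pair_distance_distribution,
    pair_distance_series,
    salt_bridge_series,
    simulate_bridge_engagement,
    vdw_contact_cutoff,
)
from poregate.errors import ValidationError

from conftest import make_topology, single_frame


def _two_atom_traj(distance):
    top = make_topology([
        ("NZ", "N", "LYS", 1, "A", (0.0, 0.0, 0.0)),
        ("P2", "P", "PIP", 1, "P", (distance, 0.0, 0.0)),
    ])
    return top, single_frame(top)


@pytest.mark.parametrize("distance,expected", [(3.9, 1.0), (4.1, 0.0)])
def test_salt_bridge_cutoff_boundary(distance, expected):
    top, traj = _two_atom_traj(distance)
    spec = SaltBridgeSpec(Selection((0,)), Selection((1,)))
    series = salt_bridge_series(traj, spec)
    assert series.values[0] == expected


def test_salt_bridge_counts_match_bruteforce_oracle():
    rng = np.random.default_rng(31)
    n_basic, n_acc, n_frames = 12, 32, 5
    records = [("NZ", "N", "LYS", i + 1, "A", (0, 0, 0)) for i in range(n_basic)]
    records += [("O1" + str(1 + i % 6), "O", "PIP", i + 1, "P", (0, 0, 0))
                for i in range(n_acc)]
    top = make_topology(records)
    frames = rng.uniform(0, 15, size=(n_frames, n_basic + n_acc, 3))
    traj = Trajectory(top, frames, np.arange(n_frames) * 0.1)
    spec = SaltBridgeSpec(Selection(tuple(range(n_basic))),
                          Selection(tuple(range(n_basic, n_basic + n_acc))))
    series = salt_bridge_series(traj, spec)
    for f in range(n_frames):
        expected = 0
        for b in range(n_basic):
            dmin = min(np.linalg.norm(frames[f, b] - frames[f, a])
                       for a in range(n_basic, n_basic + n_acc))
            expected += dmin <= 4.0
        assert series.values[f] == expected


def test_minimum_image_applies_for_wrapped_coordinates():
    """Atoms wrapped to opposite box faces are actually close."""
    top = make_topology([
        ("NZ", "N", "LYS", 1, "A", (1.0, 0.0, 0.0)),
        ("P2", "P", "PIP", 1, "P", (29.0, 0.0, 0.0)),
    ])
    traj = single_frame(top, box=(30.0, 30.0, 30.0))
    spec = SaltBridgeSpec(Selection((0,)), Selection((1,)))
    assert salt_bridge_series(traj, spec).values[0] == 1.0  # 2 A via image


def test_normalized_fold_change_identity_and_validation():
    ts = TimeSeries(np.arange(4.0), np.array([1.0, 2.0, 1.0, 2.0]))
    norm, fold = normalized_salt_bridge(ts, 3, reference=1.5 / 3)
    assert norm == pytest.approx(0.5)
    assert fold == pytest.approx(1.0)
    with pytest.raises(ValidationError):
        normalized_salt_bridge(ts, 3, reference=0.0)
    with pytest.raises(ValidationError):
        normalized_salt_bridge(ts, 0)


@pytest.mark.parametrize("prob,fold_expected", [(0.6, 1.2), (0.4, 0.8)])
def test_programmed_fold_changes_recovered(prob, fold_expected):
    traj, _ = simulate_bridge_engagement(10000, prob, n_pairs=3, seed=23)
    basic = Selection(tuple(range(0, 6, 2)))
    acceptors = Selection(tuple(range(1, 6, 2)))
    series = salt_bridge_series(traj, SaltBridgeSpec(basic, acceptors))
    norm, fold = normalized_salt_bridge(series, 3, reference=0.5)
    assert fold == pytest.approx(fold_expected, abs=0.03)


# --------------------------------------------------------------------------- #
# contacts
# --------------------------------------------------------------------------- #

@pytest.mark.parametrize("distance,expected", [(3.9, 1.0), (4.1, 0.0)])
def test_contact_cutoff_boundary(distance, expected):
    top = make_topology([
        ("CB", "C", "ALA", 1, "A", (0.0, 0.0, 0.0)),
        ("CB", "C", "ALA", 2, "A", (distance, 0.0, 0.0)),
    ])
    traj = single_frame(top)
    series = intersegment_contact_series(
        traj, Selection((0,)), Selection((1,)))
    assert series.values[0] == expected


def test_contact_totals_match_double_loop_and_rotation():
    rng = np.random.default_rng(7)
    na, nb = 50, 60
    records = [("CB", "C", "ALA", i + 1, "A", (0, 0, 0)) for i in range(na)]
    records += [("CB", "C", "ALA", i + 1, "B", (0, 0, 0)) for i in range(nb)]
    top = make_topology(records)
    coords = rng.uniform(0, 12, size=(na + nb, 3))
    traj = Trajectory(top, coords[None], np.array([0.0]))
    sa = Selection(tuple(range(na)))
    sb = Selection(tuple(range(na, na + nb)))
    got = intersegment_contact_series(traj, sa, sb, cutoff=4.0).values[0]
    expected = sum(
        np.linalg.norm(coords[i] - coords[j]) <= 4.0
        for i in range(na) for j in range(na, na + nb)
    )
    assert got == expected

    from scipy.spatial.transform import Rotation

    R = Rotation.from_euler("zyx", [0.7, -0.2, 1.9]).as_matrix()
    rotated = Trajectory(top, (coords @ R.T + 3.0)[None], np.array([0.0]))
    assert intersegment_contact_series(
        rotated, sa, sb, cutoff=4.0).values[0] == expected


def test_overlapping_contact_selections_rejected():
    top = make_topology([("CB", "C", "ALA", i + 1, "A", (i, 0, 0))
                         for i in range(3)])
    traj = single_frame(top)
    with pytest.raises(ValidationError, match="disjoint"):
        intersegment_contact_series(traj, Selection((0, 1)), Selection((1, 2)))


def test_vdw_cutoff_is_twice_the_smallest_radius():
    assert vdw_contact_cutoff() == pytest.approx(3.0)
    assert vdw_contact_cutoff(1.7) == pytest.approx(3.4)


# --------------------------------------------------------------------------- #
# typed pair distances
# --------------------------------------------------------------------------- #

def _phenyl_ring(chain, resid, center, radius=1.39):
    """Planar six-membered ring around a centroid."""
    names = ("CG", "CD1", "CD2", "CE1", "CE2", "CZ")
    records = [("CB", "C", "PHE", resid, chain,
                (center[0], center[1] - 2.5, center[2]))]
    for k, name in enumerate(names):
        ang = 2 * np.pi * k / 6
        records.append((name, "C", "PHE", resid, chain,
                        (center[0] + radius * np.cos(ang),
                         center[1] + radius * np.sin(ang), center[2])))
    return records


def test_pi_pi_uses_ring_centroids():
    records = _phenyl_ring("A", 10, (0.0, 0.0, 0.0))
    records += _phenyl_ring("A", 20, (0.0, 0.0, 3.5))
    top = make_topology(records)
    traj = single_frame(top)
    hist, engaged = pair_distance_distribution(
        traj, ("A", 10), ("A", 20), PI_PI)
    series = pair_distance_series(traj, ("A", 10), ("A", 20), PI_PI)
    assert series.values[0] == pytest.approx(3.5, abs=1e-9)
    assert engaged == 1.0


def test_pi_pi_rejects_nonaromatic_residue():
    records = _phenyl_ring("A", 10, (0.0, 0.0, 0.0))
    records += [("CB", "C", "ALA", 20, "A", (0.0, 0.0, 4.0))]
    top = make_topology(records)
    traj = single_frame(top)
    with pytest.raises(ValidationError, match="no aromatic ring"):
        pair_distance_series(traj, ("A", 10), ("A", 20), PI_PI)


def test_dipole_pair_beyond_cutoff_is_disengaged():
    records = [
        ("OD1", "O", "ASP", 5, "A", (0.0, 0.0, 0.0)),
        ("CB", "C", "ASP", 5, "A", (0.0, 1.5, 0.0)),
        ("NE1", "N", "TRP", 9, "A", (6.5, 0.0, 0.0)),
        ("CB", "C", "TRP", 9, "A", (8.0, 0.0, 0.0)),
    ]
    top = make_topology(records)
    traj = single_frame(top)
    _, engaged = pair_distance_distribution(traj, ("A", 5), ("A", 9),
                                            DIPOLE_HBOND)
    assert engaged == 0.0


def test_distance_histogram_matches_per_frame_oracle():
    rng = np.random.default_rng(3)
    n_frames = 40
    records = [
        ("OD1", "O", "ASP", 5, "A", (0, 0, 0)),
        ("OD2", "O", "ASP", 5, "A", (0, 0, 0)),
        ("CB", "C", "ASP", 5, "A", (0, 0, 0)),
        ("NZ", "N", "LYS", 9, "A", (0, 0, 0)),
        ("CB", "C", "LYS", 9, "A", (0, 0, 0)),
    ]
    top = make_topology(records)
    frames = rng.uniform(0, 8, size=(n_frames, 5, 3))
    traj = Trajectory(top, frames, np.arange(n_frames) * 0.1)
    hist, engaged = pair_distance_distribution(traj, ("A", 5), ("A", 9),
                                               CHARGE_CHARGE)
    # oracle: per-frame min over sidechain-heavy atoms
    # (ASP: OD1, OD2, CB = indices 0-2; LYS: NZ, CB = indices 3-4)
    dists = [
        min(np.linalg.norm(frames[f, i] - frames[f, j])
            for i in (0, 1, 2) for j in (3, 4))
        for f in range(n_frames)
    ]
    edges = np.arange(0.0, 12.25, 0.25)
    expected_counts, _ = np.histogram(dists, bins=edges)
    np.testing.assert_array_equal(hist.counts, expected_counts)
    assert engaged == pytest.approx(np.mean(np.array(dists) <= 4.0))


@settings(max_examples=30, deadline=None, derandomize=True)
@given(st.lists(st.floats(0.5, 11.5), min_size=5, max_size=40),
       st.floats(0.5, 11.0), st.floats(0.0, 1.0))
def test_engaged_fraction_monotone_in_cutoff(distances, cutoff, bump):
    """Raising a cutoff can only add engaged frames."""
    values = np.asarray(distances)
    frac_lo = float(np.mean(values <= cutoff))
    frac_hi = float(np.mean(values <= cutoff + bump))
    assert frac_hi >= frac_lo


def test_histogram_invariants():
    h = Histogram.from_values(np.array([0.1, 0.3, 5.0]),
                              np.arange(0.0, 12.25, 0.25))
    assert h.n == 3
    with pytest.raises(ValidationError):
        Histogram(np.array([1.0, 1.0]), np.array([0]))
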