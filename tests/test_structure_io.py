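"""Structure/trajectory I/O, role map, selection grammar and windows."""

import numpy as np
import pytest

from poregate import (
    AnalysisWindow,
    AtomRecord,
    ResidueRoleMap,
    SubunitAssignment,
    Topology,
    Trajectory,
    lookup_role,
    read_structure,
    read_trajectory,
    resolve_selection,
    write_structure,
    write_trajectory,
)
from poregate.errors import (
    FormatError,
    RoleLookupError,
    SelectionSyntaxError,
    ValidationError,
)

from conftest import make_topology, pdb_atom_line


# --------------------------------------------------------------------------- #
# PDB and fixture formats
# --------------------------------------------------------------------------- #

def test_read_single_atom_pdb(tmp_path):
    p = tmp_path / "one.pdb"
    p.write_text(pdb_atom_line(1, "CA", "ALA", "A", 5, 1.0, 2.0, 3.0) + "\nEND\n")
    top, coords = read_structure(p, "pdb")
    assert top.n_atoms == 1
    a = top.atoms[0]
    assert (a.name, a.residue_name, a.chain_id, a.residue_index) == \
        ("CA", "ALA", "A", 5)
    np.testing.assert_allclose(coords[0], [1.0, 2.0, 3.0], atol=1e-6)


def test_duplicate_atom_key_rejected(tmp_path):
    p = tmp_path / "dup.pdb"
    lines = [
        pdb_atom_line(1, "CA", "ALA", "A", 5, 0.0, 0.0, 0.0),
        pdb_atom_line(2, "CA", "ALA", "A", 5, 1.0, 0.0, 0.0),
    ]
    p.write_text("\n".join(lines) + "\n")
    with pytest.raises(ValidationError, match="duplicate"):
        read_structure(p, "pdb")


def test_malformed_pdb_line_reports_line_number(tmp_path):
    p = tmp_path / "bad.pdb"
    p.write_text(
        pdb_atom_line(1, "CA", "ALA", "A", 1, 0.0, 0.0, 0.0)
        + "\nATOM      2  CB  ALA A   1        bad   0.000   0.000\n"
    )
    with pytest.raises(FormatError, match="line 2"):
        read_structure(p, "pdb")


@pytest.mark.parametrize("fmt", ["pdb", "fixture-text"])
def test_structure_round_trip_preserves_positions(tmp_path, fmt):
    rng = np.random.default_rng(1)
    records = []
    for i in range(50):
        records.append(("CA", "C", "ALA", i + 1, "A", rng.uniform(-50, 50, 3)))
    top = make_topology(records)
    path = tmp_path / f"round.{fmt.split('-')[0]}"
    write_structure(top, path, fmt)
    top2, coords = read_structure(path, fmt)
    assert top2.n_atoms == 50
    np.testing.assert_allclose(coords, top.positions, atol=1e-3)


@pytest.mark.parametrize("fmt", ["fixture-text", "dcd"])
def test_trajectory_round_trip(tmp_path, fmt):
    rng = np.random.default_rng(2)
    top = make_topology(
        [("CA", "C", "ALA", i + 1, "A", (0, 0, 0)) for i in range(7)]
    )
    frames = rng.uniform(-30, 30, size=(5, 7, 3))
    traj = Trajectory(top, frames, np.arange(5) * 0.5,
                      np.tile([60.0, 60.0, 60.0], (5, 1)))
    path = tmp_path / ("t.txt" if fmt == "fixture-text" else "t.dcd")
    write_trajectory(traj, path, fmt)
    back = read_trajectory(top, path, fmt, dt_ns=0.5)
    assert back.n_frames == 5
    np.testing.assert_allclose(back.frames, frames, atol=1e-3)
    np.testing.assert_allclose(back.box[0], [60.0, 60.0, 60.0], atol=1e-3)


def test_trajectory_invariants():
    top = make_topology([("CA", "C", "ALA", 1, "A", (0, 0, 0))])
    with pytest.raises(ValidationError):
        Trajectory(top, np.zeros((2, 2, 3)), np.array([0.0, 1.0]))
    with pytest.raises(ValidationError):  # non-monotone times
        Trajectory(top, np.zeros((2, 1, 3)), np.array([1.0, 1.0]))


# --------------------------------------------------------------------------- #
# role map
# --------------------------------------------------------------------------- #

ROLE_TABLE = [
    ("HBC-gate", "GIRK1", (181,)),
    ("HBC-gate", "GIRK2", (192,)),
    ("G-loop-gate", "GIRK2", (313, 319)),
    ("hinge-glycine", "GIRK1", (169,)),
    ("hinge-glycine", "GIRK2", (180,)),
    ("hinge-glycine", "GIRK4", (175,)),
    ("PIP2-lysines", "GIRK1", (183, 188, 189)),
    ("PIP2-lysines", "GIRK2", (194, 199, 200)),
    ("PIP2-lysines", "GIRK4", (189, 194, 195)),
    ("TM1-wire", "GIRK1", (87, 91, 95)),
    ("pore-helix-pair", "GIRK1", (141, 137)),
    ("TM2-acidic", "GIRK1", (173,)),
    ("pre-gate-Met", "GIRK1", (180,)),
    ("SH-acids", "GIRK1", (70, 77)),
    ("CD-loop", "GIRK2", (230, 233)),
    ("ligand-source", "GIRK1", (97,)),
]


@pytest.mark.parametrize("role,subunit,expected", ROLE_TABLE)
def test_default_role_map_residues(roles, role, subunit, expected):
    assert lookup_role(roles, role, subunit) == expected


SEGMENT_TABLE = [
    ("TM1", "GIRK1", (82, 105)),
    ("SH", "GIRK1", (67, 76)),
    ("PH", "GIRK1", (130, 142)),
    ("TM2-outer", "GIRK1", (158, 162)),
    ("TM2-pivot", "GIRK1", (167, 169)),
    ("TM2-inner", "GIRK1", (174, 178)),
]


@pytest.mark.parametrize("role,subunit,rng", SEGMENT_TABLE)
def test_default_role_map_segments(roles, role, subunit, rng):
    assert roles.segment(role) == (subunit, rng)


def test_gate_hinge_register_is_twelve(roles):
    """The hinge glycine sits i-12 from the HBC gate Phe on every subunit."""
    for sub in ("GIRK1", "GIRK2", "GIRK4"):
        gate = lookup_role(roles, "HBC-gate", sub)[0]
        hinge = lookup_role(roles, "hinge-glycine", sub)[0]
        assert gate - hinge == 12


def test_lookup_role_errors(roles):
    with pytest.raises(RoleLookupError):
        lookup_role(roles, "hinge-glycine", "GIRK9")
    with pytest.raises(RoleLookupError):
        lookup_role(roles, "no-such-role", "GIRK1")
    with pytest.raises(RoleLookupError):
        lookup_role(roles, "CD-loop", "GIRK1")  # defined for GIRK2 only


# --------------------------------------------------------------------------- #
# selections
# --------------------------------------------------------------------------- #

def test_pip2_lysine_selection(toy_girk_topology, roles):
    assignment = SubunitAssignment({"A": "GIRK1", "B": "GIRK2"})
    sel = resolve_selection(toy_girk_topology,
                            "role:PIP2-lysines subunit:GIRK1 name:NZ",
                            assignment, roles)
    picked = [(toy_girk_topology.atoms[i].residue_index,
               toy_girk_topology.atoms[i].name) for i in sel.atom_indices]
    assert picked == [(183, "NZ"), (188, "NZ"), (189, "NZ")]


def test_empty_resid_range_selects_nothing(toy_girk_topology):
    sel = resolve_selection(toy_girk_topology, "resid 90-89")
    assert len(sel) == 0


def test_selection_is_deterministic_and_sorted(random_topology):
    expr = "(name:CA or name:CB) and resid 3-8"
    a = resolve_selection(random_topology, expr)
    b = resolve_selection(random_topology, expr)
    assert a.atom_indices == b.atom_indices
    assert list(a.atom_indices) == sorted(a.atom_indices)


def test_selection_matches_bruteforce_predicates(random_topology, roles):
    """Compound boolean expressions agree with per-atom predicate evaluation."""
    assignment = SubunitAssignment({"A": "GIRK1", "B": "GIRK2"})
    cases = [
        (
            "name:CA,CB or (chain:B and resid 2-5)",
            lambda a: a.name in ("CA", "CB")
            or (a.chain_id == "B" and 2 <= a.residue_index <= 5),
        ),
        (
            "scope:sidechain-heavy chain:A",
            lambda a: a.chain_id == "A"
            and a.name not in ("N", "CA", "C", "O")
            and not a.name.startswith("H"),
        ),
        (
            "resname:LYS name:NZ or element:O",
            lambda a: (a.residue_name == "LYS" and a.name == "NZ")
            or a.element == "O",
        ),
        (
            "subunit:GIRK1 scope:backbone resid 1-4",
            lambda a: a.chain_id == "A" and a.name in ("N", "CA", "C", "O")
            and a.residue_index <= 4,
        ),
    ]
    for expr, predicate in cases:
        sel = resolve_selection(random_topology, expr, assignment, roles)
        expected = [i for i, a in enumerate(random_topology.atoms) if predicate(a)]
        assert list(sel.atom_indices) == expected, expr


def test_selection_errors(toy_girk_topology, roles):
    assignment = SubunitAssignment({"A": "GIRK1"})
    with pytest.raises(SelectionSyntaxError):
        resolve_selection(toy_girk_topology, "name:CA and (resid 1-2")
    with pytest.raises(RoleLookupError):
        resolve_selection(toy_girk_topology, "role:bogus", assignment, roles)
    with pytest.raises(RoleLookupError):
        resolve_selection(toy_girk_topology, "chain:Z")


# --------------------------------------------------------------------------- #
# subunit assignment and windows
# --------------------------------------------------------------------------- #

def test_channel_assignment_invariants():
    SubunitAssignment.alternating().validate_channel()
    with pytest.raises(ValidationError):
        SubunitAssignment({"A": "GIRK1"}).validate_channel()
    with pytest.raises(ValidationError):
        SubunitAssignment(
            {c: "GIRK2" for c in "ABCD"}
        ).validate_channel()
    with pytest.raises(ValidationError):
        SubunitAssignment({"A": "KIR6"})


def test_window_selects_half_open_interval():
    top = make_topology([("CA", "C", "ALA", 1, "A", (0, 0, 0))])
    times = np.arange(10) * 1.0
    traj = Trajectory(top, np.zeros((10, 1, 3)), times)
    w = AnalysisWindow(3.0, 7.0)
    assert list(np.flatnonzero(w.frame_mask(times))) == [3, 4, 5, 6]
    last = AnalysisWindow.last_5_ns(traj)
    assert list(np.flatnonzero(last.frame_mask(times))) == [4, 5, 6, 7, 8, 9]
    with pytest.raises(ValidationError):
        AnalysisWindow(5.0, 5.0)
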