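"""Shared fixtures: toy topologies and small format helpers.

All fixtures are generated programmatically; nothing binary is stored.
"""

from __future__ import annotations

import numpy as np
import pytest

from poregate import (
    AtomRecord,
    ResidueRoleMap,
    SubunitAssignment,
    Topology,
    Trajectory,
)


def pdb_atom_line(serial, name, resname, chain, resid, x, y, z, element="C"):
    """One standard-column ATOM record."""
    return (
        f"ATOM  {serial:5d} {name:<4} {resname:>3} {chain}{resid:4d}    "
        f"{x:8.3f}{y:8.3f}{z:8.3f}  1.00  0.00          {element:>2}"
    )


def make_topology(records):
    """records: iterable of (name, element, resname, resid, chain, xyz)."""
    atoms = [
        AtomRecord(i + 1, name, element, resname, resid, chain, tuple(xyz))
        for i, (name, element, resname, resid, chain, xyz) in enumerate(records)
    ]
    return Topology(atoms)


def single_frame(topology, box=None):
    box_arr = None if box is None else np.asarray(box, dtype=float)[None, :]
    return Trajectory(topology, topology.positions[None, :, :],
                      np.array([0.0]), box_arr)


@pytest.fixture(scope="session")
def roles():
    return ResidueRoleMap.default()


@pytest.fixture(scope="session")
def assignment():
    return SubunitAssignment.alternating()


@pytest.fixture()
def toy_girk_topology():
    """A miniature two-chain channel fragment: a GIRK1 chain (A) with the
    PIP2 lysine triplet, the HBC Phe and the hinge Gly, and a GIRK2 chain (B)
    with one lysine — enough to exercise roles and selections."""
    records = []
    x = 0.0
    for resid in (183, 188, 189):
        records += [
            ("CA", "C", "LYS", resid, "A", (x, 0.0, 0.0)),
            ("CB", "C", "LYS", resid, "A", (x, 1.5, 0.0)),
            ("NZ", "N", "LYS", resid, "A", (x, 4.0, 0.0)),
        ]
        x += 10.0
    records += [
        ("CA", "C", "PHE", 181, "A", (x, 0.0, 0.0)),
        ("CB", "C", "PHE", 181, "A", (x, 1.5, 0.0)),
        ("CA", "C", "GLY", 169, "A", (x + 5.0, 0.0, 0.0)),
        ("CA", "C", "LYS", 194, "B", (x + 10.0, 0.0, 0.0)),
        ("NZ", "N", "LYS", 194, "B", (x + 10.0, 4.0, 0.0)),
    ]
    return make_topology(records)


@pytest.fixture()
def random_topology():
    """200 atoms over two chains with varied names for selection-oracle tests."""
    rng = np.random.default_rng(42)
    names = ["N", "CA", "C", "O", "CB", "CG", "NZ", "OD1", "HA", "HB2"]
    elements = {"N": "N", "CA": "C", "C": "C", "O": "O", "CB": "C", "CG": "C",
                "NZ": "N", "OD1": "O", "HA": "H", "HB2": "H"}
    resnames = ["ALA", "LYS", "ASP", "PHE", "GLY"]
    records = []
    serial = 0
    for chain in "AB":
        for resid in range(1, 11):
            resname = resnames[(resid + (chain == "B")) % len(resnames)]
            for name in names:
                serial += 1
                records.append(
                    (name, elements[name], resname, resid, chain,
                     rng.uniform(-20, 20, 3))
                )
    return make_topology(records)
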