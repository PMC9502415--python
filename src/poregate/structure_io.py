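"""Structures, trajectories, subunit roles and atom selections.

This module defines the in-memory containers every analysis stage consumes:

* :class:`Topology` — an ordered list of :class:`AtomRecord` with chain ranges;
* :class:`Trajectory` — frames (angstrom) with per-frame times (ns) and an
  optional orthorhombic box;
* :class:`SubunitAssignment` — chain id -> GIRK subunit type for heterotetramer
  analyses (GIRK1/2 neuronal, GIRK1/4 atrial);
* :class:`ResidueRoleMap` — the named functional residues of the channel
  (HBC and G-loop gates, hinge glycines, PIP2-binding lysines, the TM1
  hydrophobic wire, slide-helix acids, CD loop, ...) in canonical UniProt
  numbering, plus the helix segments used for bend/axis geometry;
* a small selection grammar (``resolve_selection``) combining subunit, role,
  chain, residue-range, atom-name and atom-scope terms with and/or.

File formats: PDB via biotite, DCD/XTC via MDAnalysis coordinate readers, and
a plain-text fixture format (bit-stable, used throughout the test suite):

* fixture structure — first line ``natoms``; then one line per atom:
  ``serial name element resname resid chain x y z``.
* fixture trajectory — first line ``natoms nframes [dt_ns [bx by bz]]``; then
  ``nframes`` blocks of ``natoms`` lines ``x y z``. When the box triple is
  omitted, minimum-image wrapping is disabled downstream.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np

from .errors import (
    FormatError,
    RoleLookupError,
    SelectionSyntaxError,
    ValidationError,
)

SUBUNIT_TYPES = ("GIRK1", "GIRK2", "GIRK4")

BACKBONE_NAMES = frozenset({"N", "CA", "C", "O"})


# --------------------------------------------------------------------------- #
# core containers
# --------------------------------------------------------------------------- #

@dataclass(frozen=True)
class AtomRecord:
    """One atom: identity plus a position in angstroms."""

    serial: int
    name: str
    element: str
    residue_name: str
    residue_index: int
    chain_id: str
    position: tuple[float, float, float]

    def __post_init__(self):
        if self.serial <= 0:
            raise ValidationError(f"atom serial must be positive, got {self.serial}")
        if not all(math.isfinite(x) for x in self.position):
            raise ValidationError(f"non-finite position for atom {self.serial}")

    @property
    def is_hydrogen(self) -> bool:
        if self.element:
            return self.element.upper() == "H"
        return _element_from_name(self.name) == "H"

    @property
    def is_backbone(self) -> bool:
        return self.name in BACKBONE_NAMES

    @property
    def is_sidechain_heavy(self) -> bool:
        return not self.is_backbone and not self.is_hydrogen


def _element_from_name(name: str) -> str:
    """Guess the element from a PDB atom name (first alphabetic character)."""
    stripped = name.strip().lstrip("0123456789")
    return stripped[:1].upper() if stripped else "X"


class Topology:
    """Ordered atom list with per-chain contiguous residue ranges.

    Atom order is stable: every Selection indexes into ``self.atoms`` and the
    same indices address trajectory frames.
    """

    def __init__(self, atoms: Sequence[AtomRecord]):
        self.atoms: tuple[AtomRecord, ...] = tuple(atoms)
        seen: set[tuple[str, int, str]] = set()
        for a in self.atoms:
            key = (a.chain_id, a.residue_index, a.name)
            if key in seen:
                raise ValidationError(
                    f"duplicate atom (chain {a.chain_id}, resid {a.residue_index}, "
                    f"name {a.name})"
                )
            seen.add(key)
        # vectorised views used by selections and distance code
        self.names = np.array([a.name for a in self.atoms], dtype=object)
        self.resnames = np.array([a.residue_name for a in self.atoms], dtype=object)
        self.resids = np.array([a.residue_index for a in self.atoms], dtype=int)
        self.chain_ids = np.array([a.chain_id for a in self.atoms], dtype=object)
        self.positions = np.array(
            [a.position for a in self.atoms], dtype=float
        ).reshape(len(self.atoms), 3)
        self.chains: dict[str, tuple[int, int]] = {}
        for a in self.atoms:
            lo, hi = self.chains.get(a.chain_id, (a.residue_index, a.residue_index))
            self.chains[a.chain_id] = (
                min(lo, a.residue_index),
                max(hi, a.residue_index),
            )

    def __len__(self) -> int:
        return len(self.atoms)

    @property
    def n_atoms(self) -> int:
        return len(self.atoms)

    def atom_indices(
        self,
        chain_id: str | None = None,
        residue_index: int | None = None,
        names: Iterable[str] | None = None,
    ) -> np.ndarray:
        mask = np.ones(len(self.atoms), dtype=bool)
        if chain_id is not None:
            mask &= self.chain_ids == chain_id
        if residue_index is not None:
            mask &= self.resids == residue_index
        if names is not None:
            nameset = set(names)
            mask &= np.array([n in nameset for n in self.names])
        return np.flatnonzero(mask)


@dataclass
class Trajectory:
    """Coordinate frames (n_frames, n_atoms, 3) in angstroms, times in ns."""

    topology: Topology
    frames: np.ndarray
    times: np.ndarray
    box: np.ndarray | None = None  # per-frame (n_frames, 3) orthorhombic lengths

    def __post_init__(self):
        self.frames = np.asarray(self.frames, dtype=float)
        self.times = np.asarray(self.times, dtype=float)
        if self.frames.ndim != 3 or self.frames.shape[2] != 3:
            raise ValidationError("frames must have shape (n_frames, n_atoms, 3)")
        if self.frames.shape[0] < 1:
            raise ValidationError("a trajectory needs at least one frame")
        if self.frames.shape[1] != self.topology.n_atoms:
            raise ValidationError(
                f"frame atom count {self.frames.shape[1]} != topology atom count "
                f"{self.topology.n_atoms}"
            )
        if self.times.shape != (self.frames.shape[0],):
            raise ValidationError("times must have one entry per frame")
        if np.any(np.diff(self.times) <= 0):
            raise ValidationError("frame times must be strictly increasing")
        if self.box is not None:
            self.box = np.asarray(self.box, dtype=float)
            if self.box.shape == (3,):
                self.box = np.tile(self.box, (self.n_frames, 1))
            if self.box.shape != (self.n_frames, 3):
                raise ValidationError("box must be (3,) or (n_frames, 3)")

    @property
    def n_frames(self) -> int:
        return int(self.frames.shape[0])

    @property
    def n_atoms(self) -> int:
        return int(self.frames.shape[1])

    def box_at(self, frame: int) -> np.ndarray | None:
        return None if self.box is None else self.box[frame]


@dataclass(frozen=True)
class AnalysisWindow:
    """Half-open time window [start_ns, end_ns)."""

    start_ns: float
    end_ns: float

    def __post_init__(self):
        if not (0 <= self.start_ns < self.end_ns):
            raise ValidationError(
                f"window requires 0 <= start < end, got [{self.start_ns}, {self.end_ns})"
            )

    @classmethod
    def last_ns(cls, traj: "Trajectory", span_ns: float) -> "AnalysisWindow":
        """The trailing ``span_ns`` of a trajectory (clipped at t=0).

        The window is half-open on the right but constructed so the final frame
        is included: end is nudged past the last time stamp.
        """
        end = float(traj.times[-1])
        eps = max(1e-9, 1e-9 * abs(end))
        return cls(max(0.0, end - span_ns), end + eps)

    # presets the analyses default to
    @classmethod
    def last_150_ns(cls, traj: "Trajectory") -> "AnalysisWindow":
        return cls.last_ns(traj, 150.0)

    @classmethod
    def last_250_ns(cls, traj: "Trajectory") -> "AnalysisWindow":
        return cls.last_ns(traj, 250.0)

    @classmethod
    def last_5_ns(cls, traj: "Trajectory") -> "AnalysisWindow":
        return cls.last_ns(traj, 5.0)

    def frame_mask(self, times: np.ndarray) -> np.ndarray:
        times = np.asarray(times, dtype=float)
        return (times >= self.start_ns) & (times < self.end_ns)


def window_frames(traj: Trajectory, window: AnalysisWindow | None) -> np.ndarray:
    """Frame indices selected by ``window`` (all frames when window is None)."""
    if window is None:
        return np.arange(traj.n_frames)
    idx = np.flatnonzero(window.frame_mask(traj.times))
    if idx.size == 0:
        raise ValidationError(
            f"window [{window.start_ns}, {window.end_ns}) ns selects no frames"
        )
    return idx


@dataclass(frozen=True)
class SubunitAssignment:
    """chain id -> subunit type (GIRK1 / GIRK2 / GIRK4)."""

    mapping: Mapping[str, str]

    def __post_init__(self):
        for chain, sub in self.mapping.items():
            if sub not in SUBUNIT_TYPES:
                raise ValidationError(
                    f"unknown subunit type {sub!r} for chain {chain!r}; "
                    f"expected one of {SUBUNIT_TYPES}"
                )

    def subunit_of(self, chain_id: str) -> str:
        try:
            return self.mapping[chain_id]
        except KeyError:
            raise RoleLookupError(f"chain {chain_id!r} has no subunit assignment")

    def chains_of(self, subunit: str) -> list[str]:
        return sorted(c for c, s in self.mapping.items() if s == subunit)

    def validate_channel(self) -> None:
        """Invariants for a tetrameric channel analysis."""
        if len(self.mapping) != 4:
            raise ValidationError(
                f"a channel analysis needs exactly 4 assigned chains, got "
                f"{len(self.mapping)}"
            )
        if "GIRK1" not in self.mapping.values():
            raise ValidationError("a GIRK1-containing channel needs >= 1 GIRK1 chain")

    @classmethod
    def alternating(cls, partner: str = "GIRK2",
                    chains: Sequence[str] = ("A", "B", "C", "D")) -> "SubunitAssignment":
        """Default convention: GIRK1 and the partner subunit alternate around
        the pore (the 2:2 arrangement is user-overridable)."""
        return cls({c: ("GIRK1" if i % 2 == 0 else partner)
                    for i, c in enumerate(chains)})


@dataclass(frozen=True)
class ResidueRoleMap:
    """Named functional residues and helix segments in canonical numbering.

    ``residues`` maps a role name to ((subunit, resid), ...); ``segments`` maps
    a role name to (subunit, (first_resid, last_resid)) inclusive.
    """

    residues: Mapping[str, tuple[tuple[str, int], ...]]
    segments: Mapping[str, tuple[str, tuple[int, int]]]

    def lookup(self, role_name: str, subunit: str) -> tuple[int, ...]:
        """Canonical residue indices of ``role_name`` on ``subunit``."""
        if subunit not in SUBUNIT_TYPES:
            raise RoleLookupError(f"unknown subunit type {subunit!r}")
        entries = self.residues.get(role_name)
        if entries is None:
            if role_name in self.segments:
                seg_sub, (lo, hi) = self.segments[role_name]
                if seg_sub != subunit:
                    raise RoleLookupError(
                        f"segment role {role_name!r} is defined for {seg_sub}, "
                        f"not {subunit}"
                    )
                return tuple(range(lo, hi + 1))
            raise RoleLookupError(f"unknown role {role_name!r}")
        out = tuple(r for s, r in entries if s == subunit)
        if not out:
            raise RoleLookupError(
                f"role {role_name!r} is not defined for subunit {subunit}"
            )
        return out

    def segment(self, role_name: str) -> tuple[str, tuple[int, int]]:
        try:
            return self.segments[role_name]
        except KeyError:
            raise RoleLookupError(f"unknown segment role {role_name!r}")

    def has_role(self, role_name: str) -> bool:
        return role_name in self.residues or role_name in self.segments

    @classmethod
    def default(cls) -> "ResidueRoleMap":
        """The packaged GIRK role table (canonical UniProt numbering:
        GIRK1 P48549, GIRK2 P48542, GIRK4 P48544)."""
        residues = {
            # transmembrane gate: four pore-lining Phe (helix bundle crossing).
            # GIRK4 F187 follows the conserved hinge+12 register.
            "HBC-gate": (("GIRK1", 181), ("GIRK2", 192), ("GIRK4", 187)),
            # cytosolic girdle gate (Met pair, defined on GIRK2)
            "G-loop-gate": (("GIRK2", 313), ("GIRK2", 319)),
            # conserved TM2 hinge glycine (i-12 from the HBC Phe)
            "hinge-glycine": (("GIRK1", 169), ("GIRK2", 180), ("GIRK4", 175)),
            # PIP2-coordinating lysine triplets
            "PIP2-lysines": (
                ("GIRK1", 183), ("GIRK1", 188), ("GIRK1", 189),
                ("GIRK2", 194), ("GIRK2", 199), ("GIRK2", 200),
                ("GIRK4", 189), ("GIRK4", 194), ("GIRK4", 195),
            ),
            # state-dependent TM1 hydrophobic wire
            "TM1-wire": (("GIRK1", 87), ("GIRK1", 91), ("GIRK1", 95)),
            # pore-helix pair E141/F137
            "pore-helix-pair": (("GIRK1", 141), ("GIRK1", 137)),
            "TM2-acidic": (("GIRK1", 173),),
            "pre-gate-Met": (("GIRK1", 180),),
            # slide-helix aspartates switching with the CD-loop arginine
            "SH-acids": (("GIRK1", 70), ("GIRK1", 77)),
            "CD-loop": (("GIRK2", 230), ("GIRK2", 233)),
            # G-loop opening trio R313/E315/K188
            "G-loop-pair": (("GIRK1", 313), ("GIRK2", 315), ("GIRK1", 188)),
            # source residue for suboptimal-path analysis (ligand site)
            "ligand-source": (("GIRK1", 97),),
        }
        segments = {
            "TM1": ("GIRK1", (82, 105)),
            "SH": ("GIRK1", (67, 76)),
            "PH": ("GIRK1", (130, 142)),
            "TM2-outer": ("GIRK1", (158, 162)),
            "TM2-pivot": ("GIRK1", (167, 169)),
            "TM2-inner": ("GIRK1", (174, 178)),
        }
        return cls(residues=residues, segments=segments)


def lookup_role(roles: ResidueRoleMap, role_name: str, subunit: str) -> tuple[int, ...]:
    """Functional residue indices for (role, subunit); exact integer arithmetic
    between roles (e.g. HBC-gate minus hinge-glycine = 12) is intended usage."""
    return roles.lookup(role_name, subunit)


@dataclass(frozen=True)
class Selection:
    """Ordered atom indices into a Topology plus the source expression."""

    atom_indices: tuple[int, ...]
    expression: str = ""

    def __post_init__(self):
        idx = self.atom_indices
        if any(b <= a for a, b in zip(idx, idx[1:])):
            raise ValidationError("selection indices must be strictly increasing")

    def __len__(self) -> int:
        return len(self.atom_indices)

    @property
    def indices(self) -> np.ndarray:
        return np.asarray(self.atom_indices, dtype=int)


# --------------------------------------------------------------------------- #
# selection grammar
# --------------------------------------------------------------------------- #

_BARE_KEYS = {"chain", "subunit", "role", "name", "resname", "resid", "scope",
              "element"}


def _tokenize(expression: str) -> list[str]:
    out: list[str] = []
    for raw in expression.replace("(", " ( ").replace(")", " ) ").split():
        out.append(raw)
    return out


class _SelectionParser:
    """Recursive-descent parser.

    Grammar::

        expr   := and_expr ('or' and_expr)*
        and_expr := term (('and')? term)*        # juxtaposition means AND
        term   := '(' expr ')' | KEY ':' VALUE | KEY VALUE

    Keys: chain, subunit, role, name, resname, resid, scope, element. Values
    may be comma-separated lists; resid values may be ranges ``lo-hi`` (an
    inverted range selects nothing).
    """

    def __init__(self, tokens: list[str], topology: Topology,
                 assignment: SubunitAssignment | None,
                 roles: ResidueRoleMap | None):
        self.tokens = tokens
        self.pos = 0
        self.top = topology
        self.assignment = assignment
        self.roles = roles

    def peek(self) -> str | None:
        return self.tokens[self.pos] if self.pos < len(self.tokens) else None

    def parse(self) -> np.ndarray:
        mask = self._expr()
        if self.peek() is not None:
            raise SelectionSyntaxError(
                f"unexpected token {self.peek()!r}", self.pos
            )
        return mask

    def _expr(self) -> np.ndarray:
        mask = self._and_expr()
        while self.peek() == "or":
            self.pos += 1
            mask = mask | self._and_expr()
        return mask

    def _and_expr(self) -> np.ndarray:
        mask = self._term()
        while True:
            tok = self.peek()
            if tok == "and":
                self.pos += 1
                mask = mask & self._term()
            elif tok is not None and tok not in ("or", ")"):
                mask = mask & self._term()
            else:
                return mask

    def _term(self) -> np.ndarray:
        tok = self.peek()
        if tok is None:
            raise SelectionSyntaxError("unexpected end of expression", self.pos)
        if tok == "(":
            self.pos += 1
            mask = self._expr()
            if self.peek() != ")":
                raise SelectionSyntaxError("missing closing parenthesis", self.pos)
            self.pos += 1
            return mask
        self.pos += 1
        if ":" in tok:
            key, value = tok.split(":", 1)
        elif tok in _BARE_KEYS:
            value = self.peek()
            if value is None:
                raise SelectionSyntaxError(f"key {tok!r} needs a value", self.pos)
            self.pos += 1
            key = tok
        else:
            raise SelectionSyntaxError(f"unrecognised term {tok!r}", self.pos - 1)
        return self._predicate(key, value)

    # -- predicates ---------------------------------------------------------

    def _predicate(self, key: str, value: str) -> np.ndarray:
        n = self.top.n_atoms
        if key == "chain":
            values = set(value.split(","))
            known = set(self.top.chains)
            missing = values - known
            if missing:
                raise RoleLookupError(f"unknown chain(s) {sorted(missing)}")
            return np.isin(self.top.chain_ids, list(values))
        if key == "name":
            values = set(value.split(","))
            return np.array([nm in values for nm in self.top.names])
        if key == "element":
            values = {v.upper() for v in value.split(",")}
            elems = [
                (a.element.upper() if a.element else _element_from_name(a.name))
                for a in self.top.atoms
            ]
            return np.array([e in values for e in elems])
        if key == "resname":
            values = set(value.split(","))
            return np.isin(self.top.resnames, list(values))
        if key == "resid":
            mask = np.zeros(n, dtype=bool)
            for part in value.split(","):
                if "-" in part[1:]:  # allow negative single ids, not used in practice
                    lo_s, hi_s = part.rsplit("-", 1)
                    try:
                        lo, hi = int(lo_s), int(hi_s)
                    except ValueError:
                        raise SelectionSyntaxError(f"bad resid range {part!r}")
                    mask |= (self.top.resids >= lo) & (self.top.resids <= hi)
                else:
                    try:
                        rid = int(part)
                    except ValueError:
                        raise SelectionSyntaxError(f"bad resid {part!r}")
                    mask |= self.top.resids == rid
            return mask
        if key == "subunit":
            if self.assignment is None:
                raise RoleLookupError("subunit term requires a SubunitAssignment")
            if value not in SUBUNIT_TYPES:
                raise RoleLookupError(f"unknown subunit type {value!r}")
            chains = self.assignment.chains_of(value)
            return np.isin(self.top.chain_ids, chains)
        if key == "role":
            if self.roles is None or self.assignment is None:
                raise RoleLookupError(
                    "role term requires a ResidueRoleMap and SubunitAssignment"
                )
            if not self.roles.has_role(value):
                raise RoleLookupError(f"unknown role {value!r}")
            mask = np.zeros(n, dtype=bool)
            for chain_id in self.top.chains:
                if chain_id not in self.assignment.mapping:
                    continue
                sub = self.assignment.subunit_of(chain_id)
                try:
                    resids = self.roles.lookup(value, sub)
                except RoleLookupError:
                    continue
                mask |= (self.top.chain_ids == chain_id) & np.isin(
                    self.top.resids, resids
                )
            return mask
        if key == "scope":
            if value == "backbone":
                return np.array([a.is_backbone for a in self.top.atoms])
            if value == "sidechain-heavy":
                return np.array([a.is_sidechain_heavy for a in self.top.atoms])
            if value == "heavy":
                return np.array([not a.is_hydrogen for a in self.top.atoms])
            if value == "all":
                return np.ones(n, dtype=bool)
            raise SelectionSyntaxError(f"unknown scope {value!r}")
        raise SelectionSyntaxError(f"unknown selection key {key!r}")


def resolve_selection(
    topology: Topology,
    expression: str,
    assignment: SubunitAssignment | None = None,
    roles: ResidueRoleMap | None = None,
) -> Selection:
    """Resolve a selection expression to an ordered, deterministic Selection.

    An expression selecting nothing (e.g. an inverted resid range) yields an
    empty Selection, not an error.
    """
    tokens = _tokenize(expression)
    if not tokens:
        raise SelectionSyntaxError("empty selection expression")
    mask = _SelectionParser(tokens, topology, assignment, roles).parse()
    return Selection(tuple(int(i) for i in np.flatnonzero(mask)), expression)


def select_atoms(
    topology: Topology,
    chain_id: str,
    residue_index: int,
    scope: str = "sidechain-heavy",
) -> np.ndarray:
    """Atom indices of one residue under an atom scope; helper used by the
    gate and interaction analyses."""
    idx = topology.atom_indices(chain_id=chain_id, residue_index=residue_index)
    if scope == "all":
        return idx
    keep = []
    for i in idx:
        a = topology.atoms[i]
        if scope == "backbone" and a.is_backbone:
            keep.append(i)
        elif scope == "sidechain-heavy" and a.is_sidechain_heavy:
            keep.append(i)
        elif scope == "heavy" and not a.is_hydrogen:
            keep.append(i)
    return np.asarray(keep, dtype=int)


# --------------------------------------------------------------------------- #
# file I/O
# --------------------------------------------------------------------------- #

def read_structure(path: str | Path, format: str = "pdb") -> tuple[Topology, np.ndarray]:
    """Read a structure file, returning (Topology, first-frame coordinates).

    ``format`` is ``"pdb"`` or ``"fixture-text"``. PDB coordinates are
    preserved to the 3 decimals the format carries.
    """
    path = Path(path)
    if not path.exists():
        raise FormatError(f"structure file not found: {path}")
    if format == "pdb":
        return _read_pdb(path)
    if format == "fixture-text":
        return _read_fixture_structure(path)
    raise ValidationError(f"unknown structure format {format!r}")


def _read_pdb(path: Path) -> tuple[Topology, np.ndarray]:
    # quick scan for malformed coordinate fields so errors carry line numbers
    for lineno, line in enumerate(path.read_text().splitlines(), start=1):
        if line.startswith(("ATOM", "HETATM")):
            try:
                float(line[30:38]); float(line[38:46]); float(line[46:54])
                int(line[22:26])
            except ValueError:
                raise FormatError(f"{path}: unparseable ATOM record at line {lineno}")
    import biotite.structure.io.pdb as pdb_io

    pdb_file = pdb_io.PDBFile.read(str(path))
    arr = pdb_file.get_structure(model=1)
    atoms = []
    for i in range(arr.array_length()):
        atoms.append(
            AtomRecord(
                serial=i + 1,
                name=str(arr.atom_name[i]),
                element=str(arr.element[i]),
                residue_name=str(arr.res_name[i]),
                residue_index=int(arr.res_id[i]),
                chain_id=str(arr.chain_id[i]),
                position=tuple(float(x) for x in arr.coord[i]),
            )
        )
    top = Topology(atoms)
    return top, top.positions.copy()


def _read_fixture_structure(path: Path) -> tuple[Topology, np.ndarray]:
    lines = path.read_text().splitlines()
    if not lines:
        raise FormatError(f"{path}: empty fixture structure")
    try:
        natoms = int(lines[0].split()[0])
    except (ValueError, IndexError):
        raise FormatError(f"{path}: bad header at line 1")
    atoms = []
    for lineno in range(1, natoms + 1):
        try:
            parts = lines[lineno].split()
            serial, name, element, resname = (
                int(parts[0]), parts[1], parts[2], parts[3])
            resid, chain = int(parts[4]), parts[5]
            x, y, z = float(parts[6]), float(parts[7]), float(parts[8])
        except (IndexError, ValueError):
            raise FormatError(f"{path}: unparseable atom at line {lineno + 1}")
        atoms.append(AtomRecord(serial, name, element, resname, resid, chain,
                                (x, y, z)))
    top = Topology(atoms)
    return top, top.positions.copy()


def write_structure(topology: Topology, path: str | Path, format: str = "pdb",
                    coordinates: np.ndarray | None = None) -> None:
    """Write a Topology (optionally with replacement coordinates)."""
    path = Path(path)
    coords = topology.positions if coordinates is None else np.asarray(coordinates)
    if format == "pdb":
        import biotite.structure as bst
        import biotite.structure.io.pdb as pdb_io

        arr = bst.AtomArray(topology.n_atoms)
        arr.coord = coords.astype(np.float32)
        arr.chain_id = np.array([a.chain_id for a in topology.atoms])
        arr.res_id = np.array([a.residue_index for a in topology.atoms])
        arr.res_name = np.array([a.residue_name for a in topology.atoms])
        arr.atom_name = np.array([a.name for a in topology.atoms])
        arr.element = np.array(
            [a.element or _element_from_name(a.name) for a in topology.atoms]
        )
        pdb_file = pdb_io.PDBFile()
        pdb_file.set_structure(arr)
        pdb_file.write(str(path))
        return
    if format == "fixture-text":
        with path.open("w") as fh:
            fh.write(f"{topology.n_atoms}\n")
            for a, xyz in zip(topology.atoms, coords):
                fh.write(
                    f"{a.serial} {a.name} {a.element or _element_from_name(a.name)} "
                    f"{a.residue_name} {a.residue_index} {a.chain_id} "
                    f"{xyz[0]:.6f} {xyz[1]:.6f} {xyz[2]:.6f}\n"
                )
        return
    raise ValidationError(f"unknown structure format {format!r}")


def read_trajectory(
    topology: Topology,
    path: str | Path,
    format: str | None = None,
    dt_ns: float | None = None,
) -> Trajectory:
    """Read coordinate frames for ``topology`` from DCD, XTC or fixture text.

    ``format`` defaults from the file suffix. ``dt_ns`` overrides the frame
    spacing for formats that do not carry reliable times.
    """
    path = Path(path)
    if not path.exists():
        raise FormatError(f"trajectory file not found: {path}")
    fmt = format or path.suffix.lstrip(".").lower() or "fixture-text"
    if fmt in ("txt", "fixture", "fixture-text"):
        return _read_fixture_trajectory(topology, path, dt_ns)
    if fmt in ("dcd", "xtc"):
        return _read_mda_trajectory(topology, path, fmt, dt_ns)
    raise ValidationError(f"unknown trajectory format {fmt!r}")


def _read_fixture_trajectory(topology: Topology, path: Path,
                             dt_ns: float | None) -> Trajectory:
    with path.open() as fh:
        header = fh.readline().split()
        try:
            natoms, nframes = int(header[0]), int(header[1])
        except (ValueError, IndexError):
            raise FormatError(f"{path}: bad trajectory header at line 1")
        file_dt = float(header[2]) if len(header) >= 3 else 1.0
        box = None
        if len(header) >= 6:
            box = np.array([float(header[3]), float(header[4]), float(header[5])])
        if natoms != topology.n_atoms:
            raise ValidationError(
                f"{path}: trajectory natoms {natoms} != topology {topology.n_atoms}"
            )
        data = np.loadtxt(fh, dtype=float, max_rows=natoms * nframes)
    data = np.atleast_2d(data)
    if data.shape != (natoms * nframes, 3):
        raise FormatError(
            f"{path}: expected {natoms * nframes} coordinate lines, "
            f"got {data.shape[0]}"
        )
    frames = data.reshape(nframes, natoms, 3)
    dt = dt_ns if dt_ns is not None else file_dt
    times = np.arange(nframes) * dt
    boxes = None if box is None else np.tile(box, (nframes, 1))
    return Trajectory(topology, frames, times, boxes)


def _read_mda_trajectory(topology: Topology, path: Path, fmt: str,
                         dt_ns: float | None) -> Trajectory:
    from MDAnalysis.coordinates.DCD import DCDReader
    from MDAnalysis.coordinates.XTC import XTCReader

    reader_cls = DCDReader if fmt == "dcd" else XTCReader
    frames, times, boxes = [], [], []
    with reader_cls(str(path)) as reader:
        for ts in reader:
            if ts.n_atoms != topology.n_atoms:
                raise ValidationError(
                    f"{path}: frame has {ts.n_atoms} atoms, topology has "
                    f"{topology.n_atoms}"
                )
            frames.append(ts.positions.astype(float).copy())
            times.append(float(ts.time) / 1000.0)  # MDAnalysis time is ps
            if ts.dimensions is not None and np.all(ts.dimensions[:3] > 0):
                boxes.append(ts.dimensions[:3].astype(float).copy())
    frames = np.array(frames)
    times = np.array(times)
    if dt_ns is not None or np.any(np.diff(times) <= 0):
        dt = dt_ns if dt_ns is not None else 1.0
        times = np.arange(len(frames)) * dt
    box = np.array(boxes) if len(boxes) == len(frames) and boxes else None
    return Trajectory(topology, frames, times, box)


def write_trajectory(traj: Trajectory, path: str | Path,
                     format: str | None = None) -> None:
    """Write a trajectory as fixture text (default), DCD or XTC."""
    path = Path(path)
    fmt = format or path.suffix.lstrip(".").lower() or "fixture-text"
    if fmt in ("txt", "fixture", "fixture-text"):
        dt = float(traj.times[1] - traj.times[0]) if traj.n_frames > 1 else 1.0
        with path.open("w") as fh:
            header = f"{traj.n_atoms} {traj.n_frames} {dt:.9g}"
            if traj.box is not None:
                b = traj.box[0]
                header += f" {b[0]:.6f} {b[1]:.6f} {b[2]:.6f}"
            fh.write(header + "\n")
            for frame in traj.frames:
                for xyz in frame:
                    fh.write(f"{xyz[0]:.6f} {xyz[1]:.6f} {xyz[2]:.6f}\n")
        return
    if fmt in ("dcd", "xtc"):
        import MDAnalysis as mda

        u = mda.Universe.empty(traj.n_atoms, trajectory=True)
        with mda.Writer(str(path), n_atoms=traj.n_atoms) as w:
            for i in range(traj.n_frames):
                u.atoms.positions = traj.frames[i]
                if traj.box is not None:
                    u.dimensions = [*traj.box[i], 90.0, 90.0, 90.0]
                w.write(u.atoms)
        return
    raise ValidationError(f"unknown trajectory format {fmt!r}")


# --------------------------------------------------------------------------- #
# configuration files (role map / assignment)
# --------------------------------------------------------------------------- #

def load_assignment(path: str | Path) -> SubunitAssignment:
    """Plain-text key-value (YAML mapping) chain -> subunit."""
    import yaml

    with Path(path).open() as fh:
        data = yaml.safe_load(fh)
    if not isinstance(data, dict):
        raise FormatError(f"{path}: expected a chain -> subunit mapping")
    return SubunitAssignment({str(k): str(v) for k, v in data.items()})
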