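"""Dynamic cross-correlation matrices, residue networks and suboptimal paths.

The dynamic cross-correlation matrix (DCCM) over C-alpha motion,

    c_ij = <dr_i . dr_j> / sqrt(<|dr_i|^2> <|dr_j|^2>),

with dr the deviation from the time-mean position after (optional) iterative
least-squares superposition, is thresholded at |c_ij| >= 0.4 into an
undirected residue network with edge length w = -log|c_ij| (perfect coupling
is a zero-cost edge). Allosteric routes between a source residue (the ligand
site, GIRK1-F97) and a sink (CD loop or PIP2 site) are the k lowest-cost
simple paths (default k = 250), found with Yen's algorithm using
lexicographic node-sequence tie-breaking so ensembles are deterministic.
Per-edge usage counts across the ensemble provide the spline weights used
for visualization.
"""

from __future__ import annotations

import heapq
from dataclasses import dataclass
from typing import Hashable

import networkx as nx
import numpy as np
import pandas as pd

from ._geometry import kabsch_align
from .errors import DegeneracyError, NoPathError, ValidationError
from .structure_io import AnalysisWindow, Selection, Trajectory, window_frames

DEFAULT_CIJ_CUTOFF = 0.4
DEFAULT_N_PATHS = 250


@dataclass
class CorrelationMatrix:
    """Symmetric unit-diagonal c_ij in [-1, 1] over residue ids."""

    residue_ids: tuple[Hashable, ...]
    values: np.ndarray

    def __post_init__(self):
        v = np.asarray(self.values, dtype=float)
        n = len(self.residue_ids)
        if v.shape != (n, n):
            raise ValidationError("correlation matrix shape must match residue ids")
        if not np.allclose(v, v.T, atol=1e-10):
            raise ValidationError("correlation matrix must be symmetric")
        if not np.allclose(np.diag(v), 1.0, atol=1e-10):
            raise ValidationError("correlation matrix diagonal must be 1")
        if np.any(np.abs(v) > 1.0 + 1e-10):
            raise ValidationError("|c_ij| must not exceed 1")
        self.values = np.clip(v, -1.0, 1.0)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.values, index=list(self.residue_ids),
                            columns=list(self.residue_ids))


@dataclass
class ResidueNetwork:
    """Thresholded correlation graph with -log|c| edge weights."""

    graph: nx.Graph
    cutoff: float

    @property
    def nodes(self):
        return self.graph.nodes

    @property
    def edges(self):
        return self.graph.edges

    def edge_table(self) -> pd.DataFrame:
        rows = [
            {"node_i": u, "node_j": v, "cij": d["cij"], "weight": d["weight"]}
            for u, v, d in self.graph.edges(data=True)
        ]
        return pd.DataFrame(rows, columns=["node_i", "node_j", "cij", "weight"])


@dataclass
class PathEnsemble:
    """Ranked simple paths between one source and one sink."""

    source: Hashable
    sink: Hashable
    paths: tuple[tuple[Hashable, ...], ...]
    weights: tuple[float, ...]

    def __post_init__(self):
        if len(self.paths) != len(self.weights):
            raise ValidationError("one weight per path required")
        if any(b < a - 1e-12 for a, b in zip(self.weights, self.weights[1:])):
            raise ValidationError("path weights must be nondecreasing")
        if len(set(self.paths)) != len(self.paths):
            raise ValidationError("paths must be distinct")

    def __len__(self) -> int:
        return len(self.paths)


def compute_dccm(
    traj: Trajectory,
    calpha: Selection,
    window: AnalysisWindow | None = None,
    superpose: bool = True,
) -> CorrelationMatrix:
    """DCCM of the selected C-alpha atoms over the analysis window.

    With ``superpose`` on (default), all frames are iteratively least-squares
    superposed onto the running mean of the selection before deviations are
    taken, removing rigid-body drift; fixtures asserting forced +-1
    correlations run with it off.
    """
    if len(calpha) < 2:
        raise ValidationError("DCCM needs at least two residues")
    fidx = window_frames(traj, window)
    if fidx.size < 10:
        raise ValidationError("DCCM needs at least 10 frames in the window")
    coords = traj.frames[np.ix_(fidx, calpha.indices)].astype(float)
    if superpose:
        ref = coords[0]
        for _ in range(10):
            aligned = np.array([kabsch_align(fr, ref) for fr in coords])
            new_ref = aligned.mean(axis=0)
            shift = float(np.max(np.abs(new_ref - ref)))
            ref = new_ref
            if shift < 1e-8:
                break
        coords = np.array([kabsch_align(fr, ref) for fr in coords])
    mean = coords.mean(axis=0)
    dev = coords - mean                       # (frames, n, 3)
    cov = np.einsum("fia,fja->ij", dev, dev) / dev.shape[0]
    var = np.diag(cov)
    resids = [traj.topology.atoms[i].residue_index for i in calpha.indices]
    for rid, v in zip(resids, var):
        if v <= 1e-12:
            raise DegeneracyError(
                f"residue {rid} has zero positional variance; c_ij undefined"
            )
    c = cov / np.sqrt(np.outer(var, var))
    c = np.clip((c + c.T) / 2.0, -1.0, 1.0)
    np.fill_diagonal(c, 1.0)
    return CorrelationMatrix(tuple(resids), c)


def build_residue_network(
    dccm: CorrelationMatrix,
    cutoff: float = DEFAULT_CIJ_CUTOFF,
    use_absolute: bool = True,
) -> ResidueNetwork:
    """Edges exactly where |c_ij| >= cutoff (or c_ij >= cutoff when
    ``use_absolute`` is off), weighted w = -log|c_ij|."""
    if not (0.0 < cutoff <= 1.0):
        raise ValidationError("cutoff must lie in (0, 1]")
    g = nx.Graph()
    g.add_nodes_from(dccm.residue_ids)
    n = len(dccm.residue_ids)
    for i in range(n):
        for j in range(i + 1, n):
            cij = dccm.values[i, j]
            magnitude = abs(cij) if use_absolute else cij
            if magnitude >= cutoff:
                g.add_edge(
                    dccm.residue_ids[i],
                    dccm.residue_ids[j],
                    cij=float(cij),
                    weight=float(-np.log(abs(cij))),
                )
    return ResidueNetwork(g, cutoff)


# --------------------------------------------------------------------------- #
# deterministic k-shortest simple paths (Yen)
# --------------------------------------------------------------------------- #

def _dijkstra_path(
    g: nx.Graph,
    source: Hashable,
    sink: Hashable,
    banned_nodes: set,
    banned_edges: set,
) -> tuple[float, tuple] | None:
    """Shortest path avoiding banned nodes/edges; equal-cost ties broken by
    lexicographic node sequence (heap entries are (cost, path))."""
    heap = [(0.0, (source,))]
    best: dict = {}
    while heap:
        cost, path = heapq.heappop(heap)
        node = path[-1]
        if node == sink:
            return cost, path
        if node in best and best[node] < (cost, path):
            continue
        for nbr, data in sorted(g[node].items(), key=lambda kv: kv[0]):
            if nbr in banned_nodes or nbr in path:
                continue
            e = (node, nbr) if node <= nbr else (nbr, node)
            if e in banned_edges:
                continue
            ncost = cost + data["weight"]
            npath = path + (nbr,)
            key = (ncost, npath)
            if nbr not in best or key < best[nbr]:
                best[nbr] = key
                heapq.heappush(heap, key)
    return None


def suboptimal_paths(
    net: ResidueNetwork,
    source: Hashable,
    sink: Hashable,
    k: int = DEFAULT_N_PATHS,
) -> PathEnsemble:
    """The k lowest-total-weight distinct simple paths source -> sink, in
    nondecreasing weight order (fewer when the graph holds fewer simple
    paths). Yen's algorithm; deterministic lexicographic tie-breaking."""
    g = net.graph
    if source not in g or sink not in g:
        raise NoPathError(f"source {source!r} or sink {sink!r} not in network")
    if source == sink:
        raise ValidationError("source and sink must differ")
    if k < 1:
        raise ValidationError("k must be >= 1")
    first = _dijkstra_path(g, source, sink, set(), set())
    if first is None:
        raise NoPathError(f"no path between {source!r} and {sink!r}")
    accepted: list[tuple[float, tuple]] = [first]
    accepted_paths = {first[1]}
    candidates: list[tuple[float, tuple]] = []
    candidate_set: set[tuple] = set()
    while len(accepted) < k:
        prev_path = accepted[-1][1]
        for i in range(len(prev_path) - 1):
            spur = prev_path[i]
            root = prev_path[: i + 1]
            root_cost = sum(
                g[root[j]][root[j + 1]]["weight"] for j in range(i)
            )
            banned_edges = set()
            for _, p in accepted:
                if len(p) > i and p[: i + 1] == root:
                    u, v = p[i], p[i + 1]
                    banned_edges.add((u, v) if u <= v else (v, u))
            banned_nodes = set(root[:-1])
            spur_res = _dijkstra_path(g, spur, sink, banned_nodes, banned_edges)
            if spur_res is None:
                continue
            spur_cost, spur_path = spur_res
            total = (root_cost + spur_cost, root[:-1] + spur_path)
            if total[1] not in accepted_paths and total[1] not in candidate_set:
                heapq.heappush(candidates, total)
                candidate_set.add(total[1])
        if not candidates:
            break
        nxt = heapq.heappop(candidates)
        candidate_set.discard(nxt[1])
        accepted.append(nxt)
        accepted_paths.add(nxt[1])
    weights, paths = zip(*[(c, p) for c, p in accepted])
    return PathEnsemble(source=source, sink=sink,
                        paths=tuple(paths), weights=tuple(float(w) for w in weights))


def edge_usage(ensemble: PathEnsemble) -> dict[tuple, int]:
    """Number of ensemble paths traversing each undirected edge (the spline
    weight in pathway visualizations)."""
    usage: dict[tuple, int] = {}
    for path in ensemble.paths:
        for u, v in zip(path, path[1:]):
            e = (u, v) if u <= v else (v, u)
            usage[e] = usage.get(e, 0) + 1
    return usage


def edge_usage_table(ensemble: PathEnsemble) -> pd.DataFrame:
    usage = edge_usage(ensemble)
    rows = [{"node_i": u, "node_j": v, "n_paths": c}
            for (u, v), c in sorted(usage.items())]
    return pd.DataFrame(rows, columns=["node_i", "node_j", "n_paths"])
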