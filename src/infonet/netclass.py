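"""Threshold-swept connected components and the nested merge hierarchy.

The normalized adjacency matrix is filtered at a mutative threshold
T_c = c * max_ij a_ij; entries below T_c are set to zero and the
connected components of the surviving graph are the classification at
multiplicity c.  Sweeping c from 1 down to 0.1 produces nested
partitions — components at a higher c are contained in components at a
lower c — recorded as a merge tree.  The merge multiplicity of two
proteins equals their bottleneck similarity (maximal over paths of the
minimal edge on the path) divided by the maximum entry, floored to the
grid, which makes the hierarchy equivalent to single-linkage clustering
on dissimilarity max(a) - a.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import networkx as nx
import numpy as np
import pandas as pd
from scipy.sparse import csr_matrix
from scipy.sparse.csgraph import connected_components as _cc

from .infometrics import CSV_FLOAT_FORMAT, AdjacencyMatrix

_EPS = 1e-9  # tolerance when flooring exact multiplicities to the grid


@dataclass
class ThresholdGrid:
    """Descending grid of threshold multiplicities c in (0, 1]."""

    values: np.ndarray

    def __post_init__(self):
        self.values = np.asarray(self.values, dtype=float)
        if len(self.values) == 0:
            raise ValueError("empty threshold grid")
        if np.any(np.diff(self.values) >= 0):
            raise ValueError("grid must be strictly descending")
        if self.values[0] > 1.0 or self.values[-1] <= 0.0:
            raise ValueError("grid values must lie in (0, 1]")

    @classmethod
    def default(cls, step: float = 0.01, c_min: float = 0.1, c_max: float = 1.0):
        """c_max down to c_min inclusive in steps of ``step`` (default
        1.00, 0.99, ..., 0.10)."""
        n = int(round((c_max - c_min) / step))
        values = np.round(c_max - step * np.arange(n + 1), 10)
        return cls(values=values)

    def floor(self, c_exact: float) -> float | None:
        """Largest grid value <= c_exact (within tolerance); None if
        c_exact falls below the whole grid."""
        for c in self.values:
            if c <= c_exact + _EPS:
                return float(c)
        return None

    def __iter__(self):
        return iter(self.values)

    def __len__(self):
        return len(self.values)


@dataclass
class ComponentPartition:
    """Connected components of a filtered adjacency matrix.

    ``blocks`` are disjoint sorted tuples of 0-based node indices,
    ordered by smallest member, covering all nodes.
    """

    blocks: list[tuple[int, ...]]
    c: float | None = None
    threshold: float | None = None
    ids: list[str] | None = None

    @property
    def n_blocks(self) -> int:
        return len(self.blocks)

    def labels(self) -> np.ndarray:
        """Block index of every node, as a flat label vector."""
        n = sum(len(b) for b in self.blocks)
        lab = np.empty(n, dtype=np.int64)
        for k, block in enumerate(self.blocks):
            for i in block:
                lab[i] = k
        return lab

    def block_of(self, i: int) -> int:
        return int(self.labels()[i])


def _blocks_from_labels(labels: np.ndarray) -> list[tuple[int, ...]]:
    groups: dict[int, list[int]] = {}
    for i, lab in enumerate(labels):
        groups.setdefault(int(lab), []).append(i)
    blocks = [tuple(sorted(g)) for g in groups.values()]
    blocks.sort(key=lambda b: b[0])
    return blocks


# --------------------------------------------------------------------------
# filtering and components
# --------------------------------------------------------------------------

def filter_adjacency(a: AdjacencyMatrix, c: float) -> AdjacencyMatrix:
    """Zero every entry below the mutative threshold T_c = c * max a_ij.

    Entries >= T_c survive unchanged, so filtering at the same c twice is
    a fixed point.  Requires a normalized matrix with at least one
    positive entry.
    """
    if not a.normalized:
        raise ValueError("filter requires a normalized adjacency matrix")
    if not (0.0 < c <= 1.0):
        raise ValueError("multiplicity c must lie in (0, 1]")
    amax = a.max_offdiag()
    if amax <= 0.0:
        raise ValueError("no edges to threshold: adjacency matrix is all zero")
    t_c = c * amax
    values = np.where(a.values >= t_c, a.values, 0.0)
    np.fill_diagonal(values, 0.0)
    out = AdjacencyMatrix(values=values, ids=list(a.ids), normalized=True)
    out.meta["c"] = c
    out.meta["threshold"] = t_c
    return out


def connected_components(a: AdjacencyMatrix) -> ComponentPartition:
    """Components of the graph whose edges are the positive entries.

    Uses a union-find-style sparse traversal; blocks are returned in
    deterministic order (by smallest member index).
    """
    graph = csr_matrix(a.values > 0.0)
    _, labels = _cc(graph, directed=False)
    return ComponentPartition(
        blocks=_blocks_from_labels(labels),
        c=a.meta.get("c"),
        threshold=a.meta.get("threshold"),
        ids=list(a.ids),
    )


def components_by_matrix_power(a: AdjacencyMatrix) -> ComponentPartition:
    """Components via positivity of the summed matrix powers.

    Two nodes share a component exactly when some power A^s (s = 1..N-1)
    of the filtered adjacency matrix has a positive entry for the pair,
    i.e. when the power sum  A_sum = sum_{s=1..N-1} A^s  is positive
    there; the identity (path length 0) is included so isolated nodes
    form well-defined singleton blocks.  Powers are accumulated on the
    support pattern of A, which has the same positivity as the weighted
    powers but cannot under- or overflow for long paths.  Restricted to
    the blocks, A_sum is block diagonal.  Must agree with
    :func:`connected_components` on every input.
    """
    n = a.n
    if n < 2:
        raise ValueError("need at least 2 nodes")
    support = (a.values > 0.0).astype(np.int8)
    np.fill_diagonal(support, 0)
    reach = np.eye(n, dtype=bool) | support.astype(bool)
    power = support.astype(bool)
    for _ in range(n - 2):
        power = (power.astype(np.int16) @ support) > 0
        reach |= power
    # reach is symmetric and transitive: rows are the blocks
    labels = np.full(n, -1, dtype=np.int64)
    next_label = 0
    for i in range(n):
        if labels[i] < 0:
            members = np.flatnonzero(reach[i])
            labels[members] = next_label
            next_label += 1
    return ComponentPartition(
        blocks=_blocks_from_labels(labels),
        c=a.meta.get("c"),
        threshold=a.meta.get("threshold"),
        ids=list(a.ids),
    )


def connectivity_profile(
    a: AdjacencyMatrix, i: int, j: int, grid: ThresholdGrid
) -> list[tuple[float, float]]:
    """Mean root-power connectivity of a node pair across the grid.

    At each multiplicity c the filtered matrix F is raised to powers
    n = 1..N-1 and the connectivity value is
    abar(i, j) = (1/(N-1)) * sum_n (F^n)_ij ** (1/n); it is positive
    exactly when i and j share a component at c.
    """
    if i == j:
        raise ValueError("connectivity profile requires two distinct nodes")
    n = a.n
    out = []
    for c in grid:
        f = filter_adjacency(a, float(c)).values
        total = 0.0
        power = np.eye(n)
        for s in range(1, n):
            power = power @ f
            entry = power[i, j]
            if entry > 0.0:
                total += entry ** (1.0 / s)
        out.append((float(c), total / (n - 1)))
    return out


# --------------------------------------------------------------------------
# merge hierarchy
# --------------------------------------------------------------------------

@dataclass
class TreeNode:
    """A cluster in the merge hierarchy.

    Leaves have ``c is None`` and a single member; internal nodes carry
    the first (largest) grid multiplicity at which their children were
    united.  Three or more blocks uniting at one c form a single
    multi-way node.
    """

    members: tuple[int, ...]
    c: float | None = None
    children: list["TreeNode"] = field(default_factory=list)

    @property
    def is_leaf(self) -> bool:
        return not self.children


@dataclass
class MergeTree:
    """The nested classification produced by the threshold sweep."""

    roots: list[TreeNode]
    ids: list[str]
    grid: ThresholdGrid

    def cut(self, c: float) -> ComponentPartition:
        """Partition at multiplicity c: the maximal clusters merged at
        or above c."""
        blocks: list[tuple[int, ...]] = []

        def descend(node: TreeNode):
            if node.is_leaf or (node.c is not None and node.c >= c - _EPS):
                blocks.append(node.members)
            else:
                for child in node.children:
                    descend(child)

        for root in self.roots:
            descend(root)
        blocks.sort(key=lambda b: b[0])
        return ComponentPartition(blocks=blocks, c=c, ids=list(self.ids))

    def merges(self) -> list[tuple[float, tuple[int, ...]]]:
        """All (c, merged member set) events, descending in c."""
        events = []

        def descend(node: TreeNode):
            if not node.is_leaf:
                events.append((node.c, node.members))
                for child in node.children:
                    descend(child)

        for root in self.roots:
            descend(root)
        events.sort(key=lambda e: (-e[0], e[1]))
        return events

    # -- exports ----------------------------------------------------------

    def _node_dict(self, node: TreeNode) -> dict:
        if node.is_leaf:
            return {"id": self.ids[node.members[0]]}
        return {
            "c": node.c,
            "members": [self.ids[m] for m in node.members],
            "children": [self._node_dict(ch) for ch in node.children],
        }

    def to_dict(self) -> dict:
        return {
            "ids": list(self.ids),
            "grid": {"c_max": float(self.grid.values[0]),
                     "c_min": float(self.grid.values[-1]),
                     "size": len(self.grid)},
            "roots": [self._node_dict(r) for r in self.roots],
        }

    def to_json(self, path: str | Path) -> None:
        Path(path).write_text(
            json.dumps(self.to_dict(), indent=2, sort_keys=True) + "\n"
        )

    def to_newick(self) -> str:
        """Newick string; internal node labels carry the merge
        multiplicity c.  A forest is joined under an unlabeled root."""

        def render(node: TreeNode) -> str:
            if node.is_leaf:
                return self.ids[node.members[0]]
            inner = ",".join(render(ch) for ch in node.children)
            return f"({inner}){node.c:g}"

        if len(self.roots) == 1:
            return render(self.roots[0]) + ";"
        return "(" + ",".join(render(r) for r in self.roots) + ");"


def sweep(a: AdjacencyMatrix, grid: ThresholdGrid | None = None) -> MergeTree:
    """Build the merge tree by descending the threshold grid.

    At every grid c the components of the filtered matrix are computed;
    whenever two or more current clusters fall into one component, a
    merge node annotated with that c (the first grid multiplicity at
    which they unite) replaces them.  Nesting is guaranteed because
    lowering c only adds edges.
    """
    if grid is None:
        grid = ThresholdGrid.default()
    if not a.normalized:
        raise ValueError("sweep requires a normalized adjacency matrix")
    active: list[TreeNode] = [TreeNode(members=(i,)) for i in range(a.n)]
    for c in grid:
        part = connected_components(filter_adjacency(a, float(c)))
        labels = part.labels()
        groups: dict[int, list[TreeNode]] = {}
        for node in active:
            groups.setdefault(int(labels[node.members[0]]), []).append(node)
        new_active: list[TreeNode] = []
        for _, nodes in sorted(groups.items(), key=lambda kv: kv[1][0].members[0]):
            if len(nodes) == 1:
                new_active.append(nodes[0])
            else:
                members = tuple(sorted(m for nd in nodes for m in nd.members))
                new_active.append(TreeNode(members=members, c=float(c),
                                           children=nodes))
        active = new_active
    active.sort(key=lambda nd: nd.members[0])
    return MergeTree(roots=active, ids=list(a.ids), grid=grid)


def merge_multiplicity(
    a: AdjacencyMatrix, i: int, j: int, grid: ThresholdGrid | None = None
) -> float | None:
    """Largest grid c at which nodes i and j share a component.

    Equals the bottleneck similarity between i and j (the widest-path
    value, read off the maximum spanning tree) divided by the maximum
    off-diagonal entry, floored to the grid; None if the pair is never
    connected on the grid.
    """
    if i == j:
        raise ValueError("merge multiplicity requires two distinct nodes")
    if grid is None:
        grid = ThresholdGrid.default()
    amax = a.max_offdiag()
    if amax <= 0.0:
        return None
    g = nx.from_numpy_array(a.values)
    if not nx.has_path(g, i, j):
        return None
    mst = nx.maximum_spanning_tree(g, weight="weight")
    path = nx.shortest_path(mst, i, j)
    bottleneck = min(
        g[u][v]["weight"] for u, v in zip(path[:-1], path[1:])
    )
    if bottleneck <= 0.0:
        return None
    return grid.floor(bottleneck / amax)


# --------------------------------------------------------------------------
# exports
# --------------------------------------------------------------------------

def write_partition_csv(part: ComponentPartition, path: str | Path) -> None:
    """Two-column CSV (id, block index) for one grid multiplicity."""
    if part.ids is None:
        raise ValueError("partition has no record ids attached")
    labels = part.labels()
    pd.DataFrame({"id": part.ids, "block": labels}).to_csv(path, index=False)


def write_edge_list_csv(a: AdjacencyMatrix, path: str | Path) -> None:
    """Three-column CSV (id_i, id_j, a_ij) of the positive edges."""
    rows = []
    for i in range(a.n):
        for j in range(i + 1, a.n):
            if a.values[i, j] > 0.0:
                rows.append((a.ids[i], a.ids[j], a.values[i, j]))
    pd.DataFrame(rows, columns=["id_i", "id_j", "a_ij"]).to_csv(
        path, index=False, float_format=CSV_FLOAT_FORMAT
    )
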