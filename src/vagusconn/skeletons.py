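"""Neuronal skeletons: SWC I/O, geodesic geometry and dendrogram linearization.

A skeleton is a rooted tree of 3D nodes (coordinates in nanometres, the
EM-native unit; no conversion happens anywhere in this package). Geodesic
distances are measured along the arbor — sums of Euclidean edge lengths on
the unique tree path — never as straight-line distances. An optional
``origin_node`` marks an anatomically designated entry point (e.g. the
nerve-junction node where the arbor enters the CNS); it is always supplied
externally, never inferred from geometry.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterator

import pandas as pd

__all__ = [
    "SkeletonNode",
    "Skeleton",
    "SwcParseError",
    "read_swc",
    "write_swc",
    "read_skeleton_manifest",
    "geodesic_distance",
    "cable_length",
    "dendrogram",
]


class SwcParseError(ValueError):
    """Structural error in an SWC file; ``line`` is the 1-based offending line."""

    def __init__(self, message: str, line: int | None = None):
        self.line = line
        if line is not None:
            message = f"line {line}: {message}"
        super().__init__(message)


@dataclass(frozen=True)
class SkeletonNode:
    """One point of a skeleton. ``parent_id`` is None for the root."""

    node_id: int
    parent_id: int | None
    x: float
    y: float
    z: float
    radius: float = -1.0
    node_type: int = 0  # SWC "type" column, preserved verbatim, semantically ignored


@dataclass
class Skeleton:
    """Rooted tree of :class:`SkeletonNode`, one per neuron.

    Invariants (checked on construction): node ids unique, exactly one root,
    every parent reference resolves, and the parent relation is a single
    connected acyclic tree.
    """

    neuron_id: str
    nodes: dict[int, SkeletonNode]
    origin_node: int | None = None
    _children: dict[int, list[int]] = field(default_factory=dict, repr=False)
    _root: int = field(default=-1, repr=False)

    def __post_init__(self) -> None:
        roots = [n.node_id for n in self.nodes.values() if n.parent_id is None]
        if len(roots) == 0:
            raise ValueError(f"skeleton {self.neuron_id}: no root node")
        if len(roots) > 1:
            raise ValueError(
                f"skeleton {self.neuron_id}: multiple roots {sorted(roots)}"
            )
        self._root = roots[0]
        children: dict[int, list[int]] = {nid: [] for nid in self.nodes}
        for n in self.nodes.values():
            if n.parent_id is None:
                continue
            if n.parent_id not in self.nodes:
                raise ValueError(
                    f"skeleton {self.neuron_id}: node {n.node_id} has "
                    f"dangling parent {n.parent_id}"
                )
            children[n.parent_id].append(n.node_id)
        # deterministic traversal order everywhere
        for nid in children:
            children[nid].sort()
        self._children = children
        # connectivity + acyclicity: a BFS from the root must reach every node
        seen = {self._root}
        stack = [self._root]
        while stack:
            cur = stack.pop()
            for c in children[cur]:
                seen.add(c)
                stack.append(c)
        if len(seen) != len(self.nodes):
            orphans = sorted(set(self.nodes) - seen)
            raise ValueError(
                f"skeleton {self.neuron_id}: nodes {orphans} unreachable from "
                f"root (cycle or disconnected component)"
            )
        if self.origin_node is not None and self.origin_node not in self.nodes:
            raise ValueError(
                f"skeleton {self.neuron_id}: origin node {self.origin_node} absent"
            )

    @property
    def root(self) -> int:
        return self._root

    def children(self, node_id: int) -> list[int]:
        return self._children[node_id]

    def __len__(self) -> int:
        return len(self.nodes)

    def __contains__(self, node_id: int) -> bool:
        return node_id in self.nodes

    def edge_length(self, node_id: int) -> float:
        """Length of the edge from ``node_id`` to its parent (0 for the root)."""
        n = self.nodes[node_id]
        if n.parent_id is None:
            return 0.0
        p = self.nodes[n.parent_id]
        return math.dist((n.x, n.y, n.z), (p.x, p.y, p.z))

    def depth_first(self) -> Iterator[int]:
        """Pre-order traversal, children in ascending node_id."""
        stack = [self._root]
        while stack:
            cur = stack.pop()
            yield cur
            stack.extend(reversed(self._children[cur]))

    def distances_from(self, source: int) -> dict[int, float]:
        """Geodesic distance from ``source`` to every node, in one sweep."""
        if source not in self.nodes:
            raise KeyError(f"unknown node id {source}")
        # re-root the tree at `source` conceptually: walk the undirected tree
        adj: dict[int, list[int]] = {nid: list(self._children[nid]) for nid in self.nodes}
        for n in self.nodes.values():
            if n.parent_id is not None:
                adj[n.node_id].append(n.parent_id)
        dist = {source: 0.0}
        stack = [source]
        while stack:
            cur = stack.pop()
            for nb in adj[cur]:
                if nb not in dist:
                    na, nn = self.nodes[cur], self.nodes[nb]
                    step = math.dist((na.x, na.y, na.z), (nn.x, nn.y, nn.z))
                    dist[nb] = dist[cur] + step
                    stack.append(nb)
        return dist


def geodesic_distance(s: Skeleton, a: int, b: int) -> float:
    """Arbor path length between two nodes (nanometres).

    Symmetric, zero iff ``a == b``. Raises :class:`KeyError` for unknown ids.
    """
    if a not in s.nodes:
        raise KeyError(f"unknown node id {a}")
    if b not in s.nodes:
        raise KeyError(f"unknown node id {b}")
    if a == b:
        return 0.0
    # climb both nodes to their lowest common ancestor, accumulating lengths
    dist_a: dict[int, float] = {}
    cur, acc = a, 0.0
    while cur is not None:
        dist_a[cur] = acc
        parent = s.nodes[cur].parent_id
        if parent is not None:
            acc += s.edge_length(cur)
        cur = parent
    cur, acc = b, 0.0
    while cur not in dist_a:
        acc += s.edge_length(cur)
        cur = s.nodes[cur].parent_id  # type: ignore[assignment]  # root is in dist_a
    return acc + dist_a[cur]


def cable_length(s: Skeleton) -> float:
    """Total arbor length: the sum of all edge lengths (nanometres)."""
    return sum(s.edge_length(nid) for nid in s.nodes)


def dendrogram(s: Skeleton) -> pd.DataFrame:
    """Linearize a skeleton into a 2-D dendrogram layout.

    Returns a DataFrame indexed by node_id with columns ``arc_nm`` (geodesic
    distance from the root — the x coordinate of the dendrogram) and ``lane``
    (an integer y coordinate). Leaves get consecutive lanes in deterministic
    depth-first order; an internal node takes the lane of its first child, so
    sibling subtrees occupy disjoint lane ranges and an unbranched chain sits
    entirely in lane 0.
    """
    arc = s.distances_from(s.root)
    lane: dict[int, int] = {}
    next_lane = 0
    # post-order assignment, children ascending by node_id
    order: list[int] = []
    stack: list[tuple[int, bool]] = [(s.root, False)]
    while stack:
        nid, expanded = stack.pop()
        if expanded:
            order.append(nid)
            continue
        stack.append((nid, True))
        for c in reversed(s.children(nid)):
            stack.append((c, False))
    for nid in order:
        kids = s.children(nid)
        if not kids:
            lane[nid] = next_lane
            next_lane += 1
        else:
            lane[nid] = lane[kids[0]]
    df = pd.DataFrame(
        {"arc_nm": [arc[nid] for nid in sorted(s.nodes)],
         "lane": [lane[nid] for nid in sorted(s.nodes)]},
        index=pd.Index(sorted(s.nodes), name="node_id"),
    )
    return df


# ---------------------------------------------------------------------------
# SWC I/O
#
# Dialect: whitespace-separated 7 columns (id, type, x, y, z, radius, parent),
# '#' comments, parent -1 marks the root, ids need not be contiguous.


def read_swc(path: str | Path, neuron_id: str | None = None,
             origin_node: int | None = None) -> Skeleton:
    """Parse one SWC file into a :class:`Skeleton`.

    Coordinates are preserved exactly as parsed. Structural violations
    (duplicate ids, multiple roots, dangling parents, cycles) raise
    :class:`SwcParseError` naming the offending line where one exists.
    """
    path = Path(path)
    if neuron_id is None:
        neuron_id = path.stem
    nodes: dict[int, SkeletonNode] = {}
    id_line: dict[int, int] = {}
    root_line: int | None = None
    with open(path) as fh:
        for lineno, raw in enumerate(fh, start=1):
            line = raw.strip()
            if not line or line.startswith("#"):
                continue
            parts = line.split()
            if len(parts) != 7:
                raise SwcParseError(
                    f"expected 7 columns, got {len(parts)}", lineno)
            try:
                nid = int(parts[0])
                ntype = int(parts[1])
                x, y, z, radius = (float(p) for p in parts[2:6])
                parent = int(parts[6])
            except ValueError as exc:
                raise SwcParseError(f"malformed field ({exc})", lineno) from exc
            if nid in nodes:
                raise SwcParseError(f"duplicate node id {nid}", lineno)
            if parent == -1:
                if root_line is not None:
                    raise SwcParseError(
                        f"second root node {nid} (first root on line {root_line})",
                        lineno)
                root_line = lineno
                parent_id = None
            else:
                parent_id = parent
            nodes[nid] = SkeletonNode(nid, parent_id, x, y, z, radius, ntype)
            id_line[nid] = lineno
    if not nodes:
        raise SwcParseError(f"{path}: no node records")
    for n in nodes.values():
        if n.parent_id is not None and n.parent_id not in nodes:
            raise SwcParseError(
                f"node {n.node_id} references absent parent {n.parent_id}",
                id_line[n.node_id])
    try:
        return Skeleton(neuron_id, nodes, origin_node=origin_node)
    except ValueError as exc:  # cycle / disconnected — no single line to blame
        raise SwcParseError(str(exc)) from exc


def write_swc(s: Skeleton, path: str | Path) -> None:
    """Write a skeleton in canonical form: one record per node, ascending id,
    floats in shortest round-trip representation. ``read_swc(write_swc(s))``
    is lossless and re-writing reproduces the bytes."""
    with open(path, "w") as fh:
        fh.write(f"# neuron {s.neuron_id}\n")
        for nid in sorted(s.nodes):
            n = s.nodes[nid]
            parent = -1 if n.parent_id is None else n.parent_id
            fh.write(f"{n.node_id} {n.node_type} {n.x} {n.y} {n.z} "
                     f"{n.radius} {parent}\n")


def read_skeleton_manifest(path: str | Path) -> list[Skeleton]:
    """Read a manifest TSV (neuron_id, swc_path, origin_node) and load every
    listed skeleton; swc_path is resolved relative to the manifest."""
    path = Path(path)
    df = pd.read_csv(path, sep="\t", dtype={"neuron_id": str})
    required = {"neuron_id", "swc_path", "origin_node"}
    missing = required - set(df.columns)
    if missing:
        raise ValueError(f"manifest {path}: missing columns {sorted(missing)}")
    skeletons = []
    for row in df.itertuples(index=False):
        origin = None if pd.isna(row.origin_node) else int(row.origin_node)
        skeletons.append(
            read_swc(path.parent / row.swc_path, neuron_id=str(row.neuron_id),
                     origin_node=origin))
    return skeletons
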