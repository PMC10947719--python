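"""Neighbor search: periodic-aware quad/octree over agent bounding volumes.

The tree partitions the domain recursively (quadtree in 2D, octree in
3D); each entry -- an axis-aligned bounding box around an agent's
sphere-swept volume -- is stored in the deepest node that fully contains
it, so a box query visits only the branches it intersects plus the
ancestors' straddling entries.  Queries return a *superset* of the true
neighbors (exact collision tests filter afterwards) and never exclude a
true neighbor, including across periodic seams, which are handled by
querying all periodic images of the query box.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field

import numpy as np

from .geometry import Domain

__all__ = ["SpatialIndex", "find_neighbors"]


class _Node:
    __slots__ = ("lo", "hi", "mid", "children", "items", "depth")

    def __init__(self, lo: np.ndarray, hi: np.ndarray, depth: int):
        self.lo = lo
        self.hi = hi
        self.mid = 0.5 * (lo + hi)
        self.children: list["_Node"] | None = None
        self.items: list[tuple[object, np.ndarray, np.ndarray]] = []
        self.depth = depth


class SpatialIndex:
    """Quadtree (2D) / octree (3D) over axis-aligned bounding boxes."""

    def __init__(self, domain: Domain, max_depth: int = 7, max_items: int = 8):
        self.domain = domain
        self.max_depth = max_depth
        self.max_items = max_items
        lengths = [L if np.isfinite(L) else 1e6 for L in domain.lengths]
        self._root = _Node(np.zeros(domain.dim), np.array(lengths, dtype=float), 0)
        self._count = 0

    def __len__(self) -> int:
        return self._count

    # -- insertion ---------------------------------------------------------
    def insert(self, key: object, lo: np.ndarray, hi: np.ndarray) -> None:
        lo = np.asarray(lo, dtype=float)
        hi = np.asarray(hi, dtype=float)
        center = 0.5 * (lo + hi)
        wrapped = self.domain.wrap_position(center)
        shift = wrapped - center
        lo = lo + shift
        hi = hi + shift
        # a box crossing a periodic seam exists on both sides: store every
        # image that touches the domain (queries deduplicate by key)
        for ilo, ihi in self._query_boxes(lo, hi):
            self._insert_one(key, ilo, ihi)
        self._count += 1

    def _insert_one(self, key: object, lo: np.ndarray, hi: np.ndarray) -> None:
        node = self._root
        while True:
            if node.depth >= self.max_depth:
                break
            if node.children is None:
                if len(node.items) < self.max_items:
                    break
                self._split(node)
            child = self._child_containing(node, lo, hi)
            if child is None:
                break  # straddles a split plane: stays at this node
            node = child
        node.items.append((key, lo, hi))

    def _split(self, node: _Node) -> None:
        dim = len(node.lo)
        node.children = []
        for corner in itertools.product((0, 1), repeat=dim):
            lo = np.where(np.array(corner, bool), node.mid, node.lo)
            hi = np.where(np.array(corner, bool), node.hi, node.mid)
            node.children.append(_Node(lo, hi, node.depth + 1))
        keep = []
        for item in node.items:
            child = self._child_containing(node, item[1], item[2])
            if child is None:
                keep.append(item)
            else:
                child.items.append(item)
        node.items = keep

    @staticmethod
    def _child_containing(node: _Node, lo: np.ndarray, hi: np.ndarray):
        if node.children is None:
            return None
        below = hi <= node.mid
        above = lo >= node.mid
        if not np.all(below | above):
            return None
        # children are ordered by itertools.product corner tuples
        corner = tuple((1 if above[ax] else 0) for ax in range(len(lo)))
        flat = 0
        for c in corner:
            flat = flat * 2 + c
        return node.children[flat]

    # -- queries -----------------------------------------------------------
    def _query_boxes(self, lo: np.ndarray, hi: np.ndarray):
        """Periodic images of a query box that intersect the root domain."""
        shifts_per_axis = []
        for ax, (L, per) in enumerate(zip(self.domain.lengths, self.domain.periodic)):
            if per and np.isfinite(L):
                opts = {0.0}
                if lo[ax] < 0:
                    opts.add(L)
                if hi[ax] > L:
                    opts.add(-L)
                shifts_per_axis.append(sorted(opts))
            else:
                shifts_per_axis.append([0.0])
        for combo in itertools.product(*shifts_per_axis):
            shift = np.array(combo)
            yield lo + shift, hi + shift

    def query(self, lo: np.ndarray, hi: np.ndarray) -> list[object]:
        """All keys whose stored box intersects the query box (superset)."""
        lo = np.asarray(lo, dtype=float)
        hi = np.asarray(hi, dtype=float)
        out: list[object] = []
        seen: set[int] = set()
        for qlo, qhi in self._query_boxes(lo, hi):
            self._collect(self._root, qlo, qhi, out, seen)
        return out

    def _collect(self, node: _Node, qlo, qhi, out, seen) -> None:
        if np.any(node.hi < qlo) or np.any(node.lo > qhi):
            return
        for key, ilo, ihi in node.items:
            if np.all(ihi >= qlo) and np.all(ilo <= qhi):
                ident = id(key) if not isinstance(key, (int, str)) else key
                if ident not in seen:
                    seen.add(ident)
                    out.append(key)
        if node.children is not None:
            for child in node.children:
                self._collect(child, qlo, qhi, out, seen)


def agent_bounds(agent) -> tuple[np.ndarray, np.ndarray]:
    pts = np.array([p.position for p in agent.points])
    return pts.min(axis=0) - agent.radius, pts.max(axis=0) + agent.radius


def build_index(agents, domain: Domain, **kwargs) -> SpatialIndex:
    index = SpatialIndex(domain, **kwargs)
    for agent in agents:
        lo, hi = agent_bounds(agent)
        index.insert(agent.id, lo, hi)
    return index


def find_neighbors(
    index: SpatialIndex,
    agents_by_id: dict,
    agent,
    search_range: float,
) -> set:
    """Exactly the agents whose collision gap to ``agent`` is <= range."""
    from .mechanics import body_gap  # late import to avoid a cycle

    lo, hi = agent_bounds(agent)
    candidates = index.query(lo - search_range, hi + search_range)
    result = set()
    for key in candidates:
        if key == agent.id:
            continue
        other = agents_by_id[key]
        res = body_gap(agent, other, index.domain)
        if res.gap <= search_range:
            result.add(key)
    return result
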