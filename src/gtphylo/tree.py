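"""Unrooted binary cell trees.

A tree over c cells is stored as an adjacency map with branch lengths in
expected mutations per SNV site.  Tips (degree 1) carry cell labels;
internal nodes have degree 3 (a rooted representation used during pruning
places a virtual root at a node or edge, which for a reversible model does
not affect the likelihood).  Newick reading/writing goes through dendropy.
"""

from __future__ import annotations

import io
from collections import deque

import dendropy
import numpy as np

MIN_BRANCH_LENGTH = 1e-9
MAX_BRANCH_LENGTH = 100.0
DEFAULT_BRANCH_LENGTH = 0.1


class CellTree:
    """Unrooted tree with labeled tips and branch lengths."""

    def __init__(self) -> None:
        self.adj: dict[int, dict[int, float]] = {}
        self.labels: dict[int, str] = {}
        self._next_id = 0

    # -- construction -----------------------------------------------------

    def new_node(self, label: str | None = None) -> int:
        nid = self._next_id
        self._next_id += 1
        self.adj[nid] = {}
        if label is not None:
            self.labels[nid] = label
        return nid

    def add_edge(self, u: int, v: int, length: float) -> None:
        self.adj[u][v] = length
        self.adj[v][u] = length

    def remove_edge(self, u: int, v: int) -> None:
        del self.adj[u][v]
        del self.adj[v][u]

    def remove_node(self, u: int) -> None:
        for v in list(self.adj[u]):
            self.remove_edge(u, v)
        del self.adj[u]
        self.labels.pop(u, None)

    def set_length(self, u: int, v: int, length: float) -> None:
        self.adj[u][v] = length
        self.adj[v][u] = length

    def length(self, u: int, v: int) -> float:
        return self.adj[u][v]

    def copy(self) -> "CellTree":
        t = CellTree()
        t.adj = {u: dict(nbrs) for u, nbrs in self.adj.items()}
        t.labels = dict(self.labels)
        t._next_id = self._next_id
        return t

    # -- queries ----------------------------------------------------------

    @property
    def nodes(self):
        return self.adj.keys()

    def degree(self, u: int) -> int:
        return len(self.adj[u])

    def tips(self) -> list[int]:
        return sorted(n for n in self.adj if len(self.adj[n]) == 1)

    def tip_labels(self) -> list[str]:
        return [self.labels[n] for n in self.tips()]

    def tip_by_label(self, label: str) -> int:
        for n, lab in self.labels.items():
            if lab == label and self.degree(n) == 1:
                return n
        raise KeyError(label)

    @property
    def n_tips(self) -> int:
        return sum(1 for n in self.adj if len(self.adj[n]) == 1)

    def edges(self) -> list[tuple[int, int]]:
        """Each undirected edge once, as (u, v) with u < v."""
        return [(u, v) for u in sorted(self.adj) for v in self.adj[u] if u < v]

    def total_length(self) -> float:
        return sum(l for _, nbrs in self.adj.items() for l in nbrs.values()) / 2

    def is_binary(self) -> bool:
        return all(len(nbrs) in (1, 3) for nbrs in self.adj.values())

    def validate(self) -> None:
        degs = [self.degree(n) for n in self.adj]
        if any(d not in (1, 3) for d in degs) and len(self.adj) > 2:
            raise ValueError("tree is not unrooted binary")
        labels = self.tip_labels()
        if len(set(labels)) != len(labels):
            raise ValueError("duplicate tip labels")

    def traversal(self, root: int | None = None):
        """Rooted traversal arrays from ``root`` (default: highest-degree node).

        Returns (order, parent, children) where ``order`` is a postorder
        node list ending at the root and ``parent[n]`` is None for the root.
        """
        if root is None:
            root = max(self.adj, key=lambda n: len(self.adj[n]))
        parent: dict[int, int | None] = {root: None}
        children: dict[int, list[int]] = {}
        order: list[int] = []
        stack = [root]
        while stack:
            u = stack.pop()
            order.append(u)
            kids = [v for v in self.adj[u] if v != parent[u]]
            children[u] = kids
            for v in kids:
                parent[v] = u
                stack.append(v)
        order.reverse()  # children before parents
        return order, parent, children

    # -- rearrangement ----------------------------------------------------

    def suppress_degree_two(self, u: int) -> tuple[int, int] | None:
        """Splice out a degree-2 node, merging its two edges; returns the
        new edge (a, b) or None if u is not degree 2."""
        if self.degree(u) != 2:
            return None
        (a, la), (b, lb) = self.adj[u].items()
        self.remove_node(u)
        self.add_edge(a, b, la + lb)
        return (a, b)

    def attach_on_edge(self, u: int, v: int, position: float = 0.5) -> int:
        """Split edge (u, v) with a new internal node; returns its id."""
        l = self.adj[u][v]
        mid = self.new_node()
        self.remove_edge(u, v)
        self.add_edge(u, mid, l * position)
        self.add_edge(mid, v, l * (1 - position))
        return mid

    def spr(self, prune_child: int, prune_parent: int,
            target_u: int, target_v: int,
            attach_length: float = DEFAULT_BRANCH_LENGTH) -> None:
        """Prune the subtree on the ``prune_child`` side of edge
        (prune_child, prune_parent) and regraft it on edge
        (target_u, target_v).

        ``prune_parent`` must be internal; the target edge must lie in the
        remaining tree.
        """
        self.remove_edge(prune_child, prune_parent)
        merged = self.suppress_degree_two(prune_parent)
        if merged is not None and {target_u, target_v} == {prune_parent}:
            raise ValueError("target edge was destroyed by pruning")
        mid = self.attach_on_edge(target_u, target_v)
        self.add_edge(prune_child, mid, attach_length)

    def edges_within_radius(self, seeds: list[int], radius: int,
                            exclude: set[int] | None = None):
        """Edges reachable within ``radius`` node-hops of any seed node."""
        exclude = exclude or set()
        dist = {s: 0 for s in seeds if s in self.adj}
        q = deque(dist)
        while q:
            u = q.popleft()
            if dist[u] >= radius:
                continue
            for v in self.adj[u]:
                if v not in dist and v not in exclude:
                    dist[v] = dist[u] + 1
                    q.append(v)
        seen = set()
        out = []
        for u in dist:
            for v in self.adj[u]:
                if v in dist and (min(u, v), max(u, v)) not in seen:
                    seen.add((min(u, v), max(u, v)))
                    out.append((u, v))
        return out

    # -- newick -----------------------------------------------------------

    def to_newick(self, root: int | None = None, support: dict | None = None,
                  precision: int = 10) -> str:
        """Newick string (unrooted: trifurcation at the root node).

        ``support`` optionally maps frozenset-of-tip-labels bipartition
        sides to labels placed on the corresponding internal edge.
        """
        order, parent, children = self.traversal(root)

        def clade_labels(n):
            if not children[n]:
                return frozenset([self.labels[n]])
            out = set()
            for k in children[n]:
                out |= clade_labels(k)
            return frozenset(out)

        def fmt(n):
            if not children[n]:
                s = self.labels[n]
            else:
                s = "(" + ",".join(fmt(k) for k in children[n]) + ")"
                if support is not None and parent[n] is not None:
                    lab = support.get(clade_labels(n))
                    if lab is not None:
                        s += str(lab)
            if parent[n] is not None:
                s += f":{self.adj[n][parent[n]]:.{precision}g}"
            return s

        root_node = order[-1]
        return fmt(root_node) + ";"

    @classmethod
    def from_newick(cls, newick: str) -> "CellTree":
        dt = dendropy.Tree.get(data=newick, schema="newick",
                               preserve_underscores=True)
        return cls.from_dendropy(dt)

    @classmethod
    def from_dendropy(cls, dtree: "dendropy.Tree") -> "CellTree":
        t = cls()
        # collapse a rooted bifurcation at the seed into an unrooted tree
        dtree.deroot()
        node_map = {}
        for nd in dtree.preorder_node_iter():
            label = nd.taxon.label if nd.taxon is not None else None
            node_map[nd] = t.new_node(label)
        for nd in dtree.preorder_node_iter():
            if nd.parent_node is not None:
                l = nd.edge.length if nd.edge.length is not None \
                    else DEFAULT_BRANCH_LENGTH
                t.add_edge(node_map[nd.parent_node], node_map[nd], max(l, 0.0))
        # dendropy may leave a degree-2 root on 2/3-tip trees
        for n in list(t.adj):
            if t.degree(n) == 2 and n not in t.labels:
                t.suppress_degree_two(n)
        return t

    def to_dendropy(self, taxon_namespace=None) -> "dendropy.Tree":
        return dendropy.Tree.get(
            data=self.to_newick(), schema="newick",
            preserve_underscores=True, taxon_namespace=taxon_namespace)

    def __repr__(self) -> str:
        return f"<CellTree with {self.n_tips} tips>"


def star_to_binary(labels: list[str]) -> CellTree:
    """Minimal tree for 2 or 3 labels (single topology)."""
    t = CellTree()
    tips = [t.new_node(lab) for lab in labels]
    if len(labels) == 2:
        t.add_edge(tips[0], tips[1], DEFAULT_BRANCH_LENGTH)
        return t
    center = t.new_node()
    for tip in tips:
        t.add_edge(center, tip, DEFAULT_BRANCH_LENGTH)
    return t


def random_tree(labels: list[str], rng: np.random.Generator,
                branch_length: float = DEFAULT_BRANCH_LENGTH) -> CellTree:
    """Uniformly random unrooted binary topology via random sequential
    addition (each of the (2c-5)!! topologies is equally likely)."""
    labels = list(labels)
    if len(set(labels)) != len(labels):
        raise ValueError("duplicate labels")
    if len(labels) < 2:
        raise ValueError("need at least 2 labels")
    if len(labels) <= 3:
        return star_to_binary(labels)
    t = star_to_binary(labels[:3])
    for lab in labels[3:]:
        edges = t.edges()
        u, v = edges[rng.integers(len(edges))]
        mid = t.attach_on_edge(u, v)
        tip = t.new_node(lab)
        t.add_edge(mid, tip, branch_length)
    return t
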