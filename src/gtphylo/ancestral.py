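"""Marginal ancestral genotype reconstruction and mutation mapping.

On a rooted tree with a fitted model, the marginal posterior of the
genotype at every node and site is computed from a downward (postorder)
pruning pass and an upward (preorder) pass.  The ML genotype per node/site
is the posterior argmax, ties broken by the fixed state-order precedence
so reconstructions are reproducible.  A mutation is predicted on a branch
whenever the ML genotypes at its two ends differ.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from . import alphabet as ab
from .ratematrix import RateMatrix
from .tree import CellTree


@dataclass
class AncestralReconstruction:
    tree: CellTree
    root: int
    node_names: dict[int, str]
    ml_genotypes: dict[int, np.ndarray]     # node -> per-site state index
    posteriors: dict[int, np.ndarray]       # node -> (sites, n_states)
    parent: dict[int, int | None] = field(default_factory=dict)
    children: dict[int, list[int]] = field(default_factory=dict)


def state_name(index: int, n_states: int) -> str:
    if n_states == 16:
        a, b = ab.phased_alleles(index)
        a, b = sorted((a, b))
        return f"{a}/{b}"
    return ab.UNPHASED_STATES[index]


def marginal_ancestral_genotypes(
        rooted_tree: CellTree, tip_vectors: dict[str, np.ndarray],
        model: RateMatrix, root: int | None = None) -> AncestralReconstruction:
    """Marginal posterior genotype vectors and ML genotypes per node/site.

    ``rooted_tree`` is typically the output of outgroup rooting (a
    degree-2 root node); ``tip_vectors`` map cell labels to
    (sites x n_states) likelihood vectors built per the input mode (error
    model, GL, or PL).
    """
    tree = rooted_tree
    if root is None:
        candidates = [n for n in tree.adj if tree.degree(n) == 2]
        root = candidates[0] if candidates else None
    order, parent, children = tree.traversal(root)
    root = order[-1]
    n_sites = next(iter(tip_vectors.values())).shape[0]
    # downward pass (conditional likelihoods of subtrees)
    down: dict[int, np.ndarray] = {}
    P_of: dict[int, np.ndarray] = {}
    for n in order:
        kids = children[n]
        if not kids:
            down[n] = tip_vectors[tree.labels[n]].astype(float)
        else:
            acc = np.ones((n_sites, model.n_states))
            for k in kids:
                P_of[k] = model.transition_matrix(tree.adj[k][n])
                acc = acc * (down[k] @ P_of[k].T)
            if n in tree.labels:
                acc = acc * tip_vectors[tree.labels[n]]
            down[n] = acc
        m = down[n].max(axis=1, keepdims=True)
        down[n] = down[n] / np.where(m > 0, m, 1.0)
    # upward pass (likelihood of the rest of the tree)
    up: dict[int, np.ndarray] = {root: np.tile(model.frequencies, (n_sites, 1))}
    for n in reversed(order):  # preorder
        for k in children[n]:
            acc = up[n].copy()
            for sib in children[n]:
                if sib != k:
                    acc = acc * (down[sib] @ P_of[sib].T)
            if n in tree.labels:
                acc = acc * tip_vectors[tree.labels[n]]
            up[k] = acc @ P_of[k]
            m = up[k].max(axis=1, keepdims=True)
            up[k] = up[k] / np.where(m > 0, m, 1.0)
    posteriors = {}
    ml = {}
    collapse = None
    if model.n_states == 16:
        # phase is unidentifiable: the ML genotype is the argmax over
        # unphased genotypes (summing both phasings), reported as the
        # canonical phased representative
        collapse = np.zeros((16, 10))
        for u, phasings in enumerate(ab.UNPHASED_TO_PHASED):
            for p in phasings:
                collapse[p, u] = 1.0
        canonical = np.array([ph[0] for ph in ab.UNPHASED_TO_PHASED])
    for n in order:
        post = down[n] * up[n]
        z = post.sum(axis=1, keepdims=True)
        post = post / np.where(z > 0, z, 1.0)
        posteriors[n] = post
        if collapse is None:
            ml[n] = np.argmax(post, axis=1)  # first index wins ties
        else:
            ml[n] = canonical[np.argmax(post @ collapse, axis=1)]
    names = {}
    counter = 0
    for n in reversed(order):
        if n in tree.labels and tree.degree(n) == 1:
            names[n] = tree.labels[n]
        else:
            names[n] = f"Node{counter}"
            counter += 1
    return AncestralReconstruction(tree, root, names, ml, posteriors,
                                   parent, children)


@dataclass
class MutationMap:
    """Per-branch lists of inferred genotype changes.

    Each branch (keyed by its child node) lists (site_id, from_state,
    to_state) with differing endpoints.
    """

    branches: dict[int, list[tuple[str, int, int]]]
    reconstruction: AncestralReconstruction
    n_states: int = 16

    @property
    def total_mutations(self) -> int:
        return sum(len(v) for v in self.branches.values())

    def to_text(self) -> str:
        """One line per branch: label, tab, comma-separated site:from>to."""
        rec = self.reconstruction
        lines = []
        for node, muts in sorted(self.branches.items(),
                                 key=lambda kv: rec.node_names[kv[0]]):
            if not muts:
                continue
            entries = ",".join(
                f"{site}:{state_name(a, self.n_states)}"
                f">{state_name(b, self.n_states)}"
                for site, a, b in muts)
            lines.append(f"{rec.node_names[node]}\t{entries}")
        return "\n".join(lines) + ("\n" if lines else "")

    def to_newick(self) -> str:
        """Branch-labeled tree: internal nodes carry the branch names used
        in the text listing."""
        rec = self.reconstruction

        def fmt(n):
            kids = rec.children[n]
            if not kids:
                s = rec.tree.labels[n]
            else:
                s = "(" + ",".join(fmt(k) for k in kids) + ")"
                s += rec.node_names[n]
            if rec.parent[n] is not None:
                s += f":{rec.tree.adj[n][rec.parent[n]]:.10g}"
            return s

        return fmt(rec.root) + ";"


def map_mutations(reconstruction: AncestralReconstruction,
                  site_ids: list[str] | None = None,
                  outgroup_labels=None) -> MutationMap:
    """Predict mutations on branches from ML endpoint genotypes.

    When the root has exactly two children (outgroup rooting), changes
    across the two root-adjacent edges are merged onto the ingroup edge,
    matching the zero-length-outgroup rooting convention.
    """
    rec = reconstruction
    n_states = next(iter(rec.posteriors.values())).shape[1]
    n_sites = rec.ml_genotypes[rec.root].shape[0]
    if site_ids is None:
        site_ids = [str(j) for j in range(n_sites)]
    outgroup = set(outgroup_labels or ())

    root_kids = rec.children[rec.root]
    merge_pair = None
    if len(root_kids) == 2:
        def clade(n):
            out = set()
            stack = [n]
            while stack:
                u = stack.pop()
                if not rec.children[u]:
                    out.add(rec.tree.labels[u])
                stack.extend(rec.children[u])
            return out
        ingroup_child = root_kids[1]
        outgroup_child = root_kids[0]
        if outgroup and clade(root_kids[1]) <= outgroup:
            ingroup_child, outgroup_child = root_kids[0], root_kids[1]
        elif outgroup and not clade(root_kids[0]) <= outgroup:
            # no side is the outgroup; default orientation
            ingroup_child = root_kids[0]
            outgroup_child = root_kids[1]
        elif not outgroup:
            ingroup_child = root_kids[0]
            outgroup_child = root_kids[1]
        merge_pair = (outgroup_child, ingroup_child)

    branches: dict[int, list[tuple[str, int, int]]] = {}
    for n in rec.parent:
        p = rec.parent[n]
        if p is None:
            continue
        if merge_pair and n in merge_pair:
            continue
        diff = np.nonzero(rec.ml_genotypes[n] != rec.ml_genotypes[p])[0]
        branches[n] = [(site_ids[j], int(rec.ml_genotypes[p][j]),
                        int(rec.ml_genotypes[n][j])) for j in diff]
    if merge_pair:
        og, ig = merge_pair
        diff = np.nonzero(rec.ml_genotypes[ig] != rec.ml_genotypes[og])[0]
        branches[ig] = [(site_ids[j], int(rec.ml_genotypes[og][j]),
                         int(rec.ml_genotypes[ig][j])) for j in diff]
        branches[og] = []
    return MutationMap(branches, rec, n_states)
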