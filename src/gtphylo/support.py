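"""Bootstrap branch support and Robinson-Foulds tree comparison.

Nonparametric bootstrap replicates resample SNV sites with replacement;
branch support for the ML tree is either the classical Felsenstein
proportion (percentage of replicate trees containing the exact
bipartition) or the transfer bootstrap expectation (TBE), which credits
inexact matches: for a branch whose lighter side has p taxa, the support
contribution of a replicate is 1 - d/(p-1) where d is the minimum transfer
distance between the branch's bipartition and any branch of the replicate
tree.  Tree accuracy is 1 - nRF, where nRF divides the Robinson-Foulds
bipartition distance by the total number of internal branches in both
trees.
"""

from __future__ import annotations

import numpy as np

from .io import GenotypeMatrix
from .tree import CellTree


def bootstrap_replicates(data: GenotypeMatrix, n: int,
                         seed: int) -> list[GenotypeMatrix]:
    """n datasets of s sites drawn i.i.d. with replacement from the
    original s columns."""
    if n < 1:
        raise ValueError("need at least one replicate")
    s = data.n_sites
    if s == 0:
        raise ValueError("cannot bootstrap an empty matrix")
    rng = np.random.default_rng(seed)
    return [data.take_sites(rng.integers(s, size=s)) for _ in range(n)]


def bootstrap_site_indices(n_sites: int, n: int, seed: int) -> list[np.ndarray]:
    """Column index vectors for bootstrap resampling (for GL-mode input,
    where genotype and likelihood columns must be resampled jointly)."""
    if n_sites == 0:
        raise ValueError("cannot bootstrap an empty matrix")
    rng = np.random.default_rng(seed)
    return [rng.integers(n_sites, size=n_sites) for _ in range(n)]


# -- bipartitions ----------------------------------------------------------


def internal_bipartitions(tree: CellTree) -> dict[frozenset, tuple[int, int]]:
    """Nontrivial bipartitions of an (un)rooted tree.

    Each internal edge maps the side excluding a fixed reference taxon
    (the lexicographically smallest label) to the edge (child, parent).
    Multifurcating trees are supported; pendant edges are excluded.
    """
    labels = sorted(tree.tip_labels())
    refset = frozenset(labels)
    order, parent, children = tree.traversal()
    clades: dict[int, frozenset] = {}
    out: dict[frozenset, tuple[int, int]] = {}
    for n in order:
        if not children[n]:
            clades[n] = frozenset([tree.labels[n]])
            continue
        clades[n] = frozenset().union(*(clades[k] for k in children[n]))
        if n in tree.labels:
            clades[n] |= frozenset([tree.labels[n]])
    ref = labels[0]
    for n in order[:-1]:
        side = clades[n]
        if len(side) < 2 or len(side) > len(labels) - 2:
            continue  # trivial (pendant) bipartition
        canon = side if ref not in side else refset - side
        out[canon] = (n, parent[n])
    return out


def _check_same_taxa(t1: CellTree, t2: CellTree) -> None:
    a, b = set(t1.tip_labels()), set(t2.tip_labels())
    if a != b:
        raise ValueError(
            f"taxon sets differ (only in first: {sorted(a - b)}, "
            f"only in second: {sorted(b - a)})")


def nrf_distance(tree1: CellTree, tree2: CellTree) -> float:
    """Normalized Robinson-Foulds distance in [0, 1].

    RF counts bipartitions unique to either tree; the denominator is the
    total number of internal branches present in both trees, so unresolved
    trees reduce it.
    """
    _check_same_taxa(tree1, tree2)
    if tree1.n_tips < 4:
        raise ValueError("nRF needs at least 4 taxa")
    b1 = set(internal_bipartitions(tree1))
    b2 = set(internal_bipartitions(tree2))
    denom = len(b1) + len(b2)
    if denom == 0:
        return 0.0
    return len(b1 ^ b2) / denom


def felsenstein_support(ml_tree: CellTree,
                        bootstrap_trees: list[CellTree]) -> dict[frozenset, float]:
    """Percentage of replicate trees containing each internal branch
    (exact bipartition matches only)."""
    for t in bootstrap_trees:
        _check_same_taxa(ml_tree, t)
    ml_bips = internal_bipartitions(ml_tree)
    counts = dict.fromkeys(ml_bips, 0)
    for t in bootstrap_trees:
        reps = set(internal_bipartitions(t))
        for b in counts:
            if b in reps:
                counts[b] += 1
    n = len(bootstrap_trees)
    return {b: 100.0 * c / n for b, c in counts.items()}


def _transfer_distance(side: frozenset, all_taxa: frozenset,
                       rep_sides: list[frozenset], p: int) -> int:
    """Minimum transfer distance of a bipartition to any branch of a
    replicate tree, capped at p-1 (achievable against a pendant edge)."""
    best = p - 1
    comp = all_taxa - side
    for r in rep_sides:
        d = min(len(side ^ r), len(comp ^ r))
        if d < best:
            best = d
            if best == 0:
                break
    return best


def transfer_support(ml_tree: CellTree,
                     bootstrap_trees: list[CellTree]) -> dict[frozenset, float]:
    """Transfer bootstrap expectation per internal branch, in percent.

    Equals the Felsenstein support when every replicate matches exactly,
    and is never smaller.
    """
    for t in bootstrap_trees:
        _check_same_taxa(ml_tree, t)
    all_taxa = frozenset(ml_tree.tip_labels())
    ml_bips = internal_bipartitions(ml_tree)
    rep_bips = [list(internal_bipartitions(t)) for t in bootstrap_trees]
    out = {}
    for side in ml_bips:
        p = min(len(side), len(all_taxa) - len(side))
        if p < 2:
            continue
        total = 0.0
        for reps in rep_bips:
            d = _transfer_distance(side, all_taxa, reps, p)
            total += 1.0 - d / (p - 1)
        out[side] = 100.0 * total / len(bootstrap_trees)
    return out


def annotate_support(tree: CellTree, support: dict[frozenset, float]) -> str:
    """Newick string with integer-rounded support as internal edge labels."""
    labels = {side: str(int(round(v))) for side, v in support.items()}
    # to_newick keys clades by their own taxon set; supply both sides
    all_taxa = frozenset(tree.tip_labels())
    both = dict(labels)
    for side, lab in labels.items():
        both[all_taxa - side] = lab
    return tree.to_newick(support=both)
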