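"""Phylogenetic likelihood of cell trees by Felsenstein pruning.

The log-likelihood of an unrooted tree is the sum over (compressed) SNV
site patterns of the log probability of the observed tip genotype
likelihood vectors, obtained by a postorder pass of conditional genotype
likelihood vectors and a stationary-frequency-weighted summation at a
virtual root.  For a reversible model the virtual root may sit on any
node/edge without changing the result.  Per-node rescaling by the maximum
conditional likelihood (with accumulated log offsets) prevents underflow.
"""

from __future__ import annotations

import numpy as np

from .ratematrix import RateMatrix
from .tree import CellTree


def compress_patterns(matrix: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Collapse identical site columns of a (cells x sites) matrix.

    Returns (patterns, weights): patterns is cells x n_patterns, weights
    the column multiplicities.  Log-likelihoods are bit-identical to the
    uncompressed computation.
    """
    cols, inverse, counts = np.unique(matrix, axis=1, return_inverse=True,
                                      return_counts=True)
    del inverse
    return cols, counts.astype(float)


class PruningEngine:
    """Likelihood calculator bound to a tree, tip vectors, and a model.

    ``tip_vectors`` maps cell label -> (n_patterns, n_states) array of
    relative genotype likelihoods; ``weights`` are pattern multiplicities.
    The tree may be mutated in place (lengths and topology); calls always
    recompute from the current state.
    """

    def __init__(self, tree: CellTree, tip_vectors: dict[str, np.ndarray],
                 weights: np.ndarray, model: RateMatrix) -> None:
        self.tree = tree
        self.model = model
        self.weights = np.asarray(weights, dtype=float)
        labels = tree.tip_labels()
        missing = set(labels) - set(tip_vectors)
        extra = set(tip_vectors) - set(labels)
        if missing or extra:
            raise ValueError(
                f"tree/tip label mismatch (missing={sorted(missing)}, "
                f"unused={sorted(extra)})")
        self.tip_vectors = tip_vectors
        first = next(iter(tip_vectors.values()))
        self.n_patterns = first.shape[0]
        if first.shape[1] != model.n_states:
            raise ValueError("tip vector state count does not match model")
        for lab, v in tip_vectors.items():
            if np.any(v.max(axis=1) <= 0):
                i = int(np.argmax(v.max(axis=1) <= 0))
                raise ValueError(
                    f"cell {lab!r}: no genotype has positive likelihood at "
                    f"pattern {i}")

    def set_tip_vectors(self, tip_vectors: dict[str, np.ndarray]) -> None:
        self.tip_vectors = tip_vectors

    # -- core pruning ------------------------------------------------------

    def _clv_pass(self, root: int | None = None):
        """Postorder conditional likelihood vectors and log scale offsets.

        Returns (order, parent, children, clv, logscale) where for node n
        clv[n] is (n_patterns, n_states), rescaled to max 1 per pattern,
        and logscale[n] the accumulated per-pattern log rescaling factors
        of the subtree below n.
        """
        tree = self.tree
        order, parent, children = tree.traversal(root)
        # transition matrices for all child edges at once
        edge_nodes = [n for n in order if parent[n] is not None]
        ts = np.array([tree.adj[n][parent[n]] for n in edge_nodes])
        Ps = self.model.transition_matrices(ts)
        P_of = {n: Ps[i] for i, n in enumerate(edge_nodes)}
        # logscale[n] is None while no rescaling has occurred in n's subtree
        clv: dict[int, np.ndarray] = {}
        logscale: dict[int, np.ndarray | None] = {}
        for n in order:
            kids = children[n]
            if not kids:
                clv[n] = self.tip_vectors[tree.labels[n]]
                logscale[n] = None
                continue
            acc = None
            ls = None
            for k in kids:
                msg = clv[k] @ P_of[k].T
                acc = msg if acc is None else acc * msg
                if logscale[k] is not None:
                    ls = logscale[k] if ls is None else ls + logscale[k]
            if n in tree.labels:  # traversal rooted at a tip
                acc = acc * self.tip_vectors[tree.labels[n]]
            # rescale lazily: only once conditional likelihoods get small
            # (zero maxima surface as non-finite values at the root check)
            m = acc.max(axis=1)
            if m.min() < 1e-120:
                with np.errstate(divide="ignore", invalid="ignore"):
                    acc = acc / m[:, None]
                    lg = np.log(m)
                ls = lg if ls is None else ls + lg
            clv[n] = acc
            logscale[n] = ls
        return order, parent, children, clv, logscale

    def site_loglikelihoods(self, root: int | None = None) -> np.ndarray:
        """Per-pattern log-likelihoods (unweighted)."""
        order, parent, children, clv, logscale = self._clv_pass(root)
        r = order[-1]
        site_like = clv[r] @ self.model.frequencies
        if np.any(site_like <= 0) or not np.all(np.isfinite(site_like)):
            bad = int(np.argmax(~(site_like > 0)))
            raise FloatingPointError(f"non-finite likelihood at pattern {bad}")
        out = np.log(site_like)
        if logscale[r] is not None:
            out = out + logscale[r]
        return out

    def loglikelihood(self, root: int | None = None) -> float:
        return float(self.weights @ self.site_loglikelihoods(root))

    # -- directional conditional vectors ----------------------------------

    def directional_clvs(self, root: int | None = None):
        """Conditional likelihood vectors for every directed edge.

        Returns (D, LS) where D[(u, v)] is the CLV *at node u* of the tree
        component containing u when edge (u, v) is cut (looking away from
        v), and LS[(u, v)] the accumulated per-pattern log scale offsets.
        Only the connected component containing ``root`` is visited, which
        lets SPR scoring work on a tree with a detached subtree.  Used for
        constant-time scoring of SPR regraft candidates.
        """
        tree = self.tree
        order, parent, children = tree.traversal(root)
        edge_nodes = [n for n in order if parent[n] is not None]
        ts = np.array([tree.adj[n][parent[n]] for n in edge_nodes])
        Ps = self.model.transition_matrices(ts)
        P_of = {n: Ps[i] for i, n in enumerate(edge_nodes)}
        D: dict[tuple[int, int], np.ndarray] = {}
        LS: dict[tuple[int, int], np.ndarray] = {}
        zero = np.zeros(self.n_patterns)
        raw_ls: dict[tuple[int, int], np.ndarray | None] = {}

        def finalize(key, acc, ls):
            m = acc.max(axis=1)
            if m.min() < 1e-120:  # lazy rescaling, as in the pruning pass
                with np.errstate(divide="ignore", invalid="ignore"):
                    acc = acc / m[:, None]
                    lg = np.log(m)
                ls = lg if ls is None else ls + lg
            D[key] = acc
            raw_ls[key] = ls
            LS[key] = zero if ls is None else ls

        def add_ls(ls, key):
            other = raw_ls[key]
            if other is None:
                return ls
            return other if ls is None else ls + other

        for n in order:  # postorder: subtree CLVs (n looking away from parent)
            p = parent[n]
            if p is None:
                continue
            kids = children[n]
            if not kids:
                D[(n, p)] = self.tip_vectors[tree.labels[n]]
                raw_ls[(n, p)] = None
                LS[(n, p)] = zero
                continue
            acc = None
            ls = None
            for k in kids:
                msg = D[(k, n)] @ P_of[k].T
                acc = msg if acc is None else acc * msg
                ls = add_ls(ls, (k, n))
            if n in tree.labels:
                acc = acc * self.tip_vectors[tree.labels[n]]
            finalize((n, p), acc, ls)
        for n in reversed(order):  # preorder: rest-of-tree CLVs
            p = parent[n]
            for c in children[n]:
                acc = None
                ls = None
                for k in children[n]:
                    if k == c:
                        continue
                    msg = D[(k, n)] @ P_of[k].T
                    acc = msg if acc is None else acc * msg
                    ls = add_ls(ls, (k, n))
                if p is not None:
                    msg = D[(p, n)] @ P_of[n].T
                    acc = msg if acc is None else acc * msg
                    ls = add_ls(ls, (p, n))
                if n in tree.labels:
                    tipv = self.tip_vectors[tree.labels[n]]
                    acc = tipv if acc is None else acc * tipv
                if acc is None:  # n is the root with a single child
                    acc = np.ones((self.n_patterns, self.model.n_states))
                finalize((n, c), acc, ls)
        return D, LS

    # -- single-edge profile ----------------------------------------------

    def edge_profile(self, u: int, v: int):
        """Factor the likelihood across edge (u, v).

        Returns a function f(t) giving the tree log-likelihood when the
        length of (u, v) is t, everything else held fixed.  Used by
        branch-length optimization: each evaluation costs a single
        matrix-vector pass instead of a full tree traversal.
        """
        # root the traversal at u; v becomes a child of u
        order, parent, children, clv, logscale = self._clv_pass(root=u)
        assert parent[v] == u
        # conditional vector at u excluding v's subtree
        tree = self.tree
        down_v = clv[v]
        base = logscale[v]
        kids = [k for k in children[u] if k != v]
        if kids:
            acc = None
            for k in kids:
                P = self.model.transition_matrix(tree.adj[k][u])
                msg = clv[k] @ P.T
                acc = msg if acc is None else acc * msg
                if logscale[k] is not None:
                    base = (logscale[k] if base is None
                            else base + logscale[k])
            if u in tree.labels and tree.degree(u) == 1:
                acc = acc * self.tip_vectors[tree.labels[u]]
        else:  # u is a tip
            acc = self.tip_vectors[tree.labels[u]]
        rest = acc * self.model.frequencies  # (npat, nstates)
        if base is None:
            base = np.zeros(self.n_patterns)
        w = self.weights

        def f(t: float) -> float:
            P = self.model.transition_matrix(t)
            site = np.einsum("ps,ps->p", rest, down_v @ P.T)
            if np.any(site <= 0):
                return -np.inf
            return float(w @ (np.log(site) + base))

        return f


def tree_loglikelihood(tree: CellTree, tip_vectors: dict[str, np.ndarray],
                       weights: np.ndarray, model: RateMatrix,
                       root: int | None = None):
    """Tree log-likelihood and per-pattern values (convenience wrapper)."""
    eng = PruningEngine(tree, tip_vectors, weights, model)
    per_site = eng.site_loglikelihoods(root)
    return float(eng.weights @ per_site), per_site


def root_with_outgroup(tree: CellTree, outgroup_labels) -> CellTree:
    """Root an unrooted tree on the edge separating the outgroup clade.

    Returns a copy with a degree-2 root node inserted on that edge.  The
    outgroup labels must form one side of a bipartition of the tree;
    otherwise a ValueError reports the offending split.
    """
    outgroup = set(outgroup_labels)
    labels = set(tree.tip_labels())
    if not outgroup or not outgroup < labels:
        raise ValueError("outgroup must be a proper nonempty subset of tips")
    if len(outgroup) == 1:
        tip = tree.tip_by_label(next(iter(outgroup)))
        rooted = tree.copy()
        nbr = next(iter(rooted.adj[tip]))
        root = rooted.attach_on_edge(tip, nbr, position=0.5)
        return rooted
    order, parent, children = tree.traversal()
    # find the edge whose tip-side clade equals the outgroup
    clades: dict[int, frozenset] = {}
    for n in order:
        if not children[n]:
            clades[n] = frozenset([tree.labels[n]])
        else:
            clades[n] = frozenset().union(*(clades[k] for k in children[n]))
    for n in order[:-1]:
        side = clades[n]
        if side == outgroup or (labels - side) == outgroup:
            rooted = tree.copy()
            rooted.attach_on_edge(n, parent[n], position=0.5)
            return rooted
    raise ValueError(
        f"outgroup {sorted(outgroup)} is not monophyletic in the tree")
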