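"""Starting trees and SPR maximum-likelihood tree search.

The search starts from parsimony-based (randomized stepwise addition with
Fitch scoring over the genotype alphabet) and/or uniformly random
topologies, then alternates subtree-pruning-and-regrafting rounds with
model / branch-length / error-rate re-optimization until no move improves
the log-likelihood by more than the convergence tolerance.  Candidate
regrafts are scored with current branch lengths (accept-if-better); branch
lengths and model parameters are fully re-optimized between rounds.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np

from . import alphabet as ab
from . import errors as err
from .io import GenotypeMatrix, PLData
from .likelihood import PruningEngine, compress_patterns
from .optimize import (build_rate_matrix, optimize_branch_lengths,
                       optimize_error_params, optimize_substitution_params)
from .ratematrix import ModelSpec, SubstitutionParams, parse_model_string
from .tree import (DEFAULT_BRANCH_LENGTH, CellTree, random_tree,
                   star_to_binary)


@dataclass
class SearchConfig:
    n_parsimony_starts: int = 10
    n_random_starts: int = 10
    spr_radius_schedule: tuple[int, ...] = (5, 10, 1000)
    loglik_epsilon: float = 0.1
    final_epsilon: float = 0.001
    seed: int = 0
    max_iterations: int = 10
    optimize_model: bool = True  # refit exchangeabilities/frequencies

    def __post_init__(self) -> None:
        if self.n_parsimony_starts + self.n_random_starts < 1:
            raise ValueError("need at least one starting tree")
        if self.loglik_epsilon <= 0:
            raise ValueError("loglik_epsilon must be positive")


# -- starting trees -------------------------------------------------------


def starting_tree_random(labels: list[str], seed: int) -> CellTree:
    """Uniformly random unrooted binary topology over the labels."""
    if len(labels) < 3:
        raise ValueError("need at least 3 labels")
    return random_tree(labels, np.random.default_rng(seed))


_FULL_MASK = np.uint16((1 << ab.N_UNPHASED) - 1)


def _fitch_masks(codes: np.ndarray) -> np.ndarray:
    """Per-cell per-site state bitmasks over the 10 unphased states."""
    masks = np.empty(codes.shape, dtype=np.uint16)
    for s in range(ab.N_UNPHASED):
        masks[codes == s] = np.uint16(1 << s)
    masks[codes == ab.MISSING_INDEX] = _FULL_MASK
    return masks


def _fitch_score(tree: CellTree, tip_masks: dict[str, np.ndarray],
                 weights: np.ndarray) -> float:
    """Weighted Fitch parsimony score of an unrooted tree."""
    order, parent, children = tree.traversal()
    sets: dict[int, np.ndarray] = {}
    score = 0.0
    for n in order:
        kids = children[n]
        if not kids:
            sets[n] = tip_masks[tree.labels[n]]
            continue
        acc = None
        for k in kids:
            if acc is None:
                acc = sets[k]
                continue
            inter = acc & sets[k]
            empty = inter == 0
            score += float(weights[empty].sum())
            acc = np.where(empty, acc | sets[k], inter)
        if n in tree.labels:
            inter = acc & tip_masks[tree.labels[n]]
            empty = inter == 0
            score += float(weights[empty].sum())
            acc = np.where(empty, acc | tip_masks[tree.labels[n]], inter)
        sets[n] = acc
    return score


def starting_tree_parsimony(codes: np.ndarray, labels: list[str],
                            weights: np.ndarray, seed: int) -> CellTree:
    """Randomized stepwise-addition parsimony tree.

    ``codes`` is cells x patterns over the unphased alphabet (10 =
    missing); at each step the next cell is inserted on the edge that
    minimizes the Fitch parsimony score, ties broken at random.
    """
    rng = np.random.default_rng(seed)
    if len(set(labels)) != len(labels):
        raise ValueError("duplicate labels")
    n = len(labels)
    masks = _fitch_masks(codes)
    tip_masks = {lab: masks[i] for i, lab in enumerate(labels)}
    addition_order = list(rng.permutation(n))
    all_missing = [i for i in addition_order
                   if np.all(codes[i] == ab.MISSING_INDEX)]
    if all_missing:
        warnings.warn(
            f"{len(all_missing)} cell(s) have only missing genotypes; "
            "their placement is effectively random")
    if n <= 3:
        return star_to_binary([labels[i] for i in addition_order])
    tree = star_to_binary([labels[i] for i in addition_order[:3]])
    for i in addition_order[3:]:
        lab = labels[i]
        best_score = np.inf
        best_edges = []
        for u, v in tree.edges():
            mid = tree.attach_on_edge(u, v)
            tip = tree.new_node(lab)
            tree.add_edge(mid, tip, DEFAULT_BRANCH_LENGTH)
            s = _fitch_score(tree, tip_masks, weights)
            # undo
            tree.remove_node(tip)
            tree.suppress_degree_two(mid)
            if s < best_score - 1e-9:
                best_score, best_edges = s, [(u, v)]
            elif s <= best_score + 1e-9:
                best_edges.append((u, v))
        u, v = best_edges[rng.integers(len(best_edges))]
        mid = tree.attach_on_edge(u, v)
        tree.add_edge(mid, tree.new_node(lab), DEFAULT_BRANCH_LENGTH)
    return tree


# -- data wrapper ----------------------------------------------------------


@dataclass
class LikelihoodData:
    """Site-pattern-compressed input for likelihood computations."""

    labels: list[str]
    weights: np.ndarray
    codes: np.ndarray | None = None        # cells x patterns (genotype mode)
    gl_tips: dict[str, np.ndarray] | None = None  # GL mode tip vectors
    n_states: int = 16

    @classmethod
    def from_genotype_matrix(cls, gm: GenotypeMatrix,
                             n_states: int = 16) -> "LikelihoodData":
        codes, weights = compress_patterns(gm.matrix)
        return cls(list(gm.cell_names), weights, codes=codes,
                   n_states=n_states)

    @classmethod
    def from_gl(cls, labels: list[str], log10_gl: np.ndarray,
                n_states: int = 16) -> "LikelihoodData":
        """From a (cells x sites x 10) array of log10 genotype likelihoods."""
        tips = {}
        for i, lab in enumerate(labels):
            vecs = [err.tip_likelihoods_from_gl(log10_gl[i, j])
                    if not np.all(np.isneginf(log10_gl[i, j])) else np.ones(16)
                    for j in range(log10_gl.shape[1])]
            V = np.asarray(vecs)
            if n_states == 10:
                V = np.stack([V[:, ab.UNPHASED_TO_PHASED[u][0]]
                              for u in range(10)], axis=1)
            tips[lab] = V
        return cls(list(labels), np.ones(log10_gl.shape[1]), gl_tips=tips,
                   n_states=n_states)

    @classmethod
    def from_pl(cls, pldata: PLData, n_states: int = 16) -> "LikelihoodData":
        tips = {}
        for i, lab in enumerate(pldata.cell_names):
            vecs = []
            for j in range(pldata.pl.shape[1]):
                v = pldata.pl[i, j]
                vec = err.tip_likelihoods_from_pl(
                    None if np.any(np.isnan(v)) else v,
                    pldata.ref[j], pldata.alt[j])
                vecs.append(vec)
            V = np.asarray(vecs)
            if n_states == 10:
                V = np.stack([V[:, ab.UNPHASED_TO_PHASED[u][0]]
                              for u in range(10)], axis=1)
            tips[lab] = V
        return cls(list(pldata.cell_names), np.ones(pldata.pl.shape[1]),
                   gl_tips=tips, n_states=n_states)

    @property
    def genotype_mode(self) -> bool:
        return self.codes is not None

    def tip_vectors(self, params: err.ErrorParams,
                    error_active: bool) -> dict[str, np.ndarray]:
        if self.genotype_mode:
            leaf = err.genotype_leaf_matrix(params, error_active,
                                            self.n_states)
            return {lab: leaf[self.codes[i]]
                    for i, lab in enumerate(self.labels)}
        return self.gl_tips


# -- SPR search ------------------------------------------------------------


@dataclass
class SearchResult:
    tree: CellTree
    loglik: float
    subst_params: SubstitutionParams
    error_params: err.ErrorParams
    model: ModelSpec
    start_logliks: list[float] = field(default_factory=list)


def _spr_round(engine: PruningEngine, radius: int, epsilon: float) -> bool:
    """One pass of SPR moves over all prunable edges; returns True if any
    move was accepted.

    Candidate regrafts are scored in constant time from directional
    conditional likelihood vectors (computed once per pruning, on the tree
    with the subtree detached) with current branch lengths; the best
    improving candidate is applied and verified with an exact
    recomputation before acceptance.
    """
    tree = engine.tree
    model = engine.model
    pi = model.frequencies
    w = engine.weights
    improved = False
    best = engine.loglikelihood()
    Dfull, LSfull = engine.directional_clvs()
    for child, par in list(tree.edges()) + [(v, u) for u, v in tree.edges()]:
        if par not in tree.adj or child not in tree.adj.get(par, {}):
            continue  # edge vanished in an earlier accepted move
        if tree.degree(par) != 3:
            continue  # pruning requires an internal attachment node
        sub_clv, sub_ls = Dfull[(child, par)], LSfull[(child, par)]
        saved = tree.copy()
        prune_len = tree.length(child, par)
        tree.remove_edge(child, par)
        merged = tree.suppress_degree_two(par)
        if merged is None:
            tree.adj = saved.adj
            tree.labels = saved.labels
            continue
        remaining = set(_component(tree, merged[0]))
        seeds = [n for n in merged if n in remaining]
        candidates = [e for e in tree.edges_within_radius(seeds, radius)
                      if e[0] in remaining and e[1] in remaining
                      and set(e) != set(merged)]
        # exact directional CLVs of the remaining tree (subtree detached)
        D, LS = engine.directional_clvs(root=merged[0])
        sub_msg = sub_clv @ model.transition_matrix(prune_len).T
        best_cand, best_ll = None, best + epsilon
        for tu, tv in candidates:
            half = tree.length(tu, tv) / 2.0
            Ph = model.transition_matrix(half)
            A = D[(tu, tv)] @ Ph.T
            B = D[(tv, tu)] @ Ph.T
            site = np.einsum("ps,ps,ps,s->p", A, B, sub_msg, pi)
            if np.any(site <= 0):
                continue
            ll = float(w @ (np.log(site) + LS[(tu, tv)] + LS[(tv, tu)]
                            + sub_ls))
            if ll > best_ll:
                best_ll, best_cand = ll, (tu, tv)
        if best_cand is not None:
            tu, tv = best_cand
            mid = tree.attach_on_edge(tu, tv)
            tree.add_edge(child, mid, prune_len)
            ll = engine.loglikelihood()
            if ll > best + epsilon:
                best = ll
                improved = True
                Dfull, LSfull = engine.directional_clvs()
                continue
        tree.adj = saved.adj
        tree.labels = saved.labels
    return improved


def _component(tree: CellTree, start: int) -> list[int]:
    seen = {start}
    stack = [start]
    while stack:
        u = stack.pop()
        for v in tree.adj[u]:
            if v not in seen:
                seen.add(v)
                stack.append(v)
    return list(seen)


def _optimize_all(engine: PruningEngine, data: LikelihoodData,
                  subst: SubstitutionParams, error: err.ErrorParams,
                  model: ModelSpec, config: SearchConfig,
                  epsilon: float | None = None,
                  optimize_subst: bool = True, max_cycles: int = 2):
    """One model/branch-length optimization cycle; returns updated params
    and logL (non-decreasing)."""
    epsilon = epsilon if epsilon is not None else config.loglik_epsilon
    ll = engine.loglikelihood()
    for _ in range(max_cycles):
        start_ll = ll
        ll = optimize_branch_lengths(engine, epsilon=epsilon)
        if optimize_subst:
            subst, ll = optimize_substitution_params(
                engine, subst,
                optimize_frequencies=(model.frequency_mode == "optimized"))
        if model.error_model and data.genotype_mode:
            error, ll = optimize_error_params(
                engine, data.codes, data.labels, error, epsilon=epsilon)
        if ll - start_ll < epsilon:
            break
    return subst, error, ll


def spr_search(start: CellTree, data: LikelihoodData, model: ModelSpec,
               config: SearchConfig,
               subst: SubstitutionParams | None = None,
               error: err.ErrorParams | None = None) -> SearchResult:
    """SPR hill-climb from one starting tree, alternating topology moves
    with model parameter re-optimization."""
    if model.error_model and not data.genotype_mode:
        raise ValueError("error model requires genotype-matrix input")
    tree = start.copy()
    subst = subst or SubstitutionParams.default(data.n_states,
                                                model.frequency_mode)
    error = error or err.ErrorParams(0.05, 0.05)
    if not model.error_model:
        error = err.ErrorParams(0.0, 0.0)
    engine = PruningEngine(tree, data.tip_vectors(error, model.error_model),
                           data.weights, build_rate_matrix(subst))
    subst, error, ll = _optimize_all(engine, data, subst, error, model,
                                     config,
                                     optimize_subst=config.optimize_model)
    for radius in config.spr_radius_schedule:
        for _round in range(config.max_iterations):
            moved = _spr_round(engine, radius, config.loglik_epsilon)
            # cheap re-optimization between rounds (branch lengths and
            # error rates); substitution parameters are refit at the end
            subst, error, new_ll = _optimize_all(
                engine, data, subst, error, model, config,
                optimize_subst=False)
            if not moved and new_ll - ll < config.loglik_epsilon:
                ll = max(ll, new_ll)
                break
            ll = new_ll
    # final full model refit and branch-length polish
    subst, error, ll = _optimize_all(engine, data, subst, error, model,
                                     config,
                                     optimize_subst=config.optimize_model)
    ll = optimize_branch_lengths(engine, epsilon=config.final_epsilon)
    return SearchResult(tree, ll, subst, error, model)


def run_search(data: LikelihoodData, model, config: SearchConfig) -> SearchResult:
    """Multi-start ML search; returns the best result over all starts."""
    if isinstance(model, str):
        model = parse_model_string(model)
    rng = np.random.default_rng(config.seed)
    starts: list[CellTree] = []
    for k in range(config.n_parsimony_starts):
        if data.genotype_mode:
            codes = data.codes
        else:
            # GL input: use the per-site ML genotype for parsimony scoring
            codes = _ml_codes_from_tips(data)
        starts.append(starting_tree_parsimony(
            codes, data.labels, data.weights,
            seed=int(rng.integers(2 ** 31))))
    for k in range(config.n_random_starts):
        starts.append(starting_tree_random(
            data.labels, seed=int(rng.integers(2 ** 31))))
    best: SearchResult | None = None
    logliks = []
    for t in starts:
        res = spr_search(t, data, model, config)
        logliks.append(res.loglik)
        if best is None or res.loglik > best.loglik:
            best = res
    best.start_logliks = logliks
    return best


def _ml_codes_from_tips(data: LikelihoodData) -> np.ndarray:
    codes = np.empty((len(data.labels), len(data.weights)), dtype=np.int8)
    for i, lab in enumerate(data.labels):
        V = data.gl_tips[lab]
        if data.n_states == 16:
            codes[i] = [ab.PHASED_TO_UNPHASED[int(np.argmax(v))] for v in V]
        else:
            codes[i] = np.argmax(V, axis=1)
        uninformative = V.min(axis=1) == V.max(axis=1)
        codes[i, uninformative] = ab.MISSING_INDEX
    return codes


def parse_tree_spec(spec: str) -> tuple[str, int]:
    """Parse start-tree specifiers "pars{N}" / "rand{N}"."""
    spec = spec.strip().lower()
    for kind in ("pars", "rand"):
        if spec.startswith(kind):
            inner = spec[len(kind):]
            if inner.startswith("{") and inner.endswith("}"):
                n = int(inner[1:-1])
                if n < 1:
                    raise ValueError("start count must be >= 1")
                return kind, n
    raise ValueError(f"bad tree specifier {spec!r} (use pars{{N}}/rand{{N}})")
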