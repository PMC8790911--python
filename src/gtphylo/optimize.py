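"""Maximum-likelihood optimization of branch lengths, substitution
parameters, and single-cell error rates.

Branch lengths are optimized one edge at a time with Brent's method on a
single-edge likelihood profile (the tree is factored across the edge so
each evaluation is one matrix-vector pass).  Exchangeabilities and
genotype frequencies are optimized jointly with L-BFGS-B on log / logistic
transforms; ADO and amplification error rates are optimized cyclically
with bounded Brent, re-initializing the tip likelihood vectors at every
evaluation.  All routines leave the incumbent untouched when they fail to
improve, so the reported log-likelihood never decreases.
"""

from __future__ import annotations

import warnings

import numpy as np
import scipy.optimize

from . import errors as err
from .likelihood import PruningEngine
from .ratematrix import (RateMatrix, SubstitutionParams,
                         build_gt10_rate_matrix, build_gt16_rate_matrix)
from .tree import MAX_BRANCH_LENGTH, MIN_BRANCH_LENGTH

FREQ_FLOOR = 1e-6


def build_rate_matrix(params: SubstitutionParams) -> RateMatrix:
    if params.n_states == 16:
        return build_gt16_rate_matrix(params)
    return build_gt10_rate_matrix(params)


def _edge_objective(engine: PruningEngine, a: np.ndarray, b: np.ndarray,
                    base: np.ndarray):
    w = engine.weights

    def f(t: float) -> float:
        P = engine.model.transition_matrix(t)
        site = np.einsum("ps,ps->p", a, b @ P.T)
        if not np.all(site > 0):
            return -np.inf
        return float(w @ (np.log(site) + base))

    return f


def _brent_edge(f, t0: float):
    res = scipy.optimize.minimize_scalar(
        lambda t: -f(t), bounds=(MIN_BRANCH_LENGTH, MAX_BRANCH_LENGTH),
        method="bounded", options={"xatol": 1e-8})
    if np.isfinite(res.fun) and -res.fun > f(t0):
        return float(res.x)
    return t0


def _exact_bl_sweep(engine: PruningEngine) -> float:
    """One per-edge sweep with freshly recomputed partials per edge."""
    tree = engine.tree
    for u, v in tree.edges():
        f = engine.edge_profile(u, v)
        tree.set_length(u, v, _brent_edge(f, tree.length(u, v)))
    return engine.loglikelihood()


def optimize_branch_lengths(engine: PruningEngine, epsilon: float = 0.01,
                            max_sweeps: int = 10) -> float:
    """Optimize all branch lengths in place; returns the final logL.

    Each sweep reuses one set of directional conditional vectors for all
    edges (a one-pass approximation); if a sweep fails to improve the
    exact log-likelihood it is reverted and repeated with per-edge exact
    partials, so the returned logL never decreases.
    """
    tree = engine.tree
    best = engine.loglikelihood()
    for _ in range(max_sweeps):
        start = best
        saved = {e: tree.length(*e) for e in tree.edges()}
        D, LS = engine.directional_clvs()
        pi = engine.model.frequencies
        for u, v in tree.edges():
            f = _edge_objective(engine, D[(u, v)] * pi, D[(v, u)],
                                LS[(u, v)] + LS[(v, u)])
            tree.set_length(u, v, _brent_edge(f, tree.length(u, v)))
        new = engine.loglikelihood()
        if new < best:
            for e, t in saved.items():
                tree.set_length(*e, t)
            new = _exact_bl_sweep(engine)
            if new < best:  # numerically converged; keep incumbent
                for e, t in saved.items():
                    tree.set_length(*e, t)
                return best
        best = new
        if best - start < epsilon:
            break
    return best


def optimize_substitution_params(
        engine: PruningEngine, params: SubstitutionParams,
        optimize_frequencies: bool = True,
        max_iterations: int = 6) -> tuple[SubstitutionParams, float]:
    """L-BFGS-B over log exchangeabilities (and logit frequencies).

    Returns updated params and the new logL; keeps the incumbent if the
    optimizer fails to improve.
    """
    n = params.n_states
    x0 = np.log(params.exchangeabilities)
    if optimize_frequencies:
        f0 = np.clip(params.frequencies, FREQ_FLOOR, None)
        x0 = np.concatenate([x0, np.log(f0 / f0[-1])[:-1]])

    def unpack(x):
        ex = np.exp(np.clip(x[:5], -20, 20))
        if optimize_frequencies:
            logits = np.concatenate([np.clip(x[5:], -30, 30), [0.0]])
            f = np.exp(logits - logits.max())
            f = np.clip(f / f.sum(), FREQ_FLOOR, None)
            f = f / f.sum()
        else:
            f = params.frequencies
        return SubstitutionParams(ex, f, params.frequency_mode)

    def negloglik(x):
        try:
            engine.model = build_rate_matrix(unpack(x))
            return -engine.loglikelihood()
        except (ValueError, FloatingPointError):
            return 1e100

    base = -negloglik(x0)
    res = scipy.optimize.minimize(
        negloglik, x0, method="L-BFGS-B",
        options={"maxiter": max_iterations, "ftol": 1e-9})
    if np.isfinite(res.fun) and -res.fun > base:
        new = unpack(res.x)
        engine.model = build_rate_matrix(new)
        return new, float(-res.fun)
    warnings.warn("substitution parameter optimization did not improve; "
                  "keeping incumbent values")
    engine.model = build_rate_matrix(params)
    return params, float(base)


def optimize_error_params(engine: PruningEngine, codes: np.ndarray,
                          labels: list[str], params: err.ErrorParams,
                          max_cycles: int = 5,
                          epsilon: float = 0.01) -> tuple[err.ErrorParams, float]:
    """Cyclic Brent optimization of the ADO rate and the error rate.

    ``codes`` is the (cells x patterns) observed genotype index matrix the
    engine's tip vectors were built from; tip vectors are re-initialized
    from the error kernel at every likelihood evaluation.  Only valid for
    genotype-matrix input (GL input has no error model).
    """
    if codes is None:
        raise ValueError("error-rate optimization requires genotype input "
                         "(the error model does not apply to GL mode)")

    def set_tips(delta, eps):
        leaf = err.genotype_leaf_matrix(err.ErrorParams(delta, eps), True,
                                        engine.model.n_states)
        engine.set_tip_vectors(
            {lab: leaf[codes[i]] for i, lab in enumerate(labels)})

    def negloglik(delta, eps):
        set_tips(delta, eps)
        try:
            return -engine.loglikelihood()
        except FloatingPointError:
            return 1e100

    delta, eps = params.delta, params.epsilon
    best = -negloglik(delta, eps)
    for _ in range(max_cycles):
        start = best
        res = scipy.optimize.minimize_scalar(
            lambda d: negloglik(d, eps), bounds=(0.0, 1.0 - 1e-9),
            method="bounded", options={"xatol": 1e-4})
        if np.isfinite(res.fun) and -res.fun > best:
            delta, best = float(res.x), float(-res.fun)
        res = scipy.optimize.minimize_scalar(
            lambda e: negloglik(delta, e), bounds=(0.0, 1.0 - 1e-9),
            method="bounded", options={"xatol": 1e-4})
        if np.isfinite(res.fun) and -res.fun > best:
            eps, best = float(res.x), float(-res.fun)
        if best - start < epsilon:
            break
    set_tips(delta, eps)
    return err.ErrorParams(delta, eps), float(best)
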