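import numpy as np
import pytest

from gtphylo.errors import ErrorParams, genotype_leaf_matrix
from gtphylo.likelihood import PruningEngine
from gtphylo.ratematrix import SubstitutionParams, build_gt16_rate_matrix
from gtphylo.tree import CellTree


@pytest.fixture
def rng():
    return np.random.default_rng(20260921)


@pytest.fixture
def quartet_tree():
    """Unrooted 4-tip tree ((a,b),(c,d)) with fixed branch lengths."""
    t = CellTree()
    a, b, c, d = [t.new_node(x) for x in "abcd"]
    u = t.new_node()
    v = t.new_node()
    t.add_edge(a, u, 0.12)
    t.add_edge(b, u, 0.30)
    t.add_edge(c, v, 0.05)
    t.add_edge(d, v, 0.20)
    t.add_edge(u, v, 0.15)
    return t


@pytest.fixture
def gt16_uniform():
    return build_gt16_rate_matrix(SubstitutionParams.default(16))


@pytest.fixture
def gt16_random(rng):
    params = SubstitutionParams(rng.uniform(0.5, 2.0, 5),
                                rng.dirichlet(np.ones(16)))
    return build_gt16_rate_matrix(params)


def make_engine(tree, codes, model, delta=0.0, epsilon=0.0,
                error_active=True, weights=None):
    """Engine over genotype codes (cells x sites int matrix)."""
    labels = tree.tip_labels()
    leaf = genotype_leaf_matrix(ErrorParams(delta, epsilon), error_active,
                                model.n_states)
    tips = {lab: leaf[codes[i]] for i, lab in enumerate(labels)}
    w = np.ones(codes.shape[1]) if weights is None else weights
    return PruningEngine(tree, tips, w, model)
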