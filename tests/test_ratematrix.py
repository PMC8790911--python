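import numpy as np
import pytest

from gtphylo import alphabet as ab
from gtphylo.errors import genotype_leaf_matrix, ErrorParams
from gtphylo.likelihood import PruningEngine
from gtphylo.ratematrix import (SIGNATURE1_GTNR_RATES, ModelSpec,
                                SubstitutionParams, build_gt10_rate_matrix,
                                build_gt16_rate_matrix, build_gtnr_matrix,
                                parse_model_string, stationary_distribution,
                                transition_probabilities)


def taylor_expm(Q, t, squarings=20, terms=24):
    """Independent scaling-and-squaring Taylor-series matrix exponential."""
    A = Q * (t / 2.0 ** squarings)
    P = np.eye(Q.shape[0])
    term = np.eye(Q.shape[0])
    for k in range(1, terms):
        term = term @ A / k
        P = P + term
    for _ in range(squarings):
        P = P @ P
    return P


@pytest.fixture
def random_params(rng):
    return SubstitutionParams(rng.uniform(0.5, 2.0, 5),
                              rng.dirichlet(np.ones(16)))


class TestGT16:
    def test_uniform_inputs_symmetric(self):
        rm = build_gt16_rate_matrix(SubstitutionParams.default(16))
        off = rm.Q.copy()
        np.fill_diagonal(off, 0.0)
        nz = off[off > 0]
        # every genotype has 6 single-allele neighbours -> 48 symmetric pairs
        assert np.count_nonzero(off) == 96
        assert np.count_nonzero(np.triu(off)) == 48
        assert np.allclose(nz, nz[0])
        assert np.allclose(rm.Q.sum(axis=1), 0.0, atol=1e-10)

    def test_double_allele_change_forbidden(self, random_params):
        rm = build_gt16_rate_matrix(random_params)
        aa = ab.phased_index("A", "A")
        cg = ab.phased_index("C", "G")
        assert rm.Q[aa, cg] == 0.0
        # and generally: zero whenever both alleles differ
        for x in range(16):
            xa, xb = divmod(x, 4)
            for y in range(16):
                ya, yb = divmod(y, 4)
                if xa != ya and xb != yb:
                    assert rm.Q[x, y] == 0.0

    def test_exchangeability_ratio(self):
        # alpha = r(A~C) doubled relative to beta = r(A~G)
        params = SubstitutionParams([2.0, 1.0, 1.0, 1.0, 1.0],
                                    np.full(16, 1 / 16))
        rm = build_gt16_rate_matrix(params)
        aa = ab.phased_index("A", "A")
        ac = ab.phased_index("A", "C")
        ag = ab.phased_index("A", "G")
        assert rm.Q[aa, ac] / rm.Q[aa, ag] == pytest.approx(2.0)

    def test_normalization_and_stationarity(self, random_params):
        rm = build_gt16_rate_matrix(random_params)
        pi = rm.frequencies
        assert -pi @ np.diag(rm.Q) == pytest.approx(1.0)
        assert np.allclose(pi @ rm.Q, 0.0, atol=1e-10)

    def test_detailed_balance(self, random_params):
        rm = build_gt16_rate_matrix(random_params)
        F = rm.frequencies[:, None] * rm.Q
        assert np.allclose(F, F.T, atol=1e-10)

    def test_time_reversibility_of_transition_matrix(self, random_params):
        rm = build_gt16_rate_matrix(random_params)
        for t in (0.01, 0.5, 3.0):
            P = rm.transition_matrix(t)
            F = rm.frequencies[:, None] * P
            assert np.allclose(F, F.T, atol=1e-10)

    def test_invalid_params_rejected(self):
        with pytest.raises(ValueError):
            SubstitutionParams([1, 1, -1, 1, 1], np.full(16, 1 / 16))
        with pytest.raises(ValueError):
            SubstitutionParams(np.ones(5), np.full(16, 1 / 8))


class TestGT10:
    def test_shape_and_reversibility(self, rng):
        params = SubstitutionParams(rng.uniform(0.5, 2.0, 5),
                                    rng.dirichlet(np.ones(10)))
        rm = build_gt10_rate_matrix(params)
        assert rm.Q.shape == (10, 10)
        assert np.allclose(rm.Q.sum(axis=1), 0.0, atol=1e-10)
        F = rm.frequencies[:, None] * rm.Q
        assert np.allclose(F, F.T, atol=1e-10)

    def test_likelihood_close_to_gt16_on_clean_unphased_data(self):
        """On error-free unphased SNV genotypes with matched parameters
        the GT10 and GT16 log-likelihoods differ by under 10% of |logL|
        (the two parameterizations support very similar inference)."""
        from gtphylo.simulate import SimulationConfig, simulate_dataset
        ds = simulate_dataset(SimulationConfig(n_cells=8, n_snvs=100,
                                               seed=5))
        codes = ds.observed.matrix
        labels = ds.observed.cell_names
        tree = ds.true_tree
        lls = {}
        for n_states, builder in ((16, build_gt16_rate_matrix),
                                  (10, build_gt10_rate_matrix)):
            rm = builder(SubstitutionParams.default(n_states))
            leaf = genotype_leaf_matrix(ErrorParams(), False, n_states)
            tips = {lab: leaf[codes[i]] for i, lab in enumerate(labels)}
            eng = PruningEngine(tree, tips, np.ones(codes.shape[1]), rm)
            lls[n_states] = eng.loglikelihood()
        assert abs(lls[10] - lls[16]) <= 0.10 * abs(lls[16])


class TestTransitionProbabilities:
    def test_identity_at_zero(self, random_params):
        rm = build_gt16_rate_matrix(random_params)
        assert np.allclose(rm.transition_matrix(0.0), np.eye(16), atol=1e-12)

    def test_stationary_limit(self, random_params):
        rm = build_gt16_rate_matrix(random_params)
        P = rm.transition_matrix(1e4)
        assert np.abs(P - rm.frequencies[None, :]).max() < 1e-6

    def test_rows_stochastic_and_nonnegative(self, random_params):
        rm = build_gt16_rate_matrix(random_params)
        for t in (0.0, 1e-6, 0.1, 1.0, 50.0):
            P = transition_probabilities(rm, t)
            assert P.min() >= 0.0
            assert np.allclose(P.sum(axis=1), 1.0, atol=1e-10)

    def test_against_taylor_oracle(self, random_params):
        rm = build_gt16_rate_matrix(random_params)
        P = rm.transition_matrix(0.1)
        assert np.abs(P - taylor_expm(rm.Q, 0.1)).max() < 1e-8

    def test_chapman_kolmogorov(self, random_params):
        rm = build_gt16_rate_matrix(random_params)
        for t1, t2 in ((0.05, 0.2), (0.4, 0.4), (1.3, 0.01)):
            lhs = rm.transition_matrix(t1 + t2)
            rhs = rm.transition_matrix(t1) @ rm.transition_matrix(t2)
            assert np.abs(lhs - rhs).max() < 1e-8

    def test_negative_time_rejected(self, gt16_uniform):
        with pytest.raises(ValueError):
            gt16_uniform.transition_matrix(-0.1)

    def test_batched_matches_single(self, random_params):
        rm = build_gt16_rate_matrix(random_params)
        ts = np.array([0.0, 0.03, 0.7])
        batch = rm.transition_matrices(ts)
        for i, t in enumerate(ts):
            assert np.allclose(batch[i], rm.transition_matrix(t))


class TestGTnR:
    def test_signature1_entries(self):
        rm = build_gtnr_matrix(SIGNATURE1_GTNR_RATES)
        scale = rm.scaling
        # entries as printed: G->A = 6.68, C->T = 0.68 (A,C,G,T order)
        g, a_, c, t = 2, 0, 1, 3
        assert rm.Q[g, a_] * scale == pytest.approx(6.68)
        assert rm.Q[c, t] * scale == pytest.approx(0.68)
        assert np.allclose(rm.Q.sum(axis=1), 0.0, atol=1e-12)

    def test_equal_rates_jukes_cantor(self):
        rm = build_gtnr_matrix(np.ones(12))
        # JC closed form: p_same = 1/4 + 3/4 exp(-4/3 t) under unit rate
        for t in (0.1, 1.0):
            P = rm.transition_matrix(t)
            expected_same = 0.25 + 0.75 * np.exp(-4.0 / 3.0 * t)
            assert np.allclose(np.diag(P), expected_same, atol=1e-10)
        P = rm.transition_matrix(100.0)
        assert np.allclose(P, 0.25, atol=1e-10)

    def test_negative_rate_rejected(self):
        bad = np.ones(12)
        bad[3] = -0.1
        with pytest.raises(ValueError):
            build_gtnr_matrix(bad)

    def test_stationary_distribution(self):
        rm = build_gtnr_matrix(SIGNATURE1_GTNR_RATES)
        pi = stationary_distribution(rm.Q)
        assert np.allclose(pi @ rm.Q, 0.0, atol=1e-12)
        assert pi.sum() == pytest.approx(1.0)


@pytest.mark.parametrize("string,expected", [
    ("GT16+FO", ModelSpec(16, "optimized", False)),
    ("GT16+FO+E", ModelSpec(16, "optimized", True)),
    ("GT10+FO+E", ModelSpec(10, "optimized", True)),
    ("GT16+FE", ModelSpec(16, "equal", False)),
    ("GT16+FC+E", ModelSpec(16, "empirical", True)),
])
def test_model_string_parser(string, expected):
    assert parse_model_string(string) == expected


def test_model_string_parser_rejects_unknown():
    with pytest.raises(ValueError):
        parse_model_string("GTR+G")
    with pytest.raises(ValueError):
        parse_model_string("GT16+X")
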