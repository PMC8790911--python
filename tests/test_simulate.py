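import numpy as np
import pytest
import scipy.stats

from gtphylo import alphabet as ab
from gtphylo.ratematrix import SIGNATURE1_GTNR_RATES, build_gtnr_matrix
from gtphylo.simulate import (Genealogy, SimulationConfig,
                              apply_genotype_errors, inject_doublets,
                              simulate_dataset, simulate_genealogy,
                              simulate_mutations_finite,
                              simulate_mutations_ism, simulate_reads,
                              variant_sites)


class TestGenealogy:
    def test_pairwise_coalescent_mean(self):
        """For two cells in a constant-size population the mean TMRCA over
        many draws matches the analytic expectation (3-sigma)."""
        config = SimulationConfig(n_cells=2, growth_rate=0.0,
                                  effective_size=5000.0,
                                  root_branch_length=0.0)
        n = 1500
        tmrcas = []
        for seed in range(1, n + 1):
            g = simulate_genealogy(config, seed=seed)
            # pairwise TMRCA = half the path length between the two cells
            t1 = g.tree.tip_by_label("cell001")
            t2 = g.tree.tip_by_label("cell002")
            d = g.tree.adj[t1][g.mrca] if g.mrca in g.tree.adj[t1] else None
            tmrcas.append(g.tree.adj[t1][next(iter(
                set(g.tree.adj[t1]) & set(g.tree.adj[t2])))])
        mean = np.mean(tmrcas)
        # exponential with mean N (haploid lineages): sd of mean = N/sqrt(n)
        assert abs(mean - 5000.0) < 3 * 5000.0 / np.sqrt(n)

    def test_ingroup_ultrametric_without_rate_variation(self):
        g = simulate_genealogy(SimulationConfig(n_cells=15, seed=4))
        order, parent, children = g.tree.traversal(g.apex)
        depth = {g.apex: 0.0}
        for n in reversed(order):
            if parent[n] is not None:
                depth[n] = depth[parent[n]] + g.tree.adj[n][parent[n]]
        tip_depths = [depth[n] for n in g.tree.adj
                      if g.tree.degree(n) == 1 and n != g.apex
                      and g.tree.labels.get(n) != "healthy"]
        assert np.ptp(tip_depths) < 1e-6

    def test_rate_multipliers_break_ultrametricity(self):
        g = simulate_genealogy(SimulationConfig(
            n_cells=15, branch_rate_gamma_shape=1.0, seed=4))
        order, parent, children = g.tree.traversal(g.apex)
        depth = {g.apex: 0.0}
        for n in reversed(order):
            if parent[n] is not None:
                depth[n] = depth[parent[n]] + g.tree.adj[n][parent[n]]
        tip_depths = [depth[n] for n in g.tree.adj
                      if g.tree.degree(n) == 1 and n != g.apex]
        assert np.ptp(tip_depths) > 1.0

    def test_outgroup_attached_at_zero_distance(self):
        g = simulate_genealogy(SimulationConfig(n_cells=10, seed=8))
        healthy = g.tree.tip_by_label("healthy")
        assert g.tree.adj[healthy][g.mrca] == 0.0

    def test_root_branch_length(self):
        cfg = SimulationConfig(n_cells=6, root_branch_length=0.1,
                               effective_size=10_000.0, seed=2)
        g = simulate_genealogy(cfg)
        assert g.tree.adj[g.apex][g.mrca] == pytest.approx(0.1 * 2 * 10_000)


class TestISM:
    @pytest.fixture
    def genealogy(self):
        return simulate_genealogy(SimulationConfig(n_cells=12, seed=13))

    def test_exact_snv_count(self, genealogy):
        truth = simulate_mutations_ism(genealogy, 250, seed=1)
        assert truth.n_sites == 250
        assert len(variant_sites(truth)) == 250

    def test_outgroup_never_mutates(self, genealogy):
        truth = simulate_mutations_ism(genealogy, 500, seed=2)
        healthy = genealogy.tree.tip_by_label("healthy")
        assert healthy not in set(truth.mutation_branch.tolist())

    def test_root_branch_mutations_shared_by_all(self, genealogy):
        truth = simulate_mutations_ism(genealogy, 800, seed=3)
        root_sites = np.nonzero(truth.mutation_branch == genealogy.mrca)[0]
        assert len(root_sites) > 0
        codes = truth.unphased_codes()
        for j in root_sites:
            col = codes[:, j]
            assert np.all(col == col[0])  # heterozygous in every cell
            a, b = ab.unphased_alleles(int(col[0]))
            assert a != b

    def test_branch_assignment_proportional_to_length(self):
        g = simulate_genealogy(SimulationConfig(n_cells=6, seed=17))
        truth = simulate_mutations_ism(g, 10_000, seed=5)
        branches = g.branches()
        lengths = np.array([b[2] for b in branches])
        expected = lengths / lengths.sum()
        counts = np.zeros(len(branches))
        child_index = {b[0]: i for i, b in enumerate(branches)}
        for child in truth.mutation_branch:
            counts[child_index[child]] += 1
        keep = expected > 0
        chi2, p = scipy.stats.chisquare(counts[keep],
                                        10_000 * expected[keep])
        assert p > 0.001

    def test_more_snvs_than_possible_rejected(self, genealogy):
        with pytest.raises(ValueError):
            simulate_mutations_ism(genealogy, 0, seed=1)


class TestFiniteSite:
    def test_zero_rate_keeps_root_genotypes(self):
        g = simulate_genealogy(SimulationConfig(n_cells=8, seed=19))
        truth = simulate_mutations_finite(g, None, 0.0, 1.0, 200, seed=7)
        assert len(variant_sites(truth)) == 0
        assert np.all(truth.alleles[..., 0] == truth.ref[None, :])

    def test_true_snv_count_magnitude(self):
        """~100 cells x 10k sites at rate 1e-6 yields on the order of 2000
        true SNVs (within a factor of two on average)."""
        counts = []
        for seed in range(1, 6):
            ds = simulate_dataset(SimulationConfig(
                n_cells=100, mutation_model="gtnr", n_sites=10_000,
                seed=seed))
            counts.append(len(variant_sites(ds.truth)))
        mean = np.mean(counts)
        assert 1000 <= mean <= 4000

    def test_substitution_spectrum_matches_model(self):
        """Single-branch transition frequencies match the finite-site DNA
        model's transition matrix (chi-square at 0.1%)."""
        t = 2000.0  # generations
        mu = 1e-5
        tree_cfg = SimulationConfig(n_cells=2, root_branch_length=0.0,
                                    seed=23)
        g = simulate_genealogy(tree_cfg)
        truth = simulate_mutations_finite(g, None, mu, None, 50_000, seed=3)
        model = build_gtnr_matrix(SIGNATURE1_GTNR_RATES)
        # compare empirical child vs root states on one cell's maternal
        # allele against P(mu * branch length)
        cell = g.tree.tip_by_label("cell001")
        order, parent, children = g.tree.traversal(g.apex)
        blen = 0.0
        n = cell
        while parent[n] is not None:
            blen += g.tree.adj[n][parent[n]]
            n = parent[n]
        P = model.transition_matrix(mu * blen)
        row = truth.labels.index("cell001")
        obs = truth.alleles[row, :, 0]
        for start in range(4):
            mask = truth.ref == start
            if mask.sum() < 500:
                continue
            counts = np.bincount(obs[mask], minlength=4)
            expected = P[start] * mask.sum()
            keep = expected > 1
            chi2, p = scipy.stats.chisquare(
                counts[keep], expected[keep] * counts[keep].sum()
                / expected[keep].sum())
            assert p > 0.001

    def test_g_to_a_dominates(self):
        """The signature-1-derived model makes G->A by far the most common
        substitution away from G."""
        g = simulate_genealogy(SimulationConfig(n_cells=2,
                                                root_branch_length=0.0,
                                                seed=29))
        truth = simulate_mutations_finite(g, None, 1e-5, None, 30_000,
                                          seed=11)
        row = truth.labels.index("cell001")
        obs = truth.alleles[row, :, 0]
        from_g = truth.ref == 2
        changed = from_g & (obs != 2)
        if changed.sum() >= 20:
            to_a = np.sum(obs[changed] == 0)
            assert to_a / changed.sum() > 0.8


class TestGenotypeErrors:
    @pytest.fixture
    def truth(self):
        g = simulate_genealogy(SimulationConfig(n_cells=10, seed=31))
        return simulate_mutations_ism(g, 400, seed=1)

    def test_no_error_identity(self, truth):
        obs = apply_genotype_errors(truth, 0.0, 0.0, seed=2)
        assert np.array_equal(obs.matrix, truth.unphased_codes())

    def test_full_ado_removes_heterozygotes(self, truth):
        obs = apply_genotype_errors(truth, 1.0, 0.0, seed=3)
        for g in np.unique(obs.matrix):
            a, b = ab.unphased_alleles(int(g))
            assert a == b

    def test_ado_fraction_matches_delta(self):
        """Fraction of heterozygous sites observed as homozygous is within
        3 sigma of delta at eps=0."""
        g = simulate_genealogy(SimulationConfig(n_cells=25, seed=37))
        truth = simulate_mutations_ism(g, 4000, seed=1)
        delta = 0.3
        obs = apply_genotype_errors(truth, delta, 0.0, seed=5)
        codes = truth.unphased_codes()
        het = np.zeros_like(codes, dtype=bool)
        for u, ph in enumerate(ab.UNPHASED_TO_PHASED):
            if len(ph) == 2:
                het |= codes == u
        n_het = int(het.sum())
        hom_after = 0
        for u in np.unique(obs.matrix[het]):
            a, b = ab.unphased_alleles(int(u))
            if a == b:
                hom_after += int(np.sum(obs.matrix[het] == u))
        frac = hom_after / n_het
        sigma = np.sqrt(delta * (1 - delta) / n_het)
        assert abs(frac - delta) < 3 * sigma


class TestReads:
    @pytest.fixture
    def truth(self):
        g = simulate_genealogy(SimulationConfig(n_cells=8, seed=41))
        return simulate_mutations_ism(g, 300, seed=1)

    def test_infinite_depth_recovers_truth(self, truth):
        reads = simulate_reads(truth, depth=10_000.0, amplification_error=0.0,
                               sequencing_error=0.0, delta=0.0, seed=2)
        assert np.array_equal(reads.ml_calls, truth.unphased_codes())

    def test_ado_halves_depth(self, truth):
        reads = simulate_reads(truth, depth=5.0, amplification_error=0.0,
                               sequencing_error=0.0, delta=0.4, seed=3)
        d = reads.depth
        mean_kept = d[~reads.dropped].mean()
        mean_dropped = d[reads.dropped].mean()
        assert mean_kept == pytest.approx(5.0, rel=0.1)
        assert mean_dropped == pytest.approx(2.5, rel=0.1)

    def test_gl_truth_ranking_improves_with_depth(self, truth):
        def top1_fraction(depth):
            reads = simulate_reads(truth, depth=depth,
                                   amplification_error=0.05,
                                   sequencing_error=0.01, delta=0.1,
                                   seed=7)
            codes = truth.unphased_codes()
            idx = np.indices(codes.shape)
            true_gl = reads.log10_gl[idx[0], idx[1], codes]
            best = reads.log10_gl.max(axis=2)
            return np.mean(true_gl >= best - 1e-12)
        assert top1_fraction(30.0) > top1_fraction(5.0)

    def test_bad_depth_rejected(self, truth):
        with pytest.raises(ValueError):
            simulate_reads(truth, depth=0.0, amplification_error=0,
                           sequencing_error=0, delta=0, seed=1)


class TestDoublets:
    @pytest.fixture
    def bundle(self):
        g = simulate_genealogy(SimulationConfig(n_cells=6, seed=43))
        truth = simulate_mutations_ism(g, 100, seed=1)
        reads = simulate_reads(truth, depth=20.0, amplification_error=0.0,
                               sequencing_error=0.0, delta=0.0, seed=2)
        matrix = truth.genotype_matrix()
        return truth, reads, matrix

    def test_rate_zero_is_identity(self, bundle):
        truth, reads, matrix = bundle
        r2, m2 = inject_doublets(truth, reads, matrix, 0.0, seed=5)
        assert np.array_equal(r2.counts, reads.counts)
        assert np.array_equal(m2.matrix, matrix.matrix)

    def test_forced_merge_creates_heterozygote(self):
        """Merging hom A/A with hom C/C read profiles leaves both allele
        counts present, and the genotype-mode union is the A/C het."""
        from gtphylo.simulate import TrueGenotypes
        alleles = np.zeros((2, 1, 2), dtype=np.int8)
        alleles[1] = 1  # cell 2 is C/C
        truth = TrueGenotypes(alleles, ["u", "v"], np.zeros(1, dtype=np.int8))
        reads = simulate_reads(truth, depth=50.0, amplification_error=0.0,
                               sequencing_error=0.0, delta=0.0, seed=3)
        matrix = truth.genotype_matrix()
        r2, m2 = inject_doublets(truth, reads, matrix, 1.0, seed=4)
        assert np.all(r2.counts[:, 0, 0] > 0)  # A reads present
        assert np.all(r2.counts[:, 0, 1] > 0)  # C reads present
        ac = ab.unphased_index("A", "C")
        assert np.all(m2.matrix == ac)

    def test_expected_doublet_count(self):
        g = simulate_genealogy(SimulationConfig(n_cells=20, seed=47))
        truth = simulate_mutations_ism(g, 20, seed=1)
        matrix = truth.genotype_matrix()
        rate = 0.2
        n_cells = truth.n_cells
        changed = 0
        trials = 300
        for seed in range(trials):
            _, m2 = inject_doublets(truth, None, matrix, rate, seed=seed)
            changed += int(np.any(m2.matrix != matrix.matrix, axis=1).sum())
        mean = changed / trials
        expected = rate * n_cells
        sigma = np.sqrt(n_cells * rate * (1 - rate) / trials)
        # merges can coincide with the original genotype, so the count of
        # visibly changed cells is at most the doublet count
        assert mean <= expected + 3 * sigma
        assert mean > 0.5 * expected

    def test_too_few_cells_rejected(self):
        from gtphylo.simulate import TrueGenotypes
        alleles = np.zeros((1, 3, 2), dtype=np.int8)
        truth = TrueGenotypes(alleles, ["solo"], np.zeros(3, dtype=np.int8))
        with pytest.raises(ValueError):
            inject_doublets(truth, None, truth.genotype_matrix(), 0.5,
                            seed=1)


class TestPipeline:
    def test_dataset_bundle_shapes(self):
        ds = simulate_dataset(SimulationConfig(
            n_cells=40, n_snvs=250, ado_rate=0.1, genotype_error_rate=0.05,
            seed=3))
        assert ds.observed.matrix.shape == (41, 250)  # 40 cells + healthy
        assert ds.true_tree.n_tips == 41
        assert ds.true_tree.is_binary()
        assert "healthy" in ds.observed.cell_names

    def test_reads_mode_bundle(self):
        ds = simulate_dataset(SimulationConfig(
            n_cells=10, n_snvs=100, observation_mode="reads",
            read_depth=5.0, amplification_error=0.05,
            sequencing_error=0.01, ado_rate=0.1, seed=9))
        assert ds.reads is not None
        assert ds.reads.log10_gl.shape == (11, 100, 10)
        assert ds.observed.matrix.shape == (11, 100)

    def test_seed_reproducibility(self):
        c = SimulationConfig(n_cells=8, n_snvs=50, ado_rate=0.2,
                             genotype_error_rate=0.1, seed=77)
        d1 = simulate_dataset(c)
        d2 = simulate_dataset(c)
        assert np.array_equal(d1.observed.matrix, d2.observed.matrix)
        assert d1.true_tree.to_newick() == d2.true_tree.to_newick()
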