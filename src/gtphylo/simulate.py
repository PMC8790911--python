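"""Coalescent simulator of single-cell SNV benchmark data.

Samples cell genealogies from an exponentially growing population
(coalescent via msprime), prepends a root branch whose mutations are
shared by all cells, attaches a healthy outgroup cell at zero distance
from the sample MRCA, and generates true diploid genotypes under either a
diploid infinite-site model (each SNV mutates exactly once, on the
maternal or the paternal chromosome) or a finite-site non-reversible DNA
model with Gamma rate variation across sites.  Observed data are produced
either by pushing true genotypes through the ADO/amplification-error
kernel, or by simulating overdispersed NGS read counts with per-read
errors, from which genotype likelihoods and ML genotype calls are
derived.  Doublets (two cells sequenced as one) can be injected.

Every run records its ground truth (genealogy, true genotypes, per-site
mutation branch) so that inference accuracy can be scored against it.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import msprime
import numpy as np

from . import alphabet as ab
from .errors import error_kernel
from .io import GenotypeMatrix
from .ratematrix import RateMatrix, SIGNATURE1_GTNR_RATES, build_gtnr_matrix
from .tree import CellTree

HEALTHY_LABEL = "healthy"


@dataclass
class SimulationConfig:
    """Study conditions for one simulated dataset.

    Defaults follow the benchmark design: cells sampled from an
    exponentially growing population (growth rate 1e-4 per generation,
    present-day effective size 10,000), a root branch of 0.1 (in
    coalescent units of 2N generations) above the sample MRCA, a healthy
    outgroup cell at zero distance from the MRCA, and a mutation rate of
    1e-6 per site per generation for the finite-site model.
    """

    n_cells: int = 40
    effective_size: float = 10_000.0
    growth_rate: float = 1e-4
    root_branch_length: float = 0.1       # units of 2N generations
    outgroup_branch_length: float = 0.0
    branch_rate_gamma_shape: float | None = None  # mean-1 Gamma multipliers
    mutation_model: str = "ism"           # ism | gtnr
    observation_mode: str = "genotype"    # genotype | reads
    n_snvs: int = 1000                    # ISM: number of SNV sites
    n_sites: int = 10_000                 # finite-site: genome size
    mutation_rate: float = 1e-6           # per site per generation
    site_rate_gamma_shape: float | None = 1.0  # finite-site +G
    ado_rate: float = 0.0                 # delta
    genotype_error_rate: float = 0.0      # epsilon
    read_depth: float = 5.0
    depth_overdispersion: float = 2.0     # negative-binomial size parameter
    amplification_error: float = 0.0
    sequencing_error: float = 0.0
    doublet_rate: float = 0.0
    seed: int = 1

    def __post_init__(self) -> None:
        if self.n_cells < 2:
            raise ValueError("need at least 2 cells")
        for name in ("growth_rate", "root_branch_length", "mutation_rate",
                     "ado_rate", "genotype_error_rate", "amplification_error",
                     "sequencing_error", "doublet_rate"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be nonnegative")
        if self.mutation_model not in ("ism", "gtnr"):
            raise ValueError("mutation_model must be 'ism' or 'gtnr'")
        if self.observation_mode not in ("genotype", "reads"):
            raise ValueError("observation_mode must be 'genotype' or 'reads'")


@dataclass
class Genealogy:
    """Rooted simulated genealogy with per-branch lengths in generations.

    ``tree`` includes an apex node above the MRCA (the top of the root
    branch) and the healthy outgroup tip; ``apex`` has degree 1.  Branch
    lengths already include any lineage rate multipliers.
    """

    tree: CellTree
    apex: int
    mrca: int
    labels: list[str]           # ingroup cell labels + healthy

    def unrooted_true_tree(self, scale: float = 1.0) -> CellTree:
        """The true unrooted tree over all cells (apex removed)."""
        t = self.tree.copy()
        nbr = next(iter(t.adj[self.apex]))
        t.remove_node(self.apex)
        if t.degree(nbr) == 2:
            t.suppress_degree_two(nbr)
        if scale != 1.0:
            for u in t.adj:
                for v in t.adj[u]:
                    t.adj[u][v] *= scale
        return t

    def branches(self):
        """(child_node, parent_node, length) for every branch incl. root."""
        order, parent, children = self.tree.traversal(self.apex)
        return [(n, parent[n], self.tree.adj[n][parent[n]])
                for n in order if parent[n] is not None]


def simulate_genealogy(config: SimulationConfig, seed: int | None = None) -> Genealogy:
    """Coalescent genealogy with exponential growth, root branch, and
    healthy outgroup; optional Gamma lineage rate multipliers."""
    seed = config.seed if seed is None else seed
    rng = np.random.default_rng(seed)
    demography = msprime.Demography()
    demography.add_population(initial_size=config.effective_size,
                              growth_rate=config.growth_rate)
    ts = msprime.sim_ancestry(
        samples={"pop_0": config.n_cells}, demography=demography, ploidy=1,
        random_seed=int(rng.integers(1, 2 ** 31)))
    mst = ts.first()
    tree = CellTree()
    node_map: dict[int, int] = {}
    labels = []
    for u in mst.nodes():
        if mst.is_leaf(u):
            lab = f"cell{u + 1:03d}"
            labels.append(lab)
            node_map[u] = tree.new_node(lab)
        else:
            node_map[u] = tree.new_node()
    for u in mst.nodes():
        p = mst.parent(u)
        if p != -1:
            tree.add_edge(node_map[p], node_map[u], mst.branch_length(u))
    mrca = node_map[mst.root]
    # healthy outgroup at the MRCA, then the root branch above it
    healthy = tree.new_node(HEALTHY_LABEL)
    tree.add_edge(mrca, healthy,
                  config.outgroup_branch_length * 2 * config.effective_size)
    apex = tree.new_node()
    tree.add_edge(apex, mrca,
                  config.root_branch_length * 2 * config.effective_size)
    labels = sorted(labels) + [HEALTHY_LABEL]
    if config.branch_rate_gamma_shape is not None:
        shape = config.branch_rate_gamma_shape
        for u, v in tree.edges():
            mult = rng.gamma(shape, 1.0 / shape)
            tree.adj[u][v] *= mult
            tree.adj[v][u] = tree.adj[u][v]
    return Genealogy(tree, apex, mrca, labels)


@dataclass
class TrueGenotypes:
    """Phased true genotypes: (cells, sites, 2) nucleotide indices 0..3."""

    alleles: np.ndarray
    labels: list[str]
    ref: np.ndarray                 # per-site reference nucleotide index
    mutation_branch: np.ndarray | None = None  # ISM: child node of the branch
    mutation_allele: np.ndarray | None = None  # ISM: 0 maternal / 1 paternal
    alt: np.ndarray | None = None   # ISM: per-site derived nucleotide index

    @property
    def n_cells(self) -> int:
        return self.alleles.shape[0]

    @property
    def n_sites(self) -> int:
        return self.alleles.shape[1]

    def unphased_codes(self) -> np.ndarray:
        """Cells x sites matrix of unphased genotype state indices."""
        a = np.minimum(self.alleles[..., 0], self.alleles[..., 1])
        b = np.maximum(self.alleles[..., 0], self.alleles[..., 1])
        lut = np.zeros((4, 4), dtype=np.int8)
        for i in range(4):
            for j in range(i, 4):
                lut[i, j] = ab.unphased_index(ab.NUCLEOTIDES[i],
                                              ab.NUCLEOTIDES[j])
        return lut[a, b]

    def genotype_matrix(self) -> GenotypeMatrix:
        ref = [ab.NUCLEOTIDES[i] for i in self.ref]
        return GenotypeMatrix(self.unphased_codes(), list(self.labels),
                              ref=ref, alt=None)


def _tip_rows(genealogy: Genealogy) -> tuple[list[int], dict[int, int]]:
    tree = genealogy.tree
    tips = [n for n in tree.adj
            if tree.degree(n) == 1 and n != genealogy.apex]
    tips.sort(key=lambda n: genealogy.labels.index(tree.labels[n]))
    return tips, {n: i for i, n in enumerate(tips)}


def simulate_mutations_ism(genealogy: Genealogy, n_snvs: int,
                           seed: int) -> TrueGenotypes:
    """Diploid infinite-site mutations: each SNV mutates exactly once, on
    a branch drawn proportionally to branch length, on the maternal or
    paternal chromosome with probability 1/2."""
    if n_snvs < 1:
        raise ValueError("need at least one SNV")
    rng = np.random.default_rng(seed)
    tree = genealogy.tree
    branch_list = genealogy.branches()
    lengths = np.array([b[2] for b in branch_list])
    if lengths.sum() <= 0:
        raise ValueError("tree has zero total length")
    probs = lengths / lengths.sum()
    tips, row_of = _tip_rows(genealogy)
    n = len(tips)
    # clade membership mask per branch (cells below the branch's child)
    order, parent, children = tree.traversal(genealogy.apex)
    below: dict[int, np.ndarray] = {}
    for node in order:
        mask = np.zeros(n, dtype=bool)
        if node in row_of:
            mask[row_of[node]] = True
        for k in children[node]:
            mask |= below[k]
        below[node] = mask
    refs = rng.integers(0, 4, size=n_snvs)
    alts = (refs + rng.integers(1, 4, size=n_snvs)) % 4
    branch_idx = rng.choice(len(branch_list), size=n_snvs, p=probs)
    which_allele = rng.integers(0, 2, size=n_snvs)
    alleles = np.empty((n, n_snvs, 2), dtype=np.int8)
    alleles[..., 0] = refs[None, :]
    alleles[..., 1] = refs[None, :]
    branch_child = np.empty(n_snvs, dtype=np.int64)
    for j in range(n_snvs):
        child = branch_list[branch_idx[j]][0]
        branch_child[j] = child
        carriers = below[child]
        alleles[carriers, j, which_allele[j]] = alts[j]
    return TrueGenotypes(alleles, list(genealogy.labels), refs,
                         branch_child, which_allele, alts)


def simulate_mutations_finite(genealogy: Genealogy,
                              dna_model: RateMatrix | None,
                              mutation_rate: float,
                              site_rate_gamma_shape: float | None,
                              n_sites: int, seed: int) -> TrueGenotypes:
    """Finite-site mutations under a (possibly non-reversible) DNA model.

    Both allele lineages of every site evolve independently along the
    genealogy with expected substitutions mu * t(generations) * r_site,
    r_site ~ Gamma(shape, 1/shape).  Simulation is exact via
    uniformization of the CTMC.
    """
    rng = np.random.default_rng(seed)
    if dna_model is None:
        dna_model = build_gtnr_matrix(SIGNATURE1_GTNR_RATES)
    Q = dna_model.Q
    pi = dna_model.frequencies
    lam = float(np.max(-np.diag(Q)))
    U = np.eye(4) + Q / lam           # uniformized jump kernel
    Ucum = np.cumsum(U, axis=1)
    site_rates = np.ones(n_sites)
    if site_rate_gamma_shape is not None:
        site_rates = rng.gamma(site_rate_gamma_shape,
                               1.0 / site_rate_gamma_shape, size=n_sites)
    refs = rng.choice(4, size=n_sites, p=pi).astype(np.int8)
    tree = genealogy.tree
    order, parent, children = tree.traversal(genealogy.apex)
    tips, row_of = _tip_rows(genealogy)
    alleles = np.empty((len(tips), n_sites, 2), dtype=np.int8)
    # evolve both chromosomes: state per (site, allele) at each node
    state: dict[int, np.ndarray] = {
        genealogy.apex: np.repeat(refs[:, None], 2, axis=1)}
    for node in reversed(order):  # preorder
        for k in children[node]:
            t = tree.adj[k][node]
            s = state[node].copy()
            n_events = rng.poisson(lam * mutation_rate * t
                                   * site_rates[:, None],
                                   size=(n_sites, 2))
            for (j, a) in zip(*np.nonzero(n_events)):
                x = s[j, a]
                for _ in range(n_events[j, a]):
                    x = int(np.searchsorted(Ucum[x], rng.random(),
                                            side="right"))
                s[j, a] = x
            state[k] = s
            if k in row_of:
                alleles[row_of[k]] = s
    return TrueGenotypes(alleles, list(genealogy.labels), refs)


def variant_sites(truth: TrueGenotypes) -> np.ndarray:
    """Indices of sites where any cell differs from the reference allele."""
    diff = (truth.alleles != truth.ref[None, :, None]).any(axis=(0, 2))
    return np.nonzero(diff)[0]


# -- observation layers ----------------------------------------------------


def apply_genotype_errors(truth: TrueGenotypes, delta: float, epsilon: float,
                          seed: int) -> GenotypeMatrix:
    """Push true genotypes through the ADO/error observation kernel.

    Each cell/site draws an observed phased genotype from P(Y|X; delta,
    epsilon) independently; the result is reported unphased.
    """
    rng = np.random.default_rng(seed)
    K = error_kernel(delta, epsilon)
    Kcum = np.cumsum(K, axis=1)
    x = (truth.alleles[..., 0].astype(np.int16) * 4
         + truth.alleles[..., 1]).ravel()
    u = rng.random(x.shape[0])
    y = np.empty_like(x)
    for xi in np.unique(x):
        m = x == xi
        y[m] = np.searchsorted(Kcum[xi], u[m], side="right")
    y = np.minimum(y, 15)
    observed = np.array(ab.PHASED_TO_UNPHASED, dtype=np.int8)[y]
    mat = observed.reshape(truth.alleles.shape[:2])
    ref = [ab.NUCLEOTIDES[i] for i in truth.ref]
    return GenotypeMatrix(mat, list(truth.labels), ref=ref)


def _misread_matrix(error: float) -> np.ndarray:
    """4x4 per-read miscall matrix for a symmetric error rate."""
    return (1 - error) * np.eye(4) + (error / 3) * (np.ones((4, 4)) - np.eye(4))


@dataclass
class ReadCounts:
    """Per cell x site read counts by nucleotide, with genotype
    likelihoods and ML calls derived from them."""

    counts: np.ndarray              # (cells, sites, 4)
    labels: list[str]
    ref: np.ndarray
    log10_gl: np.ndarray            # (cells, sites, 10), max-normalized
    ml_calls: np.ndarray            # (cells, sites) unphased codes, 10=missing
    dropped: np.ndarray             # (cells, sites) True where one allele ADO
    log10_gt_p: np.ndarray | None = None  # (10, 4) per-read emission log10-probs

    @property
    def depth(self) -> np.ndarray:
        return self.counts.sum(axis=2)

    def ml_matrix(self) -> GenotypeMatrix:
        ref = [ab.NUCLEOTIDES[i] for i in self.ref]
        return GenotypeMatrix(self.ml_calls, list(self.labels), ref=ref)


def simulate_reads(truth: TrueGenotypes, depth: float,
                   amplification_error: float, sequencing_error: float,
                   delta: float, seed: int,
                   overdispersion: float = 2.0) -> ReadCounts:
    """Simulate NGS read counts, genotype likelihoods, and ML calls.

    ADO is applied first (one allele dropped with probability delta,
    halving the expected depth); read depth is negative-binomial around
    the target; each read derives from one surviving allele uniformly,
    then suffers amplification and sequencing miscalls independently.
    Genotype log10-likelihoods use a symmetric per-read error model with
    rate min(amp + seq, 3/4); the ML genotype is the likelihood argmax,
    ties broken uniformly at random.
    """
    if depth <= 0:
        raise ValueError("depth must be positive")
    rng = np.random.default_rng(seed)
    n_cells, n_sites = truth.alleles.shape[:2]
    a = truth.alleles[..., 0].astype(np.int64)
    b = truth.alleles[..., 1].astype(np.int64)
    dropped = rng.random((n_cells, n_sites)) < delta
    keep_maternal = rng.random((n_cells, n_sites)) < 0.5
    a_eff = np.where(dropped & ~keep_maternal, b, a)
    b_eff = np.where(dropped & keep_maternal, a, b)
    mean_depth = np.where(dropped, depth / 2.0, depth)
    k = overdispersion
    n_reads = rng.negative_binomial(k, k / (k + mean_depth))
    # per-read emission distribution given the surviving allele pair
    M = _misread_matrix(amplification_error) @ _misread_matrix(sequencing_error)
    pvals = 0.5 * (M[a_eff] + M[b_eff])     # (cells, sites, 4)
    counts = rng.multinomial(n_reads, pvals)
    # genotype likelihoods under the symmetric read-error model
    e = min(amplification_error + sequencing_error, 0.75)
    Merr = _misread_matrix(e)
    gt_p = np.empty((10, 4))
    for u in range(10):
        ga, gb = ab.unphased_alleles(u)
        gt_p[u] = 0.5 * (Merr[ab.NUCLEOTIDES.index(ga)]
                         + Merr[ab.NUCLEOTIDES.index(gb)])
    # floor emission probabilities so impossible bases stay representable
    # (a zero count times a finite log contributes nothing)
    log10_gt_p = np.log10(np.maximum(gt_p, 1e-12))
    gl = counts @ log10_gt_p.T              # (cells, sites, 10)
    gl = gl - gl.max(axis=2, keepdims=True)
    # ML calls with uniform random tie-breaking; zero depth -> missing
    jitter = rng.random(gl.shape) * 1e-9
    ml = np.argmax(gl + jitter, axis=2).astype(np.int8)
    ml[n_reads == 0] = ab.MISSING_INDEX
    gl[n_reads == 0] = 0.0
    return ReadCounts(counts, list(truth.labels), truth.ref, gl,
                      ml, dropped, log10_gt_p)


def inject_doublets(truth: TrueGenotypes, reads: ReadCounts | None,
                    matrix: GenotypeMatrix | None, doublet_rate: float,
                    seed: int):
    """Replace each observed cell, with probability ``doublet_rate``, by a
    merge of itself and another uniformly chosen simulated cell.

    Read counts are summed; genotype-mode merges pool the four alleles of
    the two true genotypes and sample two of them without replacement.
    Returns (reads, matrix) with the same shapes as the inputs.
    """
    if not 0.0 <= doublet_rate <= 1.0:
        raise ValueError("doublet rate must be in [0, 1]")
    n_cells = truth.n_cells
    if n_cells < 2:
        raise ValueError("doublets need at least 2 cells")
    rng = np.random.default_rng(seed)
    is_doublet = rng.random(n_cells) < doublet_rate
    partners = np.array([
        rng.choice([j for j in range(n_cells) if j != i])
        for i in range(n_cells)])
    new_reads = None
    if reads is not None:
        counts = reads.counts.copy()
        gl = reads.log10_gl.copy()
        ml = reads.ml_calls.copy()
        for i in np.nonzero(is_doublet)[0]:
            counts[i] = reads.counts[i] + reads.counts[partners[i]]
            # re-derive likelihoods and calls from the pooled counts
            merged = counts[i] @ reads.log10_gt_p.T
            merged -= merged.max(axis=1, keepdims=True)
            gl[i] = merged
            ml[i] = np.argmax(merged, axis=1).astype(np.int8)
            ml[i][counts[i].sum(axis=1) == 0] = ab.MISSING_INDEX
        new_reads = ReadCounts(counts, list(reads.labels), reads.ref, gl,
                               ml, reads.dropped, reads.log10_gt_p)
    new_matrix = None
    if matrix is not None:
        mat = matrix.matrix.copy()
        for i in np.nonzero(is_doublet)[0]:
            j = partners[i]
            for s in range(truth.n_sites):
                # union of the two cells' alleles, capped to a diploid
                # genotype (two distinct alleles sampled when more pool up)
                pool = np.unique(np.concatenate([truth.alleles[i, s],
                                                 truth.alleles[j, s]]))
                if len(pool) == 1:
                    x = y = pool[0]
                elif len(pool) == 2:
                    x, y = pool
                else:
                    x, y = rng.choice(pool, size=2, replace=False)
                mat[i, s] = ab.unphased_index(ab.NUCLEOTIDES[x],
                                              ab.NUCLEOTIDES[y])
        new_matrix = GenotypeMatrix(mat, list(matrix.cell_names),
                                    list(matrix.site_ids),
                                    matrix.ref, matrix.alt)
    return new_reads, new_matrix


@dataclass
class SimulatedDataset:
    """Everything one simulation run produced, truth included."""

    config: SimulationConfig
    genealogy: Genealogy
    truth: TrueGenotypes
    observed: GenotypeMatrix          # observed genotype matrix
    reads: ReadCounts | None = None
    true_tree: CellTree = field(default=None)

    def truth_table(self):
        """Per-site mutation truth as a pandas DataFrame (ISM runs)."""
        import pandas as pd
        if self.truth.mutation_branch is None:
            return pd.DataFrame({"site": range(self.truth.n_sites)})
        return pd.DataFrame({
            "site": range(self.truth.n_sites),
            "ref": [ab.NUCLEOTIDES[i] for i in self.truth.ref],
            "branch_child_node": self.truth.mutation_branch,
            "allele": np.where(self.truth.mutation_allele == 0,
                               "maternal", "paternal"),
        })


def simulate_dataset(config: SimulationConfig) -> SimulatedDataset:
    """Run the full generator pipeline for one replicate."""
    rng = np.random.default_rng(config.seed)
    seeds = rng.integers(1, 2 ** 31, size=6)
    genealogy = simulate_genealogy(config, seed=int(seeds[0]))
    if config.mutation_model == "ism":
        truth = simulate_mutations_ism(genealogy, config.n_snvs,
                                       seed=int(seeds[1]))
    else:
        truth = simulate_mutations_finite(
            genealogy, None, config.mutation_rate,
            config.site_rate_gamma_shape, config.n_sites, seed=int(seeds[1]))
    reads = None
    if config.observation_mode == "reads":
        reads = simulate_reads(truth, config.read_depth,
                               config.amplification_error,
                               config.sequencing_error, config.ado_rate,
                               seed=int(seeds[2]),
                               overdispersion=config.depth_overdispersion)
        observed = reads.ml_matrix()
    else:
        observed = apply_genotype_errors(truth, config.ado_rate,
                                         config.genotype_error_rate,
                                         seed=int(seeds[3]))
    if config.doublet_rate > 0:
        reads, observed2 = inject_doublets(truth, reads, observed,
                                           config.doublet_rate,
                                           seed=int(seeds[4]))
        if observed2 is not None:
            observed = observed2
    if config.mutation_model == "ism":
        # ISM: each site mutates once somewhere on the tree, so expected
        # mutations per site on a branch is its share of the total length
        total = sum(b[2] for b in genealogy.branches())
        scale = 1.0 / total if total > 0 else 1.0
    else:
        scale = config.mutation_rate
    return SimulatedDataset(config, genealogy, truth, observed, reads,
                            genealogy.unrooted_true_tree(scale=scale))
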