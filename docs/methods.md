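# Methods

## The genotype substitution model

gtphylo models the evolution of diploid single-nucleotide variant (SNV)
genotypes along a cell lineage tree as a continuous-time reversible Markov
chain over the 16 phased genotypes Γ = {A|A, A|C, …, T|T} (GT16).  Because
somatic cells divide mitotically, both chromosomes record the same cell
history, so the phase of a genotype carries no extra phylogenetic
information; the model nevertheless works on the phased space and handles
unphased data by giving both phasings of a heterozygote the same tip
likelihood.

The rate matrix is Q = R · diag(π): a symmetric exchangeability matrix
times the stationary genotype frequencies.  Two structural assumptions cut
the parameter count: only one allele can change in an instant (all
two-allele changes have rate 0), and the rate of an allele change does not
depend on the homologous allele, i.e. r(na↔nb) = r(a↔b).  That leaves five
free nucleotide exchangeabilities (α = A↔C, β = A↔G, γ = A↔T, κ = C↔G,
λ = C↔T, with G↔T ≡ 1) and the genotype frequencies.  Q is normalized so
the expected substitution rate at stationarity is 1; branch lengths are
then expected mutations per SNV site.  The normalization constant is
exposed as `RateMatrix.scaling`.

The 10-state unphased reduction (GT10) applies the same construction on
the unphased genotypes: every pair of genotypes differing by one allele
(in the multiset sense) exchanges at the rate of the changed nucleotide
pair.  This keeps the chain reversible at the cost of equating the
homozygote→heterozygote and heterozygote→homozygote exchangeabilities,
which is known to be a factor-of-two approximation; the package treats
GT10 as a cheaper alternative, not the default.  The exact sharing of
exchangeabilities beyond that equivalence was an open design choice; we
adopted the simplest completion (one rate per changed nucleotide pair).

Transition probabilities P(t) = exp(Qt) are computed from the
eigendecomposition of the symmetrized matrix D^{1/2} Q D^{-1/2}
(D = diag π), falling back to `scipy.linalg.expm` when any frequency drops
below 1e-10 or the model is non-reversible (the simulator's GTnR DNA
matrix).  Negative entries from roundoff are clipped at zero; row sums
stay within 1e-10 of 1.

## The single-cell observation model

Observed genotypes are corrupted by allelic dropout (ADO, rate δ: one
allele fails to amplify, so a heterozygote reads as a homozygote) and by
amplification/sequencing error (rate ε: one allele is read as another
nucleotide).  At most one amplification error per genotype is allowed
(the ε² term is negligible at realistic error rates) but ADO and one error
may co-occur.  The kernel P(Y|X) is written out in `gtphylo/errors.py`;
rows sum to 1 for every (δ, ε) ∈ [0,1]², which the test suite checks on a
grid.  Dropout and error never swap maternal/paternal phase: a phased
observation b|a given truth a|b has probability 0, and unphased observed
heterozygotes sum over both phasings.

Tip genotype-likelihood vectors are initialized per input mode:

* genotype matrix with the error model active: L(X) = P(Y_obs | X);
* genotype matrix without the error model: indicator vectors (both
  phasings of a heterozygote set to 1);
* log10 genotype likelihoods over the 10 unphased states: both phasings
  get 10^G, rescaled so the maximum is 1 (the rescaling only shifts the
  log-likelihood by a per-site constant and protects against underflow);
* VCF PL triplets: 10^(−PL/10) on the four phased ref/alt genotypes, zero
  elsewhere.  The hom-alt branch of the PL mapping is implemented as
  a = ALT ∧ b = ALT.
* missing data: all-ones vectors.

## Likelihood, optimization, and tree search

The phylogenetic log-likelihood is the weighted sum over compressed site
patterns of log P(pattern | tree, model), computed by Felsenstein pruning
with a virtual root placed on an arbitrary node — provably
placement-invariant for a reversible chain, and verified by a test rather
than assumed.  Conditional likelihood vectors are rescaled per node by
their per-pattern maximum with accumulated log offsets, so no intermediate
underflows.  Identical site patterns are collapsed with multiplicity
weights; the result is bit-identical to the uncompressed computation.

Branch lengths are optimized one edge at a time with bounded Brent on a
profile obtained by factoring the tree across the edge.  A sweep reuses
one set of directional conditional vectors for all edges; if a sweep ever
fails to improve the exact log-likelihood it is reverted and repeated with
per-edge exact partials, so the reported log-likelihood never decreases.
Branch lengths live in [1e-9, 100].

Exchangeabilities (log-transformed) and genotype frequencies
(logit-transformed, floored at 1e-6) are optimized jointly with L-BFGS-B;
δ and ε are optimized cyclically with bounded Brent, re-initializing all
tip vectors at every evaluation.  Every optimizer keeps the incumbent when
it fails to improve.

Tree search starts from parsimony trees (randomized stepwise addition
scored by Fitch parsimony over the 10 unphased states; genotype-likelihood
input is first reduced to per-site ML genotypes for scoring) and/or
uniformly random topologies — by default 10 + 10, matching the standard
multi-start heuristic; single-start configurations are available and used
for the benchmark experiments.  The search alternates
subtree-pruning-and-regrafting (SPR) rounds with parameter
re-optimization.  Within a round every directed edge is pruned in turn and
all regraft edges within the round's radius are scored in constant time
from directional conditional vectors recomputed on the pruned tree, with
current branch lengths; the best improving candidate is applied and
verified by an exact recomputation before acceptance.  Between rounds
branch lengths and error rates are re-optimized; substitution parameters
are refit at the start and at the end (a documented economy — they move
little during topology moves).  The radius schedule defaults to (5, 10,
unbounded); rounds stop when no move improves the log-likelihood by more
than 0.1 log units, and a final polish optimizes branch lengths to 0.001.

The likelihood as described applies no ascertainment-bias or
invariant-site correction for SNV-only matrices.

## Branch support, tree comparison, ancestral states

Bootstrap replicates resample SNV sites with replacement (default 100
replicates).  Felsenstein support is the percentage of replicate trees
containing the exact bipartition.  Transfer support (TBE) credits inexact
matches: for a branch whose lighter side holds p taxa, a replicate
contributes 1 − d/(p−1), where d is the minimum transfer distance to any
branch of the replicate (capped at p−1, the distance achievable against a
pendant edge).  TBE never falls below the Felsenstein value.

Tree accuracy is 1 − nRF, where nRF divides the Robinson–Foulds count of
bipartitions unique to either tree by the total number of internal
branches present in both trees, so multifurcating comparison trees shrink
the denominator.

Marginal ancestral genotypes come from a downward and an upward pruning
pass.  Because phase is unidentifiable, the ML genotype at a node is the
argmax over *unphased* genotypes — both phasings of a heterozygote are
summed before the comparison (otherwise a het's posterior mass, split
between its two phasings, loses to a homozygote it actually outweighs);
posterior ties break by fixed state-order precedence for reproducibility.  A mutation is mapped onto a branch whenever the ML
genotypes at its ends differ; with outgroup rooting on a zero-length
branch, the two root-adjacent edges are merged onto the ingroup edge.
Sites mutated on the shared root branch of a simulation are heterozygous
in every cell, hence constant columns, and correctly map to no branch.

## The simulator

The generator emulates a single-cell DNA sequencing benchmark: cell
genealogies are coalescent trees from an exponentially growing population
(growth rate 1e-4 per generation, present-day effective size 10,000,
sampled with msprime; times in generations), with a root branch of 0.1 —
interpreted in coalescent units of 2N generations, since the source unit
convention is not stated — whose mutations are shared by every cell, and a
healthy outgroup cell attached at zero distance from the sample MRCA (so
outgroup and MRCA genotypes are identical).  Optional mean-1 Gamma
multipliers perturb branch rates; the default leaves them off, matching
the error-estimation study conditions, and the shape parameter is exposed
for experiments that want lineage rate variation.

Mutations follow either a diploid infinite-site model (each SNV mutates
exactly once, on a branch drawn proportionally to length, on the maternal
or paternal chromosome with probability ½, reference and derived alleles
drawn uniformly) or a finite-site non-reversible DNA model whose rates
pool the COSMIC signature-1 single-nucleotide rates (G→A strongly
dominant), scaled to mutation rate 1e-6 per site per generation, with
mean-1 Gamma rate variation across sites.  Finite-site evolution is
simulated exactly by uniformization of the CTMC.  At these settings a
100-cell, 10,000-site genome yields on the order of 2,000 true SNVs.

Observed data are generated two ways.  Genotype mode pushes the true
phased genotypes through the observation kernel P(Y|X; δ, ε) — exactly the
inference model, which makes the error-rate recovery experiments a
well-posed check of the estimator rather than of model mismatch.  Read
mode first applies ADO, then draws a negative-binomial read depth
(dispersion 2; expectation halved at dropout sites), assigns each read to
a surviving allele uniformly, and applies amplification and sequencing
miscalls independently per read.  Genotype log10-likelihoods use a
symmetric per-read error model with rate min(amp + seq, ¾) — a documented
simplification of multi-template amplification models — and the ML
genotype call breaks ties uniformly at random.  Doublets replace a cell,
with the configured probability, by a merge with a uniformly chosen other
cell: read counts are summed; in genotype mode the union of the two
genotypes' alleles is capped to a diploid genotype (two distinct alleles
sampled when more than two pool up).

What the generator does not emulate: trinucleotide-context mutational
signatures, copy-number variation, germline polymorphism, coverage
correlation along the genome, and cell-specific quality differences.
Passing tests therefore demonstrate correctness of the estimator under
its own assumptions and robustness to the modelled noise, not performance
on arbitrary real datasets.

## Numerical and design choices

* Scaling thresholds: per-node rescale-by-maximum during pruning;
  frequencies floored at 1e-6 during optimization; eigendecomposition
  replaced by `expm` below frequency 1e-10.
* Ties: posterior ties in ancestral reconstruction break by state order;
  parsimony insertion ties break by the seeded RNG; simulated ML-call ties
  break uniformly at random with the dataset seed.
* All randomness flows from a single integer seed per run; reruns with the
  same inputs and seed are bit-identical.
* Benchmark problem sizes used by the test suite and the reproduction
  script (20 replicates of 40 cells × 1000 SNVs for error-rate recovery;
  250-SNV replicates for the noise-degradation trend; 500-site read-mode
  replicates at 5× depth for the genotype-likelihood comparison; 5-cell
  exhaustive-search instances) are the package's chosen desk-scale study
  conditions.
* Known limitations: the SPR schedule is a simplified accept-if-better
  hill climb, not a full replication of mature search heuristics; GT10's
  exchangeability sharing is a documented choice; multi-allelic VCF
  records are skipped in PL mode rather than split.
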