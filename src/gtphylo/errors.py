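"""Single-cell genotype observation model.

Observed single-cell genotypes are noisy: allelic dropout (ADO, rate
delta) loses one allele during amplification so a heterozygote is read as
a homozygote, and amplification/sequencing error (rate epsilon) replaces
one allele by another nucleotide.  At most one amplification error per
genotype is allowed (the probability of two, epsilon^2, is negligible),
but ADO and one error may co-occur.  The kernel P(Y|X) below gives the
probability of observing phased genotype Y given true phased genotype X:

  true homozygote a|a:
      P(a|a | a|a) = 1 - eps + delta*eps/2
      P(a|b | a|a) = P(b|a | a|a) = (1 - delta) * eps/6       (b != a)
      P(b|b | a|a) = delta * eps / 6                          (b != a)
  true heterozygote a|b:
      P(a|a | a|b) = P(b|b | a|b) = delta/2 + eps/6 - delta*eps/3
      P(c|c | a|b) = delta * eps / 6                          (c not in {a,b})
      P(a|c | a|b) = P(c|b | a|b) = (1 - delta) * eps/6       (c not in {a,b})
      P(a|b | a|b) = (1 - delta) * (1 - eps)
      all other observations (including the phase swap b|a)   = 0

Every row sums to 1 for any (delta, eps) in [0,1]^2.  Dropout or error
never swaps maternal/paternal phase; unphased observations sum over both
phasings.

This module also initializes tip genotype-likelihood vectors from observed
genotype characters, from log10 genotype likelihoods over the 10 unphased
states, and from VCF Phred-scaled PL triplets.
"""

from __future__ import annotations

from dataclasses import dataclass
from functools import lru_cache

import numpy as np

from . import alphabet as ab


@dataclass(frozen=True)
class ErrorParams:
    """ADO rate delta and amplification/sequencing error rate epsilon."""

    delta: float = 0.0
    epsilon: float = 0.0

    def __post_init__(self) -> None:
        for name, v in (("delta", self.delta), ("epsilon", self.epsilon)):
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name}={v} outside [0, 1]")


def error_kernel(delta: float, epsilon: float) -> np.ndarray:
    """16x16 matrix K with K[x, y] = P(observe Y | true X)."""
    if not (0.0 <= delta <= 1.0 and 0.0 <= epsilon <= 1.0):
        raise ValueError("error parameters must lie in [0, 1]")
    d, e = delta, epsilon
    K = np.zeros((16, 16))
    for x in range(16):
        a, b = divmod(x, 4)
        for y in range(16):
            c, f = divmod(y, 4)
            if a == b:  # true homozygote a|a
                if y == x:
                    K[x, y] = 1.0 - e + 0.5 * d * e
                elif c == a and f != a or f == a and c != a:
                    K[x, y] = (1.0 - d) * e / 6.0
                elif c == f:  # b|b, b != a
                    K[x, y] = d * e / 6.0
            else:  # true heterozygote a|b
                if y == x:
                    K[x, y] = (1.0 - d) * (1.0 - e)
                elif c == f:
                    if c == a or c == b:
                        K[x, y] = 0.5 * d + e / 6.0 - d * e / 3.0
                    else:
                        K[x, y] = d * e / 6.0
                elif (c == a and f not in (a, b)) or (f == b and c not in (a, b)):
                    K[x, y] = (1.0 - d) * e / 6.0
                # phase swap b|a and double changes stay 0
    return K


def observation_probability(true_genotype: str, observed_genotype: str,
                            params: ErrorParams) -> float:
    """P(Y|X) for phased genotype strings like "A|C"."""
    K = error_kernel(params.delta, params.epsilon)
    x = ab.phased_index(true_genotype[0], true_genotype[2])
    y = ab.phased_index(observed_genotype[0], observed_genotype[2])
    return float(K[x, y])


@lru_cache(maxsize=64)
def _leaf_matrix_cached(delta: float, epsilon: float, error_active: bool,
                        n_states: int) -> np.ndarray:
    """(11, n_states) lookup: row u = tip likelihood vector for observed
    unphased state u (row 10 = missing -> all ones)."""
    M = np.zeros((ab.N_UNPHASED + 1, n_states))
    if error_active:
        K = error_kernel(delta, epsilon)
        for u, phasings in enumerate(ab.UNPHASED_TO_PHASED):
            if n_states == 16:
                for y in phasings:
                    M[u] += K[:, y]
            else:
                # collapse true states to unphased: rows for both phasings
                # of a true heterozygote agree after summing observations
                for x10 in range(10):
                    x16 = ab.UNPHASED_TO_PHASED[x10][0]
                    M[u, x10] = sum(K[x16, y] for y in phasings)
    else:
        for u, phasings in enumerate(ab.UNPHASED_TO_PHASED):
            if n_states == 16:
                M[u, list(phasings)] = 1.0
            else:
                M[u, u] = 1.0
    M[ab.MISSING_INDEX] = 1.0
    return M


def genotype_leaf_matrix(params: ErrorParams, error_active: bool = True,
                         n_states: int = 16) -> np.ndarray:
    """Tip-likelihood lookup table indexed by observed unphased state.

    Row u gives L(X) = P(Y_u | X) over the true genotype states (16 phased
    by default, 10 unphased for GT10), with unphased heterozygous
    observations summed over both phasings; the missing row is all ones.
    With the error model off, rows are indicator vectors (both phasings of
    a heterozygote set to 1 in the 16-state case).
    """
    if n_states not in (16, 10):
        raise ValueError("n_states must be 16 or 10")
    return _leaf_matrix_cached(float(params.delta), float(params.epsilon),
                               bool(error_active), n_states)


def tip_likelihoods_from_genotype(observed: str, params: ErrorParams,
                                  error_model_active: bool = True) -> np.ndarray:
    """16-vector of tip likelihoods for one observed genotype character."""
    u = ab.encode_char(observed)
    return genotype_leaf_matrix(params, error_model_active)[u].copy()


def tip_likelihoods_from_gl(log10_likelihoods) -> np.ndarray:
    """Tip vector from log10 genotype likelihoods over the 10 unphased states.

    Both phasings of each heterozygote receive the unphased value; the
    vector is rescaled so its maximum is 1.  -inf marks an impossible
    genotype; an all-missing entry may be passed as None.
    """
    if log10_likelihoods is None:
        return np.ones(16)
    g = np.asarray(log10_likelihoods, dtype=float)
    if g.shape != (10,):
        raise ValueError("expected 10 log10 genotype likelihoods")
    if np.any(np.isnan(g)):
        raise ValueError("genotype likelihoods must be finite or -inf")
    L = np.zeros(16)
    for u, phasings in enumerate(ab.UNPHASED_TO_PHASED):
        val = 10.0 ** (g[u] - g.max())
        for y in phasings:
            L[y] = val
    if L.max() <= 0:
        raise ValueError("all genotype likelihoods are zero")
    return L


def tip_likelihoods_from_pl(pl, ref: str, alt: str) -> np.ndarray:
    """Tip vector from a Phred-scaled (PL0, PL1, PL2) triplet.

    PL0/PL1/PL2 are for REF/REF, REF/ALT and ALT/ALT; likelihood is
    10^(-PL/10).  Genotypes involving any other allele get 0.  A missing
    call (pl None) yields the all-ones vector.
    """
    if pl is None:
        return np.ones(16)
    pl = np.asarray(pl, dtype=float)
    if pl.shape != (3,):
        raise ValueError("expected a 3-value PL field (biallelic site); "
                         "split or filter multi-allelic records upstream")
    if np.any(pl < 0):
        raise ValueError("PL values must be nonnegative")
    vals = 10.0 ** (-0.1 * (pl - pl.min()))
    L = np.zeros(16)
    L[ab.phased_index(ref, ref)] = vals[0]
    L[ab.phased_index(ref, alt)] = vals[1]
    L[ab.phased_index(alt, ref)] = vals[1]
    L[ab.phased_index(alt, alt)] = vals[2]
    return L
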