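"""Substitution models for diploid genotypes and the simulator's DNA model.

GT16 is a general time-reversible continuous-time Markov chain over the 16
phased diploid genotypes.  Its rate matrix is the product of a symmetric
exchangeability matrix and the diagonal of stationary genotype frequencies,
with the constraint that only one of the two alleles may change in an
instant, and that the rate of an allele change does not depend on the
homologous allele.  This leaves five free nucleotide exchangeabilities
(alpha=A~C, beta=A~G, gamma=A~T, kappa=C~G, lambda=C~T; G~T fixed to 1)
plus the genotype frequencies.  GT10 is the analogous reversible model on
the 10 unphased genotypes.  GTnR is a non-reversible 4-state DNA matrix
used only by the simulator.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import scipy.linalg

from . import alphabet as ab

#: Order of the exchangeability vector: A~C, A~G, A~T, C~G, C~T, G~T.
EXCHANGEABILITY_PAIRS = (("A", "C"), ("A", "G"), ("A", "T"),
                         ("C", "G"), ("C", "T"), ("G", "T"))

_PAIR_INDEX = {frozenset(p): i for i, p in enumerate(EXCHANGEABILITY_PAIRS)}

_FREQ_EXPM_FLOOR = 1e-10  # below this, eigendecomposition gives way to expm


@dataclass
class SubstitutionParams:
    """Free parameters of the GT16/GT10 model.

    ``exchangeabilities`` holds the five free rates (A~C, A~G, A~T, C~G,
    C~T); the sixth (G~T) is fixed to 1.  ``frequencies`` has 16 entries
    for GT16 or 10 for GT10 and sums to 1.
    """

    exchangeabilities: np.ndarray
    frequencies: np.ndarray
    frequency_mode: str = "optimized"

    def __post_init__(self) -> None:
        self.exchangeabilities = np.asarray(self.exchangeabilities, dtype=float)
        self.frequencies = np.asarray(self.frequencies, dtype=float)
        if self.exchangeabilities.shape != (5,):
            raise ValueError("expected 5 free exchangeabilities")
        if np.any(self.exchangeabilities <= 0):
            raise ValueError("exchangeabilities must be positive")
        if self.frequencies.shape not in ((16,), (10,)):
            raise ValueError("expected 16 or 10 genotype frequencies")
        if np.any(self.frequencies < 0):
            raise ValueError("frequencies must be nonnegative")
        if abs(self.frequencies.sum() - 1.0) > 1e-8:
            raise ValueError(
                f"frequencies sum to {self.frequencies.sum():.12g}, not 1"
            )

    @property
    def n_states(self) -> int:
        return self.frequencies.shape[0]

    @property
    def full_exchangeabilities(self) -> np.ndarray:
        """All six rates with G~T appended as 1."""
        return np.concatenate([self.exchangeabilities, [1.0]])

    @classmethod
    def default(cls, n_states: int = 16, frequency_mode: str = "optimized"):
        return cls(np.ones(5), np.full(n_states, 1.0 / n_states), frequency_mode)


@dataclass
class RateMatrix:
    """Normalized rate matrix with its eigensystem for computing P(t).

    For the reversible genotype models the eigensystem comes from the
    symmetrized matrix ``D^(1/2) Q D^(-1/2)`` (D = diag of frequencies),
    which is numerically stable; ``scaling`` is the factor the raw matrix
    was divided by so that the expected rate at stationarity is 1 (branch
    lengths are then expected mutations per SNV site).
    """

    Q: np.ndarray
    frequencies: np.ndarray
    scaling: float
    reversible: bool = True
    _eigen: tuple | None = field(default=None, repr=False)

    @property
    def n_states(self) -> int:
        return self.Q.shape[0]

    def _eigensystem(self):
        if self._eigen is None:
            pi = self.frequencies
            if self.reversible and pi.min() > _FREQ_EXPM_FLOOR:
                d = np.sqrt(pi)
                B = (self.Q * d[:, None]) / d[None, :]
                B = 0.5 * (B + B.T)  # enforce exact symmetry
                w, U = np.linalg.eigh(B)
                V = U / d[:, None]
                Vinv = U.T * d[None, :]
                self._eigen = (w, V, Vinv)
            else:
                self._eigen = None  # sentinel: use expm
                return None
        return self._eigen

    def transition_matrix(self, t: float) -> np.ndarray:
        """P(t) = exp(Qt); rows sum to 1, entries clipped at 0."""
        if t < 0:
            raise ValueError(f"negative branch length {t}")
        eig = self._eigensystem()
        if eig is None:
            P = scipy.linalg.expm(self.Q * t)
        else:
            w, V, Vinv = eig
            P = (V * np.exp(w * t)) @ Vinv
        np.clip(P, 0.0, None, out=P)
        return P

    def transition_matrices(self, ts: np.ndarray) -> np.ndarray:
        """P(t) for a vector of branch lengths, shape (len(ts), n, n)."""
        ts = np.asarray(ts, dtype=float)
        if np.any(ts < 0):
            raise ValueError("negative branch length")
        eig = self._eigensystem()
        if eig is None:
            return np.stack([scipy.linalg.expm(self.Q * t) for t in ts])
        w, V, Vinv = eig
        E = np.exp(ts[:, None] * w[None, :])  # (E, n)
        P = (V[None, :, :] * E[:, None, :]) @ Vinv
        np.clip(P, 0.0, None, out=P)
        return P


def _genotype_rate(x: tuple[int, int], y: tuple[int, int],
                   rates: np.ndarray) -> float:
    """Exchangeability between two phased genotypes (0 if inadmissible)."""
    (a, b), (c, d) = x, y
    if a == c and b != d:
        changed = (b, d)
    elif b == d and a != c:
        changed = (a, c)
    else:
        return 0.0
    pair = frozenset(ab.NUCLEOTIDES[i] for i in changed)
    return rates[_PAIR_INDEX[pair]]


def _normalize(Q: np.ndarray, pi: np.ndarray) -> tuple[np.ndarray, float]:
    np.fill_diagonal(Q, 0.0)
    np.fill_diagonal(Q, -Q.sum(axis=1))
    scaling = -float(np.dot(pi, np.diag(Q)))
    if scaling <= 0:
        raise ValueError("degenerate rate matrix: zero expected rate")
    return Q / scaling, scaling


def build_gt16_rate_matrix(params: SubstitutionParams) -> RateMatrix:
    """Rate matrix over the 16 phased genotypes.

    Off-diagonal entries are r(changed allele pair) * pi_Y when genotypes
    X, Y differ at exactly one allele, and 0 when both alleles differ.
    """
    if params.n_states != 16:
        raise ValueError("GT16 needs 16 genotype frequencies")
    rates = params.full_exchangeabilities
    pi = params.frequencies
    Q = np.zeros((16, 16))
    for x in range(16):
        xa = divmod(x, 4)
        for y in range(16):
            if x == y:
                continue
            Q[x, y] = _genotype_rate(xa, divmod(y, 4), rates) * pi[y]
    Qn, scaling = _normalize(Q, pi)
    return RateMatrix(Qn, pi, scaling, reversible=True)


def build_gt10_rate_matrix(params: SubstitutionParams) -> RateMatrix:
    """Rate matrix over the 10 unphased genotypes.

    Treats every one-allele exchange (homozygote<->heterozygote in either
    direction, or heterozygote<->heterozygote sharing one allele) with the
    same nucleotide exchangeability, which keeps the model reversible.
    """
    if params.n_states != 10:
        raise ValueError("GT10 needs 10 genotype frequencies")
    rates = params.full_exchangeabilities
    pi = params.frequencies
    Q = np.zeros((10, 10))
    for x in range(10):
        xs = sorted(ab.unphased_alleles(x))
        for y in range(10):
            if x == y:
                continue
            ys = sorted(ab.unphased_alleles(y))
            rem_x = list(xs)
            rem_y = list(ys)
            for a in xs:
                if a in rem_y:
                    rem_y.remove(a)
                    rem_x.remove(a)
            if len(rem_x) == 1:  # exactly one allele differs
                Q[x, y] = rates[_PAIR_INDEX[frozenset(rem_x + rem_y)]] * pi[y]
    Qn, scaling = _normalize(Q, pi)
    return RateMatrix(Qn, pi, scaling, reversible=True)


def transition_probabilities(model: RateMatrix, t: float) -> np.ndarray:
    """Convenience wrapper: stochastic matrix P(t) = exp(Qt)."""
    return model.transition_matrix(t)


def build_gtnr_matrix(rates: np.ndarray) -> RateMatrix:
    """Non-reversible 4-state DNA rate matrix from 12 off-diagonal rates.

    ``rates`` are row-major off-diagonal entries in A,C,G,T order:
    (A>C, A>G, A>T, C>A, C>G, C>T, G>A, G>C, G>T, T>A, T>C, T>G).
    The matrix is normalized so the expected rate at its stationary
    distribution is 1.
    """
    rates = np.asarray(rates, dtype=float)
    if rates.shape != (12,):
        raise ValueError("expected 12 off-diagonal DNA rates")
    if np.any(rates < 0):
        raise ValueError("rates must be nonnegative")
    Q = np.zeros((4, 4))
    k = 0
    for i in range(4):
        for j in range(4):
            if i != j:
                Q[i, j] = rates[k]
                k += 1
    np.fill_diagonal(Q, -Q.sum(axis=1))
    pi = stationary_distribution(Q)
    scaling = -float(np.dot(pi, np.diag(Q)))
    return RateMatrix(Q / scaling, pi, scaling, reversible=False)


#: Relative single-nucleotide rates pooled from COSMIC signature 1
#: (rows/cols A,C,G,T), used by the simulator's finite-site model.
SIGNATURE1_GTNR_RATES = np.array(
    [0.03, 0.12, 0.04,   # A -> C,G,T
     0.11, 0.02, 0.68,   # C -> A,G,T
     6.68, 0.02, 0.11,   # G -> A,C,T
     0.04, 0.12, 0.13])  # T -> A,C,G


def stationary_distribution(Q: np.ndarray) -> np.ndarray:
    """Stationary distribution of a rate matrix (left null vector of Q)."""
    w, vl = scipy.linalg.eig(Q, left=True, right=False)
    i = int(np.argmin(np.abs(w)))
    pi = np.real(vl[:, i])
    pi = np.abs(pi)
    return pi / pi.sum()


@dataclass(frozen=True)
class ModelSpec:
    """Parsed model string, e.g. GT16+FO+E."""

    n_states: int
    frequency_mode: str  # optimized | empirical | equal
    error_model: bool

    @property
    def name(self) -> str:
        tag = {"optimized": "FO", "empirical": "FC", "equal": "FE"}[
            self.frequency_mode]
        s = f"GT{self.n_states}+{tag}"
        return s + "+E" if self.error_model else s


def parse_model_string(model: str) -> ModelSpec:
    """Parse model strings like "GT16+FO", "GT16+FO+E", "GT10+FO+E"."""
    parts = model.strip().upper().split("+")
    if parts[0] not in ("GT16", "GT10"):
        raise ValueError(f"unknown model {model!r} (expected GT16 or GT10)")
    n_states = 16 if parts[0] == "GT16" else 10
    freq_mode = "optimized"
    error_model = False
    for p in parts[1:]:
        if p == "FO":
            freq_mode = "optimized"
        elif p == "FC":
            freq_mode = "empirical"
        elif p == "FE":
            freq_mode = "equal"
        elif p == "E":
            error_model = True
        else:
            raise ValueError(f"unknown model modifier {p!r} in {model!r}")
    return ModelSpec(n_states, freq_mode, error_model)
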