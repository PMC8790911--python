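"""Diploid genotype state spaces and character encodings.

The phased alphabet contains the 16 ordered maternal|paternal genotypes
(A|A, A|C, ..., T|T); the unphased alphabet collapses the two phasings of
each heterozygote into a single state, leaving 10 states.  Unphased
genotypes travel in files as single IUPAC characters: A,C,G,T for the
homozygotes and the ambiguity letters M,R,W,S,Y,K for the six heterozygote
allele pairs.
"""

from __future__ import annotations

import itertools

import numpy as np

NUCLEOTIDES = "ACGT"

#: Ordered phased genotype states; index of (a,b) is 4*a + b.
PHASED_STATES: tuple[str, ...] = tuple(
    f"{a}|{b}" for a, b in itertools.product(NUCLEOTIDES, repeat=2)
)

#: Ordered unphased states: allele pairs (a,b) with a <= b.
UNPHASED_STATES: tuple[str, ...] = tuple(
    f"{NUCLEOTIDES[i]}/{NUCLEOTIDES[j]}"
    for i in range(4)
    for j in range(i, 4)
)

N_PHASED = 16
N_UNPHASED = 10

#: Single-character codes for unphased genotypes (IUPAC ambiguity letters
#: for heterozygotes).
CHAR_TO_UNPHASED: dict[str, str] = {
    "A": "A/A",
    "C": "C/C",
    "G": "G/G",
    "T": "T/T",
    "M": "A/C",
    "R": "A/G",
    "W": "A/T",
    "S": "C/G",
    "Y": "C/T",
    "K": "G/T",
}
UNPHASED_TO_CHAR: dict[str, str] = {v: k for k, v in CHAR_TO_UNPHASED.items()}

#: Characters accepted as a missing genotype; the first is canonical on output.
MISSING_CHARS = ("N", "?", "-")
MISSING_CODE = "N"

#: Integer index used for a missing genotype in encoded matrices.
MISSING_INDEX = N_UNPHASED

_PHASED_INDEX = {s: i for i, s in enumerate(PHASED_STATES)}
_UNPHASED_INDEX = {s: i for i, s in enumerate(UNPHASED_STATES)}


def phased_index(a: str, b: str) -> int:
    """Index of phased genotype a|b in the 16-state ordering."""
    return 4 * NUCLEOTIDES.index(a) + NUCLEOTIDES.index(b)


def phased_alleles(index: int) -> tuple[str, str]:
    """Maternal and paternal alleles of a phased state index."""
    return NUCLEOTIDES[index // 4], NUCLEOTIDES[index % 4]


def unphased_index(a: str, b: str) -> int:
    """Index of the unphased genotype {a,b} in the 10-state ordering."""
    a, b = sorted((a, b))
    return _UNPHASED_INDEX[f"{a}/{b}"]


def unphased_alleles(index: int) -> tuple[str, str]:
    state = UNPHASED_STATES[index]
    return state[0], state[2]


def _build_unphased_to_phased() -> tuple[tuple[int, ...], ...]:
    out = []
    for u in UNPHASED_STATES:
        a, b = u[0], u[2]
        if a == b:
            out.append((phased_index(a, b),))
        else:
            out.append((phased_index(a, b), phased_index(b, a)))
    return tuple(out)


#: For each unphased state, the (1 or 2) phased state indices realizing it.
UNPHASED_TO_PHASED: tuple[tuple[int, ...], ...] = _build_unphased_to_phased()

#: For each phased state, the unphased state index it collapses to.
PHASED_TO_UNPHASED: tuple[int, ...] = tuple(
    unphased_index(*phased_alleles(i)) for i in range(N_PHASED)
)


def encode_char(char: str) -> int:
    """Encode a genotype character to its unphased state index.

    Missing characters map to :data:`MISSING_INDEX`.  Lowercase input is
    accepted.  Raises ``ValueError`` for anything else.
    """
    c = char.upper()
    if c in MISSING_CHARS:
        return MISSING_INDEX
    try:
        return _UNPHASED_INDEX[CHAR_TO_UNPHASED[c]]
    except KeyError:
        raise ValueError(f"unknown genotype character {char!r}") from None


def decode_index(index: int) -> str:
    """Single-character code for an unphased state index (or missing)."""
    if index == MISSING_INDEX:
        return MISSING_CODE
    return UNPHASED_TO_CHAR[UNPHASED_STATES[index]]


def encode_string(s: str) -> np.ndarray:
    """Encode a genotype row string into an int8 vector of state indices."""
    return np.fromiter((encode_char(c) for c in s), dtype=np.int8, count=len(s))


def decode_row(row: np.ndarray) -> str:
    return "".join(decode_index(int(i)) for i in row)
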