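"""Canonical representation of the translation initiation site (TIS) sequence space.

A TIS context is an 11-base RNA string covering positions -6..-1 and +1..+5
around a start codon (there is no position 0; +1 is the A of AUG).  Positions
+1..+3 are fixed to AUG, the eight remaining positions are free, giving the
complete degenerate space NNNNNNAUGNN of 4**8 = 65,536 sequences.

Contexts are handled as plain Python strings throughout the package; this
module provides validation, alphabet normalization (DNA input is accepted and
converted to RNA), exhaustive enumeration in a deterministic lexicographic
order (A < C < G < U), upstream-AUG detection, and matching against the
high-efficiency motif RYMRMVAUGGC.

For vectorized work over the full space, sequences are represented by their
base-4 digit expansion: ``space_digits()`` returns a (65536, 8) array of base
indices (A=0, C=1, G=2, U=3) at the eight variable positions, where row ``r``
corresponds to the ``r``-th sequence of ``enumerate_tis_space()``.
"""

from __future__ import annotations

import itertools
from typing import Iterator

import numpy as np

BASES = "ACGU"
BASE_INDEX = {b: i for i, b in enumerate(BASES)}

TIS_LENGTH = 11
START_OFFSET = 6  # 0-based string offset of the A of the AUG start codon

#: The eight variable positions in field coordinates (+1 = A of AUG, no 0).
VARIABLE_POSITIONS = (-6, -5, -4, -3, -2, -1, 4, 5)

#: Field-coordinate position label -> 0-based string offset in the 11-mer.
POSITION_OFFSETS = {-6: 0, -5: 1, -4: 2, -3: 3, -2: 4, -1: 5,
                    1: 6, 2: 7, 3: 8, 4: 9, 5: 10}

SPACE_SIZE = 4 ** len(VARIABLE_POSITIONS)

#: The optimal-context reference sequence; efficiency 100 by definition.
REFERENCE_TIS = "GCCACCAUGGG"

#: High-efficiency motif RYMRMVAUGGC as per-position allowed-base sets
#: (R = A/G, Y = C/U, M = A/C, V = A/C/G).
HIGH_EFFICIENCY_MOTIF = {
    -6: "AG", -5: "CU", -4: "AC", -3: "AG", -2: "AC", -1: "ACG",
    4: "G", 5: "C",
}


class AlphabetError(ValueError):
    """A sequence contains a character outside {A,C,G,T,U} (either case)."""


class InvalidTISError(ValueError):
    """A sequence is not a valid 11-base TIS context with AUG at +1..+3."""


_NORMALIZE = str.maketrans("acgtuACGTU", "ACGUUACGUU")
_VALID_RAW = set("acgtuACGTU")


def normalize_alphabet(raw: str) -> str:
    """Uppercase a nucleotide string and convert DNA (T) to RNA (U).

    Raises :class:`AlphabetError` naming the first offending position if any
    character is outside {A,C,G,T,U,a,c,g,t,u}; raises on the empty string.
    """
    if not raw:
        raise AlphabetError("empty sequence")
    for i, ch in enumerate(raw):
        if ch not in _VALID_RAW:
            raise AlphabetError(
                f"invalid character {ch!r} at position {i} (0-based); "
                "expected A/C/G/T/U"
            )
    return raw.translate(_NORMALIZE)


def validate_tis(seq: str) -> str:
    """Normalize and validate an 11-base TIS context; return the RNA string.

    Raises :class:`InvalidTISError` on wrong length or a non-AUG start codon,
    and :class:`AlphabetError` on invalid characters.
    """
    seq = normalize_alphabet(seq)
    if len(seq) != TIS_LENGTH:
        raise InvalidTISError(
            f"TIS context must be {TIS_LENGTH} bases, got {len(seq)}: {seq!r}"
        )
    if seq[START_OFFSET:START_OFFSET + 3] != "AUG":
        raise InvalidTISError(
            f"positions +1..+3 must be AUG, got "
            f"{seq[START_OFFSET:START_OFFSET + 3]!r} in {seq!r}"
        )
    return seq


def is_valid_tis(seq: str) -> bool:
    """True iff ``seq`` validates as a TIS context (after normalization)."""
    try:
        validate_tis(seq)
    except (AlphabetError, InvalidTISError):
        return False
    return True


def enumerate_tis_space() -> Iterator[str]:
    """Yield all 65,536 TIS contexts in lexicographic order (A < C < G < U).

    The first element is AAAAAAAUGAA; AUG is fixed at +1..+3.
    """
    for combo in itertools.product(BASES, repeat=len(VARIABLE_POSITIONS)):
        yield "".join(combo[:6]) + "AUG" + combo[6] + combo[7]


_SPACE_SEQUENCES: list[str] | None = None


def space_sequences() -> list[str]:
    """The full enumeration as a cached list (order as enumerate_tis_space)."""
    global _SPACE_SEQUENCES
    if _SPACE_SEQUENCES is None:
        _SPACE_SEQUENCES = list(enumerate_tis_space())
    return _SPACE_SEQUENCES


def space_digits() -> np.ndarray:
    """(65536, 8) uint8 base indices at the variable positions, row r matching
    the r-th enumerated sequence.  Digit 0..3 encodes A,C,G,U."""
    ranks = np.arange(SPACE_SIZE, dtype=np.uint32)[:, None]
    shifts = 2 * np.arange(len(VARIABLE_POSITIONS) - 1, -1, -1, dtype=np.uint32)
    return ((ranks >> shifts) & 3).astype(np.uint8)


_BYTE_TO_DIGIT = np.full(256, 255, dtype=np.uint8)
for _b, _i in BASE_INDEX.items():
    _BYTE_TO_DIGIT[ord(_b)] = _i

_VARIABLE_OFFSETS = np.array(
    [POSITION_OFFSETS[p] for p in VARIABLE_POSITIONS], dtype=np.intp
)


def contexts_to_digits(contexts) -> np.ndarray:
    """Encode validated TIS contexts as an (n, 8) array of base indices.

    Assumes the sequences are normalized RNA 11-mers; use
    :func:`validate_tis` first for untrusted input.
    """
    seqs = list(contexts)
    if not seqs:
        return np.empty((0, len(VARIABLE_POSITIONS)), dtype=np.uint8)
    buf = np.frombuffer("".join(seqs).encode("ascii"), dtype=np.uint8)
    arr = buf.reshape(len(seqs), TIS_LENGTH)
    digits = _BYTE_TO_DIGIT[arr[:, _VARIABLE_OFFSETS]]
    if (digits == 255).any():
        bad = int(np.argwhere(digits == 255)[0, 0])
        raise AlphabetError(f"non-ACGU base in context {seqs[bad]!r}")
    return digits


def tis_rank(seq: str) -> int:
    """Index of a context in the lexicographic enumeration."""
    digits = contexts_to_digits([validate_tis(seq)])[0]
    rank = 0
    for d in digits:
        rank = rank * 4 + int(d)
    return rank


def has_upstream_aug(ctx: str) -> bool:
    """True iff AUG occurs entirely within the upstream positions -6..-1.

    Windows may start at -6, -5, -4 or -3; a window straddling -1/+1 is not an
    upstream AUG (and is impossible anyway, since +1 is fixed to A).
    """
    return "AUG" in ctx[:START_OFFSET]


def space_upstream_aug_mask() -> np.ndarray:
    """Boolean mask over the enumerated space: context has an upstream AUG."""
    d = space_digits()
    a, u, g = BASE_INDEX["A"], BASE_INDEX["U"], BASE_INDEX["G"]
    mask = np.zeros(SPACE_SIZE, dtype=bool)
    for w in range(4):  # window starts -6..-3 = digit columns 0..3
        mask |= (d[:, w] == a) & (d[:, w + 1] == u) & (d[:, w + 2] == g)
    return mask


def matches_high_efficiency_motif(ctx: str) -> bool:
    """True iff the context matches the high-efficiency motif RYMRMVAUGGC."""
    return all(
        ctx[POSITION_OFFSETS[pos]] in allowed
        for pos, allowed in HIGH_EFFICIENCY_MOTIF.items()
    )


def space_motif_mask() -> np.ndarray:
    """Boolean mask over the enumerated space: matches RYMRMVAUGGC."""
    d = space_digits()
    mask = np.ones(SPACE_SIZE, dtype=bool)
    for col, pos in enumerate(VARIABLE_POSITIONS):
        allowed = [BASE_INDEX[b] for b in HIGH_EFFICIENCY_MOTIF[pos]]
        mask &= np.isin(d[:, col], allowed)
    return mask
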