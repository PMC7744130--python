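"""2-bit DNA codec: packing, reverse complement, canonical form.

Bases map A=0, C=1, G=2, T=3, so ``complement(x) == 3 - x`` and, with the
leftmost base stored in the most significant position, the integer order of
packed words coincides with the lexicographic order of the sequences.  That
makes "numerically smaller" and "lexicographically smaller" interchangeable
everywhere downstream (canonical k-mers, sorted record lists).

Words are plain Python integers, so any length up to :data:`K_MAX` works;
the default dictionary configuration targets 31-mers.
"""

from __future__ import annotations

from dataclasses import dataclass
from enum import IntEnum

__all__ = [
    "K_MAX",
    "PackedSeq",
    "Strand",
    "encode",
    "decode",
    "revcomp",
    "canonical",
]

#: Largest supported word length in bases (a k-mer then spans two 64-bit words).
K_MAX = 63

_BASES = "ACGT"
_ACGT_SET = frozenset("ACGT")
_TO_DIGITS = str.maketrans("ACGT", "0123")


class Strand(IntEnum):
    """Orientation flag returned by :func:`canonical`."""

    FORWARD = 0
    REVERSE = 1


@dataclass(frozen=True, slots=True)
class PackedSeq:
    """A DNA word as a 2-bits-per-base integer plus an explicit base count.

    ``bits`` holds the leftmost base in the most significant 2-bit group,
    so ``PackedSeq(bits, length)`` compares like the ACGT string it encodes.
    """

    bits: int
    length: int

    def __post_init__(self) -> None:
        if self.length < 0:
            raise ValueError("length must be >= 0")
        if self.length > K_MAX:
            raise ValueError(f"length {self.length} exceeds K_MAX={K_MAX}")
        if not 0 <= self.bits < (1 << (2 * self.length)):
            raise ValueError(
                f"bits={self.bits} out of range for length={self.length}"
            )

    def __len__(self) -> int:
        return self.length

    def __str__(self) -> str:
        return decode(self)

    def code_at(self, i: int) -> int:
        """2-bit code of base ``i`` (0-based from the left)."""
        if not 0 <= i < self.length:
            raise IndexError(i)
        return (self.bits >> (2 * (self.length - 1 - i))) & 3

    def codes(self) -> tuple[int, ...]:
        """Per-base 2-bit codes, leftmost base first."""
        n, b = self.length, self.bits
        return tuple((b >> (2 * (n - 1 - i))) & 3 for i in range(n))

    def subseq(self, start: int, length: int) -> "PackedSeq":
        """The ``length``-base sub-word starting at ``start``."""
        if start < 0 or length < 0 or start + length > self.length:
            raise IndexError(f"subseq({start}, {length}) out of bounds")
        shift = 2 * (self.length - start - length)
        mask = (1 << (2 * length)) - 1
        return PackedSeq((self.bits >> shift) & mask, length)


def from_codes(codes) -> PackedSeq:
    """Assemble a :class:`PackedSeq` from an iterable of 2-bit codes."""
    bits = 0
    n = 0
    for c in codes:
        bits = (bits << 2) | (c & 3)
        n += 1
    return PackedSeq(bits, n)


def encode(seq: str) -> PackedSeq:
    """Pack an A/C/G/T string (case-insensitive) into a :class:`PackedSeq`.

    Raises ``ValueError`` naming the first offending position if any
    character outside ACGT is present.  Ambiguity codes are not encoded;
    callers split sequences on them first.
    """
    s = seq.upper()
    if not s:
        return PackedSeq(0, 0)
    if not set(s) <= _ACGT_SET:
        for i, c in enumerate(s):
            if c not in _ACGT_SET:
                raise ValueError(f"non-ACGT character {c!r} at position {i}")
    return PackedSeq(int(s.translate(_TO_DIGITS), 4), len(s))


def decode(p: PackedSeq) -> str:
    """Inverse of :func:`encode`."""
    n, b = p.length, p.bits
    return "".join(_BASES[(b >> (2 * (n - 1 - i))) & 3] for i in range(n))


def revcomp(p: PackedSeq) -> PackedSeq:
    """Reverse complement; base ``i`` of the result is ``3 - base(n-1-i)``."""
    n, b = p.length, p.bits
    out = 0
    for _ in range(n):
        out = (out << 2) | (3 - (b & 3))
        b >>= 2
    return PackedSeq(out, n)


def revcomp_bits(bits: int, length: int) -> int:
    """Reverse complement on raw bits (hot path; no object construction)."""
    out = 0
    for _ in range(length):
        out = (out << 2) | (3 - (bits & 3))
        bits >>= 2
    return out


def canonical(p: PackedSeq) -> tuple[PackedSeq, Strand]:
    """The numerically smaller of ``p`` and its reverse complement.

    Palindromes (only possible for even lengths) report ``Strand.FORWARD``.
    """
    rc = revcomp(p)
    if rc.bits < p.bits:
        return rc, Strand.REVERSE
    return p, Strand.FORWARD
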