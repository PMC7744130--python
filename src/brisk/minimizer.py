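"""Minimizer selection and partitioning of sequences into super-k-mers.

A minimizer scheme ``(k, m, ordering, seed)`` assigns every k-mer the
minimal canonical m-mer among its ``w = k - m + 1`` windows.  Consecutive
k-mers of a sequence that select the *same physical occurrence* of a
minimizer are grouped into one super-k-mer: a run of ``n`` k-mers spanning
``k + n - 1`` bases, ``1 <= n <= w``.

Minimizers are compared through their *canonical* m-mer so that a k-mer and
its reverse complement always agree on the minimizer value — the property
that makes the downstream dictionary strand-neutral.  Ties (the same
canonical m-mer occurring twice inside one k-mer) are broken by the
leftmost occurrence.

Two orderings are supported:

* ``HASHED`` (default): rank = an invertible 64-bit mixing hash of the
  canonical m-mer, keyed by ``seed``.  Invertibility means distinct m-mers
  never collide, and the ordering behaves like a random permutation, under
  which the expected super-k-mer size on i.i.d. sequence is ``(w + 1) / 2``
  k-mers — 8 at the default ``k=31, m=17``.
* ``LEXICOGRAPHIC``: rank = the canonical m-mer's packed value; handy for
  hand-checkable examples but heavily biased toward A-rich minimizers.

The per-sequence scan is vectorised with numpy for ``m <= 31`` (canonical
m-mer fits one uint64); a pure-Python scan covers larger m and doubles as
an independent reference in the tests.
"""

from __future__ import annotations

from dataclasses import dataclass
from enum import Enum

import numpy as np

from .codec import K_MAX, PackedSeq, canonical, encode, revcomp_bits

__all__ = [
    "Ordering",
    "MinimizerScheme",
    "SuperKmer",
    "order_value",
    "kmer_minimizer",
    "kmer_minimizer_offsets",
    "partition",
]

_MASK64 = (1 << 64) - 1
_GOLD = 0x9E3779B97F4A7C15
_MIX1 = 0xBF58476D1CE4E5B9
_MIX2 = 0x94D049BB133111EB


class Ordering(str, Enum):
    HASHED = "hashed"
    LEXICOGRAPHIC = "lexicographic"


@dataclass(frozen=True)
class MinimizerScheme:
    """Parameters defining how minimizers are chosen.

    ``m`` is the space/time dial: larger minimizers mean shorter
    super-k-mers and more, smaller buckets (faster lookups, more space per
    k-mer); smaller minimizers pack more k-mers per record.  The defaults
    ``k=31, m=17`` give ``w = 15`` and an expected 8 k-mers per
    super-k-mer on random sequence.
    """

    k: int = 31
    m: int = 17
    ordering: Ordering = Ordering.HASHED
    seed: int = 0

    def __post_init__(self) -> None:
        if not 1 <= self.m < self.k:
            raise ValueError(f"need 1 <= m < k, got k={self.k}, m={self.m}")
        if self.k > K_MAX:
            raise ValueError(f"k={self.k} exceeds K_MAX={K_MAX}")
        if self.seed < 0:
            raise ValueError("seed must be non-negative")
        object.__setattr__(self, "ordering", Ordering(self.ordering))

    @property
    def w(self) -> int:
        """Number of m-mer windows per k-mer."""
        return self.k - self.m + 1


@dataclass(frozen=True)
class SuperKmer:
    """A maximal run of consecutive k-mers sharing one minimizer occurrence."""

    seq: PackedSeq  # spans k + n - 1 bases
    n: int  # constituent k-mer count
    minimizer_value: PackedSeq  # canonical m-mer
    minimizer_offset: int  # 0-based start of the occurrence within seq

    def __post_init__(self) -> None:
        m = self.minimizer_value.length
        if self.n < 1 or self.seq.length - self.n + 1 <= m:
            raise ValueError("inconsistent super-k-mer geometry (need k > m, n >= 1)")
        if not 0 <= self.minimizer_offset <= self.seq.length - m:
            raise ValueError("minimizer offset out of range")

    @property
    def k(self) -> int:
        return self.seq.length - self.n + 1


# ---------------------------------------------------------------------------
# ordering


def _mix64(x: int, seed: int) -> int:
    """Invertible 64-bit finalizer (xor-shift / odd-multiply), keyed by seed."""
    x = (x ^ ((seed * _GOLD + _GOLD) & _MASK64)) & _MASK64
    x ^= x >> 30
    x = (x * _MIX1) & _MASK64
    x ^= x >> 27
    x = (x * _MIX2) & _MASK64
    x ^= x >> 31
    return x


def _mix64_np(x: np.ndarray, seed: int) -> np.ndarray:
    key = np.uint64((seed * _GOLD + _GOLD) & _MASK64)
    x = x ^ key
    x = x ^ (x >> np.uint64(30))
    x = x * np.uint64(_MIX1)
    x = x ^ (x >> np.uint64(27))
    x = x * np.uint64(_MIX2)
    x = x ^ (x >> np.uint64(31))
    return x


def order_value(mmer: PackedSeq, scheme: MinimizerScheme) -> int:
    """Rank of an m-mer under the scheme's ordering (smaller = more minimal).

    The rank is a function of the *canonical* m-mer, so an m-mer and its
    reverse complement always rank identically.
    """
    if mmer.length != scheme.m:
        raise ValueError(f"expected an {scheme.m}-mer, got length {mmer.length}")
    cbits = canonical(mmer)[0].bits
    if scheme.ordering is Ordering.LEXICOGRAPHIC:
        return cbits
    return _mix64(cbits, scheme.seed)


# ---------------------------------------------------------------------------
# per-k-mer selection (scalar; used for queries and as the scan reference)


def _rank_bits(cbits: int, scheme: MinimizerScheme) -> int:
    if scheme.ordering is Ordering.LEXICOGRAPHIC:
        return cbits
    return _mix64(cbits, scheme.seed)


def kmer_minimizer_offsets(
    kmer: PackedSeq, scheme: MinimizerScheme
) -> tuple[int, list[int], list[int]]:
    """All minimal-occurrence offsets of a k-mer.

    Returns ``(canonical_mmer_bits, offsets, fwd_bits_at_offsets)`` where
    ``offsets`` lists every window position achieving the minimal rank, in
    increasing order.  Under an invertible ordering all of them carry the
    same canonical m-mer.  Exposed because the dictionary must probe every
    minimal occurrence to stay strand- and tie-robust.
    """
    k, m, w = scheme.k, scheme.m, scheme.w
    if kmer.length != k:
        raise ValueError(f"expected a {k}-mer, got length {kmer.length}")
    bits = kmer.bits
    rc = revcomp_bits(bits, k)
    mmask = (1 << (2 * m)) - 1
    best_rank = None
    best_canon = 0
    offsets: list[int] = []
    fwds: list[int] = []
    for o in range(w):
        f = (bits >> (2 * (k - m - o))) & mmask
        # rc m-mer of window o == forward m-mer of the revcomp at window k-m-o
        r = (rc >> (2 * o)) & mmask
        c = f if f <= r else r
        rank = _rank_bits(c, scheme)
        if best_rank is None or rank < best_rank:
            best_rank = rank
            best_canon = c
            offsets = [o]
            fwds = [f]
        elif rank == best_rank:
            offsets.append(o)
            fwds.append(f)
    return best_canon, offsets, fwds


def kmer_minimizer(kmer: PackedSeq, scheme: MinimizerScheme) -> tuple[PackedSeq, int]:
    """The k-mer's minimizer: canonical m-mer value and leftmost offset."""
    cbits, offsets, _ = kmer_minimizer_offsets(kmer, scheme)
    return PackedSeq(cbits, scheme.m), offsets[0]


# ---------------------------------------------------------------------------
# sequence scan


@dataclass(frozen=True)
class _Scan:
    """Per-window minimizer assignment for one ACGT fragment.

    Arrays indexed by k-mer position j (``pos``, ``tie``) or by m-mer
    position i (``fwd``, ``canon``, ``pal``).
    """

    codes: np.ndarray  # uint8 per-base codes, length L
    pos: np.ndarray  # absolute minimizer position per k-mer
    tie: np.ndarray  # bool: >1 window of minimal rank in this k-mer
    fwd: np.ndarray  # forward m-mer value per position (uint64 / object)
    canon: np.ndarray  # canonical m-mer value per position
    pal: np.ndarray  # bool: m-mer at position is its own revcomp


_CODE_LUT = np.full(256, 255, dtype=np.uint8)
for _i, _b in enumerate(b"ACGT"):
    _CODE_LUT[_b] = _i


def _seq_codes(seq: str) -> np.ndarray:
    raw = np.frombuffer(seq.upper().encode("ascii"), dtype=np.uint8)
    codes = _CODE_LUT[raw]
    if (codes == 255).any():
        i = int(np.argmax(codes == 255))
        raise ValueError(f"non-ACGT character {seq[i]!r} at position {i}")
    return codes


def _scan_np(codes: np.ndarray, scheme: MinimizerScheme) -> _Scan:
    k, m, w = scheme.k, scheme.m, scheme.w
    L = len(codes)
    nmm = L - m + 1
    nk = L - k + 1
    b = codes.astype(np.uint64)
    fwd = np.zeros(nmm, dtype=np.uint64)
    rc = np.zeros(nmm, dtype=np.uint64)
    for j in range(m):
        fwd = (fwd << np.uint64(2)) | b[j : j + nmm]
        rc = rc | ((np.uint64(3) - b[j : j + nmm]) << np.uint64(2 * j))
    canon = np.minimum(fwd, rc)
    pal = fwd == rc
    if scheme.ordering is Ordering.LEXICOGRAPHIC:
        ranks = canon
    else:
        ranks = _mix64_np(canon, scheme.seed)
    win = np.lib.stride_tricks.sliding_window_view(ranks, w)[:nk]
    rel = win.argmin(axis=1)
    wmin = win[np.arange(nk), rel]
    tie = (win == wmin[:, None]).sum(axis=1) > 1
    pos = np.arange(nk, dtype=np.int64) + rel
    return _Scan(codes, pos, tie, fwd, canon, pal)


def _scan_py(codes: np.ndarray, scheme: MinimizerScheme) -> _Scan:
    """Reference scan with Python integers; works for any m <= k <= K_MAX."""
    k, m, w = scheme.k, scheme.m, scheme.w
    L = len(codes)
    nmm = L - m + 1
    nk = L - k + 1
    cl = [int(c) for c in codes]
    fwd = []
    rc = []
    v = 0
    r = 0
    mmask = (1 << (2 * m)) - 1
    for i, c in enumerate(cl):
        v = ((v << 2) | c) & mmask
        r = (r >> 2) | ((3 - c) << (2 * (m - 1)))
        if i >= m - 1:
            fwd.append(v)
            rc.append(r)
    canon = [min(f, q) for f, q in zip(fwd, rc)]
    ranks = [_rank_bits(c, scheme) for c in canon]
    pos = np.empty(nk, dtype=np.int64)
    tie = np.empty(nk, dtype=bool)
    for j in range(nk):
        window = ranks[j : j + w]
        best = min(window)
        first = window.index(best)
        pos[j] = j + first
        tie[j] = window.count(best) > 1
    to_arr = lambda xs: np.array(xs, dtype=object)
    pal = np.array([f == q for f, q in zip(fwd, rc)], dtype=bool)
    assert len(fwd) == nmm
    return _Scan(codes, pos, tie, to_arr(fwd), to_arr(canon), pal)


def _scan(seq: str, scheme: MinimizerScheme) -> _Scan:
    codes = _seq_codes(seq)
    if len(codes) < scheme.k:
        raise ValueError(f"sequence shorter than k={scheme.k}")
    if scheme.m <= 31:
        return _scan_np(codes, scheme)
    return _scan_py(codes, scheme)


def partition(seq: str, scheme: MinimizerScheme) -> list[SuperKmer]:
    """Split a sequence into its ordered super-k-mers.

    A new super-k-mer starts exactly where the selected minimizer
    occurrence (value *and* absolute position) of consecutive k-mers
    changes, so every super-k-mer holds one physical minimizer occurrence
    shared by all of its k-mers.  Sequences shorter than k yield an empty
    list; non-ACGT characters are rejected (split on ambiguity upstream).
    """
    if len(seq) < scheme.k:
        return []
    sc = _scan(seq, scheme)
    return _group(seq, sc, scheme)


def _group(seq: str, sc: _Scan, scheme: MinimizerScheme) -> list[SuperKmer]:
    k, m = scheme.k, scheme.m
    pos = sc.pos
    nk = len(pos)
    bounds = np.flatnonzero(pos[1:] != pos[:-1]) + 1
    starts = np.concatenate(([0], bounds, [nk]))
    out = []
    su = seq.upper()
    for a, bnd in zip(starts[:-1], starts[1:]):
        a = int(a)
        n = int(bnd) - a
        p = int(pos[a])
        sk = SuperKmer(
            seq=encode(su[a : a + n - 1 + k]),
            n=n,
            minimizer_value=PackedSeq(int(sc.canon[p]), m),
            minimizer_offset=p - a,
        )
        out.append(sk)
    return out
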