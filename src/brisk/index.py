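"""The exact dynamic k-mer dictionary.

Canonical k-mers are partitioned by their minimizer into buckets.  Each
bucket holds *compacted super-k-mer records*: the super-k-mer's bases minus
the ``m`` minimizer bases, packed at 2 bits per base, with one value slot
per constituent k-mer.  Records are kept sorted so membership is a binary
search plus a short verification scan; every answer is checked against the
actual base content, so the structure gives exact membership — no false
positives, no false negatives.

Record layout
-------------
A record stores a run of ``n`` consecutive k-mers sharing one minimizer
occurrence, oriented so that the occurrence reads as the canonical m-mer.
Only the ``prefix_len`` bases before and ``suffix_len`` bases after the
occurrence are kept (``prefix_len + suffix_len == n - 1 + k - m``).  The
sort key interleaves them outward from the minimizer: suffix bases first
(the base just after the occurrence most significant), then prefix bases
nearest-first.  A query k-mer splits at its own minimizer occurrence into
``(prefix_q, suffix_q)``; records whose key starts with ``suffix_q`` form a
contiguous range found by binary search, and the prefix side is verified
per record.  Runs longer than the word capacity ``W`` (so that
``2 * (prefix_len + suffix_len) > W``) are split greedily into maximal
fitting sub-runs; at the default ``k=31, m=17, W=64`` the worst case is
``2 * (w - 1 + k - m) = 56`` bits, so no record ever splits.

Dynamism comes from per-slot tombstones: deletion marks a slot dead, and a
bucket is rebuilt without dead slots once they outnumber the live ones.
"""

from __future__ import annotations

import struct
from bisect import bisect_left, insort
from dataclasses import dataclass, field
from operator import attrgetter
from typing import BinaryIO, Callable, Iterator

import numpy as np

from .codec import PackedSeq, canonical, decode, encode, from_codes, revcomp_bits
from .minimizer import (
    MinimizerScheme,
    SuperKmer,
    _scan,
    kmer_minimizer_offsets,
)

__all__ = [
    "ABSENT",
    "SuperKmerRecord",
    "Bucket",
    "BriskIndex",
    "IndexStats",
    "compact",
    "record_superkmer",
]

#: Sentinel for "k-mer not in the dictionary" (queries return this, i.e. None).
ABSENT = None

_VALUE_MAX = (1 << 64) - 1
_COUNTER_MAX = (1 << 32) - 1


def counter_combine(old: int | None) -> int:
    """Default value-merge rule: a saturating 32-bit occurrence counter."""
    if old is None:
        return 1
    return old + 1 if old < _COUNTER_MAX else _COUNTER_MAX


@dataclass(slots=True)
class SuperKmerRecord:
    """A compacted super-k-mer: its bases minus the minimizer occurrence.

    ``key`` holds the 2-bit codes in sort-key order (suffix bases outward
    from the minimizer, then prefix bases nearest-first); slot ``t`` is the
    k-mer starting ``t`` bases into the (orientation-normalized)
    super-k-mer, so a query at minimizer offset ``a`` maps to slot
    ``prefix_len - a``.
    """

    key: tuple[int, ...]
    prefix_len: int
    suffix_len: int
    n: int
    values: list[int]
    dead: list[bool]
    live: int

    @property
    def packed(self) -> int:
        """The key folded into one integer, first code most significant."""
        x = 0
        for c in self.key:
            x = (x << 2) | c
        return x

    @property
    def bits(self) -> int:
        """Packed payload width: 2 bits per non-minimizer base."""
        return 2 * (self.prefix_len + self.suffix_len)

    def full_codes(self, minimizer_codes: tuple[int, ...]) -> tuple[int, ...]:
        """Reconstruct the super-k-mer's per-base codes (prefix+minimizer+suffix)."""
        s = self.suffix_len
        return tuple(reversed(self.key[s:])) + minimizer_codes + self.key[:s]


class Bucket:
    """All records whose super-k-mers share one minimizer value, sorted by key."""

    __slots__ = ("records", "live", "dead")

    def __init__(self) -> None:
        self.records: list[SuperKmerRecord] = []
        self.live = 0
        self.dead = 0


@dataclass(frozen=True)
class IndexStats:
    distinct_kmers: int
    bucket_count: int
    mean_kmers_per_superkmer: float
    max_record_bits: int
    mean_bits_per_kmer: float

    def as_dict(self) -> dict:
        return {
            "distinct_kmers": self.distinct_kmers,
            "bucket_count": self.bucket_count,
            "mean_kmers_per_superkmer": self.mean_kmers_per_superkmer,
            "max_record_bits": self.max_record_bits,
            "mean_bits_per_kmer": self.mean_bits_per_kmer,
        }


_reckey = attrgetter("key")


def _build_records(
    codes: tuple[int, ...],
    p_full: int,
    k: int,
    m: int,
    t0: int,
    values: list[int],
    word_bits: int,
) -> list[SuperKmerRecord]:
    """Cut the slot run ``[t0, t0+len(values))`` of a normalized super-k-mer
    into records each fitting ``word_bits`` of packed payload."""
    n_max = word_bits // 2 - (k - m) + 1
    out = []
    i = 0
    nrun = len(values)
    while i < nrun:
        cn = min(n_max, nrun - i)
        t = t0 + i
        te = t + cn - 1
        prefix = codes[t:p_full]
        suffix = codes[p_full + m : te + k]
        rec = SuperKmerRecord(
            key=tuple(suffix) + tuple(reversed(prefix)),
            prefix_len=p_full - t,
            suffix_len=te + k - m - p_full,
            n=cn,
            values=list(values[i : i + cn]),
            dead=[False] * cn,
            live=cn,
        )
        out.append(rec)
        i += cn
    return out


def _normalize_superkmer(sk: SuperKmer) -> tuple[tuple[int, ...], int]:
    """Orient a super-k-mer so its minimizer occurrence reads canonical-forward.

    Returns the oriented per-base codes and the occurrence's prefix length.
    Palindromic occurrences keep the given orientation.
    """
    m = sk.minimizer_value.length
    occ = sk.seq.subseq(sk.minimizer_offset, m)
    codes = sk.seq.codes()
    if occ.bits == sk.minimizer_value.bits:
        return codes, sk.minimizer_offset
    if revcomp_bits(occ.bits, m) != sk.minimizer_value.bits:
        raise ValueError("minimizer occurrence does not match minimizer value")
    flipped = tuple(3 - c for c in reversed(codes))
    return flipped, sk.seq.length - sk.minimizer_offset - m


def compact(
    sk: SuperKmer, word_bits: int = 64, values: list[int] | None = None
) -> list[SuperKmerRecord]:
    """Compacted, minimizer-omitted record(s) for one super-k-mer.

    One record if ``2 * (len(sk) - m) <= word_bits``; otherwise the run is
    split greedily left-to-right into the minimum number of fitting
    sub-runs.  ``word_bits`` must accommodate at least a single k-mer.
    """
    k = sk.k
    m = sk.minimizer_value.length
    if word_bits < 2 * (k - m):
        raise ValueError(
            f"word_bits={word_bits} cannot hold one {k}-mer minus a {m}-mer "
            f"(needs {2 * (k - m)} bits)"
        )
    if values is None:
        values = [0] * sk.n
    if len(values) != sk.n:
        raise ValueError("one value per constituent k-mer required")
    codes, p_full = _normalize_superkmer(sk)
    return _build_records(codes, p_full, k, m, 0, values, word_bits)


def record_superkmer(rec: SuperKmerRecord, minimizer: PackedSeq, k: int) -> SuperKmer:
    """Decode a record back into the (normalized) super-k-mer it stores."""
    codes = rec.full_codes(minimizer.codes())
    return SuperKmer(
        seq=from_codes(codes),
        n=rec.n,
        minimizer_value=minimizer,
        minimizer_offset=rec.prefix_len,
    )


def _rolling_canonical(code_list: list[int], k: int) -> list[int]:
    """Canonical k-mer value at every window start (for in-run dedup)."""
    kmask = (1 << (2 * k)) - 1
    shift = 2 * (k - 1)
    f = r = 0
    out = []
    for i, c in enumerate(code_list):
        f = ((f << 2) | c) & kmask
        r = (r >> 2) | ((3 - c) << shift)
        if i >= k - 1:
            out.append(f if f <= r else r)
    return out


class BriskIndex:
    """Dynamic exact dictionary from canonical k-mers to unsigned values.

    Parameters
    ----------
    scheme:
        Minimizer scheme; defaults to ``k=31, m=17`` with hashed ordering.
    word_bits:
        Capacity of one record's packed payload.  Must hold at least a
        single k-mer (``2 * (k - m)`` bits).
    """

    def __init__(
        self, scheme: MinimizerScheme | None = None, word_bits: int = 64
    ) -> None:
        self.scheme = scheme if scheme is not None else MinimizerScheme()
        if word_bits < 2 * (self.scheme.k - self.scheme.m):
            raise ValueError(
                f"word_bits={word_bits} too small for k={self.scheme.k}, "
                f"m={self.scheme.m} (needs >= {2 * (self.scheme.k - self.scheme.m)})"
            )
        self.word_bits = word_bits
        self.buckets: dict[int, Bucket] = {}
        self.distinct_kmers = 0
        #: instrumentation: number of bucket lookups performed
        self.bucket_fetches = 0

    # -- k-mer plumbing ----------------------------------------------------

    def _as_kmer(self, kmer: str | PackedSeq) -> PackedSeq:
        p = encode(kmer) if isinstance(kmer, str) else kmer
        if p.length != self.scheme.k:
            raise ValueError(f"expected a {self.scheme.k}-mer, got length {p.length}")
        return p

    def _candidates(
        self, kmer: PackedSeq
    ) -> tuple[int, list[tuple[tuple[int, ...], int]]]:
        """Bucket key and the (oriented codes, minimizer offset) pairs to probe.

        Every minimal occurrence is probed, in each orientation in which it
        reads canonical-forward, so lookups are robust to rank ties and to
        palindromic minimizers regardless of which occurrence an earlier
        insertion stored the k-mer under.
        """
        m = self.scheme.m
        k = self.scheme.k
        cbits, offsets, fwds = kmer_minimizer_offsets(kmer, self.scheme)
        qc = kmer.codes()
        rcq: tuple[int, ...] | None = None
        cands: list[tuple[tuple[int, ...], int]] = []
        seen: set[tuple[tuple[int, ...], int]] = set()
        for o, f in zip(offsets, fwds):
            if f == cbits:
                c = (qc, o)
                if c not in seen:
                    seen.add(c)
                    cands.append(c)
            if revcomp_bits(f, m) == cbits:
                if rcq is None:
                    rcq = tuple(3 - c for c in reversed(qc))
                c = (rcq, k - m - o)
                if c not in seen:
                    seen.add(c)
                    cands.append(c)
        return cbits, cands

    def _find(
        self, bucket: Bucket, sq: tuple[int, ...], pr: tuple[int, ...]
    ) -> tuple[tuple[SuperKmerRecord, int] | None, tuple[SuperKmerRecord, int] | None]:
        """Locate the slot matching suffix ``sq`` / reversed-prefix ``pr``.

        Binary-searches the contiguous key range starting with ``sq`` and
        verifies the prefix side per candidate record.  Returns the first
        live hit and the first tombstoned hit (either may be None).
        """
        b = len(sq)
        a = len(pr)
        recs = bucket.records
        lo = bisect_left(recs, sq, key=_reckey)
        hi = bisect_left(recs, sq + (4,), key=_reckey, lo=lo)
        live = dead = None
        for i in range(lo, hi):
            rec = recs[i]
            s = rec.suffix_len
            if s < b or rec.prefix_len < a:
                continue
            if rec.key[s : s + a] != pr:
                continue
            t = rec.prefix_len - a
            if rec.dead[t]:
                if dead is None:
                    dead = (rec, t)
            else:
                live = (rec, t)
                break
        return live, dead

    def _search(self, bucket: Bucket, cands):
        dead_first = None
        m = self.scheme.m
        for codes, a in cands:
            sq = codes[a + m :]
            pr = codes[:a][::-1]
            live, dead = self._find(bucket, sq, pr)
            if live is not None:
                return live, dead_first if dead_first is not None else dead
            if dead is not None and dead_first is None:
                dead_first = dead
        return None, dead_first

    def _probe(self, kmer: PackedSeq):
        v, cands = self._candidates(kmer)
        self.bucket_fetches += 1
        bucket = self.buckets.get(v)
        if bucket is None:
            return v, cands, None, None
        live, dead = self._search(bucket, cands)
        return v, cands, live, dead

    # -- queries -----------------------------------------------------------

    def query(self, kmer: str | PackedSeq) -> int | None:
        """Value stored for the canonical form of ``kmer``, else :data:`ABSENT`.

        Answers are identical for a k-mer and its reverse complement, and a
        value is never returned for a k-mer that was not inserted.
        """
        _, _, live, _ = self._probe(self._as_kmer(kmer))
        if live is None:
            return ABSENT
        rec, t = live
        return rec.values[t]

    def __contains__(self, kmer: str | PackedSeq) -> bool:
        return self.query(kmer) is not ABSENT

    def query_batch(self, kmers) -> list[int | None]:
        """Element-wise :meth:`query`, visiting each bucket once per group.

        K-mers are grouped by minimizer value so that all queries sharing a
        minimizer resolve against a single bucket fetch (the cache-coherence
        pattern the partitioning is designed for).
        """
        prepared = []
        for i, km in enumerate(kmers):
            p = self._as_kmer(km)
            v, cands = self._candidates(p)
            prepared.append((v, i, cands))
        prepared.sort(key=lambda x: (x[0], x[1]))
        out: list[int | None] = [ABSENT] * len(prepared)
        cur_v = None
        bucket = None
        for v, i, cands in prepared:
            if v != cur_v:
                cur_v = v
                self.bucket_fetches += 1
                bucket = self.buckets.get(v)
            if bucket is None:
                continue
            live, _ = self._search(bucket, cands)
            if live is not None:
                rec, t = live
                out[i] = rec.values[t]
        return out

    # -- mutation ----------------------------------------------------------

    def _insert_run(
        self,
        v: int,
        codes: tuple[int, ...],
        p_full: int,
        t0: int,
        values: list[int],
    ) -> None:
        bucket = self.buckets.setdefault(v, Bucket())
        for rec in _build_records(
            codes, p_full, self.scheme.k, self.scheme.m, t0, values, self.word_bits
        ):
            insort(bucket.records, rec, key=_reckey)
        bucket.live += len(values)

    def _revive(self, v: int, hit: tuple[SuperKmerRecord, int], value: int) -> None:
        rec, t = hit
        rec.dead[t] = False
        rec.values[t] = value
        rec.live += 1
        bucket = self.buckets[v]
        bucket.live += 1
        bucket.dead -= 1
        self.distinct_kmers += 1

    def insert_sequence(
        self, seq: str, combine: Callable[[int | None], int] | None = None
    ) -> int:
        """Insert every k-mer of ``seq`` (canonical form); return the number
        of k-mers that were new to the dictionary.

        Absent k-mers get ``combine(None)`` as their initial value; present
        ones are updated to ``combine(old)``.  The default rule is a
        saturating occurrence counter.  Runs of consecutive new k-mers
        within one super-k-mer are stored as a single record.  Sequences
        shorter than k are a no-op; non-ACGT characters are rejected
        (split on ambiguity upstream).
        """
        if combine is None:
            combine = counter_combine
        scheme = self.scheme
        k, m = scheme.k, scheme.m
        su = seq.upper()
        if len(su) < k:
            return 0
        sc = _scan(su, scheme)
        code_list = sc.codes.tolist()
        can_k = _rolling_canonical(code_list, k)
        pos = sc.pos
        nk = len(pos)
        bounds = np.flatnonzero(pos[1:] != pos[:-1]) + 1
        starts = [0, *bounds.tolist(), nk]
        added = 0
        for gi in range(len(starts) - 1):
            s0, e0 = starts[gi], starts[gi + 1]
            n = e0 - s0
            p = int(pos[s0])
            v = int(sc.canon[p])
            fwd_v = int(sc.fwd[p])
            pal = bool(sc.pal[p])
            flipped = fwd_v != v
            span = code_list[s0 : s0 + n - 1 + k]
            skm = tuple(3 - c for c in reversed(span)) if flipped else tuple(span)
            p_seq = p - s0
            p_full = (k + n - 1) - (p_seq + m) if flipped else p_seq
            bucket = self.buckets.get(v)
            run_start: int | None = None
            run_vals: list[int] = []
            run_map: dict[int, int] = {}

            def flush() -> None:
                nonlocal run_start, run_vals, run_map, bucket
                if run_start is not None:
                    self._insert_run(v, skm, p_full, run_start, run_vals)
                    bucket = self.buckets[v]
                    run_start = None
                    run_vals = []
                    run_map = {}

            for t in range(n):
                s_t = s0 + (n - 1 - t if flipped else t)
                cank = can_k[s_t]
                if run_start is not None and cank in run_map:
                    # duplicate of a pending slot (e.g. an inverted repeat
                    # inside one super-k-mer): merge, close the run, and do
                    # not materialize this slot.
                    j = run_map[cank]
                    run_vals[j] = combine(run_vals[j])
                    flush()
                    continue
                if pal or bool(sc.tie[s_t]):
                    kmer = from_codes(skm[t : t + k])
                    _, cands = self._candidates(kmer)
                    live, dead = (
                        self._search(bucket, cands) if bucket else (None, None)
                    )
                else:
                    if bucket is not None:
                        sq = skm[p_full + m : t + k]
                        pr = skm[t:p_full][::-1]
                        live, dead = self._find(bucket, sq, pr)
                    else:
                        live = dead = None
                if live is not None:
                    rec, tt = live
                    rec.values[tt] = combine(rec.values[tt])
                    flush()
                elif dead is not None:
                    self._revive(v, dead, combine(None))
                    added += 1
                    flush()
                else:
                    if run_start is None:
                        run_start = t
                    run_map[cank] = len(run_vals)
                    run_vals.append(combine(None))
                    self.distinct_kmers += 1
                    added += 1
            flush()
        return added

    def set(self, kmer: str | PackedSeq, value: int) -> int | None:
        """Associate ``value`` with the canonical form of ``kmer``.

        Returns the previous value, or :data:`ABSENT` if the k-mer was new
        (a singleton record is then created).
        """
        if not 0 <= value <= _VALUE_MAX:
            raise ValueError("value must fit an unsigned 64-bit slot")
        p = self._as_kmer(kmer)
        v, cands, live, dead = self._probe(p)
        if live is not None:
            rec, t = live
            old = rec.values[t]
            rec.values[t] = value
            return old
        if dead is not None:
            self._revive(v, dead, value)
            return ABSENT
        codes, a = cands[0]
        self._insert_run(v, codes, a, 0, [value])
        self.distinct_kmers += 1
        return ABSENT

    def delete(self, kmer: str | PackedSeq) -> bool:
        """Remove the canonical form of ``kmer``; True if it was present.

        The slot is tombstoned; the bucket is rebuilt without dead slots
        once they outnumber the live ones.
        """
        p = self._as_kmer(kmer)
        v, _, live, _ = self._probe(p)
        if live is None:
            return False
        rec, t = live
        rec.dead[t] = True
        rec.live -= 1
        self.distinct_kmers -= 1
        bucket = self.buckets[v]
        bucket.live -= 1
        bucket.dead += 1
        if bucket.live == 0:
            del self.buckets[v]
        elif bucket.dead > bucket.live:
            self._rebuild_bucket(v)
        return True

    def _rebuild_bucket(self, v: int) -> None:
        old = self.buckets.pop(v)
        k, m = self.scheme.k, self.scheme.m
        mcodes = PackedSeq(v, m).codes()
        for rec in old.records:
            if rec.live == 0:
                continue
            full = rec.full_codes(mcodes)
            t = 0
            while t < rec.n:
                if rec.dead[t]:
                    t += 1
                    continue
                t1 = t
                while t1 + 1 < rec.n and not rec.dead[t1 + 1]:
                    t1 += 1
                self._insert_run(
                    v, full, rec.prefix_len, t, rec.values[t : t1 + 1]
                )
                t = t1 + 1

    # -- enumeration and reporting ------------------------------------------

    def items(self) -> Iterator[tuple[str, int]]:
        """Yield ``(canonical k-mer string, value)`` for every live slot.

        Buckets are visited in minimizer order and records in sort-key
        order, so the stream is deterministic.  Mutating the index during
        iteration is undefined.
        """
        k, m = self.scheme.k, self.scheme.m
        for v in sorted(self.buckets):
            mcodes = PackedSeq(v, m).codes()
            for rec in self.buckets[v].records:
                if rec.live == 0:
                    continue
                full = rec.full_codes(mcodes)
                for t in range(rec.n):
                    if rec.dead[t]:
                        continue
                    kmer = from_codes(full[t : t + k])
                    yield decode(canonical(kmer)[0]), rec.values[t]

    def __iter__(self) -> Iterator[tuple[str, int]]:
        return self.items()

    def __len__(self) -> int:
        return self.distinct_kmers

    def stats(self) -> IndexStats:
        """Occupancy summary: how many k-mers each record carries and how
        many bits each k-mer costs (sequence payload, live basis)."""
        live_records = 0
        live_bits = 0
        max_bits = 0
        for bucket in self.buckets.values():
            for rec in bucket.records:
                if rec.bits > max_bits:
                    max_bits = rec.bits
                if rec.live > 0:
                    live_records += 1
                    live_bits += rec.bits
        distinct = self.distinct_kmers
        return IndexStats(
            distinct_kmers=distinct,
            bucket_count=len(self.buckets),
            mean_kmers_per_superkmer=distinct / live_records if live_records else 0.0,
            max_record_bits=max_bits,
            mean_bits_per_kmer=live_bits / distinct if distinct else 0.0,
        )

    # -- serialization -------------------------------------------------------

    _MAGIC = b"BRISKIDX"
    _VERSION = 1

    def dump(self, path_or_file) -> None:
        """Write a versioned little-endian binary image of the index.

        Bucket and record order are canonical (minimizer, then sort key),
        so two equal indexes dump to byte-identical files.
        """
        close = False
        if hasattr(path_or_file, "write"):
            fh: BinaryIO = path_or_file
        else:
            fh = open(path_or_file, "wb")
            close = True
        try:
            s = self.scheme
            fh.write(self._MAGIC)
            fh.write(
                struct.pack(
                    "<HBBBQHQQ",
                    self._VERSION,
                    s.k,
                    s.m,
                    1 if s.ordering.value == "hashed" else 0,
                    s.seed,
                    self.word_bits,
                    self.distinct_kmers,
                    len(self.buckets),
                )
            )
            for v in sorted(self.buckets):
                bucket = self.buckets[v]
                fh.write(v.to_bytes(16, "little"))
                fh.write(struct.pack("<I", len(bucket.records)))
                for rec in bucket.records:
                    fh.write(struct.pack("<HHH", rec.prefix_len, rec.suffix_len, rec.n))
                    nbases = rec.prefix_len + rec.suffix_len
                    fh.write(rec.packed.to_bytes((2 * nbases + 7) // 8, "little"))
                    fh.write(struct.pack(f"<{rec.n}Q", *rec.values))
                    bitmap = 0
                    for t, d in enumerate(rec.dead):
                        if d:
                            bitmap |= 1 << t
                    fh.write(bitmap.to_bytes((rec.n + 7) // 8, "little"))
        finally:
            if close:
                fh.close()

    @classmethod
    def load(cls, path_or_file) -> "BriskIndex":
        """Read an index image written by :meth:`dump` (bit-exact round trip)."""
        close = False
        if hasattr(path_or_file, "read"):
            fh: BinaryIO = path_or_file
        else:
            fh = open(path_or_file, "rb")
            close = True
        try:
            magic = fh.read(8)
            if magic != cls._MAGIC:
                raise ValueError("not a BRISK index file")
            version, k, m, hashed, seed, word_bits, distinct, nbuckets = struct.unpack(
                "<HBBBQHQQ", fh.read(struct.calcsize("<HBBBQHQQ"))
            )
            if version != cls._VERSION:
                raise ValueError(f"unsupported index format version {version}")
            from .minimizer import Ordering

            scheme = MinimizerScheme(
                k=k,
                m=m,
                ordering=Ordering.HASHED if hashed else Ordering.LEXICOGRAPHIC,
                seed=seed,
            )
            idx = cls(scheme, word_bits=word_bits)
            total = 0
            for _ in range(nbuckets):
                v = int.from_bytes(fh.read(16), "little")
                (nrec,) = struct.unpack("<I", fh.read(4))
                bucket = Bucket()
                for _ in range(nrec):
                    p, sfx, n = struct.unpack("<HHH", fh.read(6))
                    nbases = p + sfx
                    packed = int.from_bytes(fh.read((2 * nbases + 7) // 8), "little")
                    values = list(struct.unpack(f"<{n}Q", fh.read(8 * n)))
                    bitmap = int.from_bytes(fh.read((n + 7) // 8), "little")
                    dead = [bool((bitmap >> t) & 1) for t in range(n)]
                    key = tuple(
                        (packed >> (2 * (nbases - 1 - i))) & 3 for i in range(nbases)
                    )
                    live = n - sum(dead)
                    rec = SuperKmerRecord(key, p, sfx, n, values, dead, live)
                    bucket.records.append(rec)
                    bucket.live += live
                    bucket.dead += n - live
                    total += live
                idx.buckets[v] = bucket
            if total != distinct:
                raise ValueError("corrupt index: live-slot count mismatch")
            idx.distinct_kmers = distinct
            return idx
        finally:
            if close:
                fh.close()
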