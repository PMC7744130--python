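"""The dictionary itself: compaction, exact membership, dynamism, serialization."""

import io
import random

import pytest

from brisk.codec import decode, encode
from brisk.index import (
    ABSENT,
    BriskIndex,
    compact,
    record_superkmer,
)
from brisk.minimizer import MinimizerScheme, Ordering, SuperKmer, partition
from brisk.selfcheck import oracle_trace
from brisk.synthetic import GenSpec, canonical_str, naive_kmer_dict, random_sequence, revcomp_str

LEX42 = MinimizerScheme(k=4, m=2, ordering=Ordering.LEXICOGRAPHIC)
LEX53 = MinimizerScheme(k=5, m=3, ordering=Ordering.LEXICOGRAPHIC)


# -- compaction -------------------------------------------------------------


def test_compact_default_geometry_single_record():
    # k=31, m=17, n=8: span 38 bases, minus the minimizer -> 21 bases = 42 bits
    scheme = MinimizerScheme(k=31, m=17, seed=0)
    seq = random_sequence(GenSpec(5000, 11))
    sks = [sk for sk in partition(seq, scheme) if sk.n == 8]
    assert sks, "a 1 in ~15 event over ~600 super-k-mers"
    recs = compact(sks[0], word_bits=64)
    assert len(recs) == 1
    assert recs[0].bits == 42


def test_compact_worst_case_fits_64_bits():
    scheme = MinimizerScheme(k=31, m=17, seed=0)
    # worst case n == w == 15 -> 28 non-minimizer bases = 56 bits
    seq = random_sequence(GenSpec(200_000, 3))
    sks = partition(seq, scheme)
    assert max(sk.n for sk in sks) == 15
    worst = max(sks, key=lambda sk: sk.n)
    recs = compact(worst, word_bits=64)
    assert len(recs) == 1 and recs[0].bits == 56


def test_compact_splits_oversized_runs_and_reconstructs():
    # k=4, m=2, n=3: 4 non-minimizer bases = 8 bits; W=6 forces a split
    sk = max(partition("TCGTTGA", LEX42), key=lambda s: s.n)
    assert sk.n == 3
    recs = compact(sk, word_bits=6)
    assert len(recs) >= 2
    # decoding the records reproduces the super-k-mer's k-mer runs exactly
    kmers = []
    for rec in recs:
        sub = record_superkmer(rec, sk.minimizer_value, k=4)
        s = str(sub.seq)
        kmers.extend(s[i : i + 4] for i in range(sub.n))
    s, off = str(sk.seq), sk.minimizer_offset
    occ = s[off : off + 2]
    flip = min(occ, revcomp_str(occ)) != occ
    if flip:
        s = revcomp_str(s)
    want = [s[i : i + 4] for i in range(sk.n)]
    assert kmers == want


def test_word_capacity_too_small_is_configuration_error():
    with pytest.raises(ValueError):
        BriskIndex(MinimizerScheme(k=31, m=17), word_bits=26)
    sk = partition("ACGTA", LEX53)[0]
    with pytest.raises(ValueError):
        compact(sk, word_bits=2)


# -- insertion and counting -------------------------------------------------


def test_insert_homopolymer_dedups_across_superkmers():
    idx = BriskIndex(LEX42)
    added = idx.insert_sequence("AAAAA")
    assert added == 1
    assert idx.distinct_kmers == 1
    assert idx.query("AAAA") == 2  # two occurrences, one slot


def test_double_insert_is_membership_idempotent(random_seq):
    idx = BriskIndex(MinimizerScheme(k=15, m=7, seed=4))
    seq = random_seq(10_000, seed=21)
    added1 = idx.insert_sequence(seq)
    counts1 = dict(idx.items())
    added2 = idx.insert_sequence(seq)
    assert added2 == 0
    assert idx.distinct_kmers == added1
    assert dict(idx.items()) == {k: 2 * v for k, v in counts1.items()}


def test_insert_revcomp_is_strand_neutral(random_seq):
    idx = BriskIndex(MinimizerScheme(k=15, m=7, seed=4))
    seq = random_seq(5_000, seed=22)
    idx.insert_sequence(seq)
    before = dict(idx.items())
    assert idx.insert_sequence(revcomp_str(seq)) == 0
    assert dict(idx.items()) == {k: 2 * v for k, v in before.items()}


def test_counts_match_naive_oracle(random_seq):
    for k, m in [(5, 3), (15, 7), (31, 17)]:
        idx = BriskIndex(MinimizerScheme(k=k, m=m, seed=8))
        seqs = [random_seq(3000, seed=100 + k + i) for i in range(3)]
        for s in seqs:
            idx.insert_sequence(s)
        assert dict(idx.items()) == naive_kmer_dict(seqs, k)


def test_insert_too_short_sequence_is_noop():
    idx = BriskIndex(LEX53)
    assert idx.insert_sequence("ACG") == 0
    assert idx.distinct_kmers == 0


# -- queries ----------------------------------------------------------------


def test_query_empty_index_absent():
    idx = BriskIndex(LEX53)
    assert idx.query("ACGTA") is ABSENT
    assert "ACGTA" not in idx


def test_query_reverse_complement_found():
    idx = BriskIndex(LEX53)
    idx.insert_sequence("ACGTAC")
    assert idx.query("GTACG") == 1  # revcomp of CGTAC
    assert idx.query("ACGTA") == 1


def test_query_wrong_length_rejected():
    idx = BriskIndex(LEX53)
    with pytest.raises(ValueError):
        idx.query("ACGTAC")


def test_queries_match_oracle_including_absent(random_seq):
    scheme = MinimizerScheme(k=15, m=7, seed=6)
    idx = BriskIndex(scheme)
    seq = random_seq(20_000, seed=50)
    idx.insert_sequence(seq)
    oracle = naive_kmer_dict(seq, 15)
    rng = random.Random(99)
    hits = misses = 0
    for _ in range(5000):
        if rng.random() < 0.5:
            i = rng.randrange(len(seq) - 14)
            q = seq[i : i + 15]
        else:
            q = "".join(rng.choice("ACGT") for _ in range(15))
        want = oracle.get(canonical_str(q))
        got = idx.query(q)
        assert got == want
        hits += got is not None
        misses += got is None
    assert hits and misses


def test_query_batch_equals_elementwise_and_is_bucket_coherent(random_seq):
    scheme = MinimizerScheme(k=31, m=17, seed=2)
    idx = BriskIndex(scheme)
    seq = random_seq(64, seed=123)
    idx.insert_sequence(seq)
    kmers = [seq[i : i + 31] for i in range(34)]
    single = [idx.query(q) for q in kmers]
    assert all(v == 1 for v in single)
    idx.bucket_fetches = 0
    batch = idx.query_batch(kmers)
    assert batch == single
    distinct_minimizers = {str(partitioned.minimizer_value) for partitioned in partition(seq, scheme)}
    assert idx.bucket_fetches <= len(distinct_minimizers)
    # order independence and empty batch
    shuffled = list(reversed(kmers))
    assert idx.query_batch(shuffled) == list(reversed(batch))
    assert idx.query_batch([]) == []


# -- set / delete -----------------------------------------------------------


def test_set_roundtrip_and_overwrite():
    idx = BriskIndex(LEX53)
    assert idx.set("ACGTA", 7) is ABSENT
    assert idx.query("ACGTA") == 7
    assert idx.query("TACGT") == 7  # revcomp
    assert idx.set("TACGT", 9) == 7
    assert idx.query("ACGTA") == 9
    assert idx.distinct_kmers == 1


def test_delete_absent_and_annihilation(random_seq):
    scheme = MinimizerScheme(k=15, m=7, seed=1)
    idx = BriskIndex(scheme)
    assert idx.delete("A" * 15) is False
    seq = random_seq(1200, seed=31)
    idx.insert_sequence(seq)
    kmers = {canonical_str(seq[i : i + 15]) for i in range(len(seq) - 14)}
    for km in kmers:
        assert idx.delete(km) is True
    assert idx.distinct_kmers == 0
    assert not idx.buckets
    for km in list(kmers)[:100]:
        assert idx.query(km) is ABSENT


def test_delete_then_reinsert_revives_slot():
    idx = BriskIndex(LEX53)
    idx.insert_sequence("ACGTAC")
    assert idx.delete("ACGTA")
    assert idx.query("ACGTA") is ABSENT
    assert idx.query("CGTAC") == 1  # neighbour slot untouched
    idx.insert_sequence("ACGTA")
    assert idx.query("ACGTA") == 1
    assert idx.distinct_kmers == 2


@pytest.mark.parametrize(
    "k,m,ordering",
    [
        (4, 2, Ordering.LEXICOGRAPHIC),  # palindromic minimizers possible
        (5, 3, Ordering.HASHED),
        (15, 7, Ordering.HASHED),
    ],
)
def test_randomized_trace_matches_map_oracle(k, m, ordering):
    report = oracle_trace(
        MinimizerScheme(k=k, m=m, ordering=ordering, seed=3), n_ops=4000, seed=k * 10 + m
    )
    assert report.passed, report.as_dict()


# -- iteration and stats ----------------------------------------------------


def test_iterate_conserves_occurrences_and_orders_buckets(random_seq):
    scheme = MinimizerScheme(k=15, m=7, seed=5)
    idx = BriskIndex(scheme)
    seq = random_seq(5000, seed=61)
    idx.insert_sequence(seq)
    items = list(idx.items())
    assert sum(v for _, v in items) == len(seq) - 14
    assert len(items) == idx.distinct_kmers
    assert len({k for k, _ in items}) == len(items)
    for bucket in idx.buckets.values():
        keys = [r.key for r in bucket.records]
        assert keys == sorted(keys)


def test_stats_empty_index_all_zero():
    st = BriskIndex(LEX53).stats()
    assert st.as_dict() == {
        "distinct_kmers": 0,
        "bucket_count": 0,
        "mean_kmers_per_superkmer": 0.0,
        "max_record_bits": 0,
        "mean_bits_per_kmer": 0.0,
    }


def test_stats_live_basis(random_seq):
    idx = BriskIndex(MinimizerScheme(k=31, m=17, seed=7))
    idx.insert_sequence(random_seq(20_000, seed=71))
    st = idx.stats()
    assert st.distinct_kmers == idx.distinct_kmers
    assert st.bucket_count == len(idx.buckets)
    assert st.max_record_bits <= 64
    assert 0 < st.mean_bits_per_kmer < 62  # beats one-word-per-k-mer storage
    assert st.mean_kmers_per_superkmer > 1


# -- serialization ----------------------------------------------------------


def test_dump_load_roundtrip_bit_exact(random_seq):
    idx = BriskIndex(MinimizerScheme(k=21, m=11, seed=9))
    idx.insert_sequence(random_seq(4000, seed=81))
    idx.delete(canonical_str(random_seq(4000, seed=81)[:21]))
    buf = io.BytesIO()
    idx.dump(buf)
    raw = buf.getvalue()
    loaded = BriskIndex.load(io.BytesIO(raw))
    buf2 = io.BytesIO()
    loaded.dump(buf2)
    assert buf2.getvalue() == raw
    assert dict(loaded.items()) == dict(idx.items())
    assert loaded.scheme == idx.scheme
    assert loaded.word_bits == idx.word_bits


def test_load_rejects_garbage():
    with pytest.raises(ValueError):
        BriskIndex.load(io.BytesIO(b"not an index"))
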