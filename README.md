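# brisk — an exact dynamic dictionary for DNA k-mers

`brisk` associates values (by default, occurrence counts) with DNA k-mers
**exactly** — no false positives, no false negatives — while supporting
insertion and deletion at any time. It is aimed at sequence-analysis
workloads that index large k-mer sets (counting, membership, annotation)
but cannot afford either the per-k-mer memory of a general hash table or
the rebuild cost of static indexes.

## The data structure

Three ideas, applied to canonical k-mers (each k-mer is identified with
the lexicographically smaller of itself and its reverse complement):

1. **Super-k-mers instead of k-mers.** A *minimizer* scheme `(k, m)`
   assigns every k-mer the minimal canonical m-mer among its
   `w = k − m + 1` windows, under a seeded, invertible hash ordering.
   Runs of consecutive k-mers sharing one minimizer occurrence — a
   *super-k-mer* of `n` k-mers spanning `k + n − 1` bases — are stored as
   one unit, so overlapping k-mers share their bases. On random sequence
   the expected run is `(w + 1)/2` k-mers: **8** at the default
   `k = 31, m = 17`.
2. **Minimizer-keyed buckets, kept sorted.** Super-k-mers are partitioned
   by minimizer value into small buckets; inside each bucket, records are
   sorted by a suffix-major key, so membership is a binary search plus a
   short verification scan, and a batch of queries sharing a minimizer
   touches one bucket.
3. **Minimizer-omitted packing.** A record stores only the bases before
   and after the minimizer occurrence (`n − 1 + k − m` bases at 2
   bits/base) — the `m` minimizer bases live once, in the bucket key. At
   the defaults the worst case (`n = w = 15`) is
   `2·(w − 1 + k − m) = 56` bits, so **every record fits one 64-bit
   word** alongside its per-k-mer value slots.

Deletion tombstones a slot; a bucket is rebuilt without dead slots once
they outnumber live ones. Every answer is verified against actual base
content, which is what makes the structure exact rather than probabilistic.

## Worked example

```python
from brisk import BriskIndex, GenSpec, MinimizerScheme, random_sequence
from brisk.synthetic import revcomp_str

seq = random_sequence(GenSpec(length=50_000, seed=42))
index = BriskIndex(MinimizerScheme())          # k=31, m=17, hashed ordering
index.insert_sequence(seq)

probe = seq[1000:1031]
index.query(probe)                # -> 1   (occurrence count)
index.query(revcomp_str(probe))   # -> 1   (strand-neutral: same slot)
index.query("A" * 31)             # -> None (ABSENT: never inserted)
index.stats().mean_kmers_per_superkmer   # -> 7.99
index.stats().max_record_bits            # -> 56
```

Running `python examples/count_and_query.py` prints exactly this session:

```
inserted 49970 k-mer windows, 49970 distinct canonical 31-mers
query(ACAAGCTCGCGG...)          -> 1  (seen once)
query(revcomp)               -> 1  (same slot)
query(AAAAAAAAAAAA...)          -> None  (never inserted)

49970 distinct k-mers in 6256 buckets; 7.99 k-mers per super-k-mer record,
5.26 sequence bits per k-mer (vs 62 bits for a standalone 31-mer)
```

The other scripts in `examples/` demonstrate the `m` space/time dial
(`density_tradeoff.py`) and exactness under mixed insert/set/delete
workloads (`dynamic_updates.py`).

## Command line

A thin CLI wraps the library for shell use:

```sh
brisk count reads.fastq.gz -o counts.tsv --index-out reads.brisk   # k-mer counting
brisk query reads.brisk kmers.txt                                  # batch lookup
brisk stats reads.brisk --json                                     # occupancy figures
brisk selfcheck --n-ops 20000 --seed 0                             # randomized self-test
```

`count` accepts FASTA/FASTQ (plain or gzip), splits sequences on
ambiguity codes so no k-mer spans an N, and writes a sorted,
byte-reproducible TSV. All commands honor `-k`, `-m`,
`--ordering {hashed,lex}`, `--seed` and `--word-bits`.

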