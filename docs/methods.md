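# Methods

## Model

`brisk` implements an associative dictionary over *canonical* k-mers: a
k-mer and its reverse complement are one key, identified with the
lexicographically (equivalently, under the 2-bit encoding, numerically)
smaller of the two. The structure is exact — membership answers are
verified against stored base content, never inferred from a hash — and
dynamic: insert, overwrite, delete and query may be interleaved freely.

### Encoding

Bases map `A=0, C=1, G=2, T=3`, leftmost base most significant. Two
consequences are load-bearing: `complement(x) = 3 − x` (complementation is
arithmetic), and integer order equals lexicographic order, so "sorted
record list" and "lexicographically minimal canonical form" coincide. `k`
is capped at 63 so any k-mer fits two machine words; the default
configuration targets 31-mers.

### Minimizers and super-k-mers

A scheme `(k, m, ordering, seed)` ranks the `w = k − m + 1` m-mers of each
k-mer and selects the minimal one. Ranks are computed on the *canonical*
m-mer, so a k-mer and its reverse complement always agree on the minimizer
value — the property that lets a strand-neutral dictionary partition by
minimizer at all. Ties are broken by leftmost occurrence.

The default ordering is a splitmix64-style finalizer (xor-shift and odd
multiplies) keyed by the seed. It is a bijection on 64-bit words, so
distinct m-mers never tie; the ordering behaves as a random permutation,
under which the expected number of k-mers per super-k-mer on i.i.d.
sequence is `(w + 1)/2`. A lexicographic ordering is retained for
hand-checkable examples; it is biased (A-rich minimizers win) and not used
by default. `m ≤ 31` runs through a vectorised numpy scan; larger `m`
falls back to a pure-Python scan that also serves as the reference
implementation in the tests.

A sequence is partitioned by grouping consecutive k-mers whose selected
minimizer matches in **value and absolute position**. Position matters:
two adjacent k-mers can select equal-valued but physically distinct
occurrences, and only the position rule guarantees each super-k-mer
contains one shared physical occurrence — which the record layout then
relies on. Known pathological case: homopolymers fragment into singleton
super-k-mers (the leftmost-tie-break position shifts every step);
correctness is unaffected.

### Records, buckets, and the sort key

A super-k-mer is stored oriented so its minimizer occurrence reads as the
canonical m-mer, and only its non-minimizer bases are kept:
`prefix_len + suffix_len = n − 1 + k − m` bases at 2 bits each, plus one
value slot per k-mer. The sort key lists suffix bases outward from the
minimizer, then prefix bases nearest-first. A query splits at its own
minimizer occurrence into `(prefix_q, suffix_q)`; all records whose key
starts with `suffix_q` form one contiguous range (binary search), and the
prefix side plus slot liveness is verified per record within the range.
The geometry is rigid: a query at minimizer offset `a` can only live at
slot `prefix_len − a`, so verification is one tuple comparison.

Runs whose packed payload exceeds the record word `W` (default 64 bits)
are split greedily left-to-right into maximal fitting sub-runs. At the
defaults this never happens: the worst case `n = w = 15` packs
`2·(15 − 1 + 14) = 56 ≤ 64` bits. `W < 2(k − m)` — too small for even one
k-mer — is rejected at construction.

### Why queries probe every minimal occurrence

The leftmost tie-break is not strand-symmetric: if a k-mer contains two
occurrences of its minimal canonical m-mer, the leftmost in one
orientation is the rightmost in the other, so the occurrence under which a
k-mer was stored depends on which strand inserted it. Queries therefore
enumerate *all* minimal-rank occurrences, each in every orientation in
which it reads canonical-forward (both, for palindromic m-mers, which
exist only for even `m`), and probe the bucket once per candidate. Under
the hashed ordering ties require a repeated m-mer within one k-mer, so the
candidate list is almost always a single entry; the enumeration is what
makes correctness unconditional rather than probabilistic.

An insertion-side twin of the same problem: within one pending run of new
k-mers, an inverted repeat can make two slots carry the same canonical
k-mer. A per-run map of canonical k-mer values catches this; the duplicate
is merged into its twin and the run is closed at that point, preserving
the one-live-slot-per-k-mer invariant.

### Dynamism

Values are unsigned integers; the default merge rule is a saturating
32-bit occurrence counter, and any 64-bit value can be stored via `set`.
Deletion tombstones a slot (the record keeps its shape); a bucket is
rebuilt without dead slots once dead slots outnumber live ones, keeping
mutation cost bounded by the bucket size. Re-inserting a tombstoned k-mer
revives its slot in place. Buckets whose last live slot is deleted are
removed outright.

### Serialization

`dump`/`load` write a versioned little-endian image (magic, format
version, `k`, `m`, ordering, seed, `W`, then per-bucket record arrays).
Bucket order (by minimizer value) and record order (by sort key) are
canonical, so equal indexes produce byte-identical files and
`dump → load → dump` round-trips exactly.

## Parameters

| parameter | default | meaning |
|---|---|---|
| `k` | 31 | k-mer length (≤ 63); odd k avoids palindromic k-mers |
| `m` | 17 | minimizer length; the space/time dial — larger m ⇒ shorter records, more buckets |
| `ordering` | hashed | minimizer ranking; `lex` only for toy examples |
| `seed` | 0 | keys the hash ordering; fixed seed ⇒ reproducible partitions |
| `word_bits` | 64 | packed payload capacity per record |

`k = 31, m = 17` makes `(w + 1)/2 = 8` and bounds records by 56 bits —
the configuration under which both headline figures (8 k-mers per record,
one 64-bit word per record) hold simultaneously.

## Synthetic data and what the tests show

Test substrates are i.i.d. uniform (optionally GC-skewed) random
sequences plus point-mutated copies, generated from fixed seeds, with
adversarial additions (homopolymers, short-period repeats, exact long
repeats) where capacity bounds are asserted. The density expectation
`(w+1)/2` is a random-sequence property; real genomes, with repeats and
skewed composition, fragment somewhat differently, so passing density
checks says nothing quantitative about non-random inputs — correctness
properties (exactness, strand invariance, conservation), by contrast, are
input-independent and are exercised on the adversarial cases too.
Generated fragments in the randomized traces are short (k to k+40 bases),
which stresses record-boundary handling harder than long reads would.

## Verification strategy

The correctness oracle is deliberately primitive: a Python dict keyed by
canonical k-mer *strings*, maintained by sliding-window code that shares
nothing with the packed implementation. Randomized traces
(insert/query/set/delete, ≥ 10⁵ operations across k ∈ {5, 15, 31})
compare every answer and then diff full contents; k = 4, m = 2 traces
specifically exercise palindromic minimizers. Problem sizes in the
routine checks — 1 Mb per seed for density, 10⁵ strand-paired queries
against a 100 kb index, 3 × 10⁴-op traces per k — were chosen as the
smallest sizes at which the sampling error of the measured quantities sits
well inside the asserted bounds.

## Known limitations

- Pure-Python hot paths: throughput is roughly 10⁶ k-mers/s on insertion —
  ample for its analysis-library role, not competitive with native
  k-mer counters.
- No concurrent mutation, no memory-mapped or on-disk operation.
- Ambiguity codes are handled by splitting, never indexed.
- `set`/`delete` address single k-mers; there is no bulk delete-by-sequence.
- The serialized format stores values at fixed 8-byte width regardless of
  their magnitude.
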