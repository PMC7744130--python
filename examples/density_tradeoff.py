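"""The minimizer-size dial: space per k-mer versus bucket granularity.

For fixed k=31, growing the minimizer length m shortens super-k-mers
(fewer k-mers share a minimizer) but spreads the index over more, smaller
buckets — faster lookups at a higher space cost.  At m=17 the expected
run is (w+1)/2 = 8 k-mers, and the widest possible record is 56 bits, so
every record fits one 64-bit word.
"""

from brisk import BriskIndex, GenSpec, MinimizerScheme, random_sequence

seq = random_sequence(GenSpec(length=200_000, seed=7))

print(f"{'m':>3} {'w':>3} {'kmers/record':>13} {'bits/kmer':>10} {'max bits':>9} {'buckets':>8}")
for m in (11, 13, 15, 17, 19, 21):
    scheme = MinimizerScheme(k=31, m=m)
    index = BriskIndex(scheme, word_bits=256 if m < 17 else 64)
    index.insert_sequence(seq)
    st = index.stats()
    print(
        f"{m:>3} {scheme.w:>3} {st.mean_kmers_per_superkmer:>13.2f} "
        f"{st.mean_bits_per_kmer:>10.2f} {st.max_record_bits:>9} {st.bucket_count:>8}"
    )

print(
    "\nSmaller m: longer records (fewer bits per k-mer, coarser buckets);\n"
    "larger m: shorter records (more space, finer partitioning). m < 17\n"
    "needs a wider record word because runs can exceed 64 bits."
)
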