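"""Count k-mers in a small synthetic genome, then look some up.

Builds a 50 kb random sequence, counts its canonical 31-mers into a
BriskIndex, and queries a few k-mers on both strands.  The printed counts
are occurrence counts; ABSENT means the k-mer (in either orientation) was
never seen.
"""

from brisk import BriskIndex, GenSpec, MinimizerScheme, random_sequence
from brisk.synthetic import revcomp_str

seq = random_sequence(GenSpec(length=50_000, seed=42))
index = BriskIndex(MinimizerScheme())  # k=31, m=17, hashed ordering

added = index.insert_sequence(seq)
print(f"inserted {len(seq) - 30} k-mer windows, {added} distinct canonical 31-mers")

probe = seq[1000:1031]
print(f"query({probe[:12]}...)          -> {index.query(probe)}  (seen once)")
print(f"query(revcomp)               -> {index.query(revcomp_str(probe))}  (same slot)")
absent = "A" * 31
print(f"query({absent[:12]}...)          -> {index.query(absent)}  (never inserted)")

stats = index.stats()
print(
    f"\n{stats.distinct_kmers} distinct k-mers in {stats.bucket_count} buckets; "
    f"{stats.mean_kmers_per_superkmer:.2f} k-mers per super-k-mer record, "
    f"{stats.mean_bits_per_kmer:.2f} sequence bits per k-mer "
    f"(vs 62 bits for a standalone 31-mer)"
)
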