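"""Insertion, overwrite and deletion — the dictionary stays exact throughout.

Drives a small index through updates while mirroring every operation in a
plain dict keyed by canonical k-mer strings, then diffs the two.  A zero
diff means no false positives, no false negatives and no stale values.
"""

from brisk import BriskIndex, GenSpec, MinimizerScheme, random_sequence
from brisk.synthetic import canonical_str

scheme = MinimizerScheme(k=15, m=7)
index = BriskIndex(scheme)
mirror: dict[str, int] = {}

seq = random_sequence(GenSpec(2_000, seed=11))
index.insert_sequence(seq)
for i in range(len(seq) - 14):
    c = canonical_str(seq[i : i + 15])
    mirror[c] = mirror.get(c, 0) + 1
print(f"counted {len(mirror)} distinct 15-mers")

marked = list(mirror)[::10]
for km in marked:
    index.set(km, 999_999)
    mirror[km] = 999_999
print(f"overwrote {len(marked)} values via set()")

dropped = list(mirror)[::3]
for km in dropped:
    assert index.delete(km)
    del mirror[km]
print(f"deleted {len(dropped)} k-mers (tombstoned, buckets compacted on demand)")

diff = {k for k in set(mirror) | {k for k, _ in index.items()}
        if mirror.get(k) != dict(index.items()).get(k)}
print(f"disagreements with the naive mirror: {len(diff)}")
print(f"distinct k-mers now indexed: {len(index)} (mirror: {len(mirror)})")
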