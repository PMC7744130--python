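"""Seeded sequence generators and brute-force oracles.

Everything here is a pure function of its seed, so tests and the
self-check are fully reproducible.  The oracles deliberately work at the
string level — plain sliding windows and ``min(s, revcomp(s))`` — sharing
no code with the packed codec or the minimizer machinery they check.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

__all__ = [
    "GenSpec",
    "random_sequence",
    "mutate",
    "naive_kmer_dict",
    "revcomp_str",
    "canonical_str",
]

_RC = str.maketrans("ACGT", "TGCA")


@dataclass(frozen=True)
class GenSpec:
    """Recipe for one random sequence: length, seed, target GC fraction."""

    length: int
    seed: int
    gc: float = 0.5

    def __post_init__(self) -> None:
        if self.length < 0:
            raise ValueError("length must be >= 0")
        if not 0.0 <= self.gc <= 1.0:
            raise ValueError("gc must lie in [0, 1]")


def random_sequence(spec: GenSpec) -> str:
    """I.i.d. random bases with ``P(G) + P(C) == gc``; deterministic per seed."""
    if spec.length == 0:
        return ""
    rng = np.random.default_rng(spec.seed)
    at = (1.0 - spec.gc) / 2.0
    gcp = spec.gc / 2.0
    alphabet = np.frombuffer(b"ACGT", dtype=np.uint8)
    draw = rng.choice(alphabet, size=spec.length, p=[at, gcp, gcp, at])
    return draw.tobytes().decode("ascii")


def mutate(seq: str, subst_rate: float, seed: int) -> str:
    """Substitute each base independently (to a different base) with the
    given probability.  Substitutions only — no indels."""
    if not 0.0 <= subst_rate <= 1.0:
        raise ValueError("subst_rate must lie in [0, 1]")
    if not seq:
        return seq
    rng = np.random.default_rng(seed)
    raw = np.frombuffer(seq.encode("ascii"), dtype=np.uint8).copy()
    hit = rng.random(len(raw)) < subst_rate
    idx = np.flatnonzero(hit)
    if idx.size:
        lut = {65: b"CGT", 67: b"AGT", 71: b"ACT", 84: b"ACG"}
        picks = rng.integers(0, 3, size=idx.size)
        for j, i in enumerate(idx):
            raw[i] = lut[int(raw[i])][int(picks[j])]
    return raw.tobytes().decode("ascii")


def revcomp_str(seq: str) -> str:
    """String-level reverse complement (oracle; independent of the codec)."""
    return seq.translate(_RC)[::-1]


def canonical_str(kmer: str) -> str:
    """Lexicographically smaller of a k-mer and its reverse complement."""
    rc = revcomp_str(kmer)
    return kmer if kmer <= rc else rc


def naive_kmer_dict(seqs, k: int) -> dict[str, int]:
    """Canonical k-mer counts by plain sliding window — the correctness
    oracle for the dictionary.  Windows containing non-ACGT are skipped.

    ``seqs`` is a string or an iterable of strings.
    """
    if k < 1:
        raise ValueError("k must be >= 1")
    if isinstance(seqs, str):
        seqs = [seqs]
    counts: dict[str, int] = {}
    acgt = frozenset("ACGT")
    for seq in seqs:
        s = seq.upper()
        for i in range(len(s) - k + 1):
            window = s[i : i + k]
            if not set(window) <= acgt:
                continue
            c = canonical_str(window)
            counts[c] = counts.get(c, 0) + 1
    return counts
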