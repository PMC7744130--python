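"""Randomized self-verification: oracle-equivalence traces and the
super-k-mer density experiment.

The trace machinery drives a :class:`~brisk.index.BriskIndex` and a plain
``dict`` keyed by canonical k-mer *strings* through the same randomized
operation stream and counts disagreements.  Because the oracle is pure
string manipulation, any bug in the packed representation, the minimizer
partitioning or the bucket search shows up as a mismatch.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .index import BriskIndex
from .minimizer import MinimizerScheme, partition
from .synthetic import GenSpec, canonical_str, random_sequence

__all__ = ["TraceReport", "oracle_trace", "superkmer_density", "run_selfcheck"]


@dataclass
class TraceReport:
    """Outcome of one randomized oracle-equivalence trace."""

    n_ops: int
    inserts: int = 0
    queries: int = 0
    sets: int = 0
    deletes: int = 0
    false_positives: int = 0  # index reported a value the oracle lacks
    false_negatives: int = 0  # index missed a value the oracle holds
    value_mismatches: int = 0
    final_mismatches: int = 0  # full-content diff after the trace

    @property
    def mismatches(self) -> int:
        return (
            self.false_positives
            + self.false_negatives
            + self.value_mismatches
            + self.final_mismatches
        )

    @property
    def passed(self) -> bool:
        return self.mismatches == 0

    def as_dict(self) -> dict:
        return {
            "n_ops": self.n_ops,
            "inserts": self.inserts,
            "queries": self.queries,
            "sets": self.sets,
            "deletes": self.deletes,
            "false_positives": self.false_positives,
            "false_negatives": self.false_negatives,
            "value_mismatches": self.value_mismatches,
            "final_mismatches": self.final_mismatches,
            "passed": self.passed,
        }


def _compare(report: TraceReport, got: int | None, want: int | None) -> None:
    if got is None and want is None:
        return
    if got is not None and want is None:
        report.false_positives += 1
    elif got is None and want is not None:
        report.false_negatives += 1
    elif got != want:
        report.value_mismatches += 1


def oracle_trace(
    scheme: MinimizerScheme,
    n_ops: int,
    seed: int,
    word_bits: int = 64,
    perturb: bool = False,
) -> TraceReport:
    """Run a randomized insert/query/set/delete trace against the string oracle.

    Each query/set/delete answer is compared on the spot; afterwards the
    full dictionary contents are diffed.  ``perturb`` injects one
    artificial disagreement to prove the harness can fail.
    """
    rng = np.random.default_rng(seed)
    idx = BriskIndex(scheme, word_bits=word_bits)
    oracle: dict[str, int] = {}
    pool: list[str] = []  # k-mers that have appeared, for targeted ops
    k = scheme.k
    report = TraceReport(n_ops=n_ops)

    def pick_kmer() -> str:
        if pool and rng.random() < 0.7:
            return pool[int(rng.integers(len(pool)))]
        return random_sequence(GenSpec(k, int(rng.integers(1 << 31))))

    for _ in range(n_ops):
        r = rng.random()
        if r < 0.35:
            frag = random_sequence(
                GenSpec(int(rng.integers(k, k + 40)), int(rng.integers(1 << 31)))
            )
            idx.insert_sequence(frag)
            for i in range(len(frag) - k + 1):
                c = canonical_str(frag[i : i + k])
                oracle[c] = oracle.get(c, 0) + 1
                pool.append(c)
            report.inserts += 1
        elif r < 0.65:
            q = pick_kmer()
            _compare(report, idx.query(q), oracle.get(canonical_str(q)))
            report.queries += 1
        elif r < 0.8:
            q = pick_kmer()
            val = int(rng.integers(1, 1 << 20))
            c = canonical_str(q)
            _compare(report, idx.set(q, val), oracle.get(c))
            oracle[c] = val
            pool.append(c)
            report.sets += 1
        else:
            q = pick_kmer()
            c = canonical_str(q)
            was = idx.delete(q)
            if was != (c in oracle):
                if was:
                    report.false_positives += 1
                else:
                    report.false_negatives += 1
            oracle.pop(c, None)
            report.deletes += 1

    final = dict(idx.items())
    if final != oracle:
        keys = set(final) | set(oracle)
        report.final_mismatches = sum(
            1 for key in keys if final.get(key) != oracle.get(key)
        )
    if len(idx) != len(oracle):
        report.final_mismatches += 1
    if perturb:
        report.value_mismatches += 1
    return report


def superkmer_density(
    length: int, seed: int, scheme: MinimizerScheme | None = None
) -> tuple[float, int]:
    """Mean k-mers per super-k-mer on an i.i.d. random sequence.

    Returns ``(mean, total_kmers)``.  Under a hashed (random-permutation)
    ordering the expectation is ``(w + 1) / 2`` — 8 at ``k=31, m=17``.
    """
    scheme = scheme if scheme is not None else MinimizerScheme()
    seq = random_sequence(GenSpec(length, seed))
    sks = partition(seq, scheme)
    total = sum(sk.n for sk in sks)
    return total / len(sks), total


def run_selfcheck(
    n_ops: int = 20000, seed: int = 0, perturb: bool = False
) -> dict:
    """Trace equivalence at small k plus the density experiment at defaults.

    Returns a JSON-serializable report with an overall ``passed`` flag.
    """
    trace_scheme = MinimizerScheme(k=15, m=7)
    trace = oracle_trace(trace_scheme, n_ops=n_ops, seed=seed, perturb=perturb)
    scheme = MinimizerScheme()
    mean, total = superkmer_density(200_000, seed=seed + 1, scheme=scheme)
    expected = (scheme.w + 1) / 2
    density_ok = abs(mean - expected) / expected <= 0.05
    report = {
        "trace": trace.as_dict(),
        "density": {
            "length": 200_000,
            "k": scheme.k,
            "m": scheme.m,
            "mean_kmers_per_superkmer": mean,
            "expected": expected,
            "within_5pct": density_ok,
        },
        "passed": trace.passed and density_ok,
    }
    return report
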