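"""Sequence readers and result writers.

FASTA/FASTQ parsing is delegated to Biopython; this layer adds gzip and
format auto-detection, uppercase normalization, ambiguity splitting (k-mers
never span a non-ACGT base) and the TSV count writer.  FASTQ qualities are
ignored: the dictionary is sequence-only.
"""

from __future__ import annotations

import gzip
import re
from dataclasses import dataclass
from pathlib import Path
from typing import Iterator

from Bio import SeqIO

__all__ = [
    "SeqRecordLite",
    "read_sequences",
    "split_on_ambiguity",
    "write_counts_tsv",
    "read_kmer_list",
]

_ACGT_RUN = re.compile(r"[ACGT]+")


@dataclass(frozen=True)
class SeqRecordLite:
    """A sequence record reduced to what the dictionary needs."""

    id: str
    seq: str  # uppercase; may still contain ambiguity codes


def _open_maybe_gzip(path):
    with open(path, "rb") as fh:
        magic = fh.read(2)
    if magic == b"\x1f\x8b":
        return gzip.open(path, "rt")
    return open(path, "rt")


def read_sequences(path, fmt: str = "auto") -> Iterator[SeqRecordLite]:
    """Stream records from a FASTA or FASTQ file, plain or gzip.

    ``fmt`` is ``auto`` (sniff '>' vs '@' from the first byte), ``fasta``
    or ``fastq``.  Multi-line FASTA and CRLF line endings are accepted.
    Malformed input raises ``ValueError`` naming the file.
    """
    path = Path(path)
    handle = _open_maybe_gzip(path)
    try:
        if fmt == "auto":
            first = handle.read(1)
            handle.seek(0)
            if first == ">":
                fmt = "fasta"
            elif first == "@":
                fmt = "fastq"
            elif first == "":
                return
            else:
                raise ValueError(
                    f"{path}: cannot detect format from leading character {first!r}"
                )
        if fmt not in ("fasta", "fastq"):
            raise ValueError(f"unknown format {fmt!r}")
        try:
            for rec in SeqIO.parse(handle, fmt):
                seq = str(rec.seq).upper()
                if not rec.id or not seq:
                    raise ValueError(f"{path}: empty id or sequence in record")
                yield SeqRecordLite(id=rec.id, seq=seq)
        except ValueError as exc:
            raise ValueError(f"{path}: malformed {fmt} input ({exc})") from exc
    finally:
        handle.close()


def split_on_ambiguity(seq: str) -> list[str]:
    """Maximal ACGT runs of ``seq`` (uppercased), in order.

    K-mers are only formed inside these fragments, so no k-mer ever spans
    an N or other ambiguity code.  Fragments shorter than k are skipped by
    the caller.
    """
    return _ACGT_RUN.findall(seq.upper())


def write_counts_tsv(pairs, path, sort: str = "kmer") -> None:
    """Write ``(kmer, value)`` pairs as a two-column TSV with header.

    ``sort="kmer"`` sorts lexicographically for reproducible, diffable
    output; ``sort="none"`` preserves stream order.
    """
    if sort not in ("kmer", "none"):
        raise ValueError(f"unknown sort mode {sort!r}")
    rows = list(pairs)
    if sort == "kmer":
        rows.sort(key=lambda kv: kv[0])
    with open(path, "w", newline="\n") as fh:
        fh.write("kmer\tcount\n")
        for kmer, value in rows:
            fh.write(f"{kmer}\t{value}\n")


def read_kmer_list(path) -> Iterator[tuple[int, str]]:
    """Yield ``(line_number, kmer)`` from a plain-text list.

    One k-mer per line; blank lines and ``#`` comments are skipped.
    """
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            text = line.strip()
            if not text or text.startswith("#"):
                continue
            yield lineno, text.upper()
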