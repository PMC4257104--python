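"""Read-level prefilters applied to FASTQ records before alignment.

Low-quality 3' read ends inflate mismatch counts and therefore fake editing
candidates, while low-complexity reads and long N stretches are prone to
misalignment.  This module provides the two prefilters used by the pipeline:

* a plain 3' suffix-trim at a phred cutoff (default 20), dropping reads that
  end up shorter than a minimum length (default 50 nt);
* a complexity filter that rejects reads containing a run of >= ``max_n_stretch``
  consecutive N's or whose mononucleotide Shannon entropy (over A/C/G/T,
  N's ignored) falls below ``min_entropy_bits``.

Both operate on plain :class:`ReadSeq` records and are exposed over FASTQ
(phred+33) via :func:`filter_fastq` and the ``edikit readqc`` subcommand.
"""

from __future__ import annotations

import gzip
import math
import re
from dataclasses import dataclass
from typing import IO, Iterator, Optional

__all__ = [
    "ReadSeq",
    "trim_3prime_by_quality",
    "fails_complexity_filter",
    "read_fastq",
    "write_fastq_record",
    "filter_fastq",
]

_N_RUN = re.compile(r"N+")


@dataclass(frozen=True)
class ReadSeq:
    """A sequencing read: identifier, bases over {A,C,G,T,N}, per-base phred scores."""

    read_id: str
    bases: str
    quals: tuple[int, ...]

    def __post_init__(self) -> None:
        if len(self.bases) != len(self.quals):
            raise ValueError(
                f"{self.read_id}: {len(self.bases)} bases but {len(self.quals)} quality scores"
            )
        if any(q < 0 or q > 60 for q in self.quals):
            raise ValueError(f"{self.read_id}: phred scores must lie in [0, 60]")

    def __len__(self) -> int:
        return len(self.bases)


def trim_3prime_by_quality(
    read: ReadSeq, phred_cutoff: int = 20, min_length: int = 50
) -> Optional[ReadSeq]:
    """Suffix-trim low-quality 3' bases; return the trimmed read or ``None`` (dropped).

    Trailing bases are removed while their quality is below ``phred_cutoff``.
    If the retained prefix is shorter than ``min_length`` the read is dropped.
    Idempotent: a trimmed read trims to itself.
    """
    keep = len(read)
    while keep > 0 and read.quals[keep - 1] < phred_cutoff:
        keep -= 1
    if keep < min_length:
        return None
    if keep == len(read):
        return read
    return ReadSeq(read.read_id, read.bases[:keep], read.quals[:keep])


def shannon_entropy_bits(bases: str) -> float:
    """Shannon entropy (bits) of the mononucleotide composition over A,C,G,T; N's ignored.

    A read with no informative bases (all N) has entropy 0.
    """
    total = 0
    counts = []
    for b in "ACGT":
        c = bases.count(b)
        counts.append(c)
        total += c
    if total == 0:
        return 0.0
    h = 0.0
    for c in counts:
        if c:
            p = c / total
            h -= p * math.log2(p)
    return h


def fails_complexity_filter(
    read: ReadSeq, max_n_stretch: int = 10, min_entropy_bits: float = 1.0
) -> bool:
    """True if the read has a run of >= ``max_n_stretch`` N's or entropy < ``min_entropy_bits``."""
    for m in _N_RUN.finditer(read.bases):
        if m.end() - m.start() >= max_n_stretch:
            return True
    return shannon_entropy_bits(read.bases) < min_entropy_bits


# ---------------------------------------------------------------------------
# FASTQ I/O (4-line records, phred+33)
# ---------------------------------------------------------------------------


def _open_text(path: str, mode: str = "rt") -> IO[str]:
    if path.endswith(".gz"):
        return gzip.open(path, mode)
    return open(path, mode)


def read_fastq(path: str) -> Iterator[ReadSeq]:
    """Stream ReadSeq records from a (possibly gzipped) phred+33 FASTQ file."""
    with _open_text(path) as fh:
        while True:
            header = fh.readline()
            if not header:
                return
            seq = fh.readline().strip()
            plus = fh.readline()
            qual = fh.readline().strip()
            if not qual and (seq or plus.strip() != "+"):
                raise ValueError(f"{path}: truncated FASTQ record at {header.strip()!r}")
            read_id = header.strip()[1:].split()[0] if header.strip() else ""
            yield ReadSeq(read_id, seq, tuple(ord(c) - 33 for c in qual))


def write_fastq_record(fh: IO[str], read: ReadSeq) -> None:
    fh.write(f"@{read.read_id}\n{read.bases}\n+\n")
    fh.write("".join(chr(q + 33) for q in read.quals) + "\n")


def filter_fastq(
    in_path: str,
    out_path: str,
    in2_path: Optional[str] = None,
    out2_path: Optional[str] = None,
    phred_cutoff: int = 20,
    min_length: int = 50,
    max_n_stretch: int = 10,
    min_entropy_bits: float = 1.0,
) -> dict[str, int]:
    """Apply the trim and complexity filters to a FASTQ file (optionally paired).

    For paired input both mates are dropped when either mate fails.  Returns
    counters: ``total`` read (pairs), ``kept``, ``dropped``.
    """

    def clean(read: ReadSeq) -> Optional[ReadSeq]:
        trimmed = trim_3prime_by_quality(read, phred_cutoff, min_length)
        if trimmed is None or fails_complexity_filter(trimmed, max_n_stretch, min_entropy_bits):
            return None
        return trimmed

    stats = {"total": 0, "kept": 0, "dropped": 0}
    if in2_path is None:
        with _open_text(out_path, "wt") as out:
            for read in read_fastq(in_path):
                stats["total"] += 1
                kept = clean(read)
                if kept is None:
                    stats["dropped"] += 1
                else:
                    stats["kept"] += 1
                    write_fastq_record(out, kept)
        return stats

    if out2_path is None:
        raise ValueError("paired input requires a second output path")
    with _open_text(out_path, "wt") as out1, _open_text(out2_path, "wt") as out2:
        for r1, r2 in zip(read_fastq(in_path), read_fastq(in2_path), strict=True):
            stats["total"] += 1
            k1, k2 = clean(r1), clean(r2)
            if k1 is None or k2 is None:
                stats["dropped"] += 1
            else:
                stats["kept"] += 1
                write_fastq_record(out1, k1)
                write_fastq_record(out2, k2)
    return stats
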