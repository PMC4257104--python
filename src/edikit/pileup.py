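"""Filtered per-position base counts from coordinate-sorted alignments.

Editing detection compares RNA and DNA evidence site by site, so everything
downstream rests on a pileup whose counts have already been cleaned of the
alignment records and base calls that are known artifact sources: duplicate
and non-unique reads, discordant pairs, low mapping quality, low base
quality, reads on an exclusion list (e.g. mismapping-prone reads collected
upstream), and double counting of overlapping mate pairs.

Counts are kept on the genome forward strand together with per-column
tallies of the inferred transcript strand of contributing reads, so a later
step can orient minus-strand columns (A-to-I editing on a minus-strand
transcript appears as T-to-C on the forward genome).

Coordinates are 0-based half-open internally; reported positions are
1-based.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Iterable, Mapping, Optional, Union

import pysam

__all__ = [
    "LIBRARY_TYPES",
    "FilterConfig",
    "AlignedRead",
    "PileupColumn",
    "read_passes_filters",
    "infer_read_transcript_strand",
    "build_pileup",
    "column_strand",
    "orient_counts",
    "load_excluded_ids",
]

BASES = "ACGT"
BASE_INDEX = {b: i for i, b in enumerate(BASES)}
COMPLEMENT = str.maketrans("ACGTN", "TGCAN")

FR_FIRSTSTRAND = "FR_FIRSTSTRAND"
FR_SECONDSTRAND = "FR_SECONDSTRAND"
UNSTRANDED = "UNSTRANDED"
LIBRARY_TYPES = (FR_FIRSTSTRAND, FR_SECONDSTRAND, UNSTRANDED)


@dataclass(frozen=True)
class FilterConfig:
    """Every threshold the editing caller applies.

    Defaults: base quality 25 and mapping quality 20 are configurable
    placeholders; DNA coverage 10 and homopolymer length 5 follow the
    published calling protocol.
    """

    min_base_quality: int = 25
    min_mapping_quality: int = 20
    min_rna_coverage: int = 10
    min_dna_coverage: int = 10
    min_variant_reads: int = 3
    min_variant_frequency: float = 0.10
    dna_max_alt_fraction: float = 0.05
    strand_confidence: float = 0.70
    homopolymer_min_len: int = 5
    splice_window: int = 4
    trim_read_ends: int = 0
    exclude_duplicates: bool = True
    require_proper_pair: bool = True
    require_unique: bool = True
    library_type: str = FR_FIRSTSTRAND
    # With an unstranded library, take the column strand from the region
    # annotation when it is unambiguous (set False to leave it '*').
    use_annotation_strand: bool = True

    def __post_init__(self) -> None:
        for name in ("min_variant_frequency", "dna_max_alt_fraction", "strand_confidence"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name} must lie in [0, 1], got {v}")
        for name in (
            "min_base_quality",
            "min_mapping_quality",
            "min_rna_coverage",
            "min_dna_coverage",
            "min_variant_reads",
            "splice_window",
            "trim_read_ends",
        ):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be >= 0")
        if self.homopolymer_min_len < 2:
            raise ValueError("homopolymer_min_len must be >= 2")
        if self.library_type not in LIBRARY_TYPES:
            raise ValueError(f"library_type must be one of {LIBRARY_TYPES}")

    def updated(self, **kwargs) -> "FilterConfig":
        return replace(self, **kwargs)


@dataclass(frozen=True)
class AlignedRead:
    """Alignment-record view carrying exactly the fields the filters consult."""

    read_id: str
    contig: str
    pos: int  # 0-based leftmost reference coordinate
    mapq: int
    is_duplicate: bool = False
    is_paired: bool = False
    is_proper_pair: bool = False
    is_reverse: bool = False
    is_first_in_pair: bool = False
    is_secondary: bool = False
    is_supplementary: bool = False

    @property
    def unique(self) -> bool:
        # No secondary/supplementary record; aligner hit-count tags are not consulted.
        return not (self.is_secondary or self.is_supplementary)

    @classmethod
    def from_pysam(cls, seg: pysam.AlignedSegment) -> "AlignedRead":
        return cls(
            read_id=seg.query_name or "",
            contig=seg.reference_name or "",
            pos=seg.reference_start,
            mapq=seg.mapping_quality,
            is_duplicate=seg.is_duplicate,
            is_paired=seg.is_paired,
            is_proper_pair=seg.is_proper_pair,
            is_reverse=seg.is_reverse,
            is_first_in_pair=seg.is_read1,
            is_secondary=seg.is_secondary,
            is_supplementary=seg.is_supplementary,
        )


@dataclass
class PileupColumn:
    """Filtered base evidence at one reference position (1-based ``pos``).

    ``counts`` are A,C,G,T tallies on the genome forward strand;
    ``plus_transcript_reads``/``minus_transcript_reads`` count contributing
    base observations from reads whose inferred transcript strand is +/-.
    """

    contig: str
    pos: int
    ref_base: str
    counts: tuple[int, int, int, int] = (0, 0, 0, 0)
    qual_sum: int = 0
    plus_transcript_reads: int = 0
    minus_transcript_reads: int = 0

    @property
    def depth(self) -> int:
        return sum(self.counts)

    @property
    def mean_quality(self) -> float:
        d = self.depth
        return self.qual_sum / d if d else 0.0


def read_passes_filters(
    read: AlignedRead, cfg: FilterConfig, excluded_ids: frozenset[str] = frozenset()
) -> bool:
    """Record-level veto: duplicates, discordant pairs, non-unique/low-MAPQ reads,
    secondary/supplementary records, and reads on the exclusion list."""
    if read.is_secondary or read.is_supplementary:
        return False
    if cfg.exclude_duplicates and read.is_duplicate:
        return False
    if cfg.require_proper_pair and read.is_paired and not read.is_proper_pair:
        return False
    if cfg.require_unique and not read.unique:
        return False
    if read.mapq < cfg.min_mapping_quality:
        return False
    if read.read_id in excluded_ids:
        return False
    return True


def infer_read_transcript_strand(read: AlignedRead, library_type: str) -> str:
    """Transcript strand ('+'/'-'/'unknown') encoded by a read's orientation flags.

    FR_FIRSTSTRAND (dUTP-style): the first mate is antisense to the
    transcript, so a reverse-mapped first mate means a plus-strand
    transcript. FR_SECONDSTRAND is the mirror. Unpaired reads follow the
    first-mate convention of the protocol.
    """
    if library_type == UNSTRANDED:
        return "unknown"
    first = read.is_first_in_pair or not read.is_paired
    if library_type == FR_FIRSTSTRAND:
        sense_reverse = first  # mate antisense => reverse flag means '+'
    elif library_type == FR_SECONDSTRAND:
        sense_reverse = not first
    else:
        raise ValueError(f"unknown library type {library_type!r}")
    if sense_reverse:
        return "+" if read.is_reverse else "-"
    return "-" if read.is_reverse else "+"


ReferenceLike = Union[pysam.FastaFile, Mapping[str, str]]


def fetch_reference(reference: ReferenceLike, contig: str, start: int, end: int) -> str:
    """Uppercase reference slice [start, end) from a FastaFile or contig->sequence mapping."""
    if isinstance(reference, Mapping):
        seq = reference[contig][start:end]
    else:
        seq = reference.fetch(contig, start, end)
    return seq.upper()


def build_pileup(
    alignment_source: Union[pysam.AlignmentFile, Iterable[pysam.AlignedSegment]],
    contig: str,
    start: int,
    end: int,
    cfg: FilterConfig,
    excluded_ids: frozenset[str] = frozenset(),
    reference: Optional[ReferenceLike] = None,
) -> list[PileupColumn]:
    """Per-position filtered base counts over [start, end) (0-based half-open).

    Only bases with phred >= ``min_base_quality`` from reads passing
    :func:`read_passes_filters` are counted; bases within ``trim_read_ends``
    of either read end, N calls, deletions, reference skips and insertions
    contribute nothing.  Where proper mates overlap, each reference position
    of the fragment is counted once, from the mate with the higher base
    quality.  Columns with zero counted bases are omitted.
    """
    if start >= end:
        raise ValueError(f"empty interval: start {start} >= end {end}")
    if isinstance(alignment_source, pysam.AlignmentFile):
        if contig not in alignment_source.references:
            raise ValueError(f"contig {contig!r} absent from alignment header")
        reads: Iterable[pysam.AlignedSegment] = alignment_source.fetch(contig, start, end)
    else:
        reads = alignment_source

    # (fragment name, refpos) -> (qual, base index, transcript strand); the
    # better-quality observation wins so overlapping mates count once.
    best: dict[tuple[str, int], tuple[int, int, str]] = {}
    for seg in reads:
        if seg.is_unmapped or seg.reference_name != contig:
            continue
        view = AlignedRead.from_pysam(seg)
        if not read_passes_filters(view, cfg, excluded_ids):
            continue
        strand = infer_read_transcript_strand(view, cfg.library_type)
        seq = seg.query_sequence
        quals = seg.query_qualities
        if seq is None or quals is None:
            continue
        qlen = len(seq)
        trim = cfg.trim_read_ends
        for qpos, rpos in seg.get_aligned_pairs(matches_only=True):
            if rpos < start or rpos >= end:
                continue
            if qpos < trim or qpos >= qlen - trim:
                continue
            base = seq[qpos]
            if base == "N" or base not in BASE_INDEX:
                continue
            q = quals[qpos]
            if q < cfg.min_base_quality:
                continue
            key = (view.read_id, rpos)
            prev = best.get(key)
            if prev is None or q > prev[0]:
                best[key] = (q, BASE_INDEX[base], strand)

    if not best:
        return []
    ref_seq = fetch_reference(reference, contig, start, end) if reference is not None else None
    columns: dict[int, PileupColumn] = {}
    for (_, rpos), (q, bidx, strand) in best.items():
        col = columns.get(rpos)
        if col is None:
            ref_base = ref_seq[rpos - start] if ref_seq is not None else "N"
            col = PileupColumn(contig=contig, pos=rpos + 1, ref_base=ref_base)
            columns[rpos] = col
        counts = list(col.counts)
        counts[bidx] += 1
        col.counts = tuple(counts)
        col.qual_sum += q
        if strand == "+":
            col.plus_transcript_reads += 1
        elif strand == "-":
            col.minus_transcript_reads += 1
    return [columns[rpos] for rpos in sorted(columns)]


def column_strand(col: PileupColumn, cfg: FilterConfig) -> str:
    """Majority transcript strand of a column, '*' when below ``strand_confidence``."""
    plus, minus = col.plus_transcript_reads, col.minus_transcript_reads
    total = plus + minus
    if total == 0:
        return "*"
    if plus / total >= cfg.strand_confidence:
        return "+"
    if minus / total >= cfg.strand_confidence:
        return "-"
    return "*"


def orient_counts(
    counts: tuple[int, int, int, int], strand: str, ref_base: str
) -> tuple[tuple[int, int, int, int], str]:
    """Rotate forward-strand A,C,G,T counts onto the transcript strand.

    '-' complements (A<->T, C<->G swap; ref base complemented); '+' and '*'
    are the identity.  Involution for '-'.
    """
    if strand != "-":
        return counts, ref_base
    return (counts[3], counts[2], counts[1], counts[0]), ref_base.translate(COMPLEMENT)


def load_excluded_ids(path: str) -> frozenset[str]:
    """Read an exclusion list: one read name per line, blanks ignored."""
    with open(path) as fh:
        return frozenset(line.strip() for line in fh if line.strip())
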