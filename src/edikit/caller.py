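"""Position-by-position comparison of RNA and DNA pileups into an editing table.

A candidate A-to-I site is an RNA position carrying a non-reference base that
the matched genome does not explain.  Each candidate must clear, in order:

1. RNA coverage (default >= 10 filtered reads);
2. DNA coverage (>= 10 filtered DNA reads) — no genomic evidence, no call;
3. DNA homozygosity for the reference (non-reference fraction <= 5% by
   default), which removes genomic SNPs and CNV-like artifacts;
4. variant support: at least ``min_variant_reads`` reads and an editing
   level alt/(ref+alt) of at least ``min_variant_frequency``;
5. sequence context: not inside a reference homopolymer run (>= 5 nt) nor in
   the intronic flank of an annotated splice site (default 4 nt);
6. absence from the known-SNP list (dbSNP-style positions).

Counts are oriented onto the inferred transcript strand first, so editing on
minus-strand transcripts is reported as A-to-G rather than T-to-C.  Sites
failing a filter keep a named rejection status instead of disappearing.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, replace
from typing import Iterable, Mapping, Optional, Sequence, Union

import pysam
from intervaltree import IntervalTree

from .annotator import TranscriptModel, parse_gtf
from .pileup import (
    BASES,
    UNSTRANDED,
    FilterConfig,
    PileupColumn,
    ReferenceLike,
    build_pileup,
    column_strand,
    fetch_reference,
    orient_counts,
)

__all__ = [
    "STATUSES",
    "SiteCall",
    "SpliceSiteIndex",
    "in_homopolymer",
    "near_splice_site",
    "call_site",
    "remove_known_snps",
    "call_regions",
    "load_snp_positions",
    "write_table",
    "TABLE_COLUMNS",
]

log = logging.getLogger("edikit")

PASS = "PASS"
LOW_RNA_COV = "LOW_RNA_COV"
LOW_DNA_COV = "LOW_DNA_COV"
DNA_NOT_HOMOZYGOUS = "DNA_NOT_HOMOZYGOUS"
TOO_FEW_VARIANT_READS = "TOO_FEW_VARIANT_READS"
LOW_FREQUENCY = "LOW_FREQUENCY"
HOMOPOLYMER = "HOMOPOLYMER"
SPLICE_PROXIMAL = "SPLICE_PROXIMAL"
KNOWN_SNP = "KNOWN_SNP"
STATUSES = (
    PASS,
    LOW_RNA_COV,
    LOW_DNA_COV,
    DNA_NOT_HOMOZYGOUS,
    TOO_FEW_VARIANT_READS,
    LOW_FREQUENCY,
    HOMOPOLYMER,
    SPLICE_PROXIMAL,
    KNOWN_SNP,
)

TABLE_COLUMNS = [
    "Region",
    "Position",
    "Reference",
    "Strand",
    "Coverage-q",
    "MeanQ",
    "BaseCount[A,C,G,T]",
    "AllSubs",
    "Frequency",
    "gCoverage-q",
    "gMeanQ",
    "gBaseCount[A,C,G,T]",
    "gAllSubs",
    "gFrequency",
    "Status",
]


@dataclass(frozen=True)
class SiteCall:
    """One candidate editing position; counts and reference are strand-oriented."""

    contig: str
    pos: int  # 1-based
    ref_base: str
    strand: str  # '+', '-', '*'
    rna_counts: tuple[int, int, int, int]
    rna_mean_q: float
    substitutions: tuple[str, ...]  # every observed ref->alt with >= 1 read, sorted
    sub_counts: Mapping[str, int]
    sub_freqs: Mapping[str, float]
    frequency: float  # headline: max frequency among qualifying (or observed) subs
    dna_counts: Optional[tuple[int, int, int, int]]
    dna_mean_q: float
    dna_frequency: float
    status: str
    qualifying: tuple[str, ...] = ()


class SpliceSiteIndex:
    """Intronic exclusion windows flanking annotated exon boundaries.

    For every intron of every transcript, the first and last ``window``
    intronic bases are indexed; exonic bases are never included.
    """

    def __init__(self, transcripts: Iterable[TranscriptModel], window: int = 4):
        self.window = window
        self._trees: dict[str, IntervalTree] = {}
        if window <= 0:
            return
        for t in transcripts:
            tree = self._trees.setdefault(t.contig, IntervalTree())
            for (_, left_end), (right_start, _) in zip(t.exons, t.exons[1:]):
                intron_len = right_start - left_end
                w = min(window, intron_len)
                if w <= 0:  # abutting exons define no intron
                    continue
                tree.addi(left_end, left_end + w)
                tree.addi(right_start - w, right_start)

    def __contains__(self, key: tuple[str, int]) -> bool:
        contig, pos = key
        tree = self._trees.get(contig)
        return bool(tree is not None and tree.at(pos - 1))


def in_homopolymer(
    reference: ReferenceLike, contig: str, pos: int, min_len: int = 5
) -> bool:
    """True iff the maximal run of identical reference bases through 1-based
    ``pos`` has length >= ``min_len``.  Run length is strand-symmetric."""
    if pos < 1:
        raise ValueError(f"position {pos} out of range")
    lo = max(0, pos - min_len)
    window = fetch_reference(reference, contig, lo, pos + min_len - 1)
    centre = pos - 1 - lo
    if centre >= len(window):
        raise ValueError(f"position {pos} out of range for contig {contig!r}")
    base = window[centre]
    run = 1
    i = centre - 1
    while i >= 0 and window[i] == base:
        run += 1
        i -= 1
    i = centre + 1
    while i < len(window) and window[i] == base:
        run += 1
        i += 1
    return run >= min_len


def near_splice_site(contig: str, pos: int, index: SpliceSiteIndex) -> bool:
    """True iff 1-based ``pos`` falls in an intronic splice-site flank."""
    return (contig, pos) in index


def call_site(
    rna_col: PileupColumn,
    dna_col: Optional[PileupColumn],
    ref_base: str,
    strand: str,
    cfg: FilterConfig,
) -> Optional[SiteCall]:
    """Apply coverage, genotype and variant-support filters at one position.

    Both columns must already be oriented onto ``strand`` (see
    :func:`edikit.pileup.orient_counts`); ``ref_base`` is the oriented
    reference base.  Returns None for a reference N (no call possible).
    """
    if ref_base not in BASES:
        return None
    rna_depth = sum(rna_col.counts)
    ref_idx = BASES.index(ref_base)
    ref_count = rna_col.counts[ref_idx]

    sub_counts: dict[str, int] = {}
    sub_freqs: dict[str, float] = {}
    for i, b in enumerate(BASES):
        if i == ref_idx:
            continue
        c = rna_col.counts[i]
        if c >= 1:
            sub = ref_base + b
            sub_counts[sub] = c
            sub_freqs[sub] = c / (ref_count + c)
    subs = tuple(sorted(sub_counts))
    qualifying = tuple(
        s
        for s in subs
        if sub_counts[s] >= cfg.min_variant_reads
        and sub_freqs[s] >= cfg.min_variant_frequency
    )

    dna_depth = sum(dna_col.counts) if dna_col is not None else 0
    dna_freq = 0.0
    if dna_col is not None and dna_depth > 0:
        dna_freq = (dna_depth - dna_col.counts[ref_idx]) / dna_depth

    if rna_depth < cfg.min_rna_coverage:
        status = LOW_RNA_COV
    elif dna_col is None or dna_depth < cfg.min_dna_coverage:
        status = LOW_DNA_COV
    elif dna_freq > cfg.dna_max_alt_fraction:
        status = DNA_NOT_HOMOZYGOUS
    elif not qualifying:
        if any(sub_counts[s] >= cfg.min_variant_reads for s in subs):
            status = LOW_FREQUENCY
        else:
            status = TOO_FEW_VARIANT_READS
    else:
        status = PASS

    headline = qualifying if status == PASS else subs
    frequency = max((sub_freqs[s] for s in headline), default=0.0)
    return SiteCall(
        contig=rna_col.contig,
        pos=rna_col.pos,
        ref_base=ref_base,
        strand=strand,
        rna_counts=rna_col.counts,
        rna_mean_q=rna_col.mean_quality,
        substitutions=subs,
        sub_counts=sub_counts,
        sub_freqs=sub_freqs,
        frequency=frequency,
        dna_counts=dna_col.counts if dna_col is not None else None,
        dna_mean_q=dna_col.mean_quality if dna_col is not None else 0.0,
        dna_frequency=dna_freq,
        status=status,
        qualifying=qualifying,
    )


def remove_known_snps(
    calls: Sequence[SiteCall], snp_positions: set[tuple[str, int]]
) -> list[SiteCall]:
    """Flag calls at known SNP positions (by position, regardless of allele)."""
    return [
        replace(c, status=KNOWN_SNP) if (c.contig, c.pos) in snp_positions else c
        for c in calls
    ]


def load_snp_positions(path: str) -> set[tuple[str, int]]:
    """Known-SNP positions, 1-based, from a VCF or a 2-column contig/pos TSV."""
    if path.endswith((".vcf", ".vcf.gz", ".bcf")):
        with pysam.VariantFile(path) as vf:
            return {(rec.chrom, rec.pos) for rec in vf}
    out = set()
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            if not line.strip() or line.startswith("#"):
                continue
            f = line.split()
            if len(f) < 2:
                raise ValueError(f"{path}:{lineno}: expected contig and position")
            out.add((f[0], int(f[1])))
    return out


RegionsLike = Union[str, Sequence[TranscriptModel], Sequence[tuple[str, int, int, str]]]


def _region_features(regions: RegionsLike) -> list[tuple[str, int, int, str]]:
    if isinstance(regions, str):
        return [
            (contig, s, e, strand)
            for contig, _src, _feat, s, e, strand, _attrs in parse_gtf(regions)
        ]
    out = []
    for r in regions:
        if isinstance(r, TranscriptModel):
            s, e = r.span
            out.append((r.contig, s, e, r.strand))
        else:
            out.append(tuple(r))
    return out


def _merge_intervals(feats: list[tuple[str, int, int, str]]) -> dict[str, list[tuple[int, int]]]:
    by_contig: dict[str, list[tuple[int, int]]] = {}
    for contig, s, e, _ in feats:
        by_contig.setdefault(contig, []).append((s, e))
    merged: dict[str, list[tuple[int, int]]] = {}
    for contig, ivs in by_contig.items():
        ivs.sort()
        acc = [list(ivs[0])]
        for s, e in ivs[1:]:
            if s <= acc[-1][1]:
                acc[-1][1] = max(acc[-1][1], e)
            else:
                acc.append([s, e])
        merged[contig] = [(s, e) for s, e in acc]
    return merged


def _annotation_strand(tree: Optional[IntervalTree], pos: int) -> str:
    if tree is None:
        return "*"
    strands = {iv.data for iv in tree.at(pos - 1)} & {"+", "-"}
    return strands.pop() if len(strands) == 1 else "*"


def call_regions(
    rna_bam: Union[str, pysam.AlignmentFile],
    dna_bam: Union[str, pysam.AlignmentFile, None],
    reference: Union[str, ReferenceLike],
    regions: RegionsLike,
    cfg: FilterConfig,
    snp_positions: Optional[set[tuple[str, int]]] = None,
    splice_index: Optional[SpliceSiteIndex] = None,
    excluded_ids: frozenset[str] = frozenset(),
) -> list[SiteCall]:
    """Run the full calling procedure over a set of genomic regions.

    Regions may be a GTF path, transcript models, or (contig, start0, end0,
    strand) tuples; overlapping regions are merged so every position is
    evaluated once.  Output is sorted by (contig, position) and contains one
    row per position with at least one observed non-reference RNA base.
    """
    own_rna = isinstance(rna_bam, str)
    own_dna = isinstance(dna_bam, str)
    own_ref = isinstance(reference, str)
    rna = pysam.AlignmentFile(rna_bam) if own_rna else rna_bam
    dna = pysam.AlignmentFile(dna_bam) if own_dna else dna_bam
    ref = pysam.FastaFile(reference) if own_ref else reference
    try:
        feats = _region_features(regions)
        merged = _merge_intervals(feats)
        strand_trees: dict[str, IntervalTree] = {}
        for contig, s, e, strand in feats:
            strand_trees.setdefault(contig, IntervalTree()).addi(s, e, strand)

        stranded = cfg.library_type != UNSTRANDED
        calls: list[SiteCall] = []
        for contig in sorted(merged):
            if contig not in rna.references:
                log.warning("region contig %s absent from RNA alignment header; skipped", contig)
                continue
            for start, end in merged[contig]:
                rna_cols = build_pileup(rna, contig, start, end, cfg, excluded_ids, ref)
                if not rna_cols:
                    continue
                dna_cols: dict[int, PileupColumn] = {}
                if dna is not None and contig in dna.references:
                    for col in build_pileup(dna, contig, start, end, cfg, excluded_ids, ref):
                        dna_cols[col.pos] = col
                for col in rna_cols:
                    if stranded:
                        strand = column_strand(col, cfg)
                    elif cfg.use_annotation_strand:
                        strand = _annotation_strand(strand_trees.get(contig), col.pos)
                    else:
                        strand = "*"
                    o_counts, o_ref = orient_counts(col.counts, strand, col.ref_base)
                    o_rna = PileupColumn(
                        contig=col.contig,
                        pos=col.pos,
                        ref_base=o_ref,
                        counts=o_counts,
                        qual_sum=col.qual_sum,
                        plus_transcript_reads=col.plus_transcript_reads,
                        minus_transcript_reads=col.minus_transcript_reads,
                    )
                    d = dna_cols.get(col.pos)
                    o_dna = None
                    if d is not None:
                        dc, _ = orient_counts(d.counts, strand, d.ref_base)
                        o_dna = PileupColumn(
                            contig=d.contig,
                            pos=d.pos,
                            ref_base=o_ref,
                            counts=dc,
                            qual_sum=d.qual_sum,
                        )
                    call = call_site(o_rna, o_dna, o_ref, strand, cfg)
                    if call is None or not call.substitutions:
                        continue
                    if call.status == PASS and in_homopolymer(
                        ref, contig, call.pos, cfg.homopolymer_min_len
                    ):
                        call = replace(call, status=HOMOPOLYMER)
                    if (
                        call.status == PASS
                        and splice_index is not None
                        and near_splice_site(contig, call.pos, splice_index)
                    ):
                        call = replace(call, status=SPLICE_PROXIMAL)
                    calls.append(call)
        if snp_positions:
            calls = remove_known_snps(calls, snp_positions)
        calls.sort(key=lambda c: (c.contig, c.pos))
        return calls
    finally:
        if own_rna:
            rna.close()
        if own_dna and dna is not None:
            dna.close()
        if own_ref:
            ref.close()


# ---------------------------------------------------------------------------
# Table output
# ---------------------------------------------------------------------------


def _fmt_counts(counts: Optional[tuple[int, int, int, int]]) -> str:
    if counts is None:
        return "-"
    return "[" + ", ".join(str(c) for c in counts) + "]"


def call_to_row(call: SiteCall) -> list[str]:
    dna_absent = call.dna_counts is None
    return [
        call.contig,
        str(call.pos),
        call.ref_base,
        call.strand,
        str(sum(call.rna_counts)),
        f"{call.rna_mean_q:.2f}",
        _fmt_counts(call.rna_counts),
        ",".join(call.substitutions) if call.substitutions else "-",
        f"{call.frequency:.2f}",
        "-" if dna_absent else str(sum(call.dna_counts)),
        "-" if dna_absent else f"{call.dna_mean_q:.2f}",
        _fmt_counts(call.dna_counts),
        "-" if dna_absent else _dna_subs(call),
        "-" if dna_absent else f"{call.dna_frequency:.2f}",
        call.status,
    ]


def _dna_subs(call: SiteCall) -> str:
    ref_idx = BASES.index(call.ref_base)
    subs = [
        call.ref_base + b
        for i, b in enumerate(BASES)
        if i != ref_idx and call.dna_counts[i] >= 1
    ]
    return ",".join(subs) if subs else "-"


def write_table(
    calls: Sequence[SiteCall], path: str, comments: Sequence[str] = ()
) -> None:
    """Write the editing table as TSV with '#'-prefixed provenance comments."""
    with open(path, "w") as fh:
        for line in comments:
            fh.write(f"# {line}\n")
        fh.write("\t".join(TABLE_COLUMNS) + "\n")
        for call in calls:
            fh.write("\t".join(call_to_row(call)) + "\n")
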