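"""Repeat, transcript, and gene-category context for called sites.

Most human A-to-I editing falls in Alu elements, so the first question about
any called site is its repeat context (ALU / repetitive non-Alu /
non-repetitive).  The second is its transcript context (exonic vs intronic
within each overlapping lncRNA transcript), and the third the category of
the host lncRNA gene relative to protein-coding genes: antisense,
intergenic, sense exonic, or sense non-exonic.

Interval lookups use per-contig interval trees; annotation of n sites
against m features is O((n+m) log m), never a quadratic scan.
"""

from __future__ import annotations

import re
from dataclasses import dataclass
from typing import Iterable, Optional

import pandas as pd
from intervaltree import IntervalTree

__all__ = [
    "RepeatFeature",
    "TranscriptModel",
    "GENE_CATEGORIES",
    "parse_gtf",
    "read_transcripts_gtf",
    "load_repeats",
    "RepeatIndex",
    "TranscriptIndex",
    "classify_repeat_context",
    "locate_in_transcripts",
    "classify_lncrna_gene",
    "annotate_table",
]

GENE_CATEGORIES = ("ANTISENSE", "INTERGENIC", "SENSE_EXONIC", "SENSE_NON_EXONIC")

ALU = "ALU"
REP_NON_ALU = "REP_NON_ALU"
NONREP = "NONREP"


@dataclass(frozen=True)
class RepeatFeature:
    """One repeat interval, 0-based half-open, with RepeatMasker-style naming."""

    contig: str
    start: int
    end: int
    repeat_name: str
    repeat_class: str = ""
    repeat_family: str = ""

    def __post_init__(self) -> None:
        if self.start >= self.end:
            raise ValueError(f"repeat {self.repeat_name}: start {self.start} >= end {self.end}")


@dataclass(frozen=True)
class TranscriptModel:
    """A transcript as an ordered set of disjoint exon intervals (0-based half-open)."""

    gene_id: str
    transcript_id: str
    contig: str
    strand: str
    exons: tuple[tuple[int, int], ...]
    biotype: str = "lncRNA"

    def __post_init__(self) -> None:
        prev_end = -1
        for s, e in self.exons:
            if s >= e or s < prev_end:
                raise ValueError(f"{self.transcript_id}: exons must be sorted and disjoint")
            prev_end = e

    @property
    def span(self) -> tuple[int, int]:
        return self.exons[0][0], self.exons[-1][1]

    def contains(self, pos0: int) -> bool:
        s, e = self.span
        return s <= pos0 < e

    def is_exonic(self, pos0: int) -> bool:
        return any(s <= pos0 < e for s, e in self.exons)


# ---------------------------------------------------------------------------
# Parsers
# ---------------------------------------------------------------------------

_ATTR = re.compile(r'(\w+)\s+"([^"]*)"')


def parse_gtf(path: str) -> Iterable[tuple[str, str, str, int, int, str, dict[str, str]]]:
    """Yield (contig, source, feature, start0, end0, strand, attributes) per GTF line.

    GTF coordinates are 1-based inclusive; they are converted to 0-based
    half-open here.  A malformed line raises ValueError naming its number.
    """
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            if not line.strip() or line.startswith("#"):
                continue
            fields = line.rstrip("\n").split("\t")
            if len(fields) < 9:
                raise ValueError(f"{path}:{lineno}: expected 9 tab-separated GTF fields")
            contig, source, feature, start, end, _score, strand, _frame, attrs = fields[:9]
            try:
                start0, end0 = int(start) - 1, int(end)
            except ValueError as exc:
                raise ValueError(f"{path}:{lineno}: non-integer coordinates") from exc
            if start0 < 0 or start0 >= end0:
                raise ValueError(f"{path}:{lineno}: invalid interval {start}-{end}")
            yield contig, source, feature, start0, end0, strand, dict(_ATTR.findall(attrs))


def read_transcripts_gtf(path: str, biotype: str = "lncRNA") -> list[TranscriptModel]:
    """Assemble TranscriptModels from the exon lines of a GTF file.

    Requires gene_id and transcript_id attributes on every exon line.
    """
    exons: dict[str, list[tuple[int, int]]] = {}
    meta: dict[str, tuple[str, str, str]] = {}
    for contig, _src, feature, s, e, strand, attrs in parse_gtf(path):
        if feature != "exon":
            continue
        try:
            gid, tid = attrs["gene_id"], attrs["transcript_id"]
        except KeyError as exc:
            raise ValueError(f"{path}: exon line missing required attribute {exc}") from exc
        exons.setdefault(tid, []).append((s, e))
        meta[tid] = (gid, contig, strand)
    out = []
    for tid, ivs in exons.items():
        gid, contig, strand = meta[tid]
        out.append(
            TranscriptModel(gid, tid, contig, strand, tuple(sorted(ivs)), biotype=biotype)
        )
    out.sort(key=lambda t: (t.contig, t.span, t.transcript_id))
    return out


def _parse_bed_name(name: str) -> tuple[str, str, str]:
    # "AluY#SINE/Alu" carries class/family after '#'; bare names leave them
    # equal to the name so substring matching still works.
    if "#" in name:
        rep_name, rest = name.split("#", 1)
        if "/" in rest:
            rep_class, rep_family = rest.split("/", 1)
        else:
            rep_class = rep_family = rest
        return rep_name, rep_class, rep_family
    return name, name, name


def load_repeats(path: str) -> list[RepeatFeature]:
    """Read repeat annotation from a UCSC rmsk dump or a BED file (auto-detected).

    rmsk dumps are tab tables with >= 15 columns (genoName/genoStart/genoEnd at
    columns 6-8 counting the leading bin field) and 0-based starts.  BED names
    may carry class/family as ``name#class/family``.
    """
    feats: list[RepeatFeature] = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            if not line.strip() or line.startswith(("#", "track", "browser")):
                continue
            f = line.rstrip("\n").split("\t")
            try:
                if len(f) >= 15:  # UCSC rmsk dump with leading bin column
                    contig, start, end = f[5], int(f[6]), int(f[7])
                    name, rclass, rfam = f[10], f[11], f[12]
                elif len(f) >= 3:
                    contig, start, end = f[0], int(f[1]), int(f[2])
                    name, rclass, rfam = _parse_bed_name(f[3]) if len(f) >= 4 else ("", "", "")
                else:
                    raise ValueError("too few columns")
            except ValueError as exc:
                raise ValueError(f"{path}:{lineno}: malformed repeat line ({exc})") from exc
            feats.append(RepeatFeature(contig, start, end, name, rclass, rfam))
    return feats


# ---------------------------------------------------------------------------
# Interval indexes and classification
# ---------------------------------------------------------------------------


class RepeatIndex:
    """Per-contig interval tree over repeat features."""

    def __init__(self, repeats: Iterable[RepeatFeature]):
        self._trees: dict[str, IntervalTree] = {}
        for r in repeats:
            self._trees.setdefault(r.contig, IntervalTree()).addi(r.start, r.end, r)

    def overlapping(self, contig: str, pos: int) -> list[RepeatFeature]:
        """Repeat features covering 1-based position ``pos``."""
        tree = self._trees.get(contig)
        if tree is None:
            return []
        return [iv.data for iv in tree.at(pos - 1)]


class TranscriptIndex:
    """Per-contig interval tree over transcript spans."""

    def __init__(self, transcripts: Iterable[TranscriptModel]):
        self.transcripts = list(transcripts)
        self._trees: dict[str, IntervalTree] = {}
        for t in self.transcripts:
            s, e = t.span
            self._trees.setdefault(t.contig, IntervalTree()).addi(s, e, t)

    def overlapping(self, contig: str, pos: int) -> list[TranscriptModel]:
        tree = self._trees.get(contig)
        if tree is None:
            return []
        hits = [iv.data for iv in tree.at(pos - 1)]
        hits.sort(key=lambda t: t.transcript_id)
        return hits


def classify_repeat_context(contig: str, pos: int, repeats: RepeatIndex) -> str:
    """ALU if any overlapping feature's family contains 'Alu', else REP_NON_ALU
    on any overlap, else NONREP.  ``pos`` is 1-based."""
    hits = repeats.overlapping(contig, pos)
    if any("Alu" in r.repeat_family for r in hits):
        return ALU
    return REP_NON_ALU if hits else NONREP


def locate_in_transcripts(
    contig: str, pos: int, transcripts: TranscriptIndex
) -> list[tuple[str, str]]:
    """(transcript_id, EXONIC|INTRONIC) for each transcript span containing 1-based ``pos``."""
    out = []
    for t in transcripts.overlapping(contig, pos):
        out.append((t.transcript_id, "EXONIC" if t.is_exonic(pos - 1) else "INTRONIC"))
    return out


def _gene_spans(transcripts: Iterable[TranscriptModel]) -> dict[str, tuple[str, str, int, int]]:
    """gene_id -> (contig, strand, span start, span end) over all its transcripts."""
    spans: dict[str, tuple[str, str, int, int]] = {}
    for t in transcripts:
        s, e = t.span
        cur = spans.get(t.gene_id)
        if cur is None:
            spans[t.gene_id] = (t.contig, t.strand, s, e)
        else:
            spans[t.gene_id] = (cur[0], cur[1], min(cur[2], s), max(cur[3], e))
    return spans


def classify_lncrna_gene(
    lnc_transcripts: Iterable[TranscriptModel],
    coding_transcripts: Iterable[TranscriptModel],
) -> str:
    """Category of one lncRNA gene relative to protein-coding genes.

    INTERGENIC: gene span overlaps no coding gene span.  Same-strand overlap
    beats antisense; within same-strand, touching any coding exon makes the
    gene SENSE_EXONIC, otherwise it sits wholly in coding introns and is
    SENSE_NON_EXONIC.
    """
    lnc = list(lnc_transcripts)
    if not lnc:
        raise ValueError("no transcripts supplied for the lncRNA gene")
    contig, strand = lnc[0].contig, lnc[0].strand
    start = min(t.span[0] for t in lnc)
    end = max(t.span[1] for t in lnc)

    coding = list(coding_transcripts)
    coding_spans = _gene_spans(coding)
    same_strand_hit = opposite_hit = exonic_hit = False
    overlapping_same_genes = set()
    for gid, (c_contig, c_strand, c_start, c_end) in coding_spans.items():
        if c_contig != contig or c_end <= start or c_start >= end:
            continue
        if c_strand == strand:
            same_strand_hit = True
            overlapping_same_genes.add(gid)
        else:
            opposite_hit = True
    if same_strand_hit:
        for t in coding:
            if t.gene_id not in overlapping_same_genes:
                continue
            if any(es < end and ee > start for es, ee in t.exons):
                exonic_hit = True
                break
        return "SENSE_EXONIC" if exonic_hit else "SENSE_NON_EXONIC"
    if opposite_hit:
        return "ANTISENSE"
    return "INTERGENIC"


def classify_all_genes(
    lnc_transcripts: Iterable[TranscriptModel],
    coding_transcripts: Iterable[TranscriptModel],
) -> dict[str, str]:
    """gene_id -> category for every lncRNA gene in the input."""
    coding = list(coding_transcripts)
    by_gene: dict[str, list[TranscriptModel]] = {}
    for t in lnc_transcripts:
        by_gene.setdefault(t.gene_id, []).append(t)
    return {gid: classify_lncrna_gene(txs, coding) for gid, txs in by_gene.items()}


# ---------------------------------------------------------------------------
# Table annotation
# ---------------------------------------------------------------------------


def annotate_table(
    table: pd.DataFrame,
    lnc_transcripts: list[TranscriptModel],
    coding_transcripts: list[TranscriptModel],
    repeats: Iterable[RepeatFeature],
) -> pd.DataFrame:
    """Add RepeatClass, TxContext, GeneIds and GeneCategory columns to a caller table.

    TxContext is EXONIC if the site is exonic in any overlapping lncRNA
    transcript, INTRONIC if it lies only in introns, '-' outside all
    transcripts.  A site inside several lncRNA genes lists all of them (and
    all their categories), comma separated.
    """
    repeat_index = RepeatIndex(repeats)
    tx_index = TranscriptIndex(lnc_transcripts)
    categories = classify_all_genes(lnc_transcripts, coding_transcripts)
    tid_to_gene = {t.transcript_id: t.gene_id for t in lnc_transcripts}

    rep_col, ctx_col, genes_col, cat_col = [], [], [], []
    for contig, pos in zip(table["Region"], table["Position"]):
        pos = int(pos)
        rep_col.append(classify_repeat_context(contig, pos, repeat_index))
        hits = locate_in_transcripts(contig, pos, tx_index)
        if not hits:
            ctx_col.append("-")
            genes_col.append("-")
            cat_col.append("-")
            continue
        ctx_col.append("EXONIC" if any(c == "EXONIC" for _, c in hits) else "INTRONIC")
        genes = sorted({tid_to_gene[tid] for tid, _ in hits})
        genes_col.append(",".join(genes))
        cat_col.append(",".join(sorted({categories[g] for g in genes})))
    out = table.copy()
    out["RepeatClass"] = rep_col
    out["TxContext"] = ctx_col
    out["GeneIds"] = genes_col
    out["GeneCategory"] = cat_col
    return out
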