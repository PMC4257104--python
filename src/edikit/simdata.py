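"""Synthetic editing scenes with planted ground truth.

Generates every input the pipeline consumes at toy scale — a random genome
with annotated repeat tracts, protein-coding and lncRNA gene models (one
lncRNA gene per requested category relative to the coding genes), stranded
RNA alignments carrying A-to-G edits planted at known levels, and DNA
alignments carrying planted het/hom SNPs — so recovery can be scored against
a recorded truth set without any external data.

Modelling choices that matter for interpretation:

* Reads are emitted already aligned (the generator writes alignment records
  directly); aligner behaviour is outside the model, and mismapping is
  represented only through the excluded-read-list pathway of the pileup.
* An edit is a property of a genomic position and strand: every fragment
  whose transcript strand matches carries the alternative base with
  probability ``planted_level``, independently per fragment (both mates of a
  pair agree, as they would for a single cDNA molecule).
* Edit positions are chosen at callable sites: reference A on the transcript
  strand, outside homopolymer runs and splice-site flanks, and free of
  antisense transcription so the planted level is identifiable from the
  pileup.  The context filters themselves are exercised by dedicated tests.
* Base-call errors are i.i.d. substitutions at ``base_error_rate``;
  qualities are constant at ``base_quality``, so quality-threshold behaviour
  stays analyzable.
"""

from __future__ import annotations

import json
import os
from dataclasses import asdict, dataclass, field
from typing import Optional

import numpy as np
import pysam

from .annotator import RepeatFeature, TranscriptModel, classify_repeat_context, RepeatIndex
from .caller import in_homopolymer
from .pileup import FR_FIRSTSTRAND, FR_SECONDSTRAND, UNSTRANDED, LIBRARY_TYPES

__all__ = [
    "SimConfig",
    "PlantedEdit",
    "PlantedSnp",
    "TruthSet",
    "Scene",
    "make_reference_and_annotations",
    "simulate_dna_reads",
    "simulate_rna_reads",
    "simulate_scene",
    "load_truth",
]

CONTIG = "chr1"
BASES = "ACGT"

# name, class, family, typical length
_ALU_REPEATS = [("AluSx", "SINE", "Alu", 300), ("AluY", "SINE", "Alu", 310), ("AluJb", "SINE", "Alu", 290)]
_NON_ALU_REPEATS = [
    ("L1PA7", "LINE", "L1", 600),
    ("L2a", "LINE", "L2", 450),
    ("MIRb", "SINE", "MIR", 200),
    ("MLT1K", "LTR", "ERVL-MaLR", 500),
]


@dataclass(frozen=True)
class SimConfig:
    """Scene parameters.

    Defaults describe the reference scene used throughout the test suite:
    a 1 Mb genome, 50 A-to-G sites at levels 0.1-0.9, 50x RNA over mature
    lncRNA transcripts, 30x DNA, 0.1% base-call error, paired 100 nt
    dUTP-stranded reads, 100 het + 50 hom-alt SNPs.
    """

    genome_length: int = 1_000_000
    n_repeats: int = 40
    alu_fraction: float = 0.6
    n_coding_genes: int = 8
    n_lnc_genes: int = 8
    # cycled over lncRNA genes in order
    lnc_category_mix: tuple[str, ...] = (
        "INTERGENIC",
        "ANTISENSE",
        "SENSE_EXONIC",
        "SENSE_NON_EXONIC",
    )
    rna_coverage: float = 50.0
    dna_coverage: float = 30.0
    read_length: int = 100
    paired: bool = True
    library_type: str = FR_FIRSTSTRAND
    base_error_rate: float = 0.001
    base_quality: int = 30
    n_edit_sites: int = 50
    edit_level_range: tuple[float, float] = (0.1, 0.9)
    n_het_snps: int = 100
    n_hom_snps: int = 50
    # fraction of unspliced pre-mRNA fragments, giving introns coverage
    premrna_fraction: float = 0.35
    # coding-gene expression relative to lncRNA expression
    coding_expression: float = 0.25
    seed: int = 0

    def __post_init__(self) -> None:
        if self.genome_length < 10 * self.read_length:
            raise ValueError("genome_length must be at least 10 x read_length")
        for name in ("alu_fraction", "base_error_rate", "premrna_fraction"):
            if not 0.0 <= getattr(self, name) <= 1.0:
                raise ValueError(f"{name} must lie in [0, 1]")
        lo, hi = self.edit_level_range
        if not (0.0 <= lo <= hi <= 1.0):
            raise ValueError("edit_level_range must satisfy 0 <= lo <= hi <= 1")
        if self.library_type not in LIBRARY_TYPES:
            raise ValueError(f"library_type must be one of {LIBRARY_TYPES}")
        bad = set(self.lnc_category_mix) - {
            "INTERGENIC",
            "ANTISENSE",
            "SENSE_EXONIC",
            "SENSE_NON_EXONIC",
        }
        if bad:
            raise ValueError(f"unknown lncRNA categories: {sorted(bad)}")


@dataclass
class PlantedEdit:
    contig: str
    pos: int  # 1-based
    strand: str
    planted_level: float
    gene_id: str
    tx_context: str  # EXONIC or INTRONIC in the host transcript
    repeat_context: str  # ALU / REP_NON_ALU / NONREP
    realized_alt_reads: int = 0
    realized_total: int = 0  # fragments contributing >= 1 base observation


@dataclass
class PlantedSnp:
    contig: str
    pos: int  # 1-based
    genotype: str  # "het" or "hom"
    ref: str
    alt: str


@dataclass
class TruthSet:
    edits: list[PlantedEdit] = field(default_factory=list)
    snps: list[PlantedSnp] = field(default_factory=list)
    gene_categories: dict[str, str] = field(default_factory=dict)

    def snp_positions(self) -> set[tuple[str, int]]:
        return {(s.contig, s.pos) for s in self.snps}


@dataclass
class Scene:
    """An in-memory scene plus, after writing, the paths of its files."""

    cfg: SimConfig
    genome: str
    repeats: list[RepeatFeature]
    coding_transcripts: list[TranscriptModel]
    lnc_transcripts: list[TranscriptModel]
    truth: TruthSet
    paths: dict[str, str] = field(default_factory=dict)


# ---------------------------------------------------------------------------
# Reference, annotations, planted positions
# ---------------------------------------------------------------------------


def _random_genome(rng: np.random.Generator, length: int) -> np.ndarray:
    return rng.integers(0, 4, size=length, dtype=np.int8)


def _codes_to_str(codes: np.ndarray) -> str:
    lut = np.frombuffer(b"ACGT", dtype=np.uint8)
    return lut[codes].tobytes().decode("ascii")


def _make_exons(
    rng: np.random.Generator, start: int, end: int, n_exons: int, big_intron: int = 0
) -> tuple[tuple[int, int], ...]:
    """n_exons disjoint exons of equal length inside [start, end), the first
    anchored at ``start`` and the last ending at ``end``.  When ``big_intron``
    is set the first intron is guaranteed at least that long."""
    span = end - start
    if n_exons == 1 or span < 4 * n_exons * 150:
        return ((start, end),)
    exon_len = max(150, min(500, span // (2 * n_exons)))
    n_introns = n_exons - 1
    min_intron = 200
    pool = span - n_exons * exon_len - n_introns * min_intron
    intron_lens = np.full(n_introns, min_intron)
    if big_intron and pool > big_intron:
        intron_lens[0] += big_intron
        pool -= big_intron
    if pool > 0:
        w = rng.random(n_introns) + 0.1
        extra = (w / w.sum() * pool).astype(int)
        intron_lens += extra
        intron_lens[-1] += pool - int(extra.sum())  # exact span closure
    # intron lengths sum exactly to span - n*exon_len, so the last exon ends at `end`
    exons = []
    cursor = start
    for i in range(n_exons):
        exons.append((cursor, cursor + exon_len))
        if i < n_introns:
            cursor += exon_len + int(intron_lens[i])
    return tuple(exons)


def _place_coding_genes(
    rng: np.random.Generator, cfg: SimConfig
) -> tuple[list[TranscriptModel], list[tuple[int, int]]]:
    """Coding genes along the genome; returns transcripts and the free gaps
    between consecutive genes (gaps[i] follows gene i)."""
    genes: list[TranscriptModel] = []
    gaps: list[tuple[int, int]] = []
    cursor = 4000
    per_gene = max(1, (cfg.genome_length - 8000) // max(cfg.n_coding_genes, 1))
    for i in range(cfg.n_coding_genes):
        span_len = int(rng.integers(14_000, 22_000))
        gap_len = max(14_000, per_gene - span_len)
        start = cursor
        end = min(start + span_len, cfg.genome_length - 4000)
        if end - start < 10_000:
            break
        strand = "+" if i % 2 == 0 else "-"
        # every coding gene gets one >= 8 kb intron so an intronic lncRNA fits
        exons = _make_exons(rng, start, end, int(rng.integers(4, 7)), big_intron=8000)
        genes.append(
            TranscriptModel(f"CG{i+1}", f"CG{i+1}.1", CONTIG, strand, exons, biotype="coding")
        )
        cursor = end + gap_len
        gaps.append((end + 500, min(cursor - 500, cfg.genome_length - 2000)))
    return genes, gaps


def _place_lnc_genes(
    rng: np.random.Generator,
    cfg: SimConfig,
    coding: list[TranscriptModel],
    gaps: list[tuple[int, int]],
) -> tuple[list[TranscriptModel], dict[str, str]]:
    """One lncRNA gene per entry of the (cycled) category mix.

    Gene i claims coding gene i and the gap following it, so lncRNA genes
    never collide with each other: an INTERGENIC gene sits at the left edge
    of its gap, an ANTISENSE gene overlaps the tail of its coding gene and
    runs into that same left edge, a SENSE_EXONIC gene covers its coding
    gene's first exon and extends into the preceding gap's right edge, and a
    SENSE_NON_EXONIC gene sits inside its coding gene's big intron.
    """
    if cfg.n_lnc_genes > len(coding):
        raise ValueError(
            f"need n_coding_genes >= n_lnc_genes ({cfg.n_lnc_genes}) to place categories"
        )
    lnc: list[TranscriptModel] = []
    categories: dict[str, str] = {}
    for i in range(cfg.n_lnc_genes):
        category = cfg.lnc_category_mix[i % len(cfg.lnc_category_mix)]
        gid, tid = f"LNC{i+1}", f"LNC{i+1}.1"
        cg = coding[i]
        if category == "INTERGENIC":
            gstart, gend = gaps[i]
            start = gstart + 500
            span = min(6000, gend - start - 500)
            strand = "+" if i % 2 == 0 else "-"
            exons = _make_exons(rng, start, start + span, 3)
        elif category == "ANTISENSE":
            c_start, c_end = cg.span
            strand = "-" if cg.strand == "+" else "+"
            # overlap the tail of the coding span, then run free of it
            start = c_end - 2000
            end = min(start + 7000, cfg.genome_length - 2000)
            exons = _make_exons(rng, start, end, 3)
        elif category == "SENSE_EXONIC":
            c_start, _ = cg.span
            strand = cg.strand
            # cover the first coding exon and extend upstream
            end = cg.exons[0][1] + 200
            start = max(1000, c_start - 6000)
            exons = _make_exons(rng, start, end, 3)
        else:  # SENSE_NON_EXONIC: wholly inside the coding gene's big intron
            intron = max(
                ((a, b) for (_, a), (b, _) in zip(cg.exons, cg.exons[1:])),
                key=lambda iv: iv[1] - iv[0],
            )
            if intron[1] - intron[0] < 7000:
                raise ValueError(f"{cg.gene_id}: no intron large enough for an intronic lncRNA")
            strand = cg.strand
            start = intron[0] + 800
            end = min(intron[1] - 800, start + 6000)
            exons = _make_exons(rng, start, end, 2)
        lnc.append(TranscriptModel(gid, tid, CONTIG, strand, exons, biotype="lncRNA"))
        categories[gid] = category
    return lnc, categories


def _place_repeats(
    rng: np.random.Generator, cfg: SimConfig, lnc: list[TranscriptModel]
) -> list[RepeatFeature]:
    """Non-overlapping repeat tracts; about half are dropped inside lncRNA spans
    so planted edits sample all three repeat contexts."""
    taken: list[tuple[int, int]] = []
    feats: list[RepeatFeature] = []
    n_alu = int(round(cfg.n_repeats * cfg.alu_fraction))
    kinds = [_ALU_REPEATS[i % len(_ALU_REPEATS)] for i in range(n_alu)]
    kinds += [
        _NON_ALU_REPEATS[i % len(_NON_ALU_REPEATS)] for i in range(cfg.n_repeats - n_alu)
    ]
    spans = [t.span for t in lnc]
    for i, (name, rclass, rfam, length) in enumerate(kinds):
        for _ in range(200):  # rejection sampling against overlap
            if spans and i % 2 == 0:
                s0, e0 = spans[int(rng.integers(0, len(spans)))]
                if e0 - s0 <= length + 2:
                    continue
                start = int(rng.integers(s0, e0 - length))
            else:
                start = int(rng.integers(1000, cfg.genome_length - length - 1000))
            end = start + length
            if all(end <= s or start >= e for s, e in taken):
                taken.append((start, end))
                feats.append(RepeatFeature(CONTIG, start, end, name, rclass, rfam))
                break
    feats.sort(key=lambda r: r.start)
    return feats


def _splice_flank_blocklist(transcripts: list[TranscriptModel], margin: int) -> set[int]:
    """0-based positions within ``margin`` of any internal exon boundary."""
    out: set[int] = set()
    for t in transcripts:
        for (_, a), (b, _) in zip(t.exons, t.exons[1:]):
            out.update(range(a - margin, a + margin + 1))
            out.update(range(b - margin - 1, b + margin))
    return out


def _opposite_strand_cover(transcripts: list[TranscriptModel]) -> dict[str, list[tuple[int, int]]]:
    by_strand: dict[str, list[tuple[int, int]]] = {"+": [], "-": []}
    for t in transcripts:
        by_strand[t.strand].append(t.span)
    return by_strand


def _covered(pos0: int, spans: list[tuple[int, int]]) -> bool:
    return any(s <= pos0 < e for s, e in spans)


def make_reference_and_annotations(cfg: SimConfig) -> Scene:
    """Build the genome, annotations, and planted edit/SNP positions.

    Deterministic under ``cfg.seed``.  Edit sites are reference A on the
    transcript strand, inside lncRNA transcripts (exonic and intronic),
    outside homopolymer runs >= 5 and splice flanks, and not covered by any
    opposite-strand transcript span.  SNP positions are disjoint from edits.
    """
    rng = np.random.default_rng(cfg.seed)
    codes = _random_genome(rng, cfg.genome_length)

    coding, gaps = _place_coding_genes(rng, cfg)
    lnc, categories = _place_lnc_genes(rng, cfg, coding, gaps)
    repeats = _place_repeats(rng, cfg, lnc)
    genome = _codes_to_str(codes)
    ref_map = {CONTIG: genome}
    repeat_index = RepeatIndex(repeats)

    all_tx = coding + lnc
    strand_spans = _opposite_strand_cover(all_tx)
    splice_block = _splice_flank_blocklist(all_tx, margin=6)

    truth = TruthSet(gene_categories=dict(categories))
    used: set[int] = set()

    # --- edit sites: round-robin over lncRNA genes, ~60% exonic -------------
    lo, hi = cfg.edit_level_range
    want_base = {"+": "A", "-": "T"}  # A on the transcript strand
    placed = 0
    attempts = 0
    gi = 0
    while placed < cfg.n_edit_sites and attempts < cfg.n_edit_sites * 400:
        attempts += 1
        t = lnc[gi % len(lnc)]
        gi += 1
        s, e = t.span
        exonic = bool(rng.random() < 0.6)
        pos0 = int(rng.integers(s, e))
        if t.is_exonic(pos0) != exonic:
            continue
        if genome[pos0] != want_base[t.strand]:
            continue
        if pos0 in splice_block or pos0 in used or any(abs(pos0 - u) < 3 for u in used):
            continue
        opposite = "-" if t.strand == "+" else "+"
        if _covered(pos0, strand_spans[opposite]):
            continue
        if in_homopolymer(ref_map, CONTIG, pos0 + 1, 5):
            continue
        level = float(rng.uniform(lo, hi))
        truth.edits.append(
            PlantedEdit(
                contig=CONTIG,
                pos=pos0 + 1,
                strand=t.strand,
                planted_level=round(level, 4),
                gene_id=t.gene_id,
                tx_context="EXONIC" if exonic else "INTRONIC",
                repeat_context=classify_repeat_context(CONTIG, pos0 + 1, repeat_index),
            )
        )
        used.add(pos0)
        placed += 1
    if placed < cfg.n_edit_sites:
        raise RuntimeError(
            f"could only place {placed}/{cfg.n_edit_sites} edit sites; enlarge the scene"
        )

    # --- SNPs: mostly inside transcripts so the DNA veto is exercised -------
    tx_spans = [t.span for t in all_tx]
    n_snps = cfg.n_het_snps + cfg.n_hom_snps
    snp_specs = ["het"] * cfg.n_het_snps + ["hom"] * cfg.n_hom_snps
    si = 0
    attempts = 0
    while si < n_snps and attempts < n_snps * 400:
        attempts += 1
        if rng.random() < 0.8 and tx_spans:
            s, e = tx_spans[int(rng.integers(0, len(tx_spans)))]
            pos0 = int(rng.integers(s, e))
        else:
            pos0 = int(rng.integers(1000, cfg.genome_length - 1000))
        if pos0 in used or any(abs(pos0 - u) < 3 for u in used):
            continue
        ref = genome[pos0]
        alt = BASES[(BASES.index(ref) + 1 + int(rng.integers(0, 3))) % 4]
        truth.snps.append(PlantedSnp(CONTIG, pos0 + 1, snp_specs[si], ref, alt))
        used.add(pos0)
        si += 1
    if si < n_snps:
        raise RuntimeError(f"could only place {si}/{n_snps} SNPs; enlarge the scene")
    truth.edits.sort(key=lambda x: x.pos)
    truth.snps.sort(key=lambda x: x.pos)

    return Scene(
        cfg=cfg,
        genome=genome,
        repeats=repeats,
        coding_transcripts=coding,
        lnc_transcripts=lnc,
        truth=truth,
    )


# ---------------------------------------------------------------------------
# File writers for reference and annotations
# ---------------------------------------------------------------------------


def _write_fasta(scene: Scene, path: str) -> None:
    with open(path, "w") as fh:
        fh.write(f">{CONTIG}\n")
        for i in range(0, len(scene.genome), 70):
            fh.write(scene.genome[i : i + 70] + "\n")
    pysam.faidx(path)


def _write_gtf(transcripts: list[TranscriptModel], path: str, source: str) -> None:
    with open(path, "w") as fh:
        for t in transcripts:
            attrs = f'gene_id "{t.gene_id}"; transcript_id "{t.transcript_id}";'
            s, e = t.span
            fh.write(
                f"{t.contig}\t{source}\ttranscript\t{s+1}\t{e}\t.\t{t.strand}\t.\t{attrs}\n"
            )
            for es, ee in t.exons:
                fh.write(
                    f"{t.contig}\t{source}\texon\t{es+1}\t{ee}\t.\t{t.strand}\t.\t{attrs}\n"
                )


def _write_repeats_bed(repeats: list[RepeatFeature], path: str) -> None:
    with open(path, "w") as fh:
        for r in repeats:
            name = f"{r.repeat_name}#{r.repeat_class}/{r.repeat_family}"
            fh.write(f"{r.contig}\t{r.start}\t{r.end}\t{name}\t0\t+\n")


def _write_truth(truth: TruthSet, outdir: str) -> dict[str, str]:
    edits_path = os.path.join(outdir, "truth_edits.tsv")
    with open(edits_path, "w") as fh:
        fh.write(
            "contig\tpos\tstrand\tplanted_level\tgene_id\ttx_context\t"
            "repeat_context\trealized_alt_reads\trealized_total\n"
        )
        for e in truth.edits:
            fh.write(
                f"{e.contig}\t{e.pos}\t{e.strand}\t{e.planted_level}\t{e.gene_id}\t"
                f"{e.tx_context}\t{e.repeat_context}\t{e.realized_alt_reads}\t{e.realized_total}\n"
            )
    snps_path = os.path.join(outdir, "truth_snps.tsv")
    with open(snps_path, "w") as fh:
        fh.write("contig\tpos\tgenotype\tref\talt\n")
        for s in truth.snps:
            fh.write(f"{s.contig}\t{s.pos}\t{s.genotype}\t{s.ref}\t{s.alt}\n")
    cats_path = os.path.join(outdir, "truth_gene_categories.json")
    with open(cats_path, "w") as fh:
        json.dump(truth.gene_categories, fh, indent=2, sort_keys=True)
        fh.write("\n")
    return {"truth_edits": edits_path, "truth_snps": snps_path, "truth_categories": cats_path}


def load_truth(outdir: str) -> TruthSet:
    """Reload a written truth set (edits, SNPs, gene categories)."""
    truth = TruthSet()
    with open(os.path.join(outdir, "truth_edits.tsv")) as fh:
        next(fh)
        for line in fh:
            c, p, st, lv, g, tc, rc, ra, rt = line.rstrip("\n").split("\t")
            truth.edits.append(
                PlantedEdit(c, int(p), st, float(lv), g, tc, rc, int(ra), int(rt))
            )
    with open(os.path.join(outdir, "truth_snps.tsv")) as fh:
        next(fh)
        for line in fh:
            c, p, gt, ref, alt = line.rstrip("\n").split("\t")
            truth.snps.append(PlantedSnp(c, int(p), gt, ref, alt))
    with open(os.path.join(outdir, "truth_gene_categories.json")) as fh:
        truth.gene_categories = json.load(fh)
    return truth


# ---------------------------------------------------------------------------
# Read simulation
# ---------------------------------------------------------------------------


def _bam_header(cfg: SimConfig) -> dict:
    return {
        "HD": {"VN": "1.6", "SO": "coordinate"},
        "SQ": [{"SN": CONTIG, "LN": cfg.genome_length}],
    }


def _apply_errors(
    rng: np.random.Generator, bases: list[str], rate: float
) -> list[str]:
    n = rng.binomial(len(bases), rate)
    if n == 0:
        return bases
    for qpos in rng.choice(len(bases), size=n, replace=False):
        old = bases[qpos]
        choices = [b for b in BASES if b != old]
        bases[qpos] = choices[int(rng.integers(0, 3))]
    return bases


def _sort_and_index(tmp_path: str, out_path: str) -> None:
    pysam.sort("-o", out_path, tmp_path)
    pysam.index(out_path)
    os.remove(tmp_path)


def simulate_dna_reads(cfg: SimConfig, scene: Scene, out_path: str, rng=None) -> str:
    """Single-end DNA alignments at ~``dna_coverage``x mean depth.

    Reads are sampled uniformly from a diploid genome: hom SNPs appear on
    both haplotypes, het SNPs on one (each read draws a haplotype), so alt
    fractions are ~1.0 and ~0.5 respectively.
    """
    if rng is None:
        rng = np.random.default_rng(cfg.seed + 1)
    L = cfg.read_length
    n_reads = int(round(cfg.dna_coverage * cfg.genome_length / L))
    starts = np.sort(rng.integers(0, cfg.genome_length - L, size=n_reads))
    haplos = rng.integers(0, 2, size=n_reads)
    flags_rev = rng.integers(0, 2, size=n_reads)
    snp_by_pos = {s.pos - 1: s for s in scene.truth.snps}
    snp_positions = np.array(sorted(snp_by_pos), dtype=np.int64)

    tmp = out_path + ".unsorted.bam"
    quals = pysam.qualitystring_to_array(chr(cfg.base_quality + 33) * L)
    with pysam.AlignmentFile(tmp, "wb", header=_bam_header(cfg)) as bam:
        for i in range(n_reads):
            start = int(starts[i])
            bases = list(scene.genome[start : start + L])
            if snp_positions.size:
                j = np.searchsorted(snp_positions, start)
                while j < snp_positions.size and snp_positions[j] < start + L:
                    snp = snp_by_pos[int(snp_positions[j])]
                    if snp.genotype == "hom" or haplos[i] == 1:
                        bases[int(snp_positions[j]) - start] = snp.alt
                    j += 1
            bases = _apply_errors(rng, bases, cfg.base_error_rate)
            a = pysam.AlignedSegment()
            a.query_name = f"dna_{i}"
            a.query_sequence = "".join(bases)
            a.query_qualities = quals
            a.reference_id = 0
            a.reference_start = start
            a.mapping_quality = 60
            a.cigartuples = [(0, L)]
            a.flag = 16 if flags_rev[i] else 0
            bam.write(a)
    _sort_and_index(tmp, out_path)
    return out_path


def _mature_blocks(t: TranscriptModel) -> tuple[list[tuple[int, int]], int]:
    blocks = list(t.exons)
    return blocks, sum(e - s for s, e in blocks)


def _map_to_genome(
    blocks: list[tuple[int, int]], tstart: int, tend: int
) -> list[tuple[int, int]]:
    """Map [tstart, tend) in concatenated-block coordinates to genomic blocks."""
    out = []
    off = 0
    for s, e in blocks:
        blen = e - s
        lo, hi = max(tstart, off), min(tend, off + blen)
        if lo < hi:
            out.append((s + lo - off, s + hi - off))
        off += blen
    return out


def _blocks_to_cigar(gblocks: list[tuple[int, int]]) -> list[tuple[int, int]]:
    cig = []
    for k, (s, e) in enumerate(gblocks):
        if k > 0:
            cig.append((3, s - gblocks[k - 1][1]))  # N: reference skip
        cig.append((0, e - s))  # M
    return cig


def simulate_rna_reads(cfg: SimConfig, scene: Scene, out_path: str, rng=None) -> str:
    """Stranded RNA alignments over all transcripts, with edits planted.

    Mature (spliced) fragments target ``rna_coverage``x over lncRNA exons
    (``coding_expression`` of that for coding genes); a ``premrna_fraction``
    share of unspliced fragments covers introns.  Every strand-matched
    fragment covering an edit site carries the alternative base with
    probability ``planted_level``; realized per-fragment tallies are recorded
    in the truth set.
    """
    if rng is None:
        rng = np.random.default_rng(cfg.seed + 2)
    L = cfg.read_length
    edit_by_pos = {e.pos - 1: e for e in scene.truth.edits}
    snp_by_pos = {s.pos - 1: s for s in scene.truth.snps}
    for e in scene.truth.edits:
        e.realized_alt_reads = 0
        e.realized_total = 0

    tmp = out_path + ".unsorted.bam"
    quals = pysam.qualitystring_to_array(chr(cfg.base_quality + 33) * L)
    frag_serial = 0
    with pysam.AlignmentFile(tmp, "wb", header=_bam_header(cfg)) as bam:
        for t in scene.coding_transcripts + scene.lnc_transcripts:
            expr = cfg.rna_coverage * (
                cfg.coding_expression if t.biotype == "coding" else 1.0
            )
            mature, mature_len = _mature_blocks(t)
            span_s, span_e = t.span
            span_len = span_e - span_s
            jobs = []
            if mature_len >= L:
                n_mature = int(round(expr * mature_len / (2 * L if cfg.paired else L)))
                jobs.append((mature, mature_len, n_mature))
            if span_len >= L and cfg.premrna_fraction > 0:
                n_pre = int(
                    round(
                        expr
                        * cfg.premrna_fraction
                        * span_len
                        / (2 * L if cfg.paired else L)
                    )
                )
                jobs.append(([(span_s, span_e)], span_len, n_pre))
            for blocks, blen, n_frags in jobs:
                for _ in range(n_frags):
                    frag_serial += 1
                    _emit_fragment(
                        bam,
                        rng,
                        cfg,
                        scene,
                        t,
                        blocks,
                        blen,
                        f"rna_{t.transcript_id}_{frag_serial}",
                        edit_by_pos,
                        snp_by_pos,
                        quals,
                    )
    _sort_and_index(tmp, out_path)
    return out_path


def _emit_fragment(
    bam: pysam.AlignmentFile,
    rng: np.random.Generator,
    cfg: SimConfig,
    scene: Scene,
    t: TranscriptModel,
    blocks: list[tuple[int, int]],
    blen: int,
    name: str,
    edit_by_pos: dict[int, PlantedEdit],
    snp_by_pos: dict[int, PlantedSnp],
    quals,
) -> None:
    L = cfg.read_length
    flen = int(np.clip(rng.normal(300, 30), L, min(500, blen)))
    fstart = int(rng.integers(0, blen - flen + 1))
    fend = fstart + flen
    haplo = int(rng.integers(0, 2))

    if cfg.paired:
        read_ivs = [(fstart, fstart + L), (fend - L, fend)]
    else:
        read_ivs = [(fstart, fstart + L)]

    # per-fragment edit decisions, shared by both mates
    edit_decisions: dict[int, bool] = {}
    frag_covers: set[int] = set()

    prepared = []
    for tstart, tend in read_ivs:
        gblocks = _map_to_genome(blocks, tstart, tend)
        bases: list[str] = []
        gpos: list[int] = []
        for gs, ge in gblocks:
            bases.extend(scene.genome[gs:ge])
            gpos.extend(range(gs, ge))
        for qi, p in enumerate(gpos):
            snp = snp_by_pos.get(p)
            if snp is not None and (snp.genotype == "hom" or haplo == 1):
                bases[qi] = snp.alt
            edit = edit_by_pos.get(p)
            if edit is not None and edit.strand == t.strand:
                if p not in edit_decisions:
                    edit_decisions[p] = bool(rng.random() < edit.planted_level)
                frag_covers.add(p)
                if edit_decisions[p]:
                    # alt is G on the transcript strand: G forward, C reverse
                    bases[qi] = "G" if t.strand == "+" else "C"
        bases = _apply_errors(rng, bases, cfg.base_error_rate)
        prepared.append((gblocks, "".join(bases)))

    for p in frag_covers:
        edit = edit_by_pos[p]
        edit.realized_total += 1
        if edit_decisions[p]:
            edit.realized_alt_reads += 1

    # FR orientation: the forward-mapping mate sits at the fragment's left end.
    # For FR_FIRSTSTRAND the second mate carries the transcript orientation.
    if cfg.library_type == FR_SECONDSTRAND:
        sense_mate_is_read2 = False
    else:  # FR_FIRSTSTRAND and UNSTRANDED layouts are identical on the genome
        sense_mate_is_read2 = True

    if not cfg.paired:
        gblocks, seq = prepared[0]
        a = pysam.AlignedSegment()
        a.query_name = name
        a.query_sequence = seq
        a.query_qualities = quals
        a.reference_id = 0
        a.reference_start = gblocks[0][0]
        a.mapping_quality = 60
        a.cigartuples = _blocks_to_cigar(gblocks)
        # single-end: the read has the first-mate role
        read_is_sense = not sense_mate_is_read2
        reverse = (t.strand == "+") != read_is_sense
        a.flag = 16 if reverse else 0
        bam.write(a)
        return

    (gb_left, seq_left), (gb_right, seq_right) = prepared
    left_start, right_start = gb_left[0][0], gb_right[0][0]
    tlen = gb_right[-1][1] - gb_left[0][0]

    # sense mate maps forward iff transcript is '+'
    if t.strand == "+":
        sense_iv, anti_iv = (gb_left, seq_left, left_start), (gb_right, seq_right, right_start)
        sense_reverse, anti_reverse = False, True
    else:
        sense_iv, anti_iv = (gb_right, seq_right, right_start), (gb_left, seq_left, left_start)
        sense_reverse, anti_reverse = True, False

    if sense_mate_is_read2:
        read1, read2 = anti_iv, sense_iv
        r1_rev, r2_rev = anti_reverse, sense_reverse
    else:
        read1, read2 = sense_iv, anti_iv
        r1_rev, r2_rev = sense_reverse, anti_reverse

    for is_read1, (gblocks, seq, start), rev, mate_start, mate_rev in (
        (True, read1, r1_rev, read2[2], r2_rev),
        (False, read2, r2_rev, read1[2], r1_rev),
    ):
        a = pysam.AlignedSegment()
        a.query_name = name
        a.query_sequence = seq
        a.query_qualities = quals
        a.reference_id = 0
        a.reference_start = gblocks[0][0]
        a.mapping_quality = 60
        a.cigartuples = _blocks_to_cigar(gblocks)
        flag = 0x1 | 0x2  # paired, proper pair
        flag |= 0x40 if is_read1 else 0x80
        if rev:
            flag |= 0x10
        if mate_rev:
            flag |= 0x20
        a.flag = flag
        a.next_reference_id = 0
        a.next_reference_start = mate_start
        a.template_length = tlen if not rev else -tlen
        bam.write(a)


# ---------------------------------------------------------------------------
# Orchestration
# ---------------------------------------------------------------------------


def simulate_scene(cfg: SimConfig, outdir: str) -> Scene:
    """Generate and write a complete scene; returns it with file paths filled in.

    Deterministic under ``cfg.seed``: the same configuration always yields
    byte-identical annotation files and identical alignments.
    """
    os.makedirs(outdir, exist_ok=True)
    scene = make_reference_and_annotations(cfg)
    paths = {
        "reference": os.path.join(outdir, "genome.fa"),
        "repeats": os.path.join(outdir, "repeats.bed"),
        "coding_gtf": os.path.join(outdir, "coding.gtf"),
        "lncrna_gtf": os.path.join(outdir, "lncrna.gtf"),
        "rna_bam": os.path.join(outdir, "rna.bam"),
        "dna_bam": os.path.join(outdir, "dna.bam"),
        "snps": os.path.join(outdir, "snps.tsv"),
        "excluded_reads": os.path.join(outdir, "excluded_reads.txt"),
        "config": os.path.join(outdir, "config.json"),
    }
    _write_fasta(scene, paths["reference"])
    _write_gtf(scene.coding_transcripts, paths["coding_gtf"], "sim_coding")
    _write_gtf(scene.lnc_transcripts, paths["lncrna_gtf"], "sim_lncrna")
    _write_repeats_bed(scene.repeats, paths["repeats"])
    simulate_dna_reads(cfg, scene, paths["dna_bam"])
    simulate_rna_reads(cfg, scene, paths["rna_bam"])  # fills realized tallies
    paths.update(_write_truth(scene.truth, outdir))
    with open(paths["snps"], "w") as fh:
        for s in scene.truth.snps:
            fh.write(f"{s.contig}\t{s.pos}\n")
    open(paths["excluded_reads"], "w").close()
    with open(paths["config"], "w") as fh:
        json.dump(asdict(cfg), fh, indent=2, sort_keys=True)
        fh.write("\n")
    scene.paths = paths
    return scene
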