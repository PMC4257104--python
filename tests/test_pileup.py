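import pysam
import pytest

from _oracles import brute_force_pileup, random_sam_scene
from conftest import bam_from_sam_lines, write_fasta

from edikit.pileup import (
    AlignedRead,
    FilterConfig,
    PileupColumn,
    build_pileup,
    column_strand,
    infer_read_transcript_strand,
    orient_counts,
    read_passes_filters,
)


def mk_read(**kw):
    base = dict(read_id="r", contig="chr1", pos=100, mapq=50)
    base.update(kw)
    return AlignedRead(**base)


class TestReadFilters:
    def test_duplicate_rejected(self):
        assert not read_passes_filters(mk_read(is_duplicate=True), FilterConfig())

    def test_proper_unique_read_accepted(self):
        read = mk_read(is_paired=True, is_proper_pair=True)
        assert read_passes_filters(read, FilterConfig())

    def test_exclusion_list_vetoes(self):
        read = mk_read(read_id="bad")
        assert not read_passes_filters(read, FilterConfig(), frozenset({"bad"}))
        assert read_passes_filters(read, FilterConfig(), frozenset({"other"}))

    def test_discordant_pair_rejected_only_when_required(self):
        read = mk_read(is_paired=True, is_proper_pair=False)
        assert not read_passes_filters(read, FilterConfig())
        assert read_passes_filters(read, FilterConfig(require_proper_pair=False))

    def test_low_mapq_and_secondary_rejected(self):
        assert not read_passes_filters(mk_read(mapq=10), FilterConfig())
        assert not read_passes_filters(mk_read(is_secondary=True), FilterConfig())


class TestStrandInference:
    @pytest.mark.parametrize(
        "library,first,reverse,expected",
        [
            ("FR_FIRSTSTRAND", True, True, "+"),
            ("FR_FIRSTSTRAND", True, False, "-"),
            ("FR_FIRSTSTRAND", False, True, "-"),
            ("FR_FIRSTSTRAND", False, False, "+"),
            ("FR_SECONDSTRAND", True, True, "-"),
            ("FR_SECONDSTRAND", False, True, "+"),
            ("UNSTRANDED", True, True, "unknown"),
        ],
    )
    def test_protocol_mapping(self, library, first, reverse, expected):
        read = mk_read(is_paired=True, is_first_in_pair=first, is_reverse=reverse)
        assert infer_read_transcript_strand(read, library) == expected

    def test_single_end_follows_first_mate_convention(self):
        read = mk_read(is_paired=False, is_reverse=True)
        assert infer_read_transcript_strand(read, "FR_FIRSTSTRAND") == "+"


class TestColumnStrand:
    def col(self, plus, minus):
        return PileupColumn("chr1", 1, "A", plus_transcript_reads=plus, minus_transcript_reads=minus)

    def test_unanimous(self):
        assert column_strand(self.col(10, 0), FilterConfig()) == "+"

    def test_boundary_070_passes(self):
        assert column_strand(self.col(7, 3), FilterConfig()) == "+"

    def test_below_confidence_is_ambiguous(self):
        assert column_strand(self.col(6, 4), FilterConfig()) == "*"

    def test_no_tallies_is_ambiguous(self):
        assert column_strand(self.col(0, 0), FilterConfig()) == "*"


class TestOrientCounts:
    def test_minus_strand_complements(self):
        assert orient_counts((2, 0, 8, 0), "-", "T") == ((0, 8, 0, 2), "A")

    @pytest.mark.parametrize("strand", ["+", "*"])
    def test_plus_and_ambiguous_identity(self, strand):
        assert orient_counts((1, 2, 3, 4), strand, "G") == ((1, 2, 3, 4), "G")

    def test_minus_is_involution(self):
        counts, ref = (5, 1, 2, 9), "C"
        once = orient_counts(counts, "-", ref)
        twice = orient_counts(once[0], "-", once[1])
        assert twice == (counts, ref)


class TestBuildPileup:
    def _two_read_bam(self, tmp_path):
        sam = [
            "@HD\tVN:1.6",
            "@SQ\tSN:chr1\tLN:2000",
            "r1\t0\tchr1\t1001\t60\t10M\t*\t0\t0\tAAAAAAAAAA\t" + chr(30 + 33) * 10,
            "r2\t0\tchr1\t1001\t60\t10M\t*\t0\t0\tGGGGGGGGGG\t" + chr(30 + 33) * 10,
        ]
        return bam_from_sam_lines(sam, str(tmp_path / "two.bam"))

    def test_direct_count_example(self, tmp_path):
        path = self._two_read_bam(tmp_path)
        with pysam.AlignmentFile(path) as bam:
            cols = build_pileup(bam, "chr1", 1000, 1001, FilterConfig())
        assert len(cols) == 1
        assert cols[0].pos == 1001
        assert cols[0].counts == (1, 0, 1, 0)
        assert cols[0].qual_sum == 60

    def test_empty_region(self, tmp_path):
        path = self._two_read_bam(tmp_path)
        with pysam.AlignmentFile(path) as bam:
            assert build_pileup(bam, "chr1", 1, 500, FilterConfig()) == []

    def test_invalid_interval_and_contig_rejected(self, tmp_path):
        path = self._two_read_bam(tmp_path)
        with pysam.AlignmentFile(path) as bam:
            with pytest.raises(ValueError):
                build_pileup(bam, "chr1", 10, 10, FilterConfig())
            with pytest.raises(ValueError):
                build_pileup(bam, "chrMissing", 0, 10, FilterConfig())

    def test_overlapping_mates_counted_once(self, tmp_path):
        q_hi, q_lo = chr(40 + 33), chr(28 + 33)
        sam = [
            "@HD\tVN:1.6",
            "@SQ\tSN:chr1\tLN:2000",
            # proper pair, mates fully overlapping; read1 A@q40, read2 C@q28
            "p\t99\tchr1\t101\t60\t5M\t=\t101\t5\tAAAAA\t" + q_hi * 5,
            "p\t147\tchr1\t101\t60\t5M\t=\t101\t-5\tCCCCC\t" + q_lo * 5,
        ]
        path = bam_from_sam_lines(sam, str(tmp_path / "mates.bam"))
        with pysam.AlignmentFile(path) as bam:
            cols = build_pileup(bam, "chr1", 100, 105, FilterConfig())
        assert all(col.counts == (1, 0, 0, 0) for col in cols)  # higher quality wins
        assert all(col.qual_sum == 40 for col in cols)

    @pytest.mark.parametrize("seed", range(30))
    def test_matches_brute_force_sam_recount(self, seed, tmp_path):
        """Randomized scenes: identical to an independent naive SAM-text recount."""
        ref, sam_lines, excluded = random_sam_scene(seed)
        cfg = FilterConfig(
            min_base_quality=[20, 25, 30][seed % 3],
            trim_read_ends=[0, 3][seed % 2],
            library_type=["FR_FIRSTSTRAND", "FR_SECONDSTRAND", "UNSTRANDED"][seed % 3],
        )
        path = bam_from_sam_lines(sam_lines, str(tmp_path / f"rand{seed}.bam"))
        expected = brute_force_pileup(sam_lines, "chrT", 0, len(ref), cfg, excluded)
        with pysam.AlignmentFile(path) as bam:
            cols = build_pileup(bam, "chrT", 0, len(ref), cfg, excluded, {"chrT": ref})
        got = {
            c.pos: (*c.counts, c.qual_sum, c.plus_transcript_reads, c.minus_transcript_reads)
            for c in cols
        }
        assert got == expected

    def test_raising_quality_thresholds_never_increases_counts(self, tmp_path):
        ref, sam_lines, _ = random_sam_scene(99)
        path = bam_from_sam_lines(sam_lines, str(tmp_path / "mono.bam"))
        totals = []
        for min_bq in (10, 20, 30, 40):
            with pysam.AlignmentFile(path) as bam:
                cols = build_pileup(
                    bam, "chrT", 0, len(ref), FilterConfig(min_base_quality=min_bq)
                )
            totals.append({c.pos: c.counts for c in cols})
        for loose, strict in zip(totals, totals[1:]):
            for pos, counts in strict.items():
                assert all(s <= l for s, l in zip(counts, loose[pos]))

    def test_reference_bases_attached(self, tmp_path):
        path = self._two_read_bam(tmp_path)
        ref = {"chr1": "T" * 2000}
        with pysam.AlignmentFile(path) as bam:
            cols = build_pileup(bam, "chr1", 1000, 1010, FilterConfig(), reference=ref)
        assert {c.ref_base for c in cols} == {"T"}
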