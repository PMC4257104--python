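import os
from dataclasses import replace

import pysam
import pytest

from edikit.annotator import classify_all_genes
from edikit.caller import in_homopolymer
from edikit.pileup import FilterConfig
from edikit.simdata import (
    CONTIG,
    SimConfig,
    load_truth,
    make_reference_and_annotations,
    simulate_dna_reads,
    simulate_rna_reads,
    simulate_scene,
)

SMALL = SimConfig(
    genome_length=150_000,
    n_coding_genes=4,
    n_lnc_genes=4,
    n_repeats=16,
    n_edit_sites=8,
    n_het_snps=6,
    n_hom_snps=3,
    rna_coverage=30,
    dna_coverage=20,
    seed=11,
)


class TestReferenceAndAnnotations:
    def test_category_mix_is_planted_exactly(self):
        scene = make_reference_and_annotations(SMALL)
        recovered = classify_all_genes(scene.lnc_transcripts, scene.coding_transcripts)
        assert recovered == scene.truth.gene_categories
        assert set(recovered.values()) == {
            "INTERGENIC", "ANTISENSE", "SENSE_EXONIC", "SENSE_NON_EXONIC",
        }

    def test_same_seed_reproduces_annotation_files(self, tmp_path):
        d1, d2 = tmp_path / "a", tmp_path / "b"
        simulate_scene(replace(SMALL, dna_coverage=2, rna_coverage=2), str(d1))
        simulate_scene(replace(SMALL, dna_coverage=2, rna_coverage=2), str(d2))
        for name in ("genome.fa", "lncrna.gtf", "coding.gtf", "repeats.bed", "truth_snps.tsv"):
            assert (d1 / name).read_bytes() == (d2 / name).read_bytes()

    def test_zero_alu_fraction_emits_no_alu(self):
        scene = make_reference_and_annotations(replace(SMALL, alu_fraction=0.0))
        assert all("Alu" not in r.repeat_family for r in scene.repeats)
        assert all(e.repeat_context != "ALU" for e in scene.truth.edits)

    def test_edit_sites_are_reference_A_on_transcript_strand(self):
        scene = make_reference_and_annotations(SMALL)
        for e in scene.truth.edits:
            base = scene.genome[e.pos - 1]
            assert base == ("A" if e.strand == "+" else "T")
            assert not in_homopolymer({CONTIG: scene.genome}, CONTIG, e.pos, 5)

    def test_snp_and_edit_positions_disjoint(self):
        scene = make_reference_and_annotations(SMALL)
        edit_pos = {e.pos for e in scene.truth.edits}
        snp_pos = {s.pos for s in scene.truth.snps}
        assert not edit_pos & snp_pos
        assert len(snp_pos) == SMALL.n_het_snps + SMALL.n_hom_snps

    def test_repeats_do_not_overlap(self):
        scene = make_reference_and_annotations(SMALL)
        spans = sorted((r.start, r.end) for r in scene.repeats)
        for (s1, e1), (s2, e2) in zip(spans, spans[1:]):
            assert e1 <= s2


class TestDnaSimulation:
    def _pileup_base_fractions(self, bam_path, scene, pos1):
        with pysam.AlignmentFile(bam_path) as bam:
            counts = {b: 0 for b in "ACGT"}
            for pc in bam.pileup(CONTIG, pos1 - 1, pos1, truncate=True, min_base_quality=0):
                for pread in pc.pileups:
                    if pread.query_position is not None:
                        b = pread.alignment.query_sequence[pread.query_position]
                        if b in counts:
                            counts[b] += 1
        return counts

    def test_error_free_reads_match_reference(self, tmp_path):
        cfg = replace(SMALL, base_error_rate=0.0, n_het_snps=0, n_hom_snps=0, dna_coverage=4)
        scene = make_reference_and_annotations(cfg)
        path = simulate_dna_reads(cfg, scene, str(tmp_path / "dna.bam"))
        with pysam.AlignmentFile(path) as bam:
            for read in bam.fetch():
                start = read.reference_start
                assert read.query_sequence == scene.genome[start : start + cfg.read_length]

    def test_hom_snp_site_is_all_alt_without_errors(self, tmp_path):
        cfg = replace(SMALL, base_error_rate=0.0, dna_coverage=15)
        scene = make_reference_and_annotations(cfg)
        path = simulate_dna_reads(cfg, scene, str(tmp_path / "dna.bam"))
        hom = next(s for s in scene.truth.snps if s.genotype == "hom")
        counts = self._pileup_base_fractions(path, scene, hom.pos)
        assert counts[hom.alt] > 0
        assert counts[hom.ref] == 0

    def test_het_snp_alt_fraction_near_half_at_high_depth(self, tmp_path):
        cfg = replace(
            SMALL, genome_length=30_000, n_coding_genes=1, n_lnc_genes=1,
            lnc_category_mix=("INTERGENIC",), n_repeats=4, n_edit_sites=2,
            n_het_snps=3, n_hom_snps=0, base_error_rate=0.0, dna_coverage=1000, seed=5,
        )
        scene = make_reference_and_annotations(cfg)
        path = simulate_dna_reads(cfg, scene, str(tmp_path / "deep.bam"))
        het = scene.truth.snps[0]
        counts = self._pileup_base_fractions(path, scene, het.pos)
        frac = counts[het.alt] / (counts[het.alt] + counts[het.ref])
        assert abs(frac - 0.5) < 0.05


class TestRnaSimulation:
    def test_level_one_gives_frequency_one(self, tmp_path, small_scene):
        from conftest import run_caller_on_scene

        cfg = replace(
            SMALL, base_error_rate=0.0,
            edit_level_range=(1.0, 1.0), n_het_snps=0, n_hom_snps=0,
        )
        outdir = str(tmp_path / "lvl1")
        simulate_scene(cfg, outdir)
        truth = load_truth(outdir)
        calls = {c.pos: c for c in run_caller_on_scene(outdir, FilterConfig())}
        covered = [e for e in truth.edits if e.realized_total >= 10]
        assert covered
        for e in covered:
            assert calls[e.pos].frequency == pytest.approx(1.0)

    def test_level_zero_plants_nothing(self, tmp_path):
        cfg = replace(SMALL, base_error_rate=0.0, edit_level_range=(0.0, 0.0))
        outdir = str(tmp_path / "lvl0")
        simulate_scene(cfg, outdir)
        truth = load_truth(outdir)
        assert all(e.realized_alt_reads == 0 for e in truth.edits)

    def test_realized_counts_match_independent_bam_recount(self, small_scene):
        """Recount alt-carrying fragments straight from the emitted alignments."""
        alt_for = {"+": "G", "-": "C"}
        with pysam.AlignmentFile(small_scene.paths["rna_bam"]) as bam:
            for e in small_scene.truth.edits:
                frags_alt, frags_all = set(), set()
                for read in bam.fetch(e.contig, e.pos - 1, e.pos):
                    pairs = dict(
                        (r, q) for q, r in read.get_aligned_pairs(matches_only=True)
                    )
                    q = pairs.get(e.pos - 1)
                    if q is None:
                        continue
                    frags_all.add(read.query_name)
                    if read.query_sequence[q] == alt_for[e.strand]:
                        frags_alt.add(read.query_name)
                # errors may flip a base either way; exact match without them
                assert len(frags_all) == e.realized_total
                assert abs(len(frags_alt) - e.realized_alt_reads) <= 2

    def test_strand_flags_encode_library_type(self, small_scene):
        from edikit.pileup import AlignedRead, infer_read_transcript_strand

        tx_strand = {t.transcript_id: t.strand for t in small_scene.lnc_transcripts}
        tx_strand.update({t.transcript_id: t.strand for t in small_scene.coding_transcripts})
        checked = 0
        with pysam.AlignmentFile(small_scene.paths["rna_bam"]) as bam:
            for read in bam.fetch():
                tid = read.query_name.split("_")[1]
                inferred = infer_read_transcript_strand(
                    AlignedRead.from_pysam(read), "FR_FIRSTSTRAND"
                )
                assert inferred == tx_strand[tid]
                checked += 1
                if checked > 500:
                    break
        assert checked > 0


class TestSceneFiles:
    def test_all_declared_outputs_exist(self, small_scene):
        for key, path in small_scene.paths.items():
            assert os.path.exists(path), key
        assert os.path.exists(small_scene.paths["rna_bam"] + ".bai")
        assert os.path.exists(small_scene.paths["reference"] + ".fai")

    def test_truth_roundtrip(self, small_scene):
        truth = load_truth(os.path.dirname(small_scene.paths["reference"]))
        assert truth.gene_categories == small_scene.truth.gene_categories
        assert [e.pos for e in truth.edits] == [e.pos for e in small_scene.truth.edits]
        assert [s.pos for s in truth.snps] == [s.pos for s in small_scene.truth.snps]
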