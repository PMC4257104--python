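from __future__ import annotations

import os

import pysam
import pytest

from edikit.annotator import read_transcripts_gtf
from edikit.caller import SpliceSiteIndex, call_regions, load_snp_positions
from edikit.pileup import FilterConfig
from edikit.simdata import SimConfig, load_truth, simulate_scene


def bam_from_sam_lines(sam_lines, bam_path: str) -> str:
    """Write SAM text lines to a coordinate-sorted, indexed BAM."""
    header = pysam.AlignmentHeader.from_text(
        "\n".join(l for l in sam_lines if l.startswith("@")) + "\n"
    )
    tmp = bam_path + ".unsorted.bam"
    with pysam.AlignmentFile(tmp, "wb", header=header) as bam:
        for line in sam_lines:
            if not line.startswith("@"):
                bam.write(pysam.AlignedSegment.fromstring(line, header))
    pysam.sort("-o", bam_path, tmp)
    pysam.index(bam_path)
    os.remove(tmp)
    return bam_path


def write_fasta(seqs: dict[str, str], path: str) -> str:
    with open(path, "w") as fh:
        for name, seq in seqs.items():
            fh.write(f">{name}\n{seq}\n")
    pysam.faidx(path)
    return path


def run_caller_on_scene(scene_dir: str, cfg: FilterConfig, regions: str = "lncrna.gtf"):
    """Convenience: full calling run over a written scene directory."""
    lnc = read_transcripts_gtf(os.path.join(scene_dir, "lncrna.gtf"))
    return call_regions(
        os.path.join(scene_dir, "rna.bam"),
        os.path.join(scene_dir, "dna.bam"),
        os.path.join(scene_dir, "genome.fa"),
        os.path.join(scene_dir, regions),
        cfg,
        snp_positions=load_snp_positions(os.path.join(scene_dir, "snps.tsv")),
        splice_index=SpliceSiteIndex(lnc, cfg.splice_window),
    )


@pytest.fixture(scope="session")
def small_scene(tmp_path_factory):
    """A compact scene shared by unit tests: 200 kb, 12 edits, 15 SNPs."""
    outdir = str(tmp_path_factory.mktemp("small_scene"))
    cfg = SimConfig(
        genome_length=200_000,
        n_coding_genes=4,
        n_lnc_genes=4,
        n_edit_sites=12,
        n_het_snps=10,
        n_hom_snps=5,
        rna_coverage=40,
        dna_coverage=25,
        seed=7,
    )
    scene = simulate_scene(cfg, outdir)
    return scene


@pytest.fixture(scope="session")
def default_scene(tmp_path_factory):
    """The reference 1 Mb scene with its calls, used by the recovery tests."""
    outdir = str(tmp_path_factory.mktemp("default_scene"))
    sim_cfg = SimConfig(seed=1234)
    scene = simulate_scene(sim_cfg, outdir)
    cfg = FilterConfig()
    calls = run_caller_on_scene(outdir, cfg)
    truth = load_truth(outdir)
    return {"scene": scene, "calls": calls, "truth": truth, "cfg": cfg, "dir": outdir}
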