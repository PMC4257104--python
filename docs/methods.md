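# Methods

## Calling model

A candidate editing site is a reference position where filtered RNA
alignments carry a non-reference base. Evidence at a position is a pair of
pileup columns — RNA and DNA — each a vector of A/C/G/T counts restricted
to base calls with phred ≥ `min_base_quality` from alignment records that
are mapped, primary, non-duplicate, concordant (for pairs), above
`min_mapping_quality`, and not on the exclusion list. Where proper mates
overlap, each reference position of a fragment is counted once, from the
mate with the higher base quality; double counting would deflate the
variance and bias editing levels upward.

The editing level of substitution ref→b is defined per substitution as

    f_b = n_b / (n_ref + n_b)

rather than n_b over total depth: a site can carry a second, unrelated
variant (or error) and the level of the A→G change should not depend on it.
A site PASSes when, in order:

1. RNA depth ≥ `min_rna_coverage` (default 10);
2. DNA depth ≥ `min_dna_coverage` (default 10) — with no or thin genomic
   evidence the site cannot be distinguished from a SNP and is rejected,
   not rescued;
3. DNA non-reference fraction ≤ `dna_max_alt_fraction` (default 0.05). This
   is a simple fraction test, not a genotype likelihood: with ≥ 10 reads it
   cleanly separates homozygous-reference positions from het (≈ 0.5) and
   hom-alt (≈ 1.0) genotypes, and the threshold is exposed for stricter
   (0.0) or looser use;
4. some substitution has n_b ≥ `min_variant_reads` (default 3) and
   f_b ≥ `min_variant_frequency` (default 0.10), both inclusive;
5. the position is not inside a maximal reference homopolymer run ≥
   `homopolymer_min_len` (default 5) — indel-induced misalignment inside
   runs fakes substitutions;
6. the position is not within `splice_window` (default 4) intronic bases of
   an annotated exon boundary — misaligned spliced reads pile up
   mismatches there. The width is configurable because annotation quality
   varies; 4 nt covers the near-invariant donor/acceptor dinucleotides plus
   the most error-prone flank.
7. the position is not in the known-SNP set. SNP matching is by position
   only, irrespective of allele: a position polymorphic in the population
   is untrustworthy evidence for editing regardless of which alternative
   allele was catalogued.

Rejected candidates are reported with a named status
(`LOW_RNA_COV`, `LOW_DNA_COV`, `DNA_NOT_HOMOZYGOUS`,
`TOO_FEW_VARIANT_READS`, `LOW_FREQUENCY`, `HOMOPOLYMER`, `SPLICE_PROXIMAL`,
`KNOWN_SNP`), which makes filter behaviour auditable and lets a user
re-examine borderline sites without re-running the pileup. When several
substitutions qualify at one site they share one row; the row's headline
frequency is the maximum over qualifying substitutions.

## Strand handling

For dUTP-style `FR_FIRSTSTRAND` libraries the first mate is antisense to
the transcript (`FR_SECONDSTRAND` is the mirror; unpaired reads follow the
first-mate convention). Each column tallies the inferred transcript strand
of its contributing base observations; the column strand is the majority
strand if its fraction is ≥ `strand_confidence` (default 0.70, inclusive),
else `*`. Counts of minus-strand columns are complemented (A↔T, C↔G) before
calling, so editing on minus-strand transcripts is reported as A→G on `-`.
Columns left at `*` — e.g. overlapping sense/antisense transcription at
comparable levels — are reported genome-forward, where true minus-strand
editing surfaces as T→C; this mirrors the residual T→C fraction any
stranded screen shows. For unstranded libraries the strand is taken from
the region annotation when exactly one annotated strand covers the
position (disable with `use_annotation_strand=False` to force `*`).

A read is treated as unique when its record is neither secondary nor
supplementary; aligner-specific hit-count tags are deliberately not
consulted, since multi-mapper policy belongs to the upstream aligner.
Coordinates are 0-based half-open internally and 1-based in all output.

## Read prefilters

3′ trimming is a plain suffix-trim: trailing bases are dropped while their
quality is below the cutoff (default phred 20), and reads shorter than
50 nt afterwards are discarded — short reads misalign and fake candidate
sites. Sliding-window trimming is intentionally not implemented; the
suffix rule is the simplest algorithm consistent with trimming
"low-quality read ends" and is exactly testable. The complexity filter
drops reads with ≥ 10 consecutive N's or mononucleotide Shannon entropy
< 1.0 bit over A/C/G/T (N ignored); both thresholds are declared defaults,
exposed as options, not values inherited from any reference tool.

## Synthetic scenes

The generator emulates, at desk scale, a matched RNA/DNA experiment on a
genome with repeats, coding genes, and lncRNA genes in all four categories
(one category per gene, realized exactly by construction: antisense genes
overlap a coding gene's tail on the opposite strand, sense-exonic genes
cover a coding first exon on the same strand, sense-non-exonic genes sit
wholly inside a coding intron, intergenic genes in gene-free gaps). Repeat
tracts (Alu-like and non-Alu) are non-overlapping, about half placed inside
lncRNA spans so planted edits sample all three repeat contexts.

Defaults define the reference scene used by the recovery tests: 1 Mb
genome, 8 coding + 8 lncRNA genes, 40 repeats (60% Alu), 50 edit sites at
levels uniform in [0.1, 0.9], 100 het + 50 hom-alt SNPs, paired 100 nt
`FR_FIRSTSTRAND` reads, 50× RNA coverage over mature lncRNA transcripts,
30× DNA, constant base quality 30, i.i.d. base-error rate 0.001. A 35%
pre-mRNA fragment fraction gives introns ~17× coverage so intronic sites
are callable; coding genes are expressed at 25% of lncRNA depth, which
keeps antisense loci strand-resolvable at the default confidence while
still exercising mixed-strand columns.

An edit is a property of (position, strand): every fragment whose
transcript strand matches carries the alternative base with probability
`planted_level`, decided once per fragment so mates agree — as they would
for a single cDNA molecule. Edit positions are chosen at *callable* sites:
reference A on the transcript strand, outside homopolymer runs ≥ 5 and
splice flanks, and free of antisense transcription, so the planted level is
identifiable from the pileup and recovery measures the caller rather than
the (separately unit-tested) context filters. SNPs are placed mostly
inside transcripts so the DNA veto is actually exercised: RNA reads carry
het alleles at ~50% and hom alleles at ~100%, and those sites must be
rejected on DNA evidence, not missed by chance.

What the scenes do **not** model: alignment itself (reads are emitted as
alignments; mismapping exists only through the excluded-read-list
pathway), indels and soft-clip errors, position-dependent quality decay,
GC and hexamer-priming bias, PCR duplicates, and editing-level variation
between transcripts of one gene. Passing recovery tests therefore
demonstrate the correctness of the counting, filtering, strand, and
annotation logic under clean alignments — not robustness to aligner
artifacts, which on real data is delegated to the upstream mapper and the
exclusion lists.

## Numerical and design choices

* All thresholds are inclusive (≥ / ≤), asserted at their boundaries by
  tests (DNA depth 9 vs 10, homopolymer run 4 vs 5, level 3/30 vs 3/31,
  splice flank 4th vs 5th intronic base).
* Ties in the mate-overlap resolution keep the first-seen base; since both
  mates of a planted fragment agree, this affects only error bases.
* The pileup is validated against an independent brute-force recount that
  re-parses SAM text and shares no code with the implementation.
* Determinism: one seeded generator drives scene layout; read simulation
  derives per-file seeds from it. Identical configuration and seed yield
  byte-identical annotation files and editing tables.
* The editing-level histogram uses half-open bins with the last bin closed,
  so level 1.0 is counted, and bin totals always equal the PASS count.
* Recovery in the tests is scored on threshold-clearing truth sites (realized
  alt fragments ≥ 3 and realized level ≥ 0.10): a site planted at level 0.1
  that by chance realizes one alt read is not a caller failure.
* Problem sizes in the test-suite scenes (150–200 kb unit scenes, the 1 Mb
  reference scene, 100 randomized pileup scenes) were chosen as the
  smallest at which every category, context, and filter is exercised with
  comfortable statistical margins.

## Known limitations

* RNA-only calling (without DNA) is out of scope by design; `LOW_DNA_COV`
  is a terminal status.
* Hyper-edited reads with many mismatches are likely excluded upstream by
  the aligner or the uniqueness filter; no cluster-rescue is attempted.
* Gene-category counts follow a per-gene convention: a site inside two
  lncRNA genes contributes to both genes' categories.
* The DNA homozygosity test ignores base qualities beyond the counting
  threshold; with very deep DNA a likelihood model would be slightly more
  sensitive to low-fraction mosaicism.
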