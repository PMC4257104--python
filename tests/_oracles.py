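"""Independent brute-force oracles and random-scene helpers for the tests.

The pileup oracle re-parses SAM *text* and recounts naively, sharing no code
with the package's pileup implementation.
"""

from __future__ import annotations

import random
import re

_CIGAR = re.compile(r"(\d+)([MIDNSHP=X])")

# SAM flag bits
PAIRED = 0x1
PROPER = 0x2
UNMAPPED = 0x4
REVERSE = 0x10
MATE_REVERSE = 0x20
READ1 = 0x40
READ2 = 0x80
SECONDARY = 0x100
DUP = 0x400
SUPPLEMENTARY = 0x800


def _aligned_pairs_from_cigar(pos0: int, cigar: str):
    """(qpos, rpos) for every aligned (M/=/X) base, walking the CIGAR by hand."""
    out = []
    q = 0
    r = pos0
    for n, op in _CIGAR.findall(cigar):
        n = int(n)
        if op in "M=X":
            for k in range(n):
                out.append((q + k, r + k))
            q += n
            r += n
        elif op in "IS":
            q += n
        elif op in "DN":
            r += n
        # H, P consume nothing relevant
    return out


def _read_strand(flag: int, library_type: str) -> str:
    if library_type == "UNSTRANDED":
        return "unknown"
    first = bool(flag & READ1) or not (flag & PAIRED)
    reverse = bool(flag & REVERSE)
    if library_type == "FR_FIRSTSTRAND":
        sense_reverse = first
    else:  # FR_SECONDSTRAND
        sense_reverse = not first
    if sense_reverse:
        return "+" if reverse else "-"
    return "-" if reverse else "+"


def brute_force_pileup(sam_lines, contig, start, end, cfg, excluded_ids=frozenset()):
    """Naive per-position recount over [start, end) applying the same filters.

    Returns {1-based pos: (countA, countC, countG, countT, qual_sum, plus, minus)}.
    """
    best = {}
    for line in sam_lines:
        if line.startswith("@"):
            continue
        f = line.rstrip("\n").split("\t")
        qname, flag, rname, pos1, mapq, cigar, seq, qual = (
            f[0], int(f[1]), f[2], int(f[3]), int(f[4]), f[5], f[9], f[10],
        )
        if rname != contig or flag & UNMAPPED:
            continue
        if flag & (SECONDARY | SUPPLEMENTARY):
            continue
        if cfg.exclude_duplicates and flag & DUP:
            continue
        if cfg.require_proper_pair and (flag & PAIRED) and not (flag & PROPER):
            continue
        if mapq < cfg.min_mapping_quality:
            continue
        if qname in excluded_ids:
            continue
        strand = _read_strand(flag, cfg.library_type)
        qlen = len(seq)
        for qpos, rpos in _aligned_pairs_from_cigar(pos1 - 1, cigar):
            if not (start <= rpos < end):
                continue
            if qpos < cfg.trim_read_ends or qpos >= qlen - cfg.trim_read_ends:
                continue
            base = seq[qpos]
            if base not in "ACGT":
                continue
            q = ord(qual[qpos]) - 33
            if q < cfg.min_base_quality:
                continue
            key = (qname, rpos)
            if key not in best or q > best[key][0]:
                best[key] = (q, base, strand)
    columns = {}
    for (_, rpos), (q, base, strand) in best.items():
        col = columns.setdefault(rpos + 1, [0, 0, 0, 0, 0, 0, 0])
        col["ACGT".index(base)] += 1
        col[4] += q
        if strand == "+":
            col[5] += 1
        elif strand == "-":
            col[6] += 1
    return {pos: tuple(v) for pos, v in columns.items()}


def _random_cigar(rng: random.Random, read_len: int) -> str:
    """A CIGAR consuming exactly read_len query bases."""
    style = rng.randrange(5)
    if style == 0:
        return f"{read_len}M"
    if style == 1:  # deletion
        a = rng.randint(5, read_len - 5)
        return f"{a}M{rng.randint(1, 4)}D{read_len - a}M"
    if style == 2:  # insertion
        a = rng.randint(5, read_len - 8)
        ins = rng.randint(1, 3)
        return f"{a}M{ins}I{read_len - a - ins}M"
    if style == 3:  # intron skip
        a = rng.randint(5, read_len - 5)
        return f"{a}M{rng.randint(20, 60)}N{read_len - a}M"
    clip = rng.randint(1, 6)  # soft clip at the start
    return f"{clip}S{read_len - clip}M"


def random_sam_scene(seed: int, contig: str = "chrT", ref_len: int = 300):
    """A small random SAM scene: reference sequence + SAM text lines.

    Mixes single-end and paired reads, varied CIGARs, random base/mapping
    qualities, occasional duplicate/secondary/discordant flags and N bases.
    """
    rng = random.Random(seed)
    ref = "".join(rng.choice("ACGT") for _ in range(ref_len))
    lines = [
        "@HD\tVN:1.6\tSO:unsorted",
        f"@SQ\tSN:{contig}\tLN:{ref_len}",
    ]
    excluded = set()

    def make_read(name, flag, pos0, read_len):
        cigar = _random_cigar(rng, read_len)
        bases = []
        for _ in range(read_len):
            r = rng.random()
            if r < 0.05:
                bases.append("N")
            else:
                bases.append(rng.choice("ACGT"))
        qual = "".join(chr(rng.randint(5, 45) + 33) for _ in range(read_len))
        mapq = rng.choice([0, 15, 20, 25, 60])
        if rng.random() < 0.08:
            flag |= DUP
        if rng.random() < 0.05:
            flag |= SECONDARY
        lines.append(
            "\t".join(
                [
                    name,
                    str(flag),
                    contig,
                    str(pos0 + 1),
                    str(mapq),
                    cigar,
                    "*",
                    "0",
                    "0",
                    "".join(bases),
                    qual,
                ]
            )
        )

    n_frags = rng.randint(6, 20)
    for i in range(n_frags):
        read_len = rng.randint(30, 60)
        if rng.random() < 0.5:  # paired
            p1 = rng.randint(0, ref_len - 2 * read_len - 20)
            gap = rng.randint(-read_len // 2, 40)  # negative gap -> overlapping mates
            p2 = max(0, p1 + read_len + gap)
            flags = PAIRED | READ1 | MATE_REVERSE
            if rng.random() < 0.8:
                flags |= PROPER
            make_read(f"frag{i}", flags, p1, read_len)
            make_read(f"frag{i}", (flags & ~READ1) | READ2 | REVERSE, p2, read_len)
        else:
            flag = REVERSE if rng.random() < 0.5 else 0
            make_read(f"se{i}", flag, rng.randint(0, ref_len - read_len - 1), read_len)
        if rng.random() < 0.1:
            excluded.add(f"frag{i}")
    return ref, lines, frozenset(excluded)
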