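"""Summary readouts of an editing table.

Three views of a call set: the substitution spectrum (the fraction of each
of the 12 ordered base changes among PASS sites — A-to-G dominance is the
standard specificity check for an editing screen), the distribution of
editing levels, and context tallies (repeat class x exon/intron, gene
categories, per-substitution totals).
"""

from __future__ import annotations

import json
from typing import Iterable, Mapping, Optional

import numpy as np
import pandas as pd

from .caller import PASS, SiteCall

__all__ = [
    "ALL_SUBSTITUTIONS",
    "substitution_spectrum",
    "level_histogram",
    "cohort_summary",
    "read_table",
    "write_report",
    "plot_report",
]

ALL_SUBSTITUTIONS = tuple(a + b for a in "ACGT" for b in "ACGT" if a != b)


def _iter_subs(calls: Iterable[SiteCall]) -> Iterable[str]:
    for c in calls:
        yield from (c.qualifying or c.substitutions)


def substitution_spectrum(calls: Iterable[SiteCall]) -> dict[str, float]:
    """Fraction of each observed substitution type among the given PASS calls.

    Each site contributes one count per substitution type it carries
    (strand-oriented; '*' sites contribute their genome-forward change).
    Fractions sum to 1 for non-empty input; empty input gives an empty map.
    """
    counts: dict[str, int] = {}
    total = 0
    for sub in _iter_subs(calls):
        counts[sub] = counts.get(sub, 0) + 1
        total += 1
    if total == 0:
        return {}
    return {sub: counts[sub] / total for sub in sorted(counts)}


def spectrum_from_subs(subs: Iterable[str]) -> dict[str, float]:
    """Spectrum from raw substitution strings (e.g. a table's AllSubs column)."""
    counts: dict[str, int] = {}
    total = 0
    for sub in subs:
        counts[sub] = counts.get(sub, 0) + 1
        total += 1
    return {s: counts[s] / total for s in sorted(counts)} if total else {}


def level_histogram(
    calls_or_freqs: Optional[Iterable] = None, bin_width: float = 0.1
) -> list[tuple[float, float, int]]:
    """Histogram of headline editing levels in [0, 1].

    Bins are half-open [k*w, (k+1)*w) with the last bin closed at 1.0, so a
    fully edited site (level 1.0) lands in the top bin.  Returns
    (low, high, count) triples covering [0, 1]; counts sum to the number of
    input calls.
    """
    nbins = round(1.0 / bin_width)
    if abs(nbins * bin_width - 1.0) > 1e-9:
        raise ValueError(f"bin_width {bin_width} does not divide 1 evenly")
    freqs = [
        c.frequency if isinstance(c, SiteCall) else float(c) for c in (calls_or_freqs or [])
    ]
    edges = np.linspace(0.0, 1.0, nbins + 1)
    counts, _ = np.histogram(freqs, bins=edges)
    return [(float(edges[i]), float(edges[i + 1]), int(counts[i])) for i in range(nbins)]


def read_table(path: str) -> pd.DataFrame:
    """Load a caller/annotator TSV, skipping '#' provenance comments."""
    df = pd.read_csv(path, sep="\t", comment="#", dtype={"Region": str})
    return df


def cohort_summary(table: pd.DataFrame) -> dict:
    """Context tallies over the PASS rows of an annotated table.

    Returns repeat-class x transcript-context counts, per-gene-category gene
    counts, per-substitution totals, the PASS count, and the editing-level
    histogram.  Marginals of the context grid sum to the PASS count.
    """
    passed = table[table["Status"] == PASS]
    grid: dict[str, dict[str, int]] = {}
    for rep in ("ALU", "REP_NON_ALU", "NONREP"):
        grid[rep] = {"EXONIC": 0, "INTRONIC": 0, "-": 0}
    for rep, ctx in zip(passed.get("RepeatClass", []), passed.get("TxContext", [])):
        grid.setdefault(rep, {"EXONIC": 0, "INTRONIC": 0, "-": 0})
        grid[rep][ctx] = grid[rep].get(ctx, 0) + 1

    gene_categories: dict[str, set] = {}
    if "GeneIds" in passed.columns:
        for genes, cats in zip(passed["GeneIds"], passed["GeneCategory"]):
            if genes == "-" or pd.isna(genes):
                continue
            for g, cat in zip(str(genes).split(","), str(cats).split(",")):
                gene_categories.setdefault(cat, set()).add(g)
    category_counts = {cat: len(gs) for cat, gs in sorted(gene_categories.items())}

    sub_totals: dict[str, int] = {}
    for subs in passed["AllSubs"]:
        if subs == "-" or pd.isna(subs):
            continue
        for s in str(subs).split(","):
            sub_totals[s] = sub_totals.get(s, 0) + 1

    levels = [float(f) for f in passed["Frequency"]]
    return {
        "n_pass": int(len(passed)),
        "repeat_by_context": grid,
        "gene_category_gene_counts": category_counts,
        "substitution_totals": dict(sorted(sub_totals.items())),
        "substitution_spectrum": spectrum_from_subs(
            s for subs in passed["AllSubs"] if subs != "-" for s in str(subs).split(",")
        ),
        "level_histogram": level_histogram(levels),
    }


def write_report(summary: Mapping, path: str) -> None:
    with open(path, "w") as fh:
        json.dump(summary, fh, indent=2)
        fh.write("\n")


def plot_report(summary: Mapping, outdir: str) -> list[str]:
    """Bar plots of the substitution spectrum and editing-level distribution."""
    import os

    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    os.makedirs(outdir, exist_ok=True)
    written = []

    spectrum = summary.get("substitution_spectrum", {})
    fig, ax = plt.subplots(figsize=(7, 4))
    subs = list(ALL_SUBSTITUTIONS)
    vals = [100 * spectrum.get(s, 0.0) for s in subs]
    ax.bar(range(len(subs)), vals, color="steelblue")
    ax.set_xticks(range(len(subs)), [f"{s[0]}-to-{s[1]}" for s in subs], rotation=60)
    ax.set_ylabel("% of substitutions")
    ax.set_title("Substitution spectrum (PASS sites)")
    fig.tight_layout()
    p = os.path.join(outdir, "substitution_spectrum.png")
    fig.savefig(p, dpi=120)
    plt.close(fig)
    written.append(p)

    hist = summary.get("level_histogram", [])
    fig, ax = plt.subplots(figsize=(6, 4))
    ax.bar(
        [lo for lo, _, _ in hist],
        [n for _, _, n in hist],
        width=[hi - lo for lo, hi, _ in hist],
        align="edge",
        color="indianred",
        edgecolor="white",
    )
    ax.set_xlabel("editing level alt/(ref+alt)")
    ax.set_ylabel("sites")
    ax.set_title("Editing-level distribution")
    fig.tight_layout()
    p = os.path.join(outdir, "editing_levels.png")
    fig.savefig(p, dpi=120)
    plt.close(fig)
    written.append(p)
    return written
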