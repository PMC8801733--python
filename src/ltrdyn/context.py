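"""Genomic context of TE insertions.

Classifies each insertion against gene models (coding / intron / intergenic),
builds per-superfamily density summaries (elements per Mb of category DNA and
fraction of category DNA occupied), computes sliding-window gene density
(fraction of window covered by coding sequence) and solo-LTR : intact-element
ratios.

Category priority for boundary-spanning copies is coding > intron >
intergenic, so each element is counted exactly once; DNA-occupancy fractions,
by contrast, use per-base overlap so a boundary-spanning copy contributes
bases to every category it covers.
"""
from __future__ import annotations

from collections import defaultdict

import numpy as np
import pandas as pd

from .models import CATEGORIES, SUPERFAMILIES, GeneModel, GenomicWindow, TECopy

GENE_POOR_THRESHOLD = 0.05
WINDOW = 100_000
STEP = 50_000

# per-chromosome category masks: 0 intergenic, 1 intron, 2 coding
_CODE = {"intergenic": 0, "intron": 1, "coding": 2}


def category_masks(genes: list[GeneModel], chrom_lengths: dict[str, int]) -> dict[str, np.ndarray]:
    """Per-base category code for every chromosome.

    Coding = union of CDS; intron = union of intron gaps not overlapping any
    CDS; intergenic = the remainder. The three categories partition the
    genome by construction.
    """
    masks = {c: np.zeros(l, dtype=np.int8) for c, l in chrom_lengths.items()}
    for g in genes:
        if g.chrom not in masks:
            raise KeyError(f"gene {g.gene_id} on unknown chromosome {g.chrom}")
        m = masks[g.chrom]
        for s, e in g.introns:
            m[s:e] = np.maximum(m[s:e], 1)
    for g in genes:
        m = masks[g.chrom]
        for s, e in g.cds:
            m[s:e] = 2
    return masks


def classify_insertion(te: TECopy, genes: list[GeneModel]) -> str:
    """Category of one insertion: coding > intron > intergenic by priority."""
    hit_intron = False
    for g in genes:
        if g.chrom != te.chrom:
            continue
        for s, e in g.cds:
            if s < te.end and te.start < e:
                return "coding"
        for s, e in g.introns:
            if s < te.end and te.start < e:
                hit_intron = True
    return "intron" if hit_intron else "intergenic"


def insertion_summary(
    copies: list[TECopy],
    genes: list[GeneModel],
    chrom_lengths: dict[str, int],
) -> pd.DataFrame:
    """Per (superfamily x category) insertion density and DNA-occupancy table.

    Columns: ``count`` (priority-rule element count), ``category_mb``
    (genome-wide Mb of the category), ``elements_per_mb`` (count per Mb of
    category DNA), ``te_bp`` (TE bases overlapping the category),
    ``dna_fraction`` (TE bases / category bases), and
    ``elements_per_genome_mb`` (secondary, per Mb of total genome).
    """
    for te in copies:
        if te.chrom not in chrom_lengths:
            raise KeyError(f"copy {te.copy_id} on unknown chromosome {te.chrom}")
    masks = category_masks(genes, chrom_lengths)
    genome_bp = sum(chrom_lengths.values())
    cat_bp = {
        cat: sum(int((m == _CODE[cat]).sum()) for m in masks.values())
        for cat in CATEGORIES
    }
    counts: dict[tuple[str, str], int] = defaultdict(int)
    te_bp: dict[tuple[str, str], int] = defaultdict(int)
    for te in copies:
        region = masks[te.chrom][te.start : te.end]
        cat = CATEGORIES[int(region.max(initial=0))]
        counts[(te.superfamily, cat)] += 1
        for c in CATEGORIES:
            te_bp[(te.superfamily, c)] += int((region == _CODE[c]).sum())
    rows = []
    for sf in SUPERFAMILIES:
        for cat in CATEGORIES:
            bp = cat_bp[cat]
            n = counts[(sf, cat)]
            occ = te_bp[(sf, cat)]
            rows.append(
                {
                    "superfamily": sf,
                    "category": cat,
                    "count": n,
                    "category_mb": bp / 1e6,
                    "elements_per_mb": (n / (bp / 1e6)) if bp > 0 else np.nan,
                    "te_bp": occ,
                    "dna_fraction": (occ / bp) if bp > 0 else np.nan,
                    "elements_per_genome_mb": n / (genome_bp / 1e6),
                }
            )
    return pd.DataFrame(rows)


def gene_density_windows(
    genes: list[GeneModel],
    chrom_lengths: dict[str, int],
    window: int = WINDOW,
    step: int = STEP,
) -> list[GenomicWindow]:
    """Sliding windows (default 100 kb / 50 kb step) with CDS coverage fraction.

    Windows start at 0 on every scaffold; the final window is truncated at the
    scaffold end and its density computed over its actual length. A scaffold
    shorter than the step yields a single window covering the scaffold.
    """
    cds_cov: dict[str, np.ndarray] = {
        c: np.zeros(l, dtype=bool) for c, l in chrom_lengths.items()
    }
    for g in genes:
        cov = cds_cov[g.chrom]
        for s, e in g.cds:
            cov[s:e] = True
    out: list[GenomicWindow] = []
    for chrom, length in chrom_lengths.items():
        cum = np.concatenate([[0], np.cumsum(cds_cov[chrom])])
        start = 0
        while True:
            end = min(start + window, length)
            frac = float(cum[end] - cum[start]) / (end - start)
            out.append(GenomicWindow(chrom, start, end, frac))
            if start + window >= length:
                break
            start += step
    return out


def assign_window_density(te: TECopy, windows: list[GenomicWindow]) -> float:
    """Gene density of the window the copy resides in.

    Among overlapping windows the one with the largest overlap wins; ties go
    to the leftmost window.
    """
    best: GenomicWindow | None = None
    best_ov = 0
    for w in sorted(
        (w for w in windows if w.chrom == te.chrom), key=lambda w: (w.start, w.end)
    ):
        ov = min(te.end, w.end) - max(te.start, w.start)
        if ov > best_ov:
            best, best_ov = w, ov
    if best is None:
        raise ValueError(f"copy {te.copy_id} overlaps no window")
    return best.cds_fraction


def per_copy_context(
    copies: list[TECopy],
    genes: list[GeneModel],
    windows: list[GenomicWindow],
    gene_poor: float = GENE_POOR_THRESHOLD,
) -> pd.DataFrame:
    """Per-copy table: category, resident-window gene density, gene-poor flag."""
    rows = []
    for te in copies:
        dens = assign_window_density(te, windows)
        rows.append(
            {
                "copy_id": te.copy_id,
                "family": te.family,
                "superfamily": te.superfamily,
                "status": te.status,
                "category": classify_insertion(te, genes),
                "gene_density": dens,
                "gene_poor": dens < gene_poor,
            }
        )
    return pd.DataFrame(rows)


def solo_intact_ratio(copies: list[TECopy]) -> pd.DataFrame:
    """Solo-LTR : intact-element ratio per superfamily (Table-2 layout).

    The S:I ratio indexes removal of LTR retrotransposons by unequal
    intra-element recombination. Ratio is NaN (flagged undefined) when a
    superfamily has no intact copies.
    """
    rows = []
    for sf in SUPERFAMILIES:
        s = sum(1 for te in copies if te.superfamily == sf and te.status == "solo_LTR")
        i = sum(1 for te in copies if te.superfamily == sf and te.status == "intact")
        if s == 0 and i == 0:
            continue
        rows.append(
            {
                "superfamily": sf,
                "S": s,
                "I": i,
                "ratio": (s / i) if i > 0 else np.nan,
                "undefined": i == 0,
            }
        )
    return pd.DataFrame(rows, columns=["superfamily", "S", "I", "ratio", "undefined"])
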