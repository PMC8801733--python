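"""Per-element epigenetic repression: DNA methylation and siRNA density.

Methylation level of an element is the pooled proportion of methylated
cytosine calls, #C / (#C + #T), per sequence context (CG, CHG, CHH with
H in {A, C, T}), over sites covered by more than three reads (coverage >= 4).
siRNA density is weighted read count per kilobase per element, with a
multiply-mapping read contributing 1 / n_hits at each of its locations.
CHH methylation and 24-nt siRNA abundance index RNA-directed de novo
silencing of young TE copies.
"""
from __future__ import annotations

import numpy as np
import pandas as pd

from .models import TECopy
from .stats import mann_whitney

MIN_COVERAGE = 4  # "covered by more than three reads"
SIRNA_LENGTH = 24
CONTEXTS = ("CG", "CHG", "CHH")

_COMP = {"A": "T", "C": "G", "G": "C", "T": "A", "N": "N"}


def call_context(genome: dict[str, str], chrom: str, pos: int, strand: str) -> str | None:
    """Methylation context of the cytosine at ``pos`` on ``strand``.

    Inspects the next two bases 3' on the given strand (reverse complement
    for the minus strand): CG when the next base is G, CHG for C-H-G, else
    CHH. Returns None for a non-cytosine position, ambiguous (N) context, or
    a context truncated by the sequence end.
    """
    seq = genome[chrom]
    if not 0 <= pos < len(seq):
        raise IndexError(f"position {pos} outside {chrom}")
    if strand == "+":
        if seq[pos] != "C":
            return None
        nxt = seq[pos + 1] if pos + 1 < len(seq) else None
        nxt2 = seq[pos + 2] if pos + 2 < len(seq) else None
    elif strand == "-":
        if seq[pos] != "G":  # a C on the minus strand
            return None
        nxt = _COMP[seq[pos - 1]] if pos - 1 >= 0 else None
        nxt2 = _COMP[seq[pos - 2]] if pos - 2 >= 0 else None
    else:
        raise ValueError(f"bad strand {strand!r}")
    if nxt is None or nxt == "N":
        return None
    if nxt == "G":
        return "CG"
    if nxt2 is None or nxt2 == "N":
        return None
    return "CHG" if nxt2 == "G" else "CHH"


def element_methylation(
    sites: pd.DataFrame, te: TECopy, min_coverage: int = MIN_COVERAGE
) -> dict[str, dict[str, float]]:
    """Pooled per-context methylation level of one element.

    ``sites`` columns: chrom, pos (0-based), strand, context,
    count_methylated, count_unmethylated. Per context, counts are pooled over
    qualifying sites inside ``[start, end)``; the level is missing (NaN) when
    no site qualifies. ``mean_site_level`` (mean of per-site ratios) is
    emitted as a secondary statistic.
    """
    sub = sites[
        (sites["chrom"] == te.chrom)
        & (sites["pos"] >= te.start)
        & (sites["pos"] < te.end)
    ]
    cov = sub["count_methylated"] + sub["count_unmethylated"]
    sub = sub[cov >= min_coverage]
    out: dict[str, dict[str, float]] = {}
    for ctx in CONTEXTS:
        c = sub[sub["context"] == ctx]
        n = len(c)
        if n == 0:
            out[ctx] = {"level": np.nan, "n_sites": 0, "mean_site_level": np.nan}
            continue
        meth = int(c["count_methylated"].sum())
        tot = meth + int(c["count_unmethylated"].sum())
        site_levels = c["count_methylated"] / (
            c["count_methylated"] + c["count_unmethylated"]
        )
        out[ctx] = {
            "level": meth / tot,
            "n_sites": n,
            "mean_site_level": float(site_levels.mean()),
        }
    return out


def elements_methylation(
    sites: pd.DataFrame, copies: list[TECopy], min_coverage: int = MIN_COVERAGE
) -> pd.DataFrame:
    """Per-element methylation table (one row per copy, columns per context)."""
    rows = []
    for te in copies:
        res = element_methylation(sites, te, min_coverage)
        row: dict[str, object] = {"copy_id": te.copy_id}
        for ctx in CONTEXTS:
            row[f"{ctx}_level"] = res[ctx]["level"]
            row[f"{ctx}_sites"] = res[ctx]["n_sites"]
        rows.append(row)
    return pd.DataFrame(rows)


def sirna_density(
    alignments: pd.DataFrame, te: TECopy, length_filter: int | None = SIRNA_LENGTH
) -> float:
    """Weighted siRNA reads per kilobase of one element.

    ``alignments`` columns: read_id, chrom, pos (5' start, 0-based), length,
    n_hits. Membership is judged by the 5' start position; each alignment
    contributes weight 1 / n_hits. ``length_filter=None`` disables the
    read-length filter (all putative siRNAs).
    """
    if te.length <= 0:
        raise ValueError(f"{te.copy_id}: zero-length element")
    sub = alignments[
        (alignments["chrom"] == te.chrom)
        & (alignments["pos"] >= te.start)
        & (alignments["pos"] < te.end)
    ]
    if length_filter is not None:
        sub = sub[sub["length"] == length_filter]
    weight = float((1.0 / sub["n_hits"]).sum())
    return weight / (te.length / 1000.0)


def elements_sirna_density(
    alignments: pd.DataFrame,
    copies: list[TECopy],
    length_filter: int | None = SIRNA_LENGTH,
) -> pd.DataFrame:
    rows = [
        {"copy_id": te.copy_id, "sirna_density": sirna_density(alignments, te, length_filter)}
        for te in copies
    ]
    return pd.DataFrame(rows)


def compare_repression(
    values, gene_densities, threshold: float = 0.05
) -> tuple[float, float, float, float]:
    """Repression contrast between gene-poor and gene-rich residents.

    Splits per-copy values (methylation level or siRNA density) at resident
    gene density < ``threshold`` and returns
    ``(median_gene_poor, median_other, U, p)`` from a two-sided Mann-Whitney
    test. NaN values are dropped; an empty group is an error naming the group.
    """
    v = np.asarray(values, dtype=float)
    d = np.asarray(gene_densities, dtype=float)
    if v.shape != d.shape:
        raise ValueError("values and gene densities differ in length")
    ok = ~np.isnan(v)
    v, d = v[ok], d[ok]
    poor = v[d < threshold]
    other = v[d >= threshold]
    if poor.size == 0:
        raise ValueError("gene-poor group is empty")
    if other.size == 0:
        raise ValueError("gene-rich group is empty")
    u, p = mann_whitney(poor, other)
    return float(np.median(poor)), float(np.median(other)), u, p
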