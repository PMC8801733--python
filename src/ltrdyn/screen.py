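"""Salt-stress expression screen for TE co-option.

Quantifies TE and gene expression (reads/kb and RPKM), filters expressed
features, runs a negative-binomial Wald test for differential expression
between salt treatments (library-size normalization by median-of-ratios,
method-of-moments dispersion, Benjamini-Hochberg FDR, significance at
FDR < 0.05 and >= 2-fold change), pairs TEs with flanking genes (within 3 kb
of either edge, or resident in an intron), tests the paired set for
enrichment in mis-expressed genes (Fisher exact), screens TE-gene pairs for
expression correlation across salt conditions (Pearson), and nominates
miRNA-sponge candidates (shared sense-orientation sequence covering a
predicted miRNA binding site).
"""
from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from Bio import Align
from scipy import stats as _st

from .models import GeneModel, TECopy
from .stats import bh_adjust, fisher_exact_test

MIN_READS = 5          # "more than 5 reads in both biological replicates"
FLANK_DISTANCE = 3000  # bp
FDR_ALPHA = 0.05
LFC_THRESHOLD = 1.0    # log2 of the 2-fold rule
DISPERSION_FLOOR = 1e-8
PSEUDOCOUNT = 0.5


@dataclass
class CountMatrix:
    """Raw counts (features x samples) with design, lengths and library sizes."""

    counts: pd.DataFrame
    design: pd.DataFrame  # columns: sample, tissue, nacl_mM, replicate
    lengths: pd.Series
    lib_sizes: pd.Series = field(default=None)  # type: ignore[assignment]

    def __post_init__(self) -> None:
        if self.design["sample"].duplicated().any():
            raise ValueError("duplicate sample in design")
        missing = set(self.counts.columns) - set(self.design["sample"])
        if missing:
            raise ValueError(f"samples missing from design: {sorted(missing)}")
        if (self.counts.to_numpy() < 0).any():
            raise ValueError("counts must be non-negative")
        if self.lib_sizes is None:
            self.lib_sizes = self.counts.sum(axis=0)

    def samples(self, tissue: str | None = None, nacl_mM: int | None = None) -> list[str]:
        d = self.design
        if tissue is not None:
            d = d[d["tissue"] == tissue]
        if nacl_mM is not None:
            d = d[d["nacl_mM"] == nacl_mM]
        return list(d["sample"])


def te_expression(counts: pd.DataFrame, lengths: pd.Series) -> pd.DataFrame:
    """TE expression as reads per kilobase of element, per sample."""
    lengths = lengths.reindex(counts.index)
    if (lengths <= 0).any() or lengths.isna().any():
        raise ValueError("all element lengths must be positive")
    return counts.div(lengths / 1000.0, axis=0)


def gene_rpkm(count: float, length: int, library_size: int) -> float:
    """Reads Per Kilobase per Million mapped reads."""
    if length <= 0 or library_size <= 0:
        raise ValueError("length and library size must be positive")
    return count * 1e9 / (length * library_size)


def rpkm_matrix(counts: pd.DataFrame, lengths: pd.Series, lib_sizes: pd.Series) -> pd.DataFrame:
    lengths = lengths.reindex(counts.index)
    if (lengths <= 0).any() or lengths.isna().any():
        raise ValueError("all feature lengths must be positive")
    if (lib_sizes.reindex(counts.columns) <= 0).any():
        raise ValueError("library sizes must be positive")
    return counts.mul(1e9).div(lengths, axis=0).div(lib_sizes.reindex(counts.columns), axis=1)


def filter_expressed(
    counts: pd.DataFrame, design: pd.DataFrame, tissue: str, min_reads: int = MIN_READS
) -> set[str]:
    """Features expressed in a tissue.

    A feature is expressed when, under at least one salt condition, its raw
    count strictly exceeds ``min_reads`` in BOTH biological replicates.
    """
    d = design[design["tissue"] == tissue]
    expressed: set[str] = set()
    for _, grp in d.groupby("nacl_mM"):
        if len(grp) < 2:
            raise ValueError(f"condition with fewer than 2 replicates in {tissue}")
        sub = counts[list(grp["sample"])]
        ok = (sub > min_reads).all(axis=1)
        expressed.update(counts.index[ok])
    return expressed


def _te_gene_geometry(te: TECopy, g: GeneModel, max_distance: int):
    """(relation, distance) for one TE-gene pair, or None when unrelated."""
    if te.chrom != g.chrom:
        return None
    for s, e in g.introns:
        if s <= te.start and te.end <= e:
            return "intron", 0
    gap = max(g.start - te.end, te.start - g.end, 0)
    if gap > max_distance:
        return None
    te_before = te.end <= g.start or (
        not te.start >= g.end and (te.start + te.end) <= (g.start + g.end)
    )
    if g.strand == "+":
        relation = "upstream" if te_before else "downstream"
    else:
        relation = "downstream" if te_before else "upstream"
    return relation, gap


def find_flanking_pairs(
    tes: list[TECopy], genes: list[GeneModel], max_distance: int = FLANK_DISTANCE
) -> pd.DataFrame:
    """TE-gene candidate pairs: gene within ``max_distance`` bp of the TE's
    nearest edge, or the TE fully inside an intron (relation "intron",
    distance 0, taking priority over the distance rule). Relation labels the
    TE's position relative to the gene, strand-aware.
    """
    rows = []
    for te in tes:
        for g in genes:
            hit = _te_gene_geometry(te, g, max_distance)
            if hit is None:
                continue
            relation, dist = hit
            rows.append(
                {
                    "te_id": te.copy_id,
                    "gene_id": g.gene_id,
                    "relation": relation,
                    "distance": dist,
                }
            )
    return pd.DataFrame(rows, columns=["te_id", "gene_id", "relation", "distance"])


def _size_factors(counts: pd.DataFrame) -> pd.Series:
    """Median-of-ratios size factors; total-count fallback when every feature
    row contains a zero."""
    arr = counts.to_numpy(dtype=float)
    ok = (arr > 0).all(axis=1)
    if ok.sum() == 0:
        tot = counts.sum(axis=0).astype(float)
        return tot / np.exp(np.log(tot).mean())
    log_arr = np.log(arr[ok])
    log_geo = log_arr.mean(axis=1)
    sf = np.exp(np.median(log_arr - log_geo[:, None], axis=0))
    return pd.Series(sf, index=counts.columns)


def differential_expression(
    counts: pd.DataFrame,
    design: pd.DataFrame,
    cond_a: int,
    cond_b: int,
    tissue: str | None = None,
    alpha: float = FDR_ALPHA,
    lfc_threshold: float = LFC_THRESHOLD,
) -> pd.DataFrame:
    """Negative-binomial Wald test between two salt conditions.

    Normalizes by median-of-ratios size factors, estimates a per-feature
    dispersion by method of moments pooled across the two groups (floored at
    1e-8), forms a Wald statistic on the log2 ratio of normalized group
    means (delta method; pseudocount 0.5 when a mean is zero), and adjusts
    with Benjamini-Hochberg. ``significant`` requires FDR < ``alpha`` and
    |log2FC| >= ``lfc_threshold``. All-zero features are excluded.
    """
    d = design
    if tissue is not None:
        d = d[d["tissue"] == tissue]
    sa = list(d[d["nacl_mM"] == cond_a]["sample"])
    sb = list(d[d["nacl_mM"] == cond_b]["sample"])
    if len(sa) < 2 or len(sb) < 2:
        raise ValueError("need >= 2 replicates per group")
    sub = counts[sa + sb]
    sub = sub[(sub.sum(axis=1) > 0)]
    sf = _size_factors(sub)
    norm = sub.div(sf, axis=1)
    a = norm[sa].to_numpy(dtype=float)
    b = norm[sb].to_numpy(dtype=float)
    na, nb = a.shape[1], b.shape[1]
    ma, mb = a.mean(axis=1), b.mean(axis=1)
    va = a.var(axis=1, ddof=1)
    vb = b.var(axis=1, ddof=1)

    # pooled method-of-moments NB dispersion: var = mu + alpha mu^2
    with np.errstate(divide="ignore", invalid="ignore"):
        aa = np.where(ma > 0, (va - ma) / ma**2, np.nan)
        ab = np.where(mb > 0, (vb - mb) / mb**2, np.nan)
    disp = np.nanmean(np.column_stack([aa, ab]), axis=1)
    disp = np.where(np.isnan(disp), DISPERSION_FLOOR, disp)
    disp = np.maximum(disp, DISPERSION_FLOOR)

    zero = (ma == 0) | (mb == 0)
    with np.errstate(divide="ignore"):
        lfc = np.where(
            zero,
            np.log2((ma + PSEUDOCOUNT) / (mb + PSEUDOCOUNT)),
            np.log2(np.where(ma > 0, ma, 1.0) / np.where(mb > 0, mb, 1.0)),
        )
    ma_s = np.maximum(ma, PSEUDOCOUNT)
    mb_s = np.maximum(mb, PSEUDOCOUNT)
    var_ma = (ma_s + disp * ma_s**2) / na
    var_mb = (mb_s + disp * mb_s**2) / nb
    se_log2 = np.sqrt(var_ma / ma_s**2 + var_mb / mb_s**2) / np.log(2)
    z = lfc / se_log2
    p = 2.0 * _st.norm.sf(np.abs(z))
    padj = bh_adjust(p)
    return pd.DataFrame(
        {
            "feature_id": sub.index,
            "comparison": f"{cond_a}_vs_{cond_b}" + (f"_{tissue}" if tissue else ""),
            "base_mean_a": ma,
            "base_mean_b": mb,
            "log2fc": lfc,
            "pvalue": p,
            "padj": padj,
            "significant": (padj < alpha) & (np.abs(lfc) >= lfc_threshold),
        }
    ).set_index("feature_id")


def enrichment_test(
    n_de_adjacent: int, n_adjacent: int, n_de_total: int, n_total: int
) -> tuple[float, float]:
    """Fisher exact test: are TE-adjacent genes enriched in mis-expressed ones?

    Contingency table: [DE adjacent, non-DE adjacent] vs
    [DE elsewhere, non-DE elsewhere]. Returns (odds ratio, two-sided p).
    """
    if not (0 <= n_de_adjacent <= n_adjacent <= n_total and n_de_adjacent <= n_de_total <= n_total):
        raise ValueError("inconsistent contingency margins")
    n11 = n_de_adjacent
    n12 = n_adjacent - n_de_adjacent
    n21 = n_de_total - n_de_adjacent
    n22 = (n_total - n_adjacent) - n21
    if n22 < 0:
        raise ValueError("inconsistent contingency margins")
    return fisher_exact_test(n11, n12, n21, n22)


def correlate_pairs(
    te_expr: pd.DataFrame,
    gene_expr: pd.DataFrame,
    design: pd.DataFrame,
    pairs: pd.DataFrame,
    tissue: str,
    mode: str = "means",
    expressed_tes: set[str] | None = None,
    expressed_genes: set[str] | None = None,
    alpha: float = FDR_ALPHA,
) -> pd.DataFrame:
    """Pearson correlation between TE and flanking-gene expression.

    In ``means`` mode (primary) each feature is reduced to its per-condition
    mean expression in the tissue (n = 3 salt conditions); ``replicates``
    mode uses the individual samples (n = 6). Pairs whose members are not in
    the expressed sets are skipped; zero-variance vectors are reported as
    untestable (NaN statistics). p-values are BH-adjusted over the tested
    pairs of the tissue.
    """
    if mode not in ("means", "replicates"):
        raise ValueError(f"unknown mode {mode!r}")
    d = design[design["tissue"] == tissue].sort_values(["nacl_mM", "replicate"])
    conditions = sorted(d["nacl_mM"].unique())
    if len(conditions) < 3:
        raise ValueError("need >= 3 salt conditions")

    def profile(expr: pd.DataFrame, fid: str) -> np.ndarray | None:
        if fid not in expr.index:
            return None
        if mode == "means":
            return np.array(
                [expr.loc[fid, list(d[d["nacl_mM"] == c]["sample"])].mean() for c in conditions]
            )
        return expr.loc[fid, list(d["sample"])].to_numpy(dtype=float)

    rows = []
    for rec in pairs.itertuples(index=False):
        te_id, gene_id = rec.te_id, rec.gene_id
        if expressed_tes is not None and te_id not in expressed_tes:
            continue
        if expressed_genes is not None and gene_id not in expressed_genes:
            continue
        x = profile(te_expr, te_id)
        y = profile(gene_expr, gene_id)
        if x is None or y is None:
            continue
        row = {
            "te_id": te_id,
            "gene_id": gene_id,
            "relation": getattr(rec, "relation", ""),
            "distance": getattr(rec, "distance", np.nan),
            "tissue": tissue,
        }
        if np.std(x) == 0 or np.std(y) == 0:
            row.update({"r": np.nan, "pvalue": np.nan, "testable": False})
        else:
            r, p = _st.pearsonr(x, y)
            row.update({"r": float(r), "pvalue": float(p), "testable": True})
        rows.append(row)
    out = pd.DataFrame(
        rows,
        columns=["te_id", "gene_id", "relation", "distance", "tissue", "r", "pvalue", "testable"],
    )
    if len(out):
        out["padj"] = bh_adjust(out["pvalue"])
        out["significant"] = out["padj"] < alpha
    else:
        out["padj"] = pd.Series(dtype=float)
        out["significant"] = pd.Series(dtype=bool)
    return out


def _best_local_match(seq_a: str, seq_b: str):
    """Best local alignment (sense strands as given); returns
    (a_start, a_end, length, identity) of the aligned block or None."""
    aligner = Align.PairwiseAligner()
    aligner.mode = "local"
    aligner.match_score = 2
    aligner.mismatch_score = -3
    aligner.open_gap_score = -5
    aligner.extend_gap_score = -2
    alns = aligner.align(seq_a, seq_b)
    if len(alns) == 0 or alns.score <= 0:
        return None
    aln = alns[0]
    a_start, a_end = int(aln.aligned[0][0][0]), int(aln.aligned[0][-1][1])
    cols_a, cols_b = str(aln[0]), str(aln[1])
    n_cols = len(cols_a)
    ident = sum(x == y for x, y in zip(cols_a, cols_b)) / n_cols
    return a_start, a_end, n_cols, ident


def screen_sponge_pairs(
    te_sequences: dict[str, str],
    transcript_sequences: dict[str, str],
    mirna_targets: pd.DataFrame,
    expressed_tes: set[str],
    expressed_genes: set[str],
    min_match: int = 20,
    min_identity: float = 0.9,
) -> pd.DataFrame:
    """miRNA-sponge candidates: TE-gene pairs sharing a miRNA and a
    sense-orientation sequence match covering the TE's binding site.

    ``mirna_targets`` columns: mirna_id, feature_id, start, end (binding
    interval on the feature, 0-based half-open; expectation-score filtering
    is upstream). A candidate requires (i) the same miRNA predicted on both
    a TE and a transcript, (ii) a same-strand local match of >= ``min_match``
    nt at >= ``min_identity`` identity between the two sequences whose
    TE-side span covers the TE binding site, and (iii) both features in the
    expressed sets. Antisense matches are never considered: sequences are
    compared exactly as given.
    """
    needed = set(mirna_targets["feature_id"])
    missing = needed - set(te_sequences) - set(transcript_sequences)
    if missing:
        raise ValueError(f"sequences missing for target-table features: {sorted(missing)}")
    te_hits = mirna_targets[mirna_targets["feature_id"].isin(te_sequences)]
    gene_hits = mirna_targets[mirna_targets["feature_id"].isin(transcript_sequences)]
    rows = []
    for mirna in sorted(set(te_hits["mirna_id"]) & set(gene_hits["mirna_id"])):
        for t in te_hits[te_hits["mirna_id"] == mirna].itertuples(index=False):
            if t.feature_id not in expressed_tes:
                continue
            for g in gene_hits[gene_hits["mirna_id"] == mirna].itertuples(index=False):
                if g.feature_id not in expressed_genes:
                    continue
                hit = _best_local_match(
                    te_sequences[t.feature_id], transcript_sequences[g.feature_id]
                )
                if hit is None:
                    continue
                a_start, a_end, length, ident = hit
                if length < min_match or ident < min_identity:
                    continue
                if not (a_start <= t.start and t.end <= a_end):
                    continue  # binding site outside the matched block
                rows.append(
                    {
                        "mirna_id": mirna,
                        "te_id": t.feature_id,
                        "gene_id": g.feature_id,
                        "match_length": length,
                        "match_identity": ident,
                        "te_site": (int(t.start), int(t.end)),
                    }
                )
    return pd.DataFrame(
        rows,
        columns=["mirna_id", "te_id", "gene_id", "match_length", "match_identity", "te_site"],
    )
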