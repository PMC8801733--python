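"""End-to-end orchestration: dating -> genomic context -> epigenome ->
expression screen, with TSV/JSON reporting.

Every stage writes one TSV; ``report.json`` aggregates stage summaries and
records the tool version, a hash of the configuration and the random seed
for provenance. The report layer only formats numbers computed by the
stages.
"""
from __future__ import annotations

import hashlib
import json
from dataclasses import asdict, dataclass
from pathlib import Path

import numpy as np
import pandas as pd

from . import __version__
from . import context as ctx
from . import dating, epigenome, io, screen
from .simulate import SimConfig, make_design, simulate_counts, simulate_genome, \
    simulate_methylome, simulate_sirna

REPORT_FILES = (
    "dating.tsv",
    "insertion_summary.tsv",
    "solo_intact.tsv",
    "copy_context.tsv",
    "repression.tsv",
    "differential_expression.tsv",
    "te_gene_pairs.tsv",
)


@dataclass
class PipelineConfig:
    """All pipeline inputs and thresholds; defaults are the study settings."""

    outdir: str = "ltrdyn_out"
    # inputs (None + simulate=True generates them)
    genome_fasta: str | None = None
    genes_gff3: str | None = None
    tes_gff3: str | None = None
    methylation_tsv: str | None = None
    sirna_bed: str | None = None
    te_counts_tsv: str | None = None
    gene_counts_tsv: str | None = None
    design_tsv: str | None = None
    simulate: bool = True
    # parameters
    substitution_rate: float = 1.3e-8   # substitutions/site/year
    young_myr: float = 1.0              # "young" age threshold, Myr
    window: int = 100_000
    step: int = 50_000
    gene_poor: float = 0.05
    min_coverage: int = 4
    sirna_length: int = 24
    min_reads: int = 5
    flank_distance: int = 3_000
    fdr_alpha: float = 0.05
    lfc_threshold: float = 1.0          # log2 of the 2-fold rule
    correlation_mode: str = "means"
    min_scaffold: int = 0
    seed: int = 0

    def config_hash(self) -> str:
        payload = json.dumps(asdict(self), sort_keys=True, default=str)
        return hashlib.sha256(payload.encode()).hexdigest()[:16]

    @classmethod
    def from_yaml(cls, path) -> "PipelineConfig":
        data = io.load_yaml_config(path)
        unknown = set(data) - set(cls.__dataclass_fields__)
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        return cls(**data)


REPORT_SCHEMA: dict[str, type] = {
    "version": str,
    "config_hash": str,
    "seed": int,
    "thresholds": dict,
    "age_summary": dict,
    "solo_intact": list,
    "repression": list,
    "de_counts": dict,
    "enrichment": list,
    "significant_pairs": list,
}


def validate_report(report: dict) -> None:
    """Check the report against the shipped schema (required keys + types)."""
    for key, typ in REPORT_SCHEMA.items():
        if key not in report:
            raise ValueError(f"report missing required key {key!r}")
        if not isinstance(report[key], typ):
            raise ValueError(f"report key {key!r} has type {type(report[key]).__name__}, "
                             f"expected {typ.__name__}")


def _simulate_inputs(cfg: PipelineConfig, outdir: Path) -> dict[str, Path]:
    sim = SimConfig(seed=cfg.seed)
    genome, genes, copies, truth = simulate_genome(sim)
    rng = np.random.default_rng(sim.seed + 1)
    sites = simulate_methylome(genome, copies, truth, sim.coverage_lambda, rng)
    sirna, _ = simulate_sirna(copies, truth, sim.multimap_fraction, rng,
                              read_length=sim.sirna_length)
    design = make_design()
    gene_cm, te_cm, truth = simulate_counts(copies, genes, design, sim, truth, rng)
    paths = {k: outdir / v for k, v in {
        "genome_fasta": "genome.fa", "genes_gff3": "genes.gff3",
        "tes_gff3": "tes.gff3", "methylation_tsv": "methylation.tsv",
        "sirna_bed": "sirna.bed", "te_counts_tsv": "te_counts.tsv",
        "gene_counts_tsv": "gene_counts.tsv", "design_tsv": "design.tsv"}.items()}
    io.write_fasta(genome, paths["genome_fasta"])
    io.write_genes_gff3(genes, paths["genes_gff3"])
    io.write_tes_gff3(copies, paths["tes_gff3"])
    io.write_methylation_tsv(sites, paths["methylation_tsv"])
    io.write_sirna_bed(sirna, paths["sirna_bed"])
    io.write_counts_tsv(te_cm.counts, paths["te_counts_tsv"])
    io.write_counts_tsv(gene_cm.counts, paths["gene_counts_tsv"])
    io.write_design_tsv(design, paths["design_tsv"])
    io.write_truth_json(truth, outdir / "truth.json")
    return paths


def run_pipeline(cfg: PipelineConfig) -> Path:
    """Run every stage and write the per-stage TSVs plus ``report.json``.

    Returns the report directory. A stage failure aborts with an exception
    naming the stage.
    """
    outdir = Path(cfg.outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    if cfg.simulate:
        paths = _simulate_inputs(cfg, outdir)
        inputs = {k: str(v) for k, v in paths.items()}
    else:
        inputs = {k: getattr(cfg, k) for k in (
            "genome_fasta", "genes_gff3", "tes_gff3", "methylation_tsv",
            "sirna_bed", "te_counts_tsv", "gene_counts_tsv", "design_tsv")}
        missing = [k for k, v in inputs.items() if v is None]
        if missing:
            raise ValueError(f"missing inputs (and simulate=False): {missing}")

    report: dict = {
        "version": __version__,
        "config_hash": cfg.config_hash(),
        "seed": cfg.seed,
        "thresholds": {k: getattr(cfg, k) for k in (
            "substitution_rate", "young_myr", "window", "step", "gene_poor",
            "min_coverage", "sirna_length", "min_reads", "flank_distance",
            "fdr_alpha", "lfc_threshold", "correlation_mode")},
    }

    def stage(name):
        def wrap(fn):
            try:
                return fn()
            except Exception as exc:
                raise RuntimeError(f"pipeline stage {name!r} failed: {exc}") from exc
        return wrap

    genome, genes, copies = stage("load_annotation")(
        lambda: io.load_annotation(inputs["genome_fasta"], inputs["genes_gff3"],
                                   inputs["tes_gff3"]))
    chrom_lengths = {c: len(s) for c, s in genome.items()
                     if len(s) >= cfg.min_scaffold}
    genes = [g for g in genes if g.chrom in chrom_lengths]
    copies = [t for t in copies if t.chrom in chrom_lengths]

    # --- dating ----------------------------------------------------------
    def _dating():
        est = dating.date_copies(copies, genome, rate=cfg.substitution_rate)
        recent = set(dating.flag_recent_insertions(copies, genome))
        meta = {t.copy_id: t for t in copies}
        df = pd.DataFrame([{
            "copy_id": e.copy_id, "family": meta[e.copy_id].family,
            "superfamily": meta[e.copy_id].superfamily, "n_sites": e.n_sites,
            "P": e.P, "Q": e.Q, "k": e.k, "age_years": e.age,
            "saturated": e.saturated, "recent_flag": e.copy_id in recent,
        } for e in est])
        summaries = {}
        young = cfg.young_myr * 1e6
        for sf in sorted({meta[e.copy_id].superfamily for e in est}):
            sub = [e for e in est if meta[e.copy_id].superfamily == sf
                   and not e.saturated]
            if sub:
                s = dating.summarize_ages(sub, young_threshold=young)
                summaries[sf] = {"median_age_myr": s.median_age / 1e6,
                                 "young_fraction": s.young_fraction, "n": s.n}
        return est, df, summaries

    estimates, dating_df, report["age_summary"] = stage("dating")(_dating)

    # --- genomic context -------------------------------------------------
    def _context():
        windows = ctx.gene_density_windows(genes, chrom_lengths, cfg.window, cfg.step)
        summary = ctx.insertion_summary(copies, genes, chrom_lengths)
        per_copy = ctx.per_copy_context(copies, genes, windows, cfg.gene_poor)
        si = ctx.solo_intact_ratio(copies)
        return windows, summary, per_copy, si

    windows, ins_summary, per_copy, solo_intact = stage("genome_context")(_context)
    report["solo_intact"] = [
        {k: (None if pd.isna(v) else v) for k, v in row.items()}
        for row in solo_intact.to_dict("records")]

    # --- epigenome -------------------------------------------------------
    def _epigenome():
        sites = io.read_methylation_tsv(inputs["methylation_tsv"])
        sirna = io.read_sirna_bed(inputs["sirna_bed"])
        intact = [t for t in copies if t.status == "intact"]
        meth = epigenome.elements_methylation(sites, intact, cfg.min_coverage)
        dens = epigenome.elements_sirna_density(sirna, intact, cfg.sirna_length)
        tbl = meth.merge(dens, on="copy_id").merge(
            per_copy[["copy_id", "gene_density", "gene_poor"]], on="copy_id")
        rows = []
        for metric in ("CHH_level", "sirna_density"):
            vals, gd = tbl[metric].to_numpy(), tbl["gene_density"].to_numpy()
            try:
                mp, mo, u, p = epigenome.compare_repression(vals, gd, cfg.gene_poor)
                rows.append({"metric": metric, "median_gene_poor": mp,
                             "median_other": mo, "U": u, "pvalue": p})
            except ValueError as exc:
                rows.append({"metric": metric, "median_gene_poor": float("nan"),
                             "median_other": float("nan"), "U": float("nan"),
                             "pvalue": float("nan"), "note": str(exc)})
        return tbl, pd.DataFrame(rows), rows

    epi_tbl, repression_df, report["repression"] = stage("epigenome")(_epigenome)

    # --- expression screen ----------------------------------------------
    def _screen():
        te_counts = io.read_counts_tsv(inputs["te_counts_tsv"])
        gene_counts = io.read_counts_tsv(inputs["gene_counts_tsv"])
        design = io.read_design_tsv(inputs["design_tsv"])
        te_meta = {t.copy_id: t for t in copies}
        te_lengths = pd.Series({i: te_meta[i].length for i in te_counts.index
                                if i in te_meta})
        gene_meta = {g.gene_id: g for g in genes}
        gene_lengths = pd.Series(
            {i: sum(e - s for s, e in gene_meta[i].exons) for i in gene_counts.index
             if i in gene_meta})
        te_counts = te_counts.loc[te_lengths.index]
        gene_counts = gene_counts.loc[gene_lengths.index]
        te_expr = screen.te_expression(te_counts, te_lengths)
        gene_expr = screen.rpkm_matrix(gene_counts, gene_lengths,
                                       gene_counts.sum(axis=0))
        tissues = sorted(design["tissue"].unique())
        conditions = sorted(design["nacl_mM"].unique())
        control = conditions[len(conditions) // 2]
        de_frames, de_counts, enrichment = [], {}, []
        pairs = screen.find_flanking_pairs(
            [t for t in copies if t.status in ("intact", "truncated")],
            genes, cfg.flank_distance)
        pair_frames = []
        for tissue in tissues:
            expr_te = screen.filter_expressed(te_counts, design, tissue, cfg.min_reads)
            expr_gene = screen.filter_expressed(gene_counts, design, tissue, cfg.min_reads)
            de_gene_sig: set[str] = set()
            for cond in conditions:
                if cond == control:
                    continue
                for label, counts in (("te", te_counts), ("gene", gene_counts)):
                    de = screen.differential_expression(
                        counts, design, cond, control, tissue,
                        cfg.fdr_alpha, cfg.lfc_threshold)
                    de = de.reset_index()
                    de["feature_set"] = label
                    de_frames.append(de)
                    key = f"{label}_{tissue}_{cond}_vs_{control}"
                    de_counts[key] = int(de["significant"].sum())
                    if label == "gene":
                        de_gene_sig |= set(de.loc[de["significant"], "feature_id"])
            adjacent = set(pairs["gene_id"])
            n_total = len(gene_counts)
            n_adj = len(adjacent & set(gene_counts.index))
            n_de = len(de_gene_sig)
            n_de_adj = len(de_gene_sig & adjacent)
            orr, p = screen.enrichment_test(n_de_adj, n_adj, n_de, n_total)
            enrichment.append({"tissue": tissue, "n_de_adjacent": n_de_adj,
                               "n_adjacent": n_adj, "n_de_total": n_de,
                               "n_total": n_total, "odds_ratio": orr, "pvalue": p})
            pair_frames.append(screen.correlate_pairs(
                te_expr, gene_expr, design, pairs, tissue, cfg.correlation_mode,
                expr_te, expr_gene, cfg.fdr_alpha))
        de_df = pd.concat(de_frames, ignore_index=True)
        pairs_df = pd.concat(pair_frames, ignore_index=True)
        return de_df, de_counts, enrichment, pairs_df

    de_df, report["de_counts"], report["enrichment"], pairs_df = stage("screen")(_screen)
    sig = pairs_df[pairs_df["significant"] == True]  # noqa: E712
    report["significant_pairs"] = [
        {"te_id": r.te_id, "gene_id": r.gene_id, "tissue": r.tissue,
         "r": round(float(r.r), 3), "padj": float(r.padj)}
        for r in sig.itertuples(index=False)]

    write_report(outdir, dating_df=dating_df, insertion_summary=ins_summary,
                 solo_intact=solo_intact, copy_context=per_copy.merge(
                     epi_tbl.drop(columns=["gene_density", "gene_poor"]),
                     on="copy_id", how="left"),
                 repression=repression_df, differential_expression=de_df,
                 te_gene_pairs=pairs_df, windows=windows, report=report)
    return outdir


def write_report(outdir: Path, *, dating_df, insertion_summary, solo_intact,
                 copy_context, repression, differential_expression,
                 te_gene_pairs, windows, report) -> None:
    """Write stage TSVs (stable column order, fixed float precision), the
    windows BED4 and the validated JSON report."""
    outdir = Path(outdir)
    fmt = "%.6g"
    dating_df.to_csv(outdir / "dating.tsv", sep="\t", index=False, float_format=fmt)
    insertion_summary.to_csv(outdir / "insertion_summary.tsv", sep="\t",
                             index=False, float_format="%.4f")
    si = solo_intact.copy()
    si["ratio"] = si["ratio"].map(lambda x: f"{x:.2f}" if pd.notna(x) else "NA")
    si.to_csv(outdir / "solo_intact.tsv", sep="\t", index=False)
    copy_context.to_csv(outdir / "copy_context.tsv", sep="\t", index=False,
                        float_format="%.3f")
    rep = repression.copy()
    if "pvalue" in rep:
        rep["pvalue"] = rep["pvalue"].map(
            lambda x: f"{x:.3e}" if pd.notna(x) else "NA")
    rep.to_csv(outdir / "repression.tsv", sep="\t", index=False, float_format="%.3f")
    differential_expression.to_csv(outdir / "differential_expression.tsv", sep="\t",
                                   index=False, float_format=fmt)
    te_gene_pairs.to_csv(outdir / "te_gene_pairs.tsv", sep="\t", index=False,
                         float_format=fmt)
    with open(outdir / "windows.bed", "w") as fh:
        for w in windows:
            fh.write(f"{w.chrom}\t{w.start}\t{w.end}\t{w.cds_fraction:.4f}\n")
    validate_report(report)
    with open(outdir / "report.json", "w") as fh:
        json.dump(report, fh, indent=1, sort_keys=True)
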