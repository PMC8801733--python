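"""File I/O for the standard formats the pipeline consumes and emits.

GFF3 on disk is 1-based closed; BED is 0-based half-open; internal
coordinates are 0-based half-open everywhere. TE attributes carried in GFF3
column 9: ID, Family, Superfamily, Status, LTR5, LTR3 (1-based closed
"start-end" sub-intervals), TSD5, TSD3.
"""
from __future__ import annotations

import json
from dataclasses import asdict

import pandas as pd
import yaml
from pyfaidx import Fasta

from .models import GeneModel, TECopy
from .simulate import PlantedPair, SimTruth

_WRAP = 60


# ---------------------------------------------------------------------------
# FASTA

def write_fasta(genome: dict[str, str], path) -> None:
    with open(path, "w") as fh:
        for name, seq in genome.items():
            fh.write(f">{name}\n")
            for i in range(0, len(seq), _WRAP):
                fh.write(seq[i : i + _WRAP] + "\n")


def read_fasta(path) -> dict[str, str]:
    fa = Fasta(str(path))
    return {name: str(fa[name][:]).upper() for name in fa.keys()}


# ---------------------------------------------------------------------------
# GFF3

def _fmt_attrs(attrs: dict[str, str]) -> str:
    return ";".join(f"{k}={v}" for k, v in attrs.items() if v is not None)


def _parse_attrs(col9: str) -> dict[str, str]:
    out = {}
    for item in col9.strip().split(";"):
        if not item:
            continue
        if "=" not in item:
            raise ValueError(f"malformed GFF3 attribute {item!r}")
        k, v = item.split("=", 1)
        out[k] = v
    return out


def write_genes_gff3(genes: list[GeneModel], path) -> None:
    with open(path, "w") as fh:
        fh.write("##gff-version 3\n")
        for g in genes:
            fh.write(f"{g.chrom}\tltrdyn\tgene\t{g.start + 1}\t{g.end}\t.\t{g.strand}\t.\t"
                     + _fmt_attrs({"ID": g.gene_id}) + "\n")
            mrna = f"{g.gene_id}.t1"
            fh.write(f"{g.chrom}\tltrdyn\tmRNA\t{g.start + 1}\t{g.end}\t.\t{g.strand}\t.\t"
                     + _fmt_attrs({"ID": mrna, "Parent": g.gene_id}) + "\n")
            for s, e in g.exons:
                fh.write(f"{g.chrom}\tltrdyn\texon\t{s + 1}\t{e}\t.\t{g.strand}\t.\t"
                         + _fmt_attrs({"Parent": mrna}) + "\n")
            for s, e in g.cds:
                fh.write(f"{g.chrom}\tltrdyn\tCDS\t{s + 1}\t{e}\t.\t{g.strand}\t0\t"
                         + _fmt_attrs({"Parent": mrna}) + "\n")


def read_genes_gff3(path) -> list[GeneModel]:
    spans: dict[str, dict] = {}
    mrna_to_gene: dict[str, str] = {}
    for line in open(path):
        if line.startswith("#") or not line.strip():
            continue
        f = line.rstrip("\n").split("\t")
        if len(f) != 9:
            raise ValueError(f"malformed GFF3 row: {line!r}")
        chrom, _, ftype, start, end, _, strand, _, col9 = f
        attrs = _parse_attrs(col9)
        s, e = int(start) - 1, int(end)
        if ftype == "gene":
            gid = attrs["ID"]
            spans[gid] = {"chrom": chrom, "strand": strand, "start": s, "end": e,
                          "exons": [], "cds": []}
        elif ftype == "mRNA":
            mrna_to_gene[attrs["ID"]] = attrs["Parent"]
        elif ftype in ("exon", "CDS"):
            gid = mrna_to_gene.get(attrs["Parent"], attrs["Parent"])
            if gid not in spans:
                raise ValueError(f"{ftype} with unknown parent {attrs['Parent']}")
            spans[gid]["exons" if ftype == "exon" else "cds"].append((s, e))
    return [GeneModel(gene_id=gid, **info) for gid, info in spans.items()]


_STATUS_TYPE = {
    "intact": "LTR_retrotransposon",
    "truncated": "transposable_element_fragment",
    "solo_LTR": "solo_LTR",
}
_TYPE_STATUS = {v: k for k, v in _STATUS_TYPE.items()}


def write_tes_gff3(copies: list[TECopy], path) -> None:
    def iv(interval):
        return f"{interval[0] + 1}-{interval[1]}" if interval else None

    with open(path, "w") as fh:
        fh.write("##gff-version 3\n")
        for te in copies:
            attrs = {
                "ID": te.copy_id,
                "Family": te.family,
                "Superfamily": te.superfamily,
                "Status": te.status,
                "LTR5": iv(te.ltr5),
                "LTR3": iv(te.ltr3),
                "TSD5": te.tsd5,
                "TSD3": te.tsd3,
            }
            fh.write(
                f"{te.chrom}\tltrdyn\t{_STATUS_TYPE[te.status]}\t{te.start + 1}\t{te.end}"
                f"\t.\t{te.strand}\t.\t" + _fmt_attrs(attrs) + "\n")


def read_tes_gff3(path) -> list[TECopy]:
    def iv(text):
        if text is None:
            return None
        a, b = text.split("-")
        return int(a) - 1, int(b)

    copies = []
    for line in open(path):
        if line.startswith("#") or not line.strip():
            continue
        f = line.rstrip("\n").split("\t")
        if len(f) != 9:
            raise ValueError(f"malformed GFF3 row: {line!r}")
        chrom, _, _, start, end, _, strand, _, col9 = f
        attrs = _parse_attrs(col9)
        if "Status" not in attrs:
            raise ValueError(f"TE record {attrs.get('ID', '?')} missing Status attribute")
        copies.append(TECopy(
            copy_id=attrs["ID"], family=attrs["Family"], superfamily=attrs["Superfamily"],
            chrom=chrom, start=int(start) - 1, end=int(end), strand=strand,
            status=attrs["Status"], ltr5=iv(attrs.get("LTR5")), ltr3=iv(attrs.get("LTR3")),
            tsd5=attrs.get("TSD5"), tsd3=attrs.get("TSD3")))
    return copies


# ---------------------------------------------------------------------------
# methylation / siRNA / counts

def write_methylation_tsv(sites: pd.DataFrame, path) -> None:
    out = sites.copy()
    out["pos"] = out["pos"].astype(int) + 1  # 1-based on disk
    out.to_csv(path, sep="\t", index=False)


def read_methylation_tsv(path) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t", dtype={"chrom": str})
    df["pos"] = df["pos"].astype(int) - 1
    return df


def write_sirna_bed(alignments: pd.DataFrame, path) -> None:
    with open(path, "w") as fh:
        for rec in alignments.itertuples(index=False):
            fh.write(f"{rec.chrom}\t{rec.pos}\t{rec.pos + rec.length}\t{rec.read_id}"
                     f"\t0\t+\t{rec.length}\t{rec.n_hits}\n")


def read_sirna_bed(path) -> pd.DataFrame:
    df = pd.read_csv(
        path, sep="\t", header=None,
        names=["chrom", "pos", "end", "read_id", "score", "strand", "length", "n_hits"],
        dtype={"chrom": str})
    return df[["read_id", "chrom", "pos", "length", "n_hits"]]


def write_counts_tsv(counts: pd.DataFrame, path) -> None:
    counts.to_csv(path, sep="\t", index_label="feature_id")


def read_counts_tsv(path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t", index_col="feature_id")


def write_design_tsv(design: pd.DataFrame, path) -> None:
    design.to_csv(path, sep="\t", index=False)


def read_design_tsv(path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t")


# ---------------------------------------------------------------------------
# truth JSON

def write_truth_json(truth: SimTruth, path) -> None:
    payload = asdict(truth)
    with open(path, "w") as fh:
        json.dump(payload, fh, indent=1, sort_keys=True)


def read_truth_json(path) -> SimTruth:
    payload = json.load(open(path))
    payload["planted_pairs"] = [PlantedPair(**p) for p in payload.get("planted_pairs", [])]
    return SimTruth(**payload)


# ---------------------------------------------------------------------------
# annotation bundle

def load_annotation(genome_fasta, genes_gff3, tes_gff3):
    """Load and cross-validate genome + gene models + TE copies.

    Checks that every feature's chromosome exists, coordinates fit the
    sequence, and LTR sub-intervals of intact copies lie inside their copy
    (the TECopy constructor enforces the latter). Returns
    ``(genome, genes, copies)`` in internal 0-based half-open coordinates.
    """
    genome = read_fasta(genome_fasta)
    genes = read_genes_gff3(genes_gff3)
    copies = read_tes_gff3(tes_gff3)
    for g in genes:
        if g.chrom not in genome:
            raise ValueError(f"gene {g.gene_id}: unknown chromosome {g.chrom}")
        if g.end > len(genome[g.chrom]):
            raise ValueError(f"gene {g.gene_id}: coordinates beyond chromosome end")
    for te in copies:
        if te.chrom not in genome:
            raise ValueError(f"TE {te.copy_id}: unknown chromosome {te.chrom}")
        if te.end > len(genome[te.chrom]):
            raise ValueError(f"TE {te.copy_id}: coordinates beyond chromosome end")
    return genome, genes, copies


def load_yaml_config(path) -> dict:
    with open(path) as fh:
        data = yaml.safe_load(fh) or {}
    if not isinstance(data, dict):
        raise ValueError("config file must contain a mapping")
    return data
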