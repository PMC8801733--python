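"""Synthetic genomes, annotations, methylomes, siRNA alignments and count
matrices with the statistical structure the downstream analyses assume.

The generator plants known quantities and records them in a
:class:`SimTruth`, so every stage of the pipeline can be checked by
parameter recovery:

* LTR pairs of intact copies diverge from a common ancestral LTR under a
  per-site Kimura two-parameter substitution process (Poisson number of
  events per site per branch), so the dating model is the exact inverse of
  the generator.
* Chromosomes are designated gene-poor (no genes; every 100-kb window has
  coding fraction < 0.05) or gene-dense (regularly spaced gene models;
  every window >= 0.15), making the gene-poor threshold deterministic.
* Methylation counts are binomial around per-context probabilities that
  differ between gene-poor and gene-rich residents; coverage is Poisson.
* siRNA reads are placed inside elements at a per-group rate; a configured
  fraction multimaps among same-family copies.
* Expression counts are negative-binomial; planted TE-gene pairs share a
  salt-condition-dependent mean shift with a chosen sign.
"""
from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional

import numpy as np
import pandas as pd

from .models import GeneModel, TECopy

BASES = np.array(list("ACGT"))
_TRANSITION = {"A": "G", "G": "A", "C": "T", "T": "C"}
_TRANSVERSIONS = {"A": "CT", "G": "CT", "C": "AG", "T": "AG"}

# gene architecture of the simulator: two exons around one large intron, so
# that an intact element (default 3 kb) fits entirely inside the intron
GENE_EXON1 = 1000
GENE_INTRON = 3100
GENE_EXON2 = 1000
GENE_SPAN = GENE_EXON1 + GENE_INTRON + GENE_EXON2  # 5100
TSD_LEN = 5


@dataclass
class FamilyConfig:
    """Copy counts and placement preference for one TE family."""

    superfamily: str
    n_intact: int = 10
    n_truncated: int = 4
    n_solo: int = 4
    gene_poor_fraction: float = 0.5  # fraction of copies placed in gene-poor chromatin
    p_intron: float = 0.05           # placement probability: resident in an intron
    p_coding: float = 0.05           # placement probability: overlapping a CDS


@dataclass
class SimConfig:
    """Study conditions of the synthetic dataset.

    Defaults emulate the analysed system: a genome split between gene-dense
    and gene-poor (heterochromatin-like) compartments, two chromodomain-type
    Gypsy families preferring gene-poor regions plus one Copia family,
    r = 1.3e-8 substitutions/site/year, a CHH methylation contrast of
    0.10 (gene-poor) vs 0.45 (gene-rich), a two-fold 24-nt siRNA abundance
    contrast, and a 3-condition (0/250/500 mM NaCl) x 2-tissue x 2-replicate
    expression design.
    """

    seed: int = 0
    n_chrom: int = 2
    chrom_length: int = 1_000_000
    gene_density_gradient: float = 0.5  # fraction of chromosomes that are gene-poor
    n_genes: Optional[int] = None       # per dense chromosome; None = capacity
    gene_spacing: int = 12_000
    families: dict[str, FamilyConfig] = field(default_factory=lambda: {
        "RLG_a": FamilyConfig("Gypsy", n_intact=30, n_truncated=10, n_solo=12,
                              gene_poor_fraction=0.5),
        "RLG_b": FamilyConfig("Gypsy", n_intact=30, n_truncated=10, n_solo=10,
                              gene_poor_fraction=0.5),
        "RLC_a": FamilyConfig("Copia", n_intact=20, n_truncated=8, n_solo=15,
                              gene_poor_fraction=0.1),
    })
    ltr_length: int = 500
    internal_length: int = 2_000
    truncated_length: int = 1_500
    true_ages: Optional[dict[str, list[float]]] = None  # per family, years; None = drawn
    age_scale: float = 1.5e6        # mean of the exponential age draw, years
    recent_fraction: float = 0.1    # fraction of intact copies forced to age 0
    substitution_rate: float = 1.3e-8
    kappa: float = 2.0
    methyl_means: dict[str, tuple[float, float]] = field(default_factory=lambda: {
        "CG": (0.60, 0.90), "CHG": (0.30, 0.70), "CHH": (0.10, 0.45)})
    coverage_lambda: float = 20.0
    sirna_abundance: tuple[float, float] = (4.0, 8.0)  # reads/kb: gene-poor, other
    sirna_length: int = 24
    multimap_fraction: float = 0.3
    nb_mean: float = 100.0
    nb_dispersion: float = 0.01
    nb_mean_sigma: float = 1.0      # lognormal spread of per-feature base means
    root_multiplier: float = 2.0    # TE expression boost in roots
    n_planted_pairs: int = 5
    planted_log2fc: float = 2.0

    def __post_init__(self) -> None:
        if self.ltr_length < 1:
            raise ValueError("ltr_length must be >= 1")
        for ctx, (p_poor, p_other) in self.methyl_means.items():
            if not (0 <= p_poor <= 1 and 0 <= p_other <= 1):
                raise ValueError(f"methylation probabilities for {ctx} outside [0,1]")

    @property
    def intact_length(self) -> int:
        return 2 * self.ltr_length + self.internal_length


@dataclass
class PlantedPair:
    te_id: str
    gene_id: str
    sign: int       # +1 or -1: direction of the shared condition response
    log2fc: float   # per-condition-step log2 shift


@dataclass
class SimTruth:
    """Ground truth of a simulated dataset, keyed by emitted feature ids."""

    ages: dict[str, float] = field(default_factory=dict)
    contexts: dict[str, str] = field(default_factory=dict)
    gene_poor: dict[str, bool] = field(default_factory=dict)
    methyl_means: dict[str, dict[str, float]] = field(default_factory=dict)
    sirna_abundance: dict[str, float] = field(default_factory=dict)
    planted_pairs: list[PlantedPair] = field(default_factory=list)
    log2fc: dict[str, float] = field(default_factory=dict)


# ---------------------------------------------------------------------------
# substitution process

def _evolve_branch(seq: str, age: float, rate: float, kappa: float,
                   rng: np.random.Generator) -> str:
    """Evolve one branch for ``age`` years under the two-parameter process.

    Each site receives Poisson(rate * age) substitution events; an event is
    a transition with probability kappa / (kappa + 2), otherwise one of the
    two transversions with equal probability.
    """
    n_events = rng.poisson(rate * age, size=len(seq))
    if n_events.sum() == 0:
        return seq
    chars = list(seq)
    p_ts = kappa / (kappa + 2.0)
    for i in np.nonzero(n_events)[0]:
        base = chars[i]
        for _ in range(int(n_events[i])):
            if rng.random() < p_ts:
                base = _TRANSITION[base]
            else:
                base = _TRANSVERSIONS[base][int(rng.integers(2))]
        chars[i] = base
    return "".join(chars)


def evolve_ltr_pair(ltr_seq: str, age: float, rate: float, kappa: float,
                    seed: int | np.random.Generator) -> tuple[str, str]:
    """Evolve the two LTRs of an insertion independently for ``age`` years.

    Expected pairwise divergence is 2 * rate * age substitutions/site
    (before multiple-hit correction).
    """
    if age < 0:
        raise ValueError("age must be non-negative")
    if rate <= 0:
        raise ValueError("rate must be positive")
    if not ltr_seq:
        raise ValueError("LTR sequence must be non-empty")
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    if age == 0:
        return ltr_seq, ltr_seq
    return (_evolve_branch(ltr_seq, age, rate, kappa, rng),
            _evolve_branch(ltr_seq, age, rate, kappa, rng))


def _random_seq(rng: np.random.Generator, length: int) -> str:
    return "".join(BASES[rng.integers(0, 4, size=length)])


# ---------------------------------------------------------------------------
# genome / annotation

def _make_genes(chrom: str, length: int, n_genes: Optional[int],
                spacing: int) -> list[GeneModel]:
    offset = 1_000
    capacity = max(0, (length - offset - GENE_SPAN - 200) // spacing + 1)
    if n_genes is None:
        n_genes = capacity
    if n_genes > capacity:
        raise ValueError(f"cannot place {n_genes} genes on {chrom} (capacity {capacity})")
    genes = []
    for i in range(n_genes):
        start = offset + i * spacing
        exon1 = (start, start + GENE_EXON1)
        exon2 = (start + GENE_EXON1 + GENE_INTRON, start + GENE_SPAN)
        genes.append(GeneModel(
            gene_id=f"{chrom}_g{i:04d}", chrom=chrom, strand="+" if i % 2 == 0 else "-",
            start=start, end=start + GENE_SPAN,
            exons=[exon1, exon2], cds=[exon1, exon2]))
    return genes


class _Allocator:
    """Non-overlapping placement from a pool of free intervals.

    Allocates from the left edge of a randomly chosen interval with enough
    room, keeping a fixed spacer between consecutive placements.
    """

    def __init__(self, intervals: list[tuple[str, int, int]],
                 rng: np.random.Generator, spacer: int = 100):
        self.iv = list(intervals)
        self.rng = rng
        self.spacer = spacer

    def alloc(self, length: int) -> tuple[str, int] | None:
        order = list(self.rng.permutation(len(self.iv)))
        for i in order:
            c, lo, hi = self.iv[i]
            if hi - lo >= length:
                self.iv[i] = (c, lo + length + self.spacer, hi)
                return c, lo
        return None


def simulate_genome(cfg: SimConfig) -> tuple[dict[str, str], list[GeneModel],
                                             list[TECopy], SimTruth]:
    """Generate genome sequences, gene models, TE copies and ground truth.

    Chromosomes are designated gene-poor or gene-dense according to
    ``gene_density_gradient``; TE copies are placed without overlap in
    intergenic gaps, inside introns, or overlapping a CDS, with the context
    and compartment of every copy recorded in the truth. Intact copies carry
    LTR pairs evolved to their true age and 5-bp TSDs (identical for age-0
    copies, substitution-mutated in proportion to age otherwise).

    Raises ``ValueError`` when the requested copies exceed placement capacity.
    """
    rng = np.random.default_rng(cfg.seed)
    n_poor = int(round(cfg.gene_density_gradient * cfg.n_chrom))
    n_poor = min(max(n_poor, 0), cfg.n_chrom)
    chrom_names = [f"chr{i+1}" for i in range(cfg.n_chrom)]
    poor_chroms = set(chrom_names[:n_poor])

    genome = {c: list(_random_seq(rng, cfg.chrom_length)) for c in chrom_names}
    genes: list[GeneModel] = []
    for c in chrom_names:
        if c not in poor_chroms:
            genes.extend(_make_genes(c, cfg.chrom_length, cfg.n_genes, cfg.gene_spacing))

    # --- placement pools --------------------------------------------------
    # Every 4th gene's upstream gap is reserved for CDS-overlap placements so
    # coding-slot TEs can never collide with intergenic allocations.
    margin = 100
    gap_iv: list[tuple[str, int, int]] = []
    intron_iv: list[tuple[str, int, int]] = []
    coding_slots: list[tuple[str, int, int]] = []  # (chrom, exon1_start, gap_lo)
    by_chrom: dict[str, list[GeneModel]] = {}
    for g in genes:
        by_chrom.setdefault(g.chrom, []).append(g)
    for c, gs in by_chrom.items():
        gs = sorted(gs, key=lambda g: g.start)
        prev_end = 0
        for i, g in enumerate(gs):
            lo, hi = prev_end + margin, g.start - margin
            if i % 4 == 3:
                if hi > lo:
                    coding_slots.append((c, g.start, lo))
            elif hi - lo > 0:
                gap_iv.append((c, lo, hi))
            s, e = g.introns[0]
            intron_iv.append((c, s + 50, e - 50))
            prev_end = g.end
    poor_iv = [(c, margin, cfg.chrom_length - margin) for c in poor_chroms]
    gap_alloc = _Allocator(gap_iv, rng)
    intron_alloc = _Allocator(intron_iv, rng)
    poor_alloc = _Allocator(poor_iv, rng)
    rng.shuffle(coding_slots)  # type: ignore[arg-type]

    truth = SimTruth()
    copies: list[TECopy] = []

    def stamp(chrom: str, start: int, seq: str) -> None:
        genome[chrom][start:start + len(seq)] = list(seq)

    for fam, fc in cfg.families.items():
        anc_ltr = _random_seq(rng, cfg.ltr_length)
        ages_cfg = (cfg.true_ages or {}).get(fam)
        if ages_cfg is not None:
            if len(ages_cfg) != fc.n_intact:
                raise ValueError(f"{fam}: true_ages length != n_intact")
            ages = list(ages_cfg)
        else:
            ages = list(rng.exponential(cfg.age_scale, size=fc.n_intact))
            n_recent = int(round(cfg.recent_fraction * fc.n_intact))
            for i in range(n_recent):
                ages[i] = 0.0

        specs = ([("intact", cfg.intact_length)] * fc.n_intact
                 + [("truncated", cfg.truncated_length)] * fc.n_truncated
                 + [("solo_LTR", cfg.ltr_length)] * fc.n_solo)
        intact_i = 0
        for j, (status, te_len) in enumerate(specs):
            copy_id = f"{fam}_{status[0].upper()}{j:03d}"
            u = rng.random()
            placed = None
            if u < fc.p_coding:
                # overlap the last 100 bp before the exon plus 100 bp into it
                while coding_slots:
                    c, exon_start, gap_lo = coding_slots.pop()
                    start = exon_start + 100 - te_len
                    if start >= gap_lo:
                        placed = (c, start, "coding", False)
                        break
            elif u < fc.p_coding + fc.p_intron:
                got = intron_alloc.alloc(te_len)
                if got is not None:
                    placed = (*got, "intron", False)
            if placed is None:
                # preferred compartment first, the other as overflow
                poor = rng.random() < fc.gene_poor_fraction
                first, second = (poor_alloc, gap_alloc) if poor else (gap_alloc, poor_alloc)
                got = first.alloc(te_len)
                if got is None:
                    poor = not poor
                    got = second.alloc(te_len)
                if got is None:
                    raise ValueError(f"placement capacity exceeded at {copy_id}")
                if not poor_chroms:
                    poor = False
                placed = (*got, "intergenic", poor)
            c, start, ctx, poor = placed
            end = start + te_len

            if status == "intact":
                age = float(ages[intact_i])
                intact_i += 1
                ltr5, ltr3 = evolve_ltr_pair(anc_ltr, age, cfg.substitution_rate,
                                             cfg.kappa, rng)
                internal = _random_seq(rng, cfg.internal_length)
                tsd5 = _random_seq(rng, TSD_LEN)
                if age == 0:
                    tsd3 = tsd5
                else:
                    p_mut = min(0.95, 2.0 * cfg.substitution_rate * age)
                    tsd3 = "".join(
                        BASES[int(rng.integers(0, 4))] if rng.random() < p_mut else b
                        for b in tsd5)
                stamp(c, start - TSD_LEN, tsd5)
                stamp(c, start, ltr5 + internal + ltr3)
                stamp(c, end, tsd3)
                te = TECopy(copy_id, fam, fc.superfamily, c, start, end,
                            status="intact",
                            ltr5=(start, start + cfg.ltr_length),
                            ltr3=(end - cfg.ltr_length, end),
                            tsd5=tsd5, tsd3=tsd3)
                truth.ages[copy_id] = age
            else:
                frag = _evolve_branch(anc_ltr if status == "solo_LTR"
                                      else _random_seq(rng, te_len),
                                      float(rng.exponential(cfg.age_scale)),
                                      cfg.substitution_rate, cfg.kappa, rng)
                if len(frag) < te_len:
                    frag = frag + _random_seq(rng, te_len - len(frag))
                stamp(c, start, frag[:te_len])
                te = TECopy(copy_id, fam, fc.superfamily, c, start, end, status=status)
            truth.contexts[copy_id] = ctx
            truth.gene_poor[copy_id] = poor
            truth.methyl_means[copy_id] = {
                ctx_name: means[0] if poor else means[1]
                for ctx_name, means in cfg.methyl_means.items()}
            truth.sirna_abundance[copy_id] = (
                cfg.sirna_abundance[0] if poor else cfg.sirna_abundance[1])
            copies.append(te)

    genome_str = {c: "".join(s) for c, s in genome.items()}
    copies.sort(key=lambda t: (t.chrom, t.start))
    return genome_str, genes, copies, truth


# ---------------------------------------------------------------------------
# methylome

def simulate_methylome(genome: dict[str, str], copies: list[TECopy],
                       truth: SimTruth, coverage_lambda: float,
                       seed: int | np.random.Generator) -> pd.DataFrame:
    """Per-cytosine methylation calls for every cytosine inside TE copies.

    Coverage is Poisson(``coverage_lambda``) per site; the methylated count
    is binomial with the copy's true per-context probability. Only covered
    sites are emitted.
    """
    from .epigenome import call_context

    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    cols = ("chrom", "pos", "strand", "context", "count_methylated", "count_unmethylated")
    if coverage_lambda <= 0:
        return pd.DataFrame({k: [] for k in cols})
    frames = []
    for te in copies:
        seq = genome[te.chrom]
        positions, strands, contexts, probs = [], [], [], []
        pmap = truth.methyl_means[te.copy_id]
        for pos in range(te.start, te.end):
            base = seq[pos]
            if base == "C":
                ctx = call_context(genome, te.chrom, pos, "+")
                strand = "+"
            elif base == "G":
                ctx = call_context(genome, te.chrom, pos, "-")
                strand = "-"
            else:
                continue
            if ctx is None:
                continue
            positions.append(pos)
            strands.append(strand)
            contexts.append(ctx)
            probs.append(pmap[ctx])
        if not positions:
            continue
        cov = rng.poisson(coverage_lambda, size=len(positions))
        meth = rng.binomial(cov, probs)
        keep = cov > 0
        frames.append(pd.DataFrame({
            "chrom": te.chrom,
            "pos": np.array(positions)[keep],
            "strand": np.array(strands)[keep],
            "context": np.array(contexts)[keep],
            "count_methylated": meth[keep],
            "count_unmethylated": (cov - meth)[keep],
        }))
    if not frames:
        return pd.DataFrame({k: [] for k in cols})
    return pd.concat(frames, ignore_index=True)


# ---------------------------------------------------------------------------
# siRNA

def simulate_sirna(copies: list[TECopy], truth: SimTruth,
                   multimap_fraction: float, seed: int | np.random.Generator,
                   read_length: int = 24) -> tuple[pd.DataFrame, int]:
    """siRNA alignments inside TE copies at each copy's true reads/kb rate.

    A ``multimap_fraction`` of reads maps to 2-3 locations distributed among
    same-family copies (``n_hits`` set accordingly); the rest map uniquely.
    Returns the alignment table and the number of distinct reads emitted.
    """
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    fam_copies: dict[str, list[TECopy]] = {}
    for te in copies:
        fam_copies.setdefault(te.family, []).append(te)
    rows = []
    read_n = 0
    for te in copies:
        rate = truth.sirna_abundance[te.copy_id]
        n_reads = int(rng.poisson(rate * te.length / 1000.0))
        for _ in range(n_reads):
            read_id = f"r{read_n:07d}"
            read_n += 1
            targets = [te]
            sibs = [t for t in fam_copies[te.family]
                    if t.copy_id != te.copy_id and t.length > read_length]
            if sibs and rng.random() < multimap_fraction:
                extra = int(rng.integers(1, min(2, len(sibs)) + 1))
                pick = rng.choice(len(sibs), size=extra, replace=False)
                targets += [sibs[int(i)] for i in pick]
            n_hits = len(targets)
            for t in targets:
                pos = int(rng.integers(t.start, max(t.start + 1, t.end - read_length)))
                rows.append({"read_id": read_id, "chrom": t.chrom, "pos": pos,
                             "length": read_length, "n_hits": n_hits})
    return (pd.DataFrame(rows, columns=["read_id", "chrom", "pos", "length", "n_hits"]),
            read_n)


# ---------------------------------------------------------------------------
# expression counts

def make_design(tissues=("leaf", "root"), conditions=(0, 250, 500),
                n_replicates: int = 2) -> pd.DataFrame:
    rows = [
        {"sample": f"{t}_{c}_r{r}", "tissue": t, "nacl_mM": c, "replicate": r}
        for t in tissues for c in conditions for r in range(1, n_replicates + 1)
    ]
    return pd.DataFrame(rows)


def _nb_draw(rng: np.random.Generator, mean: np.ndarray, dispersion: float) -> np.ndarray:
    mean = np.asarray(mean, dtype=float)
    if dispersion <= 0:
        return rng.poisson(mean)
    n = 1.0 / dispersion
    p = n / (n + mean)
    return rng.negative_binomial(n, p)


def simulate_counts(copies: list[TECopy], genes: list[GeneModel],
                    design: pd.DataFrame, cfg: SimConfig,
                    truth: SimTruth, seed: int | np.random.Generator,
                    flanking_pairs: pd.DataFrame | None = None):
    """Negative-binomial count matrices for genes and TE copies.

    Null features keep a constant mean across salt conditions (TEs get a
    tissue effect: ``root_multiplier`` in roots). Planted TE-gene pairs share
    a per-condition-step mean shift of ``planted_log2fc`` log2 units with the
    planted sign, in both tissues, which induces the planted expression
    correlation. Returns ``(gene_counts, te_counts, truth)`` where the count
    objects are :class:`~ltrdyn.screen.CountMatrix`.
    """
    from .screen import CountMatrix, find_flanking_pairs

    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    for _, grp in design.groupby(["tissue", "nacl_mM"]):
        if len(grp) < 2:
            raise ValueError("design needs >= 2 replicates per condition x tissue")

    te_feats = [te for te in copies if te.status in ("intact", "truncated")]
    te_ids = [t.copy_id for t in te_feats]
    te_lengths = pd.Series({t.copy_id: t.length for t in te_feats})
    gene_ids = [g.gene_id for g in genes]
    gene_lengths = pd.Series(
        {g.gene_id: sum(e - s for s, e in g.exons) for g in genes})

    # choose planted pairs among true flanking adjacencies
    if flanking_pairs is None:
        flanking_pairs = find_flanking_pairs(te_feats, genes)
    planted: list[PlantedPair] = []
    if cfg.n_planted_pairs > 0 and len(flanking_pairs):
        pool = flanking_pairs.drop_duplicates("te_id").drop_duplicates("gene_id")
        k = min(cfg.n_planted_pairs, len(pool))
        pick = rng.choice(len(pool), size=k, replace=False)
        for i, idx in enumerate(sorted(int(x) for x in pick)):
            rec = pool.iloc[idx]
            planted.append(PlantedPair(rec["te_id"], rec["gene_id"],
                                       sign=1 if i % 2 == 0 else -1,
                                       log2fc=cfg.planted_log2fc))
    truth.planted_pairs = planted
    planted_te = {p.te_id: p for p in planted}
    planted_gene = {p.gene_id: p for p in planted}

    conditions = sorted(design["nacl_mM"].unique())
    # planted condition-mean multipliers: TEs rise 2^(lfc * step); positive-sign
    # genes share that profile (r = +1 in means), negative-sign genes get the
    # affine reflection tmax + tmin - t, which is exactly anti-collinear
    t_prof = 2.0 ** (cfg.planted_log2fc * np.arange(len(conditions)))
    t_neg = t_prof.max() + t_prof.min() - t_prof

    def matrix(ids, lengths, is_te: bool) -> pd.DataFrame:
        base = np.exp(rng.normal(np.log(cfg.nb_mean), cfg.nb_mean_sigma, size=len(ids)))
        cols = {}
        for rec in design.itertuples(index=False):
            mu = base.copy()
            if is_te and rec.tissue == "root":
                mu = mu * cfg.root_multiplier
            ci = conditions.index(rec.nacl_mM)
            for j, fid in enumerate(ids):
                p = planted_te.get(fid) if is_te else planted_gene.get(fid)
                if p is not None:
                    if is_te or p.sign > 0:
                        mu[j] = mu[j] * t_prof[ci]
                    else:
                        mu[j] = mu[j] * t_neg[ci]
            cols[rec.sample] = _nb_draw(rng, mu, cfg.nb_dispersion)
        return pd.DataFrame(cols, index=ids)

    gene_cm = CountMatrix(matrix(gene_ids, gene_lengths, False), design, gene_lengths)
    te_cm = CountMatrix(matrix(te_ids, te_lengths, True), design, te_lengths)
    for p in planted:
        truth.log2fc[p.te_id] = p.log2fc
        truth.log2fc[p.gene_id] = p.sign * p.log2fc
    return gene_cm, te_cm, truth


def simulate_null_matrix(n_features: int, design: pd.DataFrame, cfg: SimConfig,
                         seed: int | np.random.Generator) -> pd.DataFrame:
    """Counts with no condition effect at all: every feature keeps one mean
    across every sample. Used for type-I-error calibration of the DE test."""
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    base = np.exp(rng.normal(np.log(cfg.nb_mean), cfg.nb_mean_sigma, size=n_features))
    cols = {rec.sample: _nb_draw(rng, base, cfg.nb_dispersion)
            for rec in design.itertuples(index=False)}
    return pd.DataFrame(cols, index=[f"f{i:05d}" for i in range(n_features)])


def simulate_pair_panel(n_planted: int, n_null: int, design: pd.DataFrame,
                        cfg: SimConfig, seed: int | np.random.Generator):
    """Correlation-screen calibration panel.

    Builds ``n_planted`` TE-gene pairs whose condition means are exactly
    collinear (alternating sign; |true r| = 1) plus ``n_null`` independent
    pairs, with NB replicate noise. Returns ``(te_counts, gene_counts,
    pairs, signs)`` where ``pairs`` is a candidate table for
    :func:`ltrdyn.screen.correlate_pairs` and ``signs`` maps planted TE ids
    to the planted correlation sign (null pairs absent).
    """
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    conditions = sorted(design["nacl_mM"].unique())
    t_prof = 2.0 ** (cfg.planted_log2fc * np.arange(len(conditions)))
    t_neg = t_prof.max() + t_prof.min() - t_prof
    n = n_planted + n_null
    te_ids = [f"TE{i:04d}" for i in range(n)]
    gene_ids = [f"G{i:04d}" for i in range(n)]
    base_t = np.exp(rng.normal(np.log(cfg.nb_mean), cfg.nb_mean_sigma, size=n))
    base_g = np.exp(rng.normal(np.log(cfg.nb_mean), cfg.nb_mean_sigma, size=n))
    signs = {te_ids[i]: (1 if i % 2 == 0 else -1) for i in range(n_planted)}
    te_cols, gene_cols = {}, {}
    for rec in design.itertuples(index=False):
        ci = conditions.index(rec.nacl_mM)
        mu_t, mu_g = base_t.copy(), base_g.copy()
        for i in range(n_planted):
            mu_t[i] *= t_prof[ci]
            mu_g[i] *= t_prof[ci] if signs[te_ids[i]] > 0 else t_neg[ci]
        te_cols[rec.sample] = _nb_draw(rng, mu_t, cfg.nb_dispersion)
        gene_cols[rec.sample] = _nb_draw(rng, mu_g, cfg.nb_dispersion)
    pairs = pd.DataFrame({"te_id": te_ids, "gene_id": gene_ids,
                          "relation": "upstream", "distance": 500})
    return (pd.DataFrame(te_cols, index=te_ids),
            pd.DataFrame(gene_cols, index=gene_ids), pairs, signs)
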