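"""Core domain types.

Coordinates are 0-based half-open throughout the package; GFF3 I/O converts
to/from the 1-based closed convention at the file boundary.
"""
from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional

Interval = tuple[int, int]

SUPERFAMILIES = ("Copia", "Gypsy", "DNA_transposon", "Other")
STATUSES = ("intact", "truncated", "solo_LTR")
CONTEXTS = ("CG", "CHG", "CHH")
CATEGORIES = ("intergenic", "intron", "coding")


@dataclass
class TECopy:
    """One annotated transposable-element insertion.

    Intact LTR retrotransposons carry the two long-terminal-repeat
    sub-intervals (``ltr5``/``ltr3``, genome coordinates inside
    ``[start, end)``) and the flanking 5-bp target-site-duplication strings.
    """

    copy_id: str
    family: str
    superfamily: str
    chrom: str
    start: int
    end: int
    strand: str = "+"
    status: str = "intact"
    ltr5: Optional[Interval] = None
    ltr3: Optional[Interval] = None
    tsd5: Optional[str] = None
    tsd3: Optional[str] = None

    def __post_init__(self) -> None:
        if self.start >= self.end:
            raise ValueError(f"{self.copy_id}: start must be < end")
        if self.superfamily not in SUPERFAMILIES:
            raise ValueError(f"{self.copy_id}: unknown superfamily {self.superfamily!r}")
        if self.status not in STATUSES:
            raise ValueError(f"{self.copy_id}: unknown status {self.status!r}")
        if self.status == "intact":
            if self.ltr5 is None or self.ltr3 is None:
                raise ValueError(f"{self.copy_id}: intact copy lacks LTR sub-intervals")
            for name, (s, e) in (("LTR5", self.ltr5), ("LTR3", self.ltr3)):
                if not (self.start <= s < e <= self.end):
                    raise ValueError(f"{self.copy_id}: {name} outside copy bounds")
            if not self.ltr5[1] <= self.ltr3[0]:
                raise ValueError(f"{self.copy_id}: LTR intervals overlap")

    @property
    def length(self) -> int:
        return self.end - self.start


@dataclass
class GeneModel:
    """A protein-coding gene model with exon/CDS structure."""

    gene_id: str
    chrom: str
    strand: str
    start: int
    end: int
    exons: list[Interval] = field(default_factory=list)
    cds: list[Interval] = field(default_factory=list)

    def __post_init__(self) -> None:
        self.exons = sorted(self.exons)
        self.cds = sorted(self.cds)
        for s, e in self.cds:
            if not (self.start <= s < e <= self.end):
                raise ValueError(f"{self.gene_id}: CDS interval outside gene span")
        for (s1, e1), (s2, e2) in zip(self.cds, self.cds[1:]):
            if s2 < e1:
                raise ValueError(f"{self.gene_id}: overlapping CDS intervals")

    @property
    def introns(self) -> list[Interval]:
        """Gaps between consecutive exons (empty for single-exon genes)."""
        ex = self.exons if self.exons else self.cds
        return [(e1, s2) for (_, e1), (s2, _) in zip(ex, ex[1:]) if s2 > e1]


@dataclass
class GenomicWindow:
    """A fixed-step sliding window with its coding-sequence fraction."""

    chrom: str
    start: int
    end: int
    cds_fraction: float

    def __post_init__(self) -> None:
        if not 0.0 <= self.cds_fraction <= 1.0:
            raise ValueError("cds_fraction outside [0, 1]")


@dataclass
class DivergenceEstimate:
    """LTR-pair divergence summary for one intact element.

    ``P`` and ``Q`` are the transition and transversion proportions over
    ungapped alignment columns, ``k`` the Kimura two-parameter distance, and
    ``age`` the insertion age in years from T = k / (2 r). ``saturated`` marks
    pairs whose divergence puts the K2P logarithms out of domain; such
    estimates carry NaN ``k``/``age`` and are excluded from summaries.
    """

    copy_id: str
    n_sites: int
    P: float
    Q: float
    k: float
    age: float
    saturated: bool = False


@dataclass
class AgeSummary:
    median_age: float
    bin_width: float
    bin_edges: list[float]
    bin_counts: list[int]
    young_fraction: float
    n: int
    n_saturated: int = 0
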