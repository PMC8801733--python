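"""Insertion-age estimation for intact LTR retrotransposons.

The two long terminal repeats of a retrotransposon are identical at the
moment of insertion and diverge thereafter at the neutral substitution rate.
Aligning the 5' and 3' LTRs of an intact copy, correcting the observed
transition (P) and transversion (Q) proportions with Kimura's two-parameter
distance

    k = -1/2 ln(1 - 2P - Q) - 1/4 ln(1 - 2Q)

and dividing by twice the substitution rate gives the insertion age
T = k / (2 r).  The default rate is r = 1.3e-8 substitutions/site/year.
"""
from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
from Bio import Align

from .models import AgeSummary, DivergenceEstimate, TECopy
from .stats import mann_whitney

DEFAULT_RATE = 1.3e-8
YEAR_PER_MYR = 1e6

TRANSITIONS = {("A", "G"), ("G", "A"), ("C", "T"), ("T", "C")}
_VALID = set("ACGTN")


@dataclass
class AlignParams:
    match: float = 1.0
    mismatch: float = -1.0
    gap_open: float = -5.0
    gap_extend: float = -1.0


def _make_aligner(params: AlignParams) -> Align.PairwiseAligner:
    aligner = Align.PairwiseAligner()
    aligner.mode = "global"
    aligner.match_score = params.match
    aligner.mismatch_score = params.mismatch
    aligner.open_gap_score = params.gap_open
    aligner.extend_gap_score = params.gap_extend
    return aligner


def align_ltr_pair(ltr5: str, ltr3: str, params: AlignParams | None = None) -> tuple[str, str]:
    """Globally align two LTR sequences with affine gap penalties.

    Returns the two gapped rows of the optimal alignment (first of the
    optimal set, which is deterministic for fixed inputs).
    """
    if not ltr5 or not ltr3:
        raise ValueError("LTR sequences must be non-empty")
    ltr5, ltr3 = ltr5.upper(), ltr3.upper()
    for seq in (ltr5, ltr3):
        bad = set(seq) - _VALID
        if bad:
            raise ValueError(f"invalid bases in LTR sequence: {sorted(bad)}")
    aln = _make_aligner(params or AlignParams()).align(ltr5, ltr3)[0]
    return str(aln[0]), str(aln[1])


def count_site_patterns(row5: str, row3: str) -> tuple[float, float, int]:
    """Transition/transversion proportions over ungapped, unambiguous columns.

    Columns containing a gap or N are excluded. Transitions are A<->G and
    C<->T; every other mismatch is a transversion. Returns ``(P, Q, n_sites)``.
    """
    if len(row5) != len(row3):
        raise ValueError("alignment rows differ in length")
    n = transitions = transversions = 0
    for x, y in zip(row5, row3):
        if x in "-N" or y in "-N":
            continue
        n += 1
        if x != y:
            if (x, y) in TRANSITIONS:
                transitions += 1
            else:
                transversions += 1
    if n == 0:
        raise ValueError("no ungapped, unambiguous columns in alignment")
    return transitions / n, transversions / n, n


def k2p_distance(P: float, Q: float) -> float:
    """Kimura two-parameter distance; NaN when the divergence is saturated.

    Saturation (1 - 2P - Q <= 0 or 1 - 2Q <= 0) is reported as NaN rather
    than clamped, so downstream summaries can exclude it explicitly.
    """
    if P < 0 or Q < 0 or P + Q > 1:
        raise ValueError("require P, Q >= 0 and P + Q <= 1")
    a = 1.0 - 2.0 * P - Q
    b = 1.0 - 2.0 * Q
    if a <= 0 or b <= 0:
        return math.nan
    k = -0.5 * math.log(a) - 0.25 * math.log(b)
    return 0.0 if k == 0 else k  # avoid IEEE -0.0 at zero divergence


def estimate_age(k: float, rate: float = DEFAULT_RATE) -> float:
    """Insertion age in years, T = k / (2 r)."""
    if rate <= 0:
        raise ValueError("substitution rate must be positive")
    if math.isnan(k):
        return math.nan
    if k < 0:
        raise ValueError("distance k must be non-negative")
    return k / (2.0 * rate)


def date_ltr_pair(
    ltr5: str,
    ltr3: str,
    copy_id: str = "",
    rate: float = DEFAULT_RATE,
    params: AlignParams | None = None,
) -> DivergenceEstimate:
    """Full dating path for one LTR pair: align, count, correct, convert."""
    row5, row3 = align_ltr_pair(ltr5, ltr3, params)
    P, Q, n = count_site_patterns(row5, row3)
    k = k2p_distance(P, Q)
    return DivergenceEstimate(
        copy_id=copy_id,
        n_sites=n,
        P=P,
        Q=Q,
        k=k,
        age=estimate_age(k, rate),
        saturated=math.isnan(k),
    )


def date_copies(
    copies: list[TECopy],
    genome: dict[str, str],
    rate: float = DEFAULT_RATE,
    params: AlignParams | None = None,
) -> list[DivergenceEstimate]:
    """Date every intact copy by extracting its LTR pair from the genome."""
    out = []
    for te in copies:
        if te.status != "intact":
            continue
        if te.ltr5 is None or te.ltr3 is None:
            raise ValueError(f"{te.copy_id}: intact copy lacks LTR intervals")
        seq = genome[te.chrom]
        ltr5 = seq[te.ltr5[0] : te.ltr5[1]]
        ltr3 = seq[te.ltr3[0] : te.ltr3[1]]
        out.append(date_ltr_pair(ltr5, ltr3, te.copy_id, rate, params))
    return out


def summarize_ages(
    estimates: list[DivergenceEstimate],
    bin_width: float = 0.5 * YEAR_PER_MYR,
    young_threshold: float = 1.0 * YEAR_PER_MYR,
) -> AgeSummary:
    """Median, histogram and young fraction over defined (non-saturated) ages.

    Saturated estimates are counted separately and excluded from the median,
    the bins and the young fraction.
    """
    ages = np.array([e.age for e in estimates if not e.saturated], dtype=float)
    n_sat = sum(e.saturated for e in estimates)
    if ages.size == 0:
        raise ValueError("no defined age estimates to summarize")
    n_bins = max(1, math.ceil(max(ages.max(), bin_width) / bin_width))
    edges = np.arange(n_bins + 1) * bin_width
    if edges[-1] <= ages.max():
        edges = np.append(edges, edges[-1] + bin_width)
    counts, edges = np.histogram(ages, bins=edges)
    return AgeSummary(
        median_age=float(np.median(ages)),
        bin_width=bin_width,
        bin_edges=[float(e) for e in edges],
        bin_counts=[int(c) for c in counts],
        young_fraction=float((ages < young_threshold).mean()),
        n=int(ages.size),
        n_saturated=int(n_sat),
    )


def compare_age_distributions(ages_a, ages_b) -> tuple[float, float]:
    """Two-sided Mann-Whitney U comparison of two age samples."""
    return mann_whitney(ages_a, ages_b)


def flag_recent_insertions(copies: list[TECopy], genome: dict[str, str]) -> list[str]:
    """Copies with identical LTR pairs and perfect 5-bp TSDs.

    Such copies have accumulated no substitutions since insertion and are
    newly originated. Non-intact copies are ignored; an intact copy without
    LTR intervals is an annotation error.
    """
    flagged = []
    for te in copies:
        if te.status != "intact":
            continue
        if te.ltr5 is None or te.ltr3 is None:
            raise ValueError(f"{te.copy_id}: intact copy lacks LTR intervals")
        seq = genome[te.chrom]
        ltr5 = seq[te.ltr5[0] : te.ltr5[1]]
        ltr3 = seq[te.ltr3[0] : te.ltr3[1]]
        if (
            ltr5 == ltr3
            and te.tsd5 is not None
            and te.tsd5 == te.tsd3
            and len(te.tsd5) == 5
        ):
            flagged.append(te.copy_id)
    return flagged
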