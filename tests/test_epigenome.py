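"""Per-element methylation and siRNA density."""
import numpy as np
import pandas as pd
import pytest

from ltrdyn.epigenome import (call_context, compare_repression,
                              element_methylation, elements_methylation,
                              elements_sirna_density, sirna_density)
from ltrdyn.models import TECopy
from ltrdyn.simulate import (FamilyConfig, SimConfig, simulate_genome,
                             simulate_methylome, simulate_sirna)


class TestCallContext:
    def test_plus_strand_cg(self):
        assert call_context({"c": "ACGT"}, "c", 1, "+") == "CG"

    def test_plus_strand_chg(self):
        assert call_context({"c": "ACAGT"}, "c", 1, "+") == "CHG"

    def test_plus_strand_chh(self):
        assert call_context({"c": "ACATT"}, "c", 1, "+") == "CHH"

    def test_minus_strand_cg(self):
        # plus-strand ACG: the G at index 2 is a C on the minus strand whose
        # 3' neighbour (complement of index 1) is G -> CG
        assert call_context({"c": "ACG"}, "c", 2, "-") == "CG"

    def test_non_cytosine_returns_none(self):
        assert call_context({"c": "AAAA"}, "c", 0, "+") is None

    def test_truncated_context_returns_none(self):
        assert call_context({"c": "AAC"}, "c", 2, "+") is None
        assert call_context({"c": "ACAC"}, "c", 3, "+") is None

    def test_agrees_with_brute_force_triplet_scan(self):
        """Every cytosine of a random 10-kb sequence gets the same context as
        an independent scan over explicit plus/minus triplets."""
        rng = np.random.default_rng(3)
        seq = "".join(rng.choice(list("ACGT"), 10_000))
        comp = {"A": "T", "C": "G", "G": "C", "T": "A"}
        rc = lambda s: "".join(comp[b] for b in reversed(s))
        for pos in range(len(seq)):
            if seq[pos] == "C":
                tri = seq[pos:pos + 3]
                if len(tri) < 2:
                    expected = None
                elif tri[1] == "G":
                    expected = "CG"
                elif len(tri) < 3:
                    expected = None
                else:
                    expected = "CHG" if tri[2] == "G" else "CHH"
                assert call_context({"c": seq}, "c", pos, "+") == expected
            if seq[pos] == "G":
                tri = rc(seq[max(0, pos - 2):pos + 1])
                if len(tri) < 2:
                    expected = None
                elif tri[1] == "G":
                    expected = "CG"
                elif len(tri) < 3:
                    expected = None
                else:
                    expected = "CHG" if tri[2] == "G" else "CHH"
                assert call_context({"c": seq}, "c", pos, "-") == expected


def _sites(records):
    return pd.DataFrame(records, columns=["chrom", "pos", "strand", "context",
                                          "count_methylated", "count_unmethylated"])


def _te(start=0, end=1000):
    return TECopy("te1", "f", "Gypsy", "c", start, end, status="truncated")


class TestElementMethylation:
    def test_single_qualifying_site(self):
        sites = _sites([("c", 10, "+", "CHH", 3, 1)])
        res = element_methylation(sites, _te())
        assert res["CHH"]["level"] == pytest.approx(0.75)

    def test_coverage_three_is_filtered(self):
        """'More than three reads' is strict: coverage 3 never qualifies."""
        sites = _sites([("c", 10, "+", "CHH", 2, 1), ("c", 20, "+", "CHH", 3, 0)])
        res = element_methylation(sites, _te())
        assert np.isnan(res["CHH"]["level"]) and res["CHH"]["n_sites"] == 0

    def test_pooled_counts_not_mean_of_ratios(self):
        sites = _sites([("c", 10, "+", "CHH", 3, 1), ("c", 20, "+", "CHH", 0, 4)])
        res = element_methylation(sites, _te())
        assert res["CHH"]["level"] == pytest.approx(3 / 8)
        assert res["CHH"]["mean_site_level"] == pytest.approx(0.375)

    def test_sites_outside_element_ignored(self):
        sites = _sites([("c", 2000, "+", "CG", 5, 0)])
        res = element_methylation(sites, _te())
        assert np.isnan(res["CG"]["level"])

    def test_pooled_level_equals_coverage_weighted_site_mean(self):
        """Algebraic identity: pooling counts equals coverage-weighting the
        per-site levels."""
        rng = np.random.default_rng(4)
        cov = rng.integers(4, 30, size=50)
        meth = rng.binomial(cov, 0.4)
        sites = _sites([("c", int(10 + i), "+", "CG", int(m), int(c - m))
                        for i, (c, m) in enumerate(zip(cov, meth))])
        res = element_methylation(sites, _te())
        weighted = (meth / cov * cov).sum() / cov.sum()
        assert res["CG"]["level"] == pytest.approx(weighted)


class TestSirnaDensity:
    def _aln(self, records):
        return pd.DataFrame(records, columns=["read_id", "chrom", "pos",
                                              "length", "n_hits"])

    def test_weighted_reads_per_kb(self):
        rows = [(f"u{i}", "c", 10 * i, 24, 1) for i in range(10)]
        rows += [("m1", "c", 500, 24, 2), ("m2", "c", 600, 24, 2)]
        te = _te(0, 2000)
        assert sirna_density(self._aln(rows), te) == pytest.approx((10 + 1.0) / 2)

    def test_no_alignments_zero(self):
        assert sirna_density(self._aln([]), _te(0, 2000)) == 0.0

    def test_length_filter(self):
        rows = [("a", "c", 5, 24, 1), ("b", "c", 6, 21, 1)]
        assert sirna_density(self._aln(rows), _te(0, 1000)) == pytest.approx(1.0)
        assert sirna_density(self._aln(rows), _te(0, 1000),
                             length_filter=None) == pytest.approx(2.0)

    def test_multimapper_weight_conserved_across_elements(self):
        te_a, te_b = _te(0, 1000), TECopy("te2", "f", "Gypsy", "c", 2000, 3000,
                                          status="truncated")
        aln = self._aln([("m", "c", 100, 24, 2), ("m", "c", 2100, 24, 2)])
        total = sirna_density(aln, te_a) * 1.0 + sirna_density(aln, te_b) * 1.0
        assert total == pytest.approx(1.0)  # 1 kb elements: density == weight


class TestCompareRepression:
    def test_identical_groups_nonsignificant(self):
        vals = [0.2, 0.3, 0.4, 0.2, 0.3, 0.4]
        dens = [0.0, 0.0, 0.0, 0.2, 0.2, 0.2]
        mp, mo, _, p = compare_repression(vals, dens)
        assert mp == mo == pytest.approx(0.3)
        assert p > 0.9

    def test_all_copies_gene_poor_is_error(self):
        with pytest.raises(ValueError, match="gene-rich"):
            compare_repression([0.1, 0.2], [0.0, 0.01])

    def test_planted_contrast_recovered(self):
        """Planted CHH means 0.10 (gene-poor) vs 0.45 at coverage 20 are
        recovered within +/-0.05 with p < 0.001 (60 elements per group)."""
        cfg = SimConfig(seed=42, families={
            "RLG_a": FamilyConfig("Gypsy", n_intact=120, n_truncated=0,
                                  n_solo=0, gene_poor_fraction=0.5,
                                  p_intron=0.0, p_coding=0.0)})
        genome, genes, copies, truth = simulate_genome(cfg)
        sites = simulate_methylome(genome, copies, truth, 20.0, 43)
        meth = elements_methylation(sites, copies)
        poor = np.array([truth.gene_poor[c] for c in meth.copy_id])
        dens = np.where(poor, 0.0, 0.2)
        mp, mo, _, p = compare_repression(meth.CHH_level.to_numpy(), dens)
        assert min(poor.sum(), (~poor).sum()) >= 50
        assert abs(mp - 0.10) <= 0.05
        assert abs(mo - 0.45) <= 0.05
        assert p < 0.001


def test_sirna_planted_abundance_ratio(sim_dataset):
    """The planted two-fold siRNA abundance contrast between gene-poor and
    gene-rich elements is recovered within 20% by the weighted density."""
    _, genome, genes, copies, truth = sim_dataset
    aln, n_reads = simulate_sirna(copies, truth, 0.3, 17)
    assert aln["read_id"].nunique() == n_reads
    dens = elements_sirna_density(aln, copies)
    poor = np.array([truth.gene_poor[c] for c in dens.copy_id])
    ratio = (dens.sirna_density[~poor].mean() / dens.sirna_density[poor].mean())
    true_ratio = 8.0 / 4.0
    assert abs(ratio - true_ratio) / true_ratio < 0.2
    # weight conservation: every alignment weight sums back to the read count
    assert (1.0 / aln.n_hits).sum() == pytest.approx(n_reads)


def test_methylation_monotone_in_planted_probability():
    """Recovered element levels rise monotonically across a grid of planted
    methylation probabilities."""
    medians = []
    for i, p in enumerate((0.1, 0.3, 0.5, 0.9)):
        cfg = SimConfig(seed=60 + i, n_chrom=1, chrom_length=200_000,
                        gene_density_gradient=1.0,
                        families={"F": FamilyConfig("Gypsy", n_intact=12,
                                                    n_truncated=0, n_solo=0,
                                                    gene_poor_fraction=1.0,
                                                    p_intron=0, p_coding=0)},
                        methyl_means={"CG": (p, p), "CHG": (p, p), "CHH": (p, p)})
        genome, genes, copies, truth = simulate_genome(cfg)
        sites = simulate_methylome(genome, copies, truth, 12.0, 61)
        meth = elements_methylation(sites, copies)
        medians.append(meth.CHH_level.median())
    assert all(a < b for a, b in zip(medians, medians[1:]))
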