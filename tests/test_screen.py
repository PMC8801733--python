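"""Expression screen: quantification, filters, DE, pairing, correlation."""
import numpy as np
import pandas as pd
import pytest

from ltrdyn.models import GeneModel, TECopy
from ltrdyn.screen import (correlate_pairs, differential_expression,
                           enrichment_test, filter_expressed,
                           find_flanking_pairs, gene_rpkm, rpkm_matrix,
                           screen_sponge_pairs, te_expression)
from ltrdyn.simulate import (SimConfig, make_design, simulate_null_matrix,
                             simulate_pair_panel)


def design2():
    return make_design(tissues=("leaf",), conditions=(0, 250, 500), n_replicates=2)


class TestQuantification:
    @pytest.mark.parametrize("count,length_bp,expected",
                             [(200, 4000, 50.0), (0, 4000, 0.0), (13, 2600, 5.0)])
    def test_reads_per_kb(self, count, length_bp, expected):
        counts = pd.DataFrame({"s1": [count]}, index=["te1"])
        lengths = pd.Series({"te1": length_bp})
        assert te_expression(counts, lengths).iloc[0, 0] == pytest.approx(expected)

    def test_zero_length_rejected(self):
        with pytest.raises(ValueError):
            te_expression(pd.DataFrame({"s": [1]}, index=["x"]), pd.Series({"x": 0}))

    @pytest.mark.parametrize("count,length_bp,lib,expected",
                             [(100, 1000, 1_000_000, 100.0), (0, 1000, 1e6, 0.0),
                              (10, 2000, 1e7, 0.5)])
    def test_rpkm(self, count, length_bp, lib, expected):
        assert gene_rpkm(count, length_bp, lib) == pytest.approx(expected)

    def test_rpkm_invariant_to_joint_scaling(self):
        rng = np.random.default_rng(0)
        counts = pd.DataFrame(rng.integers(0, 100, (5, 3)),
                              index=list("abcde"), columns=["s1", "s2", "s3"])
        lengths = pd.Series(1000, index=counts.index)
        libs = pd.Series([1e6, 2e6, 3e6], index=counts.columns)
        r1 = rpkm_matrix(counts, lengths, libs)
        r2 = rpkm_matrix(counts * 2, lengths, libs * 2)
        pd.testing.assert_frame_equal(r1, r2, check_dtype=False)


class TestExpressedFilter:
    def _counts(self, per_condition):
        d = design2()
        cols = {}
        for ci, c in enumerate((0, 250, 500)):
            for r in (1, 2):
                cols[f"leaf_{c}_r{r}"] = [per_condition[ci][r - 1]]
        return pd.DataFrame(cols, index=["f1"]), d

    def test_both_replicates_above_threshold(self):
        counts, d = self._counts([(6, 6), (0, 0), (0, 0)])
        assert filter_expressed(counts, d, "leaf") == {"f1"}

    def test_exactly_five_reads_fails_strict_rule(self):
        counts, d = self._counts([(5, 100), (5, 100), (5, 100)])
        assert filter_expressed(counts, d, "leaf") == set()

    def test_one_replicate_zero_fails(self):
        counts, d = self._counts([(6, 0), (6, 0), (6, 0)])
        assert filter_expressed(counts, d, "leaf") == set()


def brute_force_pairs(tes, genes, max_distance=3000):
    """Independent all-vs-all interval scan for the pairing rule."""
    hits = set()
    for te in tes:
        for g in genes:
            if te.chrom != g.chrom:
                continue
            if any(s <= te.start and te.end <= e for s, e in g.introns):
                hits.add((te.copy_id, g.gene_id, 0))
                continue
            gap = max(g.start - te.end, te.start - g.end, 0)
            if gap <= max_distance:
                hits.add((te.copy_id, g.gene_id, gap))
    return hits


class TestFlankingPairs:
    def _gene(self, start, strand="+"):
        exon1 = (start, start + 500)
        exon2 = (start + 4500, start + 5000)
        return GeneModel("g1", "c", strand, start, start + 5000,
                         exons=[exon1, exon2], cds=[exon1, exon2])

    def _te(self, start, end):
        return TECopy("t1", "f", "Gypsy", "c", start, end, status="truncated")

    def test_505bp_downstream_gene_paired(self):
        te = self._te(1000, 2000)
        gene = self._gene(2505)
        df = find_flanking_pairs([te], [gene])
        assert len(df) == 1 and df.iloc[0].distance == 505
        assert df.iloc[0].relation == "upstream"  # TE upstream of a + gene

    def test_gap_beyond_3kb_excluded(self):
        te = self._te(0, 1000)
        gene = self._gene(4001)
        assert len(find_flanking_pairs([te], [gene])) == 0
        gene = self._gene(4000)
        assert len(find_flanking_pairs([te], [gene])) == 1

    def test_te_inside_intron(self):
        gene = self._gene(0)
        te = self._te(600, 4400)
        df = find_flanking_pairs([te], [gene])
        assert df.iloc[0].relation == "intron" and df.iloc[0].distance == 0

    def test_strand_flips_relation(self):
        te = self._te(1000, 2000)
        gene = self._gene(2505, strand="-")
        assert find_flanking_pairs([te], [gene]).iloc[0].relation == "downstream"

    def test_agrees_with_brute_force_scan(self):
        rng = np.random.default_rng(9)
        for _ in range(10):
            genes = []
            pos = 0
            for i in range(5):
                pos += int(rng.integers(1000, 8000))
                g = self._gene(pos)
                g.gene_id = f"g{i}"
                genes.append(g)
                pos = g.end
            tes = []
            for i in range(15):
                s = int(rng.integers(0, 60_000))
                te = self._te(s, s + int(rng.integers(100, 4000)))
                te.copy_id = f"t{i}"
                tes.append(te)
            df = find_flanking_pairs(tes, genes)
            got = set(zip(df.te_id, df.gene_id, df.distance))
            assert got == brute_force_pairs(tes, genes)


class TestDifferentialExpression:
    def test_identical_groups_not_significant(self):
        d = design2()
        counts = pd.DataFrame({s: [100, 50] for s in d["sample"]},
                              index=["f1", "f2"])
        res = differential_expression(counts, d, 0, 250)
        assert np.allclose(res.log2fc, 0)
        assert not res.significant.any()

    def test_fourfold_means_give_lfc_two(self):
        # one 4x feature among many stable ones, so median-of-ratios size
        # factors are pinned by the stable majority
        d = design2()
        cols = {}
        for c in (0, 250, 500):
            for r in (1, 2):
                cols[f"leaf_{c}_r{r}"] = [40 if c == 0 else 10] + [100] * 9
        counts = pd.DataFrame(cols, index=["f1"] + [f"ref{i}" for i in range(9)])
        res = differential_expression(counts, d, 0, 250)
        assert res.loc["f1", "log2fc"] == pytest.approx(2.0, abs=0.05)

    def test_single_replicate_rejected(self):
        d = make_design(tissues=("leaf",), conditions=(0, 250), n_replicates=1)
        counts = pd.DataFrame({s: [10] for s in d["sample"]}, index=["f1"])
        with pytest.raises(ValueError):
            differential_expression(counts, d, 0, 250)

    def test_null_false_discovery_controlled(self):
        """2000 NB null features, 2 vs 2: the flagged fraction stays within
        the binomial envelope of alpha."""
        d = make_design(tissues=("leaf",), conditions=(0, 250), n_replicates=2)
        cfg = SimConfig()
        counts = simulate_null_matrix(2000, d, cfg, seed=31)
        res = differential_expression(counts, d, 0, 250)
        frac = res.significant.mean()
        se = np.sqrt(0.05 * 0.95 / len(res))
        assert frac <= 0.05 + 2 * se


class TestEnrichment:
    def test_proportional_table(self):
        odds, p = enrichment_test(1, 10, 11, 110)
        assert odds == pytest.approx(1.0)
        assert p == pytest.approx(1.0)

    def test_adjacent_set_is_whole_set(self):
        _, p = enrichment_test(7, 100, 7, 100)
        assert p == pytest.approx(1.0)

    def test_complete_concentration_significant(self):
        _, p = enrichment_test(5, 5, 5, 100)
        assert p < 1e-3

    def test_inconsistent_margins_rejected(self):
        with pytest.raises(ValueError):
            enrichment_test(5, 3, 5, 100)


class TestCorrelatePairs:
    def _setup(self, te_vals, gene_vals):
        d = design2()
        te = pd.DataFrame({s: [v] for s, v in zip(d["sample"], te_vals)},
                          index=["te1"])
        gene = pd.DataFrame({s: [v] for s, v in zip(d["sample"], gene_vals)},
                            index=["g1"])
        pairs = pd.DataFrame({"te_id": ["te1"], "gene_id": ["g1"],
                              "relation": ["upstream"], "distance": [100]})
        return te, gene, d, pairs

    def test_collinear_pair_r_one(self):
        te, gene, d, pairs = self._setup([1, 1, 2, 2, 3, 3], [2, 2, 4, 4, 6, 6])
        res = correlate_pairs(te, gene, d, pairs, "leaf")
        assert res.iloc[0].r == pytest.approx(1.0)

    def test_anticollinear_pair_r_minus_one(self):
        te, gene, d, pairs = self._setup([1, 1, 2, 2, 3, 3], [3, 3, 2, 2, 1, 1])
        res = correlate_pairs(te, gene, d, pairs, "leaf")
        assert res.iloc[0].r == pytest.approx(-1.0)

    def test_constant_vector_untestable(self):
        te, gene, d, pairs = self._setup([1, 1, 2, 2, 3, 3], [5, 5, 5, 5, 5, 5])
        res = correlate_pairs(te, gene, d, pairs, "leaf")
        assert not res.iloc[0].testable and np.isnan(res.iloc[0].r)

    def test_unexpressed_members_skipped(self):
        te, gene, d, pairs = self._setup([1, 1, 2, 2, 3, 3], [2, 2, 4, 4, 6, 6])
        res = correlate_pairs(te, gene, d, pairs, "leaf", expressed_tes=set())
        assert len(res) == 0

    def test_planted_pairs_recovered_null_pairs_controlled(self):
        """Replicate-mode screen on a calibration panel: >= 90% of planted
        collinear pairs pass BH while null pairs stay at or below alpha."""
        d = design2()
        te_c, gene_c, pairs, signs = simulate_pair_panel(
            50, 500, d, SimConfig(), seed=77)
        res = correlate_pairs(te_c.astype(float), gene_c.astype(float), d,
                              pairs, "leaf", mode="replicates")
        res = res.set_index("te_id")
        planted = res.loc[list(signs)]
        null = res.drop(index=list(signs))
        assert (planted.significant).mean() >= 0.9
        assert null.significant.mean() <= 0.05
        # recovered signs match the planted signs
        ok = [np.sign(planted.loc[t].r) == s for t, s in signs.items()
              if planted.loc[t].testable]
        assert all(ok)


class TestSpongePairs:
    def _tables(self, te_seq, tx_seq, te_site=(40, 61)):
        targets = pd.DataFrame({
            "mirna_id": ["miR1", "miR1"],
            "feature_id": ["te1", "g1"],
            "start": [te_site[0], 5],
            "end": [te_site[1], 26],
        })
        return {"te1": te_seq}, {"g1": tx_seq}, targets

    def test_shared_sense_block_with_site_is_candidate(self):
        rng = np.random.default_rng(13)
        block = "".join(rng.choice(list("ACGT"), 60))
        te_seq = "".join(rng.choice(list("ACGT"), 30)) + block
        tx_seq = block + "".join(rng.choice(list("ACGT"), 30))
        tes, txs, targets = self._tables(te_seq, tx_seq, te_site=(40, 61))
        res = screen_sponge_pairs(tes, txs, targets, {"te1"}, {"g1"})
        assert len(res) == 1 and res.iloc[0].match_length >= 20

    def test_antisense_match_rejected(self):
        comp = {"A": "T", "C": "G", "G": "C", "T": "A"}
        rng = np.random.default_rng(14)
        block = "".join(rng.choice(list("ACGT"), 60))
        rc = "".join(comp[b] for b in reversed(block))
        tes, txs, targets = self._tables("A" * 30 + block, rc + "A" * 30)
        res = screen_sponge_pairs(tes, txs, targets, {"te1"}, {"g1"})
        assert len(res) == 0

    def test_site_outside_matched_block_rejected(self):
        rng = np.random.default_rng(15)
        block = "".join(rng.choice(list("ACGT"), 40))
        te_seq = block + "".join(rng.choice(list("ACGT"), 200))
        tx_seq = block
        # binding site far beyond the shared block
        tes, txs, targets = self._tables(te_seq, tx_seq, te_site=(150, 171))
        res = screen_sponge_pairs(tes, txs, targets, {"te1"}, {"g1"})
        assert len(res) == 0

    def test_unexpressed_te_rejected(self):
        rng = np.random.default_rng(16)
        block = "".join(rng.choice(list("ACGT"), 60))
        tes, txs, targets = self._tables("A" * 30 + block, block)
        res = screen_sponge_pairs(tes, txs, targets, set(), {"g1"})
        assert len(res) == 0

    def test_missing_sequence_is_error(self):
        targets = pd.DataFrame({"mirna_id": ["m"], "feature_id": ["ghost"],
                                "start": [0], "end": [21]})
        with pytest.raises(ValueError):
            screen_sponge_pairs({}, {}, targets, set(), set())
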