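"""Isoform model IO, merging rules, diversity, and the chi-square
differential-usage test."""

import random

import numpy as np
import pandas as pd
import pytest
from scipy import stats as scipy_stats

from oracles import chi2_closed_form_2x2, transitive_closure_groups
from sclrtools.isoforms import (
    DegenerateTableError,
    DiffUsageParams,
    IsoformModel,
    MergeParams,
    chi2_contingency,
    collect_site_support,
    diff_isoform_usage,
    diversity_stats,
    merge_isoforms,
    quantify_by_group,
    read_psl,
    splice_sites_equivalent,
    usage_results_frame,
    write_psl,
)
from sclrtools.simulate import simulate_cell_isoforms


def iso(iid, src, start, end, chain, support=1, gene=None, chrom="chr1", strand="+"):
    return IsoformModel(iid, src, chrom, strand, start, end, chain, support, gene)


CHAIN = ((1000, 2000), (3000, 4000))


class TestPsl:
    def test_round_trip_and_golden_bytes(self, tmp_path):
        models = [
            iso("iso1", "c1", 500, 5000, CHAIN),
            iso("iso2", "c1", 100, 900, ()),
        ]
        p = tmp_path / "models.psl"
        write_psl(models, p)
        back = read_psl(p, source="c1")
        for a, b in zip(models, back):
            assert (a.isoform_id, a.chrom, a.strand, a.start, a.end, a.splice_chain) == (
                b.isoform_id, b.chrom, b.strand, b.start, b.end, b.splice_chain
            )
        p2 = tmp_path / "again.psl"
        write_psl(back, p2)
        assert p.read_bytes() == p2.read_bytes()

    def test_three_exon_chain_from_blocks(self, tmp_path):
        # hand-written PSL: blocks 100-200, 300-450, 600-700
        line = "\t".join(
            [
                "350", "0", "0", "0", "0", "0", "0", "0", "+", "manual",
                "350", "0", "350", "chr9", "1000", "100", "700", "3",
                "100,150,100,", "0,100,250,", "100,300,600,",
            ]
        )
        p = tmp_path / "hand.psl"
        p.write_text(line + "\n")
        (m,) = read_psl(p)
        assert m.splice_chain == ((200, 300), (450, 600))

    def test_empty_file(self, tmp_path):
        p = tmp_path / "empty.psl"
        p.write_text("")
        assert read_psl(p) == []

    def test_malformed_line_reports_number(self, tmp_path):
        p = tmp_path / "bad.psl"
        p.write_text("only\tthree\tcolumns\n")
        with pytest.raises(ValueError, match="bad.psl:1"):
            read_psl(p)

    def test_invalid_chain_rejected(self):
        with pytest.raises(ValueError, match="strictly increasing"):
            iso("x", "c", 0, 100, ((50, 40),))


class TestSpliceEquivalence:
    def test_identical_chains(self):
        assert splice_sites_equivalent(CHAIN, CHAIN, {})

    def test_one_bp_off_requires_abundance_skew(self):
        other = ((1000, 2001), (3000, 4000))
        support = {2000: 100, 2001: 2}
        assert splice_sites_equivalent(CHAIN, other, support)
        support = {2000: 100, 2001: 99}
        assert not splice_sites_equivalent(CHAIN, other, support)

    def test_two_bp_off_never_equivalent(self):
        other = ((1000, 2002), (3000, 4000))
        assert not splice_sites_equivalent(CHAIN, other, {2000: 1000, 2002: 1})

    def test_different_lengths(self):
        assert not splice_sites_equivalent(CHAIN, CHAIN[:1], {})


class TestMergeIsoforms:
    def test_end_window_boundary(self):
        a = iso("A", "c1", 50, 5000, CHAIN)
        b = iso("B", "c2", 50, 5008, CHAIN)  # 8 nt apart -> merge
        assert len(merge_isoforms([a, b])) == 1
        c = iso("C", "c3", 50, 5011, CHAIN)  # 11 nt apart -> no merge
        assert len(merge_isoforms([a, c])) == 2

    def test_chained_linkage(self):
        a = iso("A", "c1", 50, 5000, CHAIN)
        b = iso("B", "c2", 50, 5008, CHAIN)
        c = iso("C", "c3", 50, 5017, CHAIN)  # 17 nt from A, 9 from B
        groups = merge_isoforms([a, b, c])
        assert len(groups) == 1 and len(groups[0].members) == 3

    def test_strand_and_chrom_separate(self):
        a = iso("A", "c1", 50, 5000, CHAIN, strand="+")
        b = iso("B", "c2", 50, 5000, CHAIN, strand="-")
        c = iso("C", "c3", 50, 5000, CHAIN, chrom="chr2")
        assert len(merge_isoforms([a, b, c])) == 3

    def test_partition_and_shuffle_invariance(self):
        rng = random.Random(3)
        models = self._random_models(rng, 40)
        base = merge_isoforms(models)
        assert sum(len(g.members) for g in base) == len(models)
        shuffled = models[:]
        rng.shuffle(shuffled)
        again = merge_isoforms(shuffled)
        key = lambda groups: sorted(
            tuple(sorted(m.isoform_id for m in g.members)) for g in groups
        )
        assert key(base) == key(again)

    def test_agrees_with_transitive_closure_oracle(self):
        params = MergeParams()
        rng = random.Random(11)
        for trial in range(25):
            models = self._random_models(rng, 30)
            groups = merge_isoforms(models, params)
            support = collect_site_support(models)

            def linked(x, y):
                if (x.chrom, x.strand) != (y.chrom, y.strand):
                    return False
                ctx = {
                    pos: s
                    for (c, st, pos), s in support.items()
                    if c == x.chrom and st == x.strand
                }
                return (
                    abs(x.start - y.start) <= params.end_window
                    and abs(x.end - y.end) <= params.end_window
                    and splice_sites_equivalent(x.splice_chain, y.splice_chain, ctx, params)
                )

            expected = {
                frozenset(m.isoform_id for m in g)
                for g in transitive_closure_groups(models, linked)
            }
            got = {frozenset(m.isoform_id for m in g.members) for g in groups}
            assert got == expected

    @staticmethod
    def _random_models(rng, n):
        models = []
        for i in range(n):
            start = rng.randrange(0, 40)
            end = 5000 + rng.randrange(0, 40)
            donor = 1000 + rng.choice([0, 1, 2])
            chain = ((donor, 2000), (3000, 4000)) if rng.random() < 0.8 else ((1000, 2000),)
            models.append(
                iso(f"i{i:03d}", f"c{i:03d}", start, end, chain, support=rng.randrange(1, 200))
            )
        return models

    def test_representative_and_cell_count(self):
        a = iso("A", "c1", 50, 5000, CHAIN, support=10)
        b = iso("B", "c2", 50, 5005, CHAIN, support=3)
        c = iso("C", "c1", 50, 5003, CHAIN, support=3)
        (g,) = merge_isoforms([a, b, c])
        assert g.representative.isoform_id == "A"
        assert g.cell_count == 2  # c1 appears twice
        assert g.total_support == 16


class TestDiversity:
    def test_single_shared_isoform(self):
        models = simulate_cell_isoforms("RPL35_like", 5, 1, seed=1)
        groups = merge_isoforms(models)
        table = diversity_stats(groups)
        row = table.iloc[0]
        assert row["cells_expressing"] == 5 and row["unique_merged_isoforms"] == 1

    def test_all_distinct_isoforms(self):
        base = [
            iso(f"I{k}", f"c{k}", 100, 5000, ((1000 + 40 * k, 2000), (3000, 4000)), gene="G")
            for k in range(5)
        ]
        table = diversity_stats(merge_isoforms(base))
        assert table.iloc[0]["unique_merged_isoforms"] == 5

    def test_low_vs_high_diversity_ordering(self):
        low = simulate_cell_isoforms("low_div", 40, 2, seed=2)
        high = simulate_cell_isoforms("high_div", 40, 40, seed=3, gene_start=900_000)
        table = diversity_stats(merge_isoforms(low + high))
        t = table.set_index("gene_id")
        assert (
            t.loc["high_div", "unique_merged_isoforms"]
            > t.loc["low_div", "unique_merged_isoforms"]
        )

    def test_bulk_ratio_undefined_flag(self):
        models = simulate_cell_isoforms("g1", 3, 1, seed=4)
        table = diversity_stats(merge_isoforms(models), {"other_gene": 5})
        assert bool(table.iloc[0]["ratio_undefined"])


class TestQuantify:
    def _supports(self):
        return pd.DataFrame(
            {
                "gene_id": ["g1"] * 4 + ["g2"] * 2,
                "isoform_id": ["a", "a", "b", "b", "c", "c"],
                "cell_id": ["c1", "c2", "c1", "c3", "c1", "c9"],
                "support": [2, 3, 1, 4, 5, 7],
            }
        )

    def test_hand_summed_tensor(self):
        types = pd.DataFrame(
            {"cell_id": ["c1", "c2", "c3"], "cell_type": ["B", "B", "T"]}
        )
        tensor, dropped = quantify_by_group(self._supports(), types)
        assert dropped == 1  # c9 unmapped
        assert tensor.loc[("g1", "a"), "B"] == 5
        assert tensor.loc[("g1", "b"), "T"] == 4
        assert tensor.to_numpy().sum() == 2 + 3 + 1 + 4 + 5

    def test_single_cell_type_collapses(self):
        types = pd.DataFrame({"cell_id": ["c1", "c2", "c3", "c9"], "cell_type": "B"})
        tensor, dropped = quantify_by_group(self._supports(), types)
        assert dropped == 0
        assert list(tensor.columns) == ["B"]


class TestChi2:
    def test_uniform_table_is_zero(self):
        chi2, df, p = chi2_contingency([[10, 10], [10, 10]])
        assert chi2 == 0.0 and df == 1 and p == 1.0

    def test_closed_form_2x2(self):
        table = [[20, 5], [5, 20]]
        chi2, df, _ = chi2_contingency(table)
        assert chi2 == pytest.approx(chi2_closed_form_2x2(table))
        assert chi2 == pytest.approx(18.0)

    def test_matches_reference_implementation(self):
        rng = np.random.default_rng(7)
        checked = 0
        while checked < 300:
            table = rng.integers(0, 60, size=(rng.integers(2, 5), rng.integers(2, 5)))
            if not (table.sum(axis=1).all() and table.sum(axis=0).all()):
                continue
            chi2, df, p = chi2_contingency(table)
            ref = scipy_stats.chi2_contingency(table, correction=False)
            assert chi2 == pytest.approx(ref.statistic, abs=1e-10)
            assert p == pytest.approx(ref.pvalue, abs=1e-10)
            assert df == ref.dof
            checked += 1

    def test_p_monotone_under_scaling(self):
        table = np.array([[12, 8], [8, 12]])
        ps = [chi2_contingency(table * k)[2] for k in (1, 2, 4)]
        assert ps[0] > ps[1] > ps[2]

    def test_degenerate_raises(self):
        with pytest.raises(DegenerateTableError):
            chi2_contingency([[5, 5]])
        with pytest.raises(DegenerateTableError):
            chi2_contingency([[5, 0], [7, 0]])


class TestDiffUsage:
    def _tensor(self, rows):
        df = pd.DataFrame(rows, columns=["gene_id", "isoform_id", "B", "T", "M"])
        return df.set_index(["gene_id", "isoform_id"])

    def test_single_cell_type_gene_skipped(self):
        tensor = self._tensor([("g1", "a", 10, 0, 0), ("g1", "b", 20, 0, 0)])
        assert diff_isoform_usage(tensor) == []

    def test_single_isoform_gene_skipped(self):
        tensor = self._tensor([("g1", "a", 10, 12, 9)])
        assert diff_isoform_usage(tensor) == []

    def test_identical_proportions_not_significant(self):
        tensor = self._tensor(
            [("g1", "a", 100, 200, 300), ("g1", "b", 100, 200, 300)]
        )
        (res,) = diff_isoform_usage(tensor)
        assert not res.significant and res.p_value == pytest.approx(1.0)

    def test_power_exceeds_null_rate(self):
        rng = np.random.default_rng(15)
        rows = []
        n_null, n_alt = 150, 150
        for g in range(n_null):
            p = np.array([0.5, 0.5])
            counts_b = rng.multinomial(200, p)
            counts_t = rng.multinomial(200, p)
            rows.append((f"null{g}", "a", counts_b[0], counts_t[0], 0))
            rows.append((f"null{g}", "b", counts_b[1], counts_t[1], 0))
        for g in range(n_alt):
            counts_b = rng.multinomial(200, [0.8, 0.2])
            counts_t = rng.multinomial(200, [0.2, 0.8])
            rows.append((f"alt{g}", "a", counts_b[0], counts_t[0], 0))
            rows.append((f"alt{g}", "b", counts_b[1], counts_t[1], 0))
        tensor = self._tensor(rows)
        results = diff_isoform_usage(tensor, DiffUsageParams(alpha=0.01))
        frame = usage_results_frame(results)
        alt_rate = frame[frame.gene_id.str.startswith("alt")]["significant"].mean()
        null_rate = frame[frame.gene_id.str.startswith("null")]["significant"].mean()
        assert alt_rate > 0.95
        assert null_rate < 0.05
        assert alt_rate > null_rate
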