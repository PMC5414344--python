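"""ESCG completeness/contamination, F1, categories and binning comparison."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from binref import (
    BinAssignmentTable,
    BinrefError,
    ESCGTable,
    bin_quality_report,
    categorize,
    compare_binnings,
    escg_stats,
    f1_score,
    method_averages,
    quality_from_checkm,
)
from binref.quality import (
    brute_force_ari,
    completeness_category,
    contamination_category,
    pairwise_ari,
)


def make_escg(counts: dict, universe_size=109, genes=None):
    genes = genes or sorted({g for row in counts.values() for g in row})
    df = pd.DataFrame(0, index=list(counts), columns=genes, dtype=int)
    for cid, row in counts.items():
        for g, n in row.items():
            df.loc[cid, g] = n
    return ESCGTable(counts=df, universe_size=universe_size)


class TestEscgStats:
    def test_full_single_copy_panel(self):
        genes = [f"g{i}" for i in range(109)]
        escg = make_escg({"c1": {g: 1 for g in genes}}, genes=genes)
        q = escg_stats(["c1"], escg)
        assert (q.completeness, q.contamination, q.n_multi) == (100.0, 0.0, 0)

    def test_empty_selection_scores_zero(self):
        escg = make_escg({"c1": {"g1": 1}})
        q = escg_stats([], escg)
        assert (q.completeness, q.contamination, q.n_found) == (0.0, 0.0, 0)

    def test_partial_panel_with_duplicates(self):
        # 50 genes present, 10 of them in exactly two copies
        counts = {f"c{i}": {f"g{i}": 1} for i in range(50)}
        for i in range(10):
            counts[f"d{i}"] = {f"g{i}": 1}
        escg = make_escg(counts)
        q = escg_stats(list(counts), escg)
        assert q.completeness == pytest.approx(100 * 50 / 109)
        assert q.contamination == pytest.approx(100 * 10 / 109)
        assert q.n_multi == 10

    def test_extra_namespace_genes_ignored(self):
        df = pd.DataFrame({"g1": [1], "weird": [5]}, index=["c1"])
        escg = ESCGTable(counts=df, universe_size=109, extra_genes=["weird"])
        q = escg_stats(["c1"], escg)
        assert q.n_found == 1
        assert q.contamination == 0.0

    @settings(max_examples=40, deadline=None)
    @given(st.data())
    def test_monotone_in_selection_growth(self, data):
        rng_seed = data.draw(st.integers(0, 1000))
        rng = np.random.default_rng(rng_seed)
        ids = [f"c{i}" for i in range(8)]
        genes = [f"g{i}" for i in range(6)]
        counts = pd.DataFrame(
            rng.integers(0, 3, size=(8, 6)), index=ids, columns=genes
        )
        escg = ESCGTable(counts=counts, universe_size=6)
        k = data.draw(st.integers(0, 7))
        small, big = ids[:k], ids[: k + 1]
        qs, qb = escg_stats(small, escg), escg_stats(big, escg)
        assert qb.completeness >= qs.completeness
        assert qb.contamination >= qs.contamination


class TestF1:
    @pytest.mark.parametrize(
        "completeness,contamination,expected",
        [(100, 0, 100.0), (50, 120, 0.0), (0, 0, 0.0), (80, 100, 2 * 0 * 80 / 80)],
    )
    def test_boundary_rules(self, completeness, contamination, expected):
        assert f1_score(completeness, contamination) == pytest.approx(expected)

    @settings(max_examples=80, deadline=None)
    @given(
        st.floats(0, 100),
        st.floats(0, 150),
        st.floats(0, 150),
    )
    def test_non_increasing_in_contamination(self, c, x1, x2):
        lo, hi = sorted((x1, x2))
        assert f1_score(c, hi) <= f1_score(c, lo) + 1e-9

    @settings(max_examples=80, deadline=None)
    @given(st.floats(0, 100), st.floats(0, 100), st.floats(0, 100))
    def test_non_decreasing_in_completeness(self, x, c1, c2):
        lo, hi = sorted((c1, c2))
        assert f1_score(hi, x) + 1e-9 >= f1_score(lo, x)

    def test_out_of_range_rejected(self):
        with pytest.raises(BinrefError):
            f1_score(101, 0)
        with pytest.raises(BinrefError):
            f1_score(50, -1)


class TestBinQualityReport:
    def test_single_bin_equals_full_set_stats(self, small_community):
        table = BinAssignmentTable(
            data=pd.DataFrame(
                {"m": ["all"] * len(small_community.contigs)},
                index=small_community.contigs.ids,
            )
        )
        report = bin_quality_report(table, "m", small_community.escg)
        direct = escg_stats(small_community.contigs.ids, small_community.escg)
        assert len(report) == 1
        assert report[0].completeness == direct.completeness
        assert report[0].contamination == direct.contamination

    def test_one_row_per_bin_sorted_by_completeness(self, small_community):
        report = bin_quality_report(
            small_community.truth, "truth", small_community.escg,
            contigs=small_community.contigs,
        )
        assert len(report) == 3
        comp = [q.completeness for q in report]
        assert comp == sorted(comp, reverse=True)
        assert all(q.total_nt and q.total_nt > 0 for q in report)

    def test_splitting_a_bin_never_raises_either_parts_completeness(
        self, small_community
    ):
        members = small_community.truth.bins("truth")["genome1"]
        whole = escg_stats(members, small_community.escg)
        for cut in (1, len(members) // 2, len(members) - 1):
            a = escg_stats(members[:cut], small_community.escg)
            b = escg_stats(members[cut:], small_community.escg)
            assert a.completeness <= whole.completeness
            assert b.completeness <= whole.completeness


class TestCategories:
    @pytest.mark.parametrize(
        "value,category",
        [(95, "near"), (90, "near"), (89.9, "substantial"), (70, "substantial"),
         (50, "moderate"), (49.9, "partial"), (0, "partial")],
    )
    def test_completeness_boundaries_closed_on_left(self, value, category):
        assert completeness_category(value) == category

    @pytest.mark.parametrize(
        "value,category",
        [(0, "low"), (5, "low"), (5.3, "medium"), (10, "medium"),
         (10.1, "high"), (15, "high"), (15.1, "very_high"), (120, "very_high")],
    )
    def test_contamination_boundaries(self, value, category):
        assert contamination_category(value) == category

    def test_counts_sum_to_number_of_bins(self):
        qualities = [quality_from_checkm(c, x) for c, x in
                     [(95, 1), (60, 7), (40, 20), (75, 3)]]
        summary = categorize(qualities)
        assert sum(summary.completeness_counts.values()) == 4
        assert sum(summary.contamination_counts.values()) == 4

    def test_empty_input_all_zero(self):
        summary = categorize([])
        assert set(summary.completeness_counts.values()) == {0}
        assert summary.n_bins == 0


class TestMethodAverages:
    def test_single_bin_means_equal_its_values(self):
        avg = method_averages([quality_from_checkm(80.0, 2.0)])
        assert avg.mean_completeness == 80.0
        assert avg.mean_contamination == 2.0
        assert avg.mean_f1 == pytest.approx(f1_score(80.0, 2.0))

    def test_empty_rejected(self):
        with pytest.raises(BinrefError):
            method_averages([])


class TestCompareBinnings:
    def _table(self, a, b):
        ids = [f"c{i}" for i in range(len(a))]
        return BinAssignmentTable(
            data=pd.DataFrame({"ma": a, "mb": b}, index=ids)
        )

    def test_identical_columns_ari_one(self):
        labels = ["x", "x", "y", "y", "z"]
        _, ari = compare_binnings(self._table(labels, labels), "ma", "mb")
        assert ari == pytest.approx(1.0)

    def test_singletons_vs_one_bin_ari_zero(self):
        a = [f"s{i}" for i in range(6)]
        b = ["all"] * 6
        _, ari = compare_binnings(self._table(a, b), "ma", "mb")
        assert ari == pytest.approx(0.0)

    @pytest.mark.parametrize("seed", range(5))
    def test_matches_brute_force_pair_counting_oracle(self, seed):
        rng = np.random.default_rng(seed)
        n = int(rng.integers(5, 21))
        a = [f"a{v}" for v in rng.integers(0, 4, n)]
        b = [f"b{v}" for v in rng.integers(0, 3, n)]
        assert pairwise_ari(a, b) == pytest.approx(brute_force_ari(a, b), abs=1e-12)

    def test_contingency_counts_shared_contigs(self):
        table = self._table(["x", "x", "y", "y"], ["p", "p", "p", "q"])
        contingency, _ = compare_binnings(table, "ma", "mb")
        assert contingency.loc["x", "p"] == 2
        assert contingency.loc["y", "q"] == 1

    def test_unbinned_in_either_method_excluded(self):
        table = self._table(["x", "x", "unbinned"], ["p", "p", "p"])
        contingency, _ = compare_binnings(table, "ma", "mb")
        assert contingency.to_numpy().sum() == 2
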