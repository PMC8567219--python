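"""Setup integration, fold-change classification and statistical tests."""

from itertools import combinations
from math import comb

import numpy as np
import pandas as pd
import pytest

from phosphoflow import (
    ClassRules,
    FormatError,
    assign_sets,
    classify_dependency,
    classify_hog1_dependence,
    classify_regulation,
    compare_distributions,
    enrichment_test,
    merge_setups,
    summarize_fractions,
)
from phosphoflow.sites import PhosphoSite


def _site(protein, positions, residues, setup, final):
    return PhosphoSite(
        protein_id=protein, positions=positions, residues=residues, setup=setup,
        per_replicate_log2={"r1": final}, final_log2=final, n_evidence=1,
    )


class TestMergeSetups:
    def test_outer_join_counts(self):
        a = [_site("P1", (1,), "S", "A", 0.1), _site("P1", (2,), "S", "A", 0.2),
             _site("P2", (3,), "T", "A", 0.3)]
        b = [_site("P1", (2,), "S", "B", 0.5), _site("P3", (9,), "S", "B", 0.6),
             _site("P4", (4,), "T", "B", 0.7)]
        matrix = merge_setups({"A": a, "B": b})
        assert len(matrix) == 5
        assert matrix.loc[("P1", "2"), "A"] == 0.2
        assert matrix.loc[("P1", "2"), "B"] == 0.5
        assert np.isnan(matrix.loc[("P2", "3"), "B"])

    def test_identical_tables_keep_row_count(self):
        a = [_site("P1", (1,), "S", "A", 0.1)]
        b = [_site("P1", (1,), "S", "B", 0.9)]
        assert len(merge_setups({"A": a, "B": b})) == 1

    def test_empty_second_table_all_missing_column(self):
        a = [_site("P1", (1,), "S", "A", 0.1)]
        matrix = merge_setups({"A": a, "B": []})
        assert len(matrix) == 1
        assert matrix["B"].isna().all()

    def test_conflicting_residues_rejected(self):
        a = [_site("P1", (1,), "S", "A", 0.1)]
        b = [_site("P1", (1,), "T", "B", 0.2)]
        with pytest.raises(FormatError, match="conflicting"):
            merge_setups({"A": a, "B": b})

    def test_outer_join_conserves_sites(self):
        a = [_site("P1", (i,), "S", "A", float(i)) for i in range(1, 6)]
        b = [_site("P1", (i,), "S", "B", float(i)) for i in range(3, 9)]
        matrix = merge_setups({"A": a, "B": b})
        assert len(matrix) == 8  # union of identities, each exactly once


class TestClassification:
    @pytest.mark.parametrize(
        "log2, expected",
        [(1.0, "induced"), (-1.0, "decreased"), (0.99, "static"),
         (-0.99, "static"), (2.5, "induced")],
    )
    def test_twofold_cutoff(self, log2, expected):
        assert classify_regulation(log2) == expected

    def test_missing_is_unclassified(self):
        assert classify_regulation(float("nan")) is None

    @pytest.mark.parametrize(
        "sr, inh, expected",
        [(1.2, -1.5, True), (1.2, -0.5, False), (0.5, -2.0, False)],
    )
    def test_hog1_dependence(self, sr, inh, expected):
        assert classify_hog1_dependence(sr, inh) is expected

    def test_hog1_dependence_missing_undetermined(self):
        assert classify_hog1_dependence(float("nan"), -2.0) is None

    @pytest.mark.parametrize(
        "log2, expected", [(1.5, True), (-1.5, True), (0.5, False), (1.0, False)]
    )
    def test_dependency_rule(self, log2, expected):
        assert classify_dependency(log2) is expected

    def test_monotone_in_ratio(self):
        order = {"decreased": 0, "static": 1, "induced": 2}
        grid = np.linspace(-3, 3, 61)
        ranks = [order[classify_regulation(x)] for x in grid]
        assert ranks == sorted(ranks)


class TestAssignSets:
    def _matrix(self, igo_values):
        rows = []
        for i, igo in enumerate(igo_values):
            rows.append(("P1", str(i), "S", 1.5, 1.5, igo))
        df = pd.DataFrame(
            rows, columns=["protein", "positions", "residues", "SR", "cdc55",
                           "SR_igo1igo2"],
        ).set_index(["protein", "positions"])
        return df

    def test_rule_evaluation(self):
        matrix = self._matrix([-1.7, -0.4, 0.2, np.nan])
        labels = assign_sets(matrix)
        assert list(labels) == ["Set1", "Set2", "other", pd.NA]

    def test_outside_universe_unassigned(self):
        matrix = self._matrix([-1.7])
        matrix["SR"] = 0.5  # not stress-induced
        assert assign_sets(matrix).isna().all()

    def test_set1_set2_mutually_exclusive(self):
        labels = assign_sets(self._matrix(list(np.linspace(-3, 1, 41))))
        assert not (labels.eq("Set1") & labels.eq("Set2")).any()


class TestSummarizeFractions:
    def test_counting(self):
        values = [1.5, 2.0] + [-1.2] + [0.0] * 7
        matrix = pd.DataFrame({"SR": values})
        out = summarize_fractions(matrix)
        assert tuple(out.loc["SR", ["induced_pct", "decreased_pct", "static_pct"]]) == (
            20.0, 10.0, 70.0,
        )

    def test_all_static(self):
        out = summarize_fractions(pd.DataFrame({"SR": [0.0, 0.2, -0.3]}))
        assert tuple(out.loc["SR", ["induced_pct", "decreased_pct", "static_pct"]]) == (
            0.0, 0.0, 100.0,
        )

    def test_rows_sum_to_100_and_missing_excluded(self):
        rng = np.random.default_rng(4)
        values = rng.normal(0, 1.5, 50)
        values[::7] = np.nan
        out = summarize_fractions(pd.DataFrame({"A": values, "B": -values}))
        sums = out[["induced_pct", "decreased_pct", "static_pct"]].sum(axis=1)
        assert np.allclose(sums, 100.0)
        assert (out["n"] == np.isfinite(values).sum()).all()


def fisher_exact_enumeration(table):
    """Oracle: two-sided Fisher p by exact hypergeometric enumeration with
    integer binomial coefficients."""
    (a, b), (c, d) = table
    r1, r2, c1 = a + b, c + d, a + c
    n = r1 + r2
    denom = comb(n, c1)

    def weight(x):
        return comb(r1, x) * comb(r2, c1 - x)

    w_obs = weight(a)
    total = sum(
        weight(x)
        for x in range(max(0, c1 - r2), min(r1, c1) + 1)
        if weight(x) <= w_obs
    )
    return total / denom


class TestEnrichmentTest:
    def test_no_association(self):
        odds, p = enrichment_test([[10, 10], [10, 10]])
        assert odds == pytest.approx(1.0)
        assert p == pytest.approx(1.0)

    def test_or_and_p_match_enumeration(self):
        odds, p = enrichment_test([[8, 2], [2, 8]])
        assert odds == pytest.approx(16.0)
        assert p == pytest.approx(fisher_exact_enumeration([[8, 2], [2, 8]]), abs=1e-10)

    def test_infinite_or_flagged_min_tail(self):
        odds, p = enrichment_test([[5, 0], [0, 5]])
        assert np.isinf(odds)
        assert p == pytest.approx(fisher_exact_enumeration([[5, 0], [0, 5]]), abs=1e-10)
        assert p == pytest.approx(2 / comb(10, 5), abs=1e-12)

    def test_zero_margin_flagged(self):
        odds, p = enrichment_test([[0, 0], [3, 4]])
        assert np.isnan(odds)
        assert p == 1.0

    def test_random_tables_match_enumeration(self):
        rng = np.random.default_rng(0)
        for _ in range(200):
            t = rng.integers(0, 15, size=(2, 2))
            if 0 in t.sum(axis=0) or 0 in t.sum(axis=1):
                continue
            _, p = enrichment_test(t)
            assert p == pytest.approx(fisher_exact_enumeration(t.tolist()), abs=1e-10)

    def test_random_tables_match_scipy_fisher_exact(self):
        from scipy import stats

        rng = np.random.default_rng(1)
        for _ in range(200):
            t = rng.integers(0, 40, size=(2, 2))
            if 0 in t.sum(axis=0) or 0 in t.sum(axis=1):
                continue
            odds, p = enrichment_test(t)
            ref_odds, ref_p = stats.fisher_exact(t)
            assert p == pytest.approx(ref_p, abs=1e-10)
            assert odds == pytest.approx(ref_odds)

    @pytest.mark.parametrize("alternative", ["greater", "less"])
    def test_one_sided_variants_match_scipy(self, alternative):
        from scipy import stats

        table = [[12, 5], [4, 11]]
        _, p = enrichment_test(table, alternative=alternative)
        assert p == pytest.approx(
            stats.fisher_exact(table, alternative=alternative).pvalue, abs=1e-12
        )


def rank_sum_enumeration(a, b):
    """Oracle: exact two-sided rank-sum p over all group assignments."""
    from scipy.stats import rankdata

    pooled = np.concatenate([a, b])
    ranks = rankdata(pooled)
    na, n = len(a), len(pooled)
    mean = na * (n + 1) / 2
    obs = abs(ranks[: na].sum() - mean)
    hits = sum(
        abs(ranks[list(idx)].sum() - mean) >= obs - 1e-12
        for idx in combinations(range(n), na)
    )
    return hits / comb(n, na)


class TestCompareDistributions:
    def test_identical_groups_p_one(self):
        assert compare_distributions([1, 2, 3], [1, 2, 3]) == pytest.approx(1.0)

    def test_smallest_attainable_exact_p_4v4(self):
        a, b = [0.0] * 4, [5.0] * 4
        p = compare_distributions(a, b)
        assert p == pytest.approx(2 / comb(8, 4))
        assert p == pytest.approx(rank_sum_enumeration(a, b))

    def test_small_samples_match_enumeration(self):
        rng = np.random.default_rng(7)
        for _ in range(20):
            a = rng.normal(0, 1, rng.integers(2, 6))
            b = rng.normal(0.5, 1, rng.integers(2, 6))
            assert compare_distributions(a, b) == pytest.approx(
                rank_sum_enumeration(a, b)
            )

    def test_shifted_normals_strongly_significant(self):
        rng = np.random.default_rng(1)
        for _ in range(50):
            a = rng.normal(0.0, 0.3, 200)
            b = rng.normal(1.0, 0.3, 200)
            assert compare_distributions(a, b, method="wilcoxon") < 1e-6
            assert compare_distributions(a, b, method="t") < 1e-6

    def test_welch_matches_scipy(self):
        from scipy import stats

        rng = np.random.default_rng(2)
        a, b = rng.normal(0, 1, 10), rng.normal(0.5, 2, 12)
        assert compare_distributions(a, b, method="t") == pytest.approx(
            stats.ttest_ind(a, b, equal_var=False).pvalue
        )

    def test_small_group_rejected(self):
        with pytest.raises(FormatError):
            compare_distributions([1.0], [1.0, 2.0])
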