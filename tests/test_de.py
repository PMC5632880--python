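"""Unit and property tests for the two-library exact DE machinery."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st
from scipy.stats import binomtest

from mitomir import (
    CountTable,
    bh_fdr,
    call_de,
    cpm_normalize,
    exact_poisson_test,
    hierarchical_cluster,
    log2_fold_change,
    pairwise_profile,
)
from mitomir.de import _correlation_distance, de_table

from oracles import average_linkage_heights, minlike_binomial_p, step_up_q


class TestExactPoissonTest:
    def test_no_information_gives_p_one(self):
        assert exact_poisson_test(0, 0, 1e6, 2e6) == 1.0

    def test_all_or_nothing_split_equal_sizes(self):
        # Binomial(10, 1/2): only k=0 and k=10 have mass <= P(10)
        assert exact_poisson_test(10, 0, 1e6, 1e6) == pytest.approx(
            2 / 2**10, abs=1e-15
        )

    @pytest.mark.parametrize("ratio", [1.0, 2.0, 5.0])
    def test_matches_scipy_binomtest(self, ratio):
        """Independent cross-check against scipy's two-sided binomial test."""
        rng = np.random.default_rng(11)
        n1, n2 = 1e6 * ratio, 1e6
        pi = n1 / (n1 + n2)
        for _ in range(50):
            n = int(rng.integers(1, 2000))
            x1 = int(rng.integers(0, n + 1))
            ours = exact_poisson_test(x1, n - x1, n1, n2)
            ref = binomtest(x1, n, pi, alternative="two-sided").pvalue
            assert ours == pytest.approx(ref, abs=1e-9)

    @given(
        n=st.integers(0, 50),
        x1_frac=st.floats(0, 1),
        ratio=st.sampled_from([1.0, 2.0, 5.0, 0.5]),
    )
    @settings(max_examples=200, deadline=None, derandomize=True)
    def test_swap_symmetry(self, n, x1_frac, ratio):
        x1 = int(round(n * x1_frac))
        x2 = n - x1
        n1, n2 = 1e6 * ratio, 1e6
        assert exact_poisson_test(x1, x2, n1, n2) == pytest.approx(
            exact_poisson_test(x2, x1, n2, n1), abs=1e-12
        )

    def test_large_n_tail_algorithm_matches_enumeration(self):
        rng = np.random.default_rng(5)
        for _ in range(40):
            n = int(rng.integers(1000, 3000))
            x1 = int(rng.integers(0, n + 1))
            n1 = float(rng.choice([1e6, 2e6, 5e6]))
            assert exact_poisson_test(x1, n - x1, n1, 1e6) == pytest.approx(
                minlike_binomial_p(x1, n - x1, n1, 1e6), abs=1e-10
            )

    def test_rejects_invalid_inputs(self):
        with pytest.raises(ValueError):
            exact_poisson_test(-1, 0, 1e6, 1e6)
        with pytest.raises(ValueError):
            exact_poisson_test(1, 1, 0, 1e6)


class TestCpmNormalize:
    def test_simple_arithmetic_and_zero_column(self):
        counts = np.array([[100, 0], [0, 0], [900, 0]])
        meta = pd.DataFrame(
            {
                "library_id": ["a", "b"],
                "compartment": ["mitochondrial"] * 2,
                "condition": ["sham", "tac4w"],
                "library_size": [10**6, 5000],
            }
        )
        table = CountTable(["m1", "m2", "m3"], meta, counts)
        cpm = cpm_normalize(table)
        assert cpm.loc["m1", "a"] == pytest.approx(100.0)
        assert (cpm["b"] == 0).all()

    def test_column_sums_scale_with_declared_size(self):
        rng = np.random.default_rng(2)
        counts = rng.integers(0, 500, size=(5, 3))
        sizes = counts.sum(axis=0) + np.array([0, 1000, 50])
        meta = pd.DataFrame(
            {
                "library_id": list("abc"),
                "compartment": ["total"] * 3,
                "condition": ["sham", "tac4w", "tac8w"],
                "library_size": sizes,
            }
        )
        table = CountTable([f"m{i}" for i in range(5)], meta, counts)
        cpm = cpm_normalize(table)
        np.testing.assert_allclose(
            cpm.sum(axis=0), 1e6 * counts.sum(axis=0) / sizes
        )


class TestLog2FoldChange:
    def test_reference_points(self):
        assert log2_fold_change(10, 10, 1e6, 1e6, pseudo_cpm=0) == 0.0
        assert log2_fold_change(10, 40, 1e6, 1e6, pseudo_cpm=0) == pytest.approx(2.0)
        assert log2_fold_change(5, 40, 1e6, 1e6, pseudo_cpm=0.5) == pytest.approx(
            np.log2(40.5 / 5.5)
        )

    def test_double_zero_without_pseudocount_is_missing(self):
        assert np.isnan(log2_fold_change(0, 0, 1e6, 1e6, pseudo_cpm=0.0))

    @given(
        x1=st.integers(0, 10_000),
        x2=st.integers(0, 10_000),
        ratio=st.floats(0.2, 5.0),
    )
    @settings(max_examples=200, deadline=None, derandomize=True)
    def test_antisymmetric_under_swap(self, x1, x2, ratio):
        n1, n2 = 1e6 * ratio, 1e6
        forward = log2_fold_change(x1, x2, n1, n2)
        backward = log2_fold_change(x2, x1, n2, n1)
        assert forward == pytest.approx(-backward, abs=1e-9)


class TestBhFdr:
    def test_step_up_example(self):
        np.testing.assert_allclose(
            bh_fdr([0.01, 0.02, 0.03, 0.5]), [0.04, 0.04, 0.04, 0.5]
        )

    def test_degenerate_vectors(self):
        assert bh_fdr([0.123]) == pytest.approx([0.123])
        np.testing.assert_allclose(bh_fdr([1.0, 1.0, 1.0]), 1.0)

    def test_matches_textbook_definition_on_random_vectors(self):
        rng = np.random.default_rng(17)
        for _ in range(100):
            p = rng.uniform(size=rng.integers(1, 60))
            np.testing.assert_allclose(bh_fdr(p), step_up_q(p), atol=1e-12)

    def test_q_dominates_p_after_sorting(self):
        rng = np.random.default_rng(8)
        p = np.sort(rng.uniform(size=40))
        q = bh_fdr(p)
        assert np.all(np.diff(q) >= -1e-15)
        assert np.all(q >= p - 1e-15)

    def test_rejects_out_of_range(self):
        with pytest.raises(ValueError):
            bh_fdr([0.5, 1.2])


class TestCallDe:
    def _frame(self, lfc, p):
        return pd.DataFrame(
            {"mirna": [f"m{i}" for i in range(len(lfc))],
             "log2_fc": lfc, "p_value": p, "q_value": p}
        )

    def test_strict_boundary_is_ns(self):
        frame = self._frame([1.0], [0.001])
        assert call_de(frame).loc[0, "call"] == "ns"

    def test_up_down_ns_partition(self):
        frame = self._frame([1.5, -1.5, 1.5, 0.2], [0.01, 0.01, 0.5, 0.01])
        assert list(call_de(frame)["call"]) == ["up", "down", "ns", "ns"]

    def test_missing_fold_change_is_ns(self):
        frame = self._frame([np.nan], [0.0001])
        assert call_de(frame).loc[0, "call"] == "ns"

    def test_invalid_thresholds_rejected(self):
        with pytest.raises(ValueError):
            call_de(self._frame([1.0], [0.5]), fc_up=0.9)


class TestPairwiseProfile:
    def test_identical_libraries_all_ns(self, two_library_table):
        tables = pairwise_profile(two_library_table, [("sham", "tac4w")])
        frame = tables[("sham", "tac4w")]
        assert (frame["p_value"] == 1.0).all()
        assert (frame["call"] == "ns").all()

    def test_undetected_mirnas_excluded(self, two_library_table):
        table = two_library_table
        table.counts[0, :] = 0
        tables = pairwise_profile(table, [("sham", "tac4w")], min_count=1)
        assert table.mirna_ids[0] not in set(tables[("sham", "tac4w")]["mirna"])

    def test_planted_eightfold_changes_recovered(self):
        """>= 18/20 planted 8-fold shifts called up at pooled depth 2e6."""
        depth = 2_000_000
        hits = []
        for seed in range(5):
            rng = np.random.default_rng(seed)
            base = rng.lognormal(0, 1.5, 200)
            shifted = base.copy()
            shifted[:20] *= 8.0
            x1 = rng.poisson(depth * base / base.sum())
            x2 = rng.poisson(depth * shifted / shifted.sum())
            frame = de_table(x1, x2, depth, depth, [f"m{i}" for i in range(200)])
            hits.append((frame["call"][:20] == "up").sum())
        assert np.mean(hits) >= 18

    def test_missing_condition_rejected(self, two_library_table):
        with pytest.raises(ValueError):
            pairwise_profile(two_library_table, [("sham", "tac8w")])


class TestHierarchicalCluster:
    def test_identical_rows_merge_first_at_zero_height(self):
        rng = np.random.default_rng(1)
        data = rng.normal(size=(4, 6))
        data[1] = data[0]
        order, link = hierarchical_cluster(data)
        assert link[0, 2] == pytest.approx(0.0, abs=1e-12)
        assert {int(link[0, 0]), int(link[0, 1])} == {0, 1}
        pos = {r: i for i, r in enumerate(order)}
        assert abs(pos[0] - pos[1]) == 1

    def test_correlated_rows_group_against_anticorrelated(self):
        x = np.array([1.0, 2.0, 3.0, 4.0])
        data = np.vstack([x, 2 * x + 1, -x])
        order, _ = hierarchical_cluster(data)
        pos = {r: i for i, r in enumerate(order)}
        assert abs(pos[0] - pos[1]) == 1

    def test_linkage_heights_match_brute_force(self):
        rng = np.random.default_rng(42)
        data = rng.normal(size=(10, 6))
        _, link = hierarchical_cluster(data)
        condensed, _ = _correlation_distance(data)
        full = np.zeros((10, 10))
        full[np.triu_indices(10, 1)] = condensed
        full += full.T
        np.testing.assert_allclose(
            link[:, 2], average_linkage_heights(full), atol=1e-10
        )

    def test_zero_variance_rows_warned_and_placed_last(self):
        rng = np.random.default_rng(9)
        data = rng.normal(size=(5, 4))
        data[2] = 3.0
        with pytest.warns(UserWarning, match="zero variance"):
            order, _ = hierarchical_cluster(data)
        assert order[-1] == 2
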