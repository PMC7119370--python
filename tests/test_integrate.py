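"""Fold-change/stability classification, correlations, group tests, overlaps."""

import itertools
import math

import numpy as np
import pandas as pd
import pytest
from hypothesis import given
from hypothesis import strategies as st

import decayatlas as da
from decayatlas.decay import estimate_half_lives
from decayatlas.integrate import (
    benjamini_hochberg,
    classify_expression_change,
    classify_stability_change,
    correlate,
    exact_rank_sum_p,
    group_compare,
    overlap_sets,
    predict_steady_state,
    rank_order_table,
)


class TestExpressionClassification:
    @pytest.mark.parametrize(
        "ctrl, ko, expected",
        [
            (1.0, 3.0, "increased"),
            (4.0, 1.0, "decreased"),
            (1.0, 2.0, "unchanged"),  # ratio exactly 2, strict
            (1.0, 0.5, "unchanged"),  # ratio exactly 1/2, strict
            (0.0, 1.0, "unavailable"),
        ],
    )
    def test_two_fold_rule(self, ctrl, ko, expected):
        assert classify_expression_change(ctrl, ko) == expected


class TestStabilityClassification:
    @pytest.mark.parametrize(
        "hc, hk, expected",
        [
            (2.0, 8.0, "stabilized"),
            (10.0, 4.0, "destabilized"),
            (5.0, 5.0, "unchanged"),
            (5.0, 10.0, "unchanged"),  # ratio exactly 2, strict
        ],
    )
    def test_ratio_rule(self, hc, hk, expected):
        assert classify_stability_change(hc, hk) == expected

    def test_excluded_estimates_unavailable(self):
        assert classify_stability_change(2.0, 8.0, "excluded_over_cap", "ok") == "unavailable"


class TestPredictSteadyState:
    def test_product(self):
        assert predict_steady_state(2.0, 3.0) == 6.0
        assert predict_steady_state(0.5, 10.0) == 5.0

    def test_nan_propagates(self):
        assert math.isnan(predict_steady_state(math.nan, 3.0))


class TestCorrelate:
    def test_monotone_series(self):
        x = np.arange(1.0, 11.0)
        assert correlate(x, 2 * x, "spearman")[0] == pytest.approx(1.0)
        assert correlate(x, -x, "spearman")[0] == pytest.approx(-1.0)
        assert correlate(x, -x, "pearson")[0] == pytest.approx(-1.0)

    def test_worked_five_point_example_matches_hand_rank_formula(self):
        x = [1, 2, 3, 4, 5]
        y = [2, 1, 4, 3, 5]
        # ranks are the values themselves; d = x - y, sum d^2 = 4,
        # rho = 1 - 6*4 / (5*(25-1)) = 1 - 24/120 = 0.8
        d2 = sum((xi - yi) ** 2 for xi, yi in zip(x, y))
        assert d2 == 4
        expected = 1 - 6 * d2 / (5 * (5**2 - 1))
        rho, _ = correlate(x, y, "spearman")
        assert rho == pytest.approx(expected, abs=1e-12)

    def test_constant_vector_undefined(self):
        rho, p = correlate([1.0, 1.0, 1.0], [1.0, 2.0, 3.0])
        assert math.isnan(rho)

    def test_too_few_pairs_rejected(self):
        with pytest.raises(ValueError):
            correlate([1.0, 2.0], [2.0, 1.0])


def brute_force_rank_sum_p(a, b):
    """Independent enumeration oracle: average ranks computed from scratch."""
    pooled = list(a) + list(b)
    order = sorted(range(len(pooled)), key=lambda i: pooled[i])
    ranks = [0.0] * len(pooled)
    i = 0
    while i < len(order):
        j = i
        while j < len(order) and pooled[order[j]] == pooled[order[i]]:
            j += 1
        avg = (i + j + 1) / 2  # mean of 1-based ranks i+1..j
        for k in range(i, j):
            ranks[order[k]] = avg
        i = j
    n_a = len(a)
    mu = sum(ranks) / len(ranks) * n_a
    w_obs = sum(ranks[:n_a])
    hits = total = 0
    for combo in itertools.combinations(range(len(pooled)), n_a):
        w = sum(ranks[i] for i in combo)
        if abs(w - mu) >= abs(w_obs - mu) - 1e-12:
            hits += 1
        total += 1
    return hits / total


class TestGroupCompare:
    def test_exact_rank_sum_textbook_example(self):
        # fully separated groups of 3: 2 of the 20 labelings are as extreme
        assert group_compare([1, 2, 3], [10, 11, 12]) == pytest.approx(0.1)

    @pytest.mark.parametrize(
        "a, b",
        [
            ([1, 2, 3], [4, 5, 6, 7]),
            ([1.5, 2.5], [0.5, 3.5, 4.5]),
            ([1, 1, 2], [2, 3, 3]),       # ties across groups
            ([5], [1, 2, 3, 4]),
            ([2, 2, 2], [2, 2, 2]),       # all tied
        ],
    )
    def test_matches_brute_force_enumeration(self, a, b):
        assert group_compare(a, b) == pytest.approx(brute_force_rank_sum_p(a, b))

    @given(
        st.lists(st.integers(0, 5), min_size=2, max_size=4),
        st.lists(st.integers(0, 5), min_size=2, max_size=4),
    )
    def test_matches_brute_force_on_random_small_instances(self, a, b):
        assert group_compare(a, b) == pytest.approx(brute_force_rank_sum_p(a, b))

    def test_large_groups_use_tie_corrected_normal_approximation(self):
        rng = np.random.default_rng(0)
        a = rng.normal(0, 1, 40)
        b = rng.normal(1, 1, 40)
        p = group_compare(a, b)
        assert 0 < p < 0.01

    def test_signed_rank_identical_pairs(self):
        assert group_compare([1.0, 2.0, 3.0], [1.0, 2.0, 3.0], test="signed_rank") == 1.0

    def test_signed_rank_shifted_pairs(self):
        a = np.arange(1.0, 11.0)
        p = group_compare(a + 2.0, a, test="signed_rank")
        assert p < 0.01

    def test_empty_group_rejected(self):
        with pytest.raises(ValueError):
            group_compare([], [1.0])


class TestOverlapSets:
    def test_disjoint_sets(self):
        counts = overlap_sets(
            {"a", "b", "c", "d"},
            {"x": {"a"}, "y": {"b"}, "z": {"c"}},
        )
        assert counts["x_y"] == counts["x_z"] == counts["y_z"] == 0
        assert counts["x_y_z"] == 0
        assert counts["x_only"] == 1

    def test_identical_sets(self):
        genes = {"g1", "g2", "g3", "g4", "g5"}
        counts = overlap_sets(genes, {"x": genes, "y": genes, "z": genes})
        assert counts["x_y_z"] == 5
        assert counts["x_only"] == 0

    def test_hand_enumerated_overlap(self):
        stabilized = set(range(1, 12))
        a = set(range(1, 7))       # {1..6}
        b = set(range(4, 10))      # {4..9}
        c = set(range(6, 12))      # {6..11}
        counts = overlap_sets(stabilized, {"a": a, "b": b, "c": c})
        # |A∩B|=3 ({4,5,6}), |A∩C|=1 ({6}), |B∩C|=4 ({6..9}), |A∩B∩C|=1 ({6})
        assert counts["a_b"] + counts["a_b_c"] == 3
        assert counts["a_c"] + counts["a_b_c"] == 1
        assert counts["b_c"] + counts["a_b_c"] == 4
        assert counts["a_b_c"] == 1


class TestRankOrder:
    def test_ascending_order(self):
        table = rank_order_table(pd.Series({"a": 3.0, "b": 1.0, "c": 2.0}))
        assert list(table.index) == ["b", "c", "a"]
        assert list(table["rank"]) == [1, 2, 3]

    def test_ties_keep_input_order(self):
        table = rank_order_table(pd.Series({"a": 1.0, "b": 1.0}))
        assert list(table.index) == ["a", "b"]

    def test_rank_is_permutation(self):
        rng = np.random.default_rng(1)
        values = pd.Series(rng.normal(size=100), index=[f"g{i}" for i in range(100)])
        table = rank_order_table(values)
        assert sorted(table["rank"]) == list(range(1, 101))


def test_benjamini_hochberg_monotone():
    p = [0.001, 0.01, 0.04, 0.5]
    adj = benjamini_hochberg(p)
    assert (np.diff(adj) >= 0).all()
    assert adj[0] == pytest.approx(0.004)


class TestSteadyStateReconstruction:
    def test_loglog_pearson_is_one_in_expectation_mode(
        self, expectation_dataset, expectation_fpkm
    ):
        ds = expectation_dataset
        hl = estimate_half_lives(expectation_fpkm, ds.manifest, "Rplp0", condition="control")
        intron_fpkm = da.compute_fpkm(ds.intronic, ds.gene_lengths)
        ctrl_intron = ds.manifest.loc[
            (ds.manifest["assay"] == "chase")
            & (ds.manifest["condition"] == "control")
            & (ds.manifest["timepoint_h"] == 0.0),
            "sample_id",
        ].tolist()
        intron_mean = intron_fpkm.values[ctrl_intron].mean(axis=1)
        fpkm_mean = expectation_fpkm.values[ctrl_intron].mean(axis=1)
        ok = hl["status"] == "ok"
        genes = ok[ok].index.intersection(intron_mean[intron_mean > 0].index)
        predicted = hl.loc[genes, "half_life_h"] * intron_mean[genes]
        rho, _ = correlate(np.log(predicted), np.log(fpkm_mean[genes]), "pearson")
        assert rho == pytest.approx(1.0, abs=1e-9)
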