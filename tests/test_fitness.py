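"""Cost function, stratified holdout, and SVM mask evaluation."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from budl import (
    CostConfig,
    FeatureTable,
    SVMSettings,
    eq1_cost,
    evaluate_mask,
    make_fitness,
    stratified_holdout,
)


class TestCost:
    @pytest.mark.parametrize(
        "accuracy,n_sel,n_tot,expected",
        [
            (1.0, 1, 100, 0.99 * 0.0 + 0.01 * 1 / 100),
            (0.9679, 562, 2048, 0.99 * (1 - 0.9679) + 0.01 * 562 / 2048),
            (0.0, 2048, 2048, 1.0),
            (0.5, 10, 20, 0.99 * 0.5 + 0.01 * 0.5),
        ],
    )
    def test_matches_independent_arithmetic(self, accuracy, n_sel, n_tot, expected):
        assert eq1_cost(accuracy, n_sel, n_tot) == pytest.approx(expected, abs=1e-12)

    def test_empty_subset_rejected(self):
        with pytest.raises(ValueError, match="positive"):
            eq1_cost(0.9, 0, 100)

    @settings(max_examples=50, deadline=None, derandomize=True)
    @given(
        acc=st.floats(0.0, 1.0),
        n_sel=st.integers(1, 99),
        n_tot=st.integers(100, 2048),
    )
    def test_monotone_in_both_terms(self, acc, n_sel, n_tot):
        # more features at fixed accuracy costs strictly more; better accuracy
        # at fixed subset size costs strictly less
        c = eq1_cost(acc, n_sel, n_tot)
        assert eq1_cost(acc, n_sel + 1, n_tot) > c
        if acc <= 1.0 - 1e-6:
            assert eq1_cost(acc + 1e-6, n_sel, n_tot) < c


class TestHoldout:
    def test_per_class_rounding_on_clinical_class_sizes(self):
        labels = np.array(["A"] * 437 + ["B"] * 210 + ["C"] * 133, dtype=object)
        split = stratified_holdout(labels, 0.2, seed=0)
        test_labels = labels[split.test_indices]
        counts = {c: int((test_labels == c).sum()) for c in "ABC"}
        assert counts == {"A": 87, "B": 42, "C": 27}
        assert len(split.train_indices) == 624
        assert len(split.test_indices) == 156

    def test_half_split_of_two_per_class(self):
        labels = np.array(["A", "A", "B", "B"], dtype=object)
        split = stratified_holdout(labels, 0.5, seed=1)
        for cls in "AB":
            assert (labels[split.test_indices] == cls).sum() == 1
            assert (labels[split.train_indices] == cls).sum() == 1

    def test_deterministic_under_seed(self):
        labels = np.array(["x"] * 30 + ["y"] * 20, dtype=object)
        s1 = stratified_holdout(labels, 0.2, seed=42)
        s2 = stratified_holdout(labels, 0.2, seed=42)
        assert np.array_equal(s1.test_indices, s2.test_indices)
        assert np.array_equal(s1.train_indices, s2.train_indices)

    def test_singleton_class_rejected(self):
        labels = np.array(["a", "a", "b"], dtype=object)
        with pytest.raises(ValueError, match="'b'"):
            stratified_holdout(labels, 0.2, seed=0)


def _separable_table(n=30, d=6):
    rng = np.random.default_rng(0)
    matrix = rng.standard_normal((n, d))
    labels = np.array(["pos"] * (n // 2) + ["neg"] * (n - n // 2), dtype=object)
    matrix[: n // 2, 0] += 10.0  # column 0 perfectly separates the classes
    return FeatureTable(matrix=matrix, labels=labels, feature_ids=[f"f{i}" for i in range(d)])


class TestEvaluateMask:
    def test_separating_feature_gives_perfect_accuracy(self):
        table = _separable_table()
        split = stratified_holdout(table.labels, 0.3, seed=0)
        mask = np.zeros(6, dtype=bool)
        mask[0] = True
        res = evaluate_mask(table, split, mask)
        assert res.accuracy == 1.0
        assert res.cost == pytest.approx(0.01 * 1 / 6, abs=1e-12)

    def test_repeated_evaluation_is_bit_identical(self):
        table = _separable_table()
        split = stratified_holdout(table.labels, 0.3, seed=0)
        mask = np.array([1, 0, 1, 1, 0, 1], dtype=bool)
        r1 = evaluate_mask(table, split, mask)
        r2 = evaluate_mask(table, split, mask)
        assert r1 == r2

    def test_empty_mask_rejected(self):
        table = _separable_table()
        split = stratified_holdout(table.labels, 0.3, seed=0)
        with pytest.raises(ValueError, match="empty subset"):
            evaluate_mask(table, split, np.zeros(6, dtype=bool))

    def test_constant_column_does_not_divide_by_zero(self):
        table = _separable_table()
        table.matrix[:, 3] = 5.0
        split = stratified_holdout(table.labels, 0.3, seed=0)
        mask = np.array([1, 0, 0, 1, 0, 0], dtype=bool)
        res = evaluate_mask(table, split, mask)
        assert np.isfinite(res.cost)
        assert res.accuracy == 1.0  # column 0 still separates


class TestFitnessEvaluatorCache:
    def test_cache_serves_repeat_masks(self):
        table = _separable_table()
        split = stratified_holdout(table.labels, 0.3, seed=0)
        fit = make_fitness(table, split)
        mask = np.array([1, 1, 0, 0, 0, 0], dtype=bool)
        r1 = fit(mask)
        r2 = fit(mask)
        assert fit.n_calls == 2 and fit.n_fits == 1
        assert r1 == r2

    def test_distinct_masks_fit_independently(self):
        table = _separable_table()
        split = stratified_holdout(table.labels, 0.3, seed=0)
        fit = make_fitness(table, split)
        fit(np.array([1, 0, 0, 0, 0, 0], dtype=bool))
        fit(np.array([0, 1, 0, 0, 0, 0], dtype=bool))
        assert fit.n_fits == 2

    def test_cache_can_be_disabled(self):
        table = _separable_table()
        split = stratified_holdout(table.labels, 0.3, seed=0)
        fit = make_fitness(table, split, svm_settings=SVMSettings(cache=False))
        mask = np.array([1, 0, 0, 0, 0, 0], dtype=bool)
        fit(mask)
        fit(mask)
        assert fit.n_fits == 2

    def test_all_ones_mask_matches_unmasked_fit(self, small_table, small_split, small_fitness):
        table, _ = small_table
        full = small_fitness(np.ones(table.n_features, dtype=bool))
        direct = evaluate_mask(table, small_split, np.ones(table.n_features, dtype=bool))
        assert full == direct
        assert full.n_selected == table.n_features
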