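"""Confusion-matrix metrics, rollups, temporal tables and reliability."""

import numpy as np
import pytest
from scipy.stats import pearsonr

from pollentrace import evaluate as ev
from pollentrace.errors import ContractError, UndefinedCorrelationError


class TestConfusion:
    def test_hand_count(self):
        cm = ev.confusion(["a", "a", "b", "b"], ["a", "b", "b", "b"], ["a", "b"])
        np.testing.assert_array_equal(cm.counts, [[1, 1], [0, 2]])

    def test_perfect_is_diagonal(self, rng):
        y = rng.choice(["x", "y", "z"], 60)
        cm = ev.confusion(y, y, ["x", "y", "z"])
        assert (cm.counts == np.diag(np.diag(cm.counts))).all()

    def test_row_sums_are_true_counts(self, rng):
        y = rng.choice(list("abc"), 100)
        p = rng.choice(list("abc"), 100)
        cm = ev.confusion(y, p, list("abc"))
        for i, c in enumerate("abc"):
            assert cm.counts[i].sum() == (y == c).sum()

    def test_unknown_label_rejected(self):
        with pytest.raises(ContractError):
            ev.confusion(["a"], ["q"], ["a", "b"])


class TestMetrics:
    def test_toy_matrix_hand_arithmetic(self):
        rep = ev.metrics(ev.ConfusionMatrix(np.array([[8, 2], [1, 9]]), ["c1", "c2"]))
        assert rep.accuracy == pytest.approx(0.85)
        assert rep.per_class.loc["c1", "precision"] == pytest.approx(8 / 9)
        assert rep.per_class.loc["c2", "precision"] == pytest.approx(9 / 11)
        assert rep.per_class.loc["c1", "recall"] == pytest.approx(0.8)
        assert rep.per_class.loc["c2", "recall"] == pytest.approx(0.9)
        f1_1 = 2 * (8 / 9) * 0.8 / (8 / 9 + 0.8)
        f1_2 = 2 * (9 / 11) * 0.9 / (9 / 11 + 0.9)
        assert rep.per_class.loc["c1", "f1"] == pytest.approx(f1_1, abs=1e-4)
        assert rep.per_class.loc["c2", "f1"] == pytest.approx(f1_2, abs=1e-4)
        assert f1_1 == pytest.approx(0.8421, abs=5e-5)
        assert f1_2 == pytest.approx(0.8571, abs=5e-5)
        assert rep.balanced_accuracy == pytest.approx(0.85)
        assert rep.weighted_f1 == pytest.approx(0.5 * f1_1 + 0.5 * f1_2)

    def test_diagonal_matrix_all_ones(self):
        rep = ev.metrics(ev.ConfusionMatrix(np.diag([5, 3, 9]), list("abc")))
        for v in (
            rep.accuracy,
            rep.balanced_accuracy,
            rep.macro_f1,
            rep.macro_precision,
            rep.macro_recall,
            rep.weighted_f1,
        ):
            assert v == 1.0

    def test_macro_f1_within_per_class_range(self, rng):
        counts = rng.integers(0, 20, (4, 4))
        counts += np.diag(rng.integers(1, 10, 4))
        rep = ev.metrics(ev.ConfusionMatrix(counts, list("abcd")))
        f1 = rep.per_class["f1"]
        assert f1.min() <= rep.macro_f1 <= f1.max()

    def test_identity_on_self_predictions(self, rng):
        y = rng.choice(list("pqrs"), 80)
        rep = ev.metrics(ev.confusion(y, y, list("pqrs")))
        assert rep.accuracy == rep.macro_f1 == 1.0

    def test_zero_division_conventions(self):
        # class b never predicted and never correct: precision = recall = f1 = 0
        cm = ev.ConfusionMatrix(np.array([[4, 0], [2, 0]]), ["a", "b"])
        rep = ev.metrics(cm)
        assert rep.per_class.loc["b", "f1"] == 0.0
        assert rep.per_class.loc["b", "precision"] == 0.0


class TestMunicipalityRollup:
    MAP = {"p1": "M", "p2": "M", "p3": "N"}

    def test_within_municipality_confusion_forgiven(self):
        rep = ev.municipality_rollup(["p1"], ["p2"], self.MAP)
        assert rep.accuracy == 1.0

    def test_bijection_equals_producer_metrics(self, rng):
        mapping = {"p1": "A", "p2": "B", "p3": "C"}
        y = rng.choice(list(mapping), 50)
        p = rng.choice(list(mapping), 50)
        roll = ev.municipality_rollup(y, p, mapping)
        prod = ev.metrics(ev.confusion(y, p, sorted(mapping)))
        assert roll.accuracy == prod.accuracy
        np.testing.assert_allclose(
            roll.per_class["f1"].to_numpy(), prod.per_class["f1"].to_numpy()
        )

    def test_rollup_accuracy_never_below_producer(self, rng):
        producers = list(self.MAP)
        for _ in range(100):
            y = rng.choice(producers, 30)
            p = rng.choice(producers, 30)
            prod_acc = ev.metrics(ev.confusion(y, p, producers)).accuracy
            assert ev.municipality_rollup(y, p, self.MAP).accuracy >= prod_acc

    def test_unmapped_producer_rejected(self):
        with pytest.raises(ContractError):
            ev.municipality_rollup(["p9"], ["p1"], self.MAP)


class TestTemporalTable:
    def test_identical_visits_identical_rows(self):
        y = ["a", "b"] * 8
        p = ["a", "a"] * 8
        visits = [1] * 8 + [2] * 8
        table = ev.temporal_table(y, p, visits)
        assert list(table.index) == [1, 2]
        np.testing.assert_allclose(table.loc[1], table.loc[2])

    def test_one_row_per_visit(self, rng):
        y = rng.choice(list("ab"), 60)
        p = rng.choice(list("ab"), 60)
        visits = rng.choice([1, 2, 4], 60)
        assert set(ev.temporal_table(y, p, visits).index) == {1, 2, 4}

    def test_pooling_visits_with_equal_metrics_preserves_weighted_f1(self, rng):
        for _ in range(20):
            y_half = rng.choice(list("abc"), 25)
            p_half = rng.choice(list("abc"), 25)
            y = np.r_[y_half, y_half]
            p = np.r_[p_half, p_half]
            visits = np.r_[np.ones(25, int), np.full(25, 2)]
            table = ev.temporal_table(y, p, visits)
            classes = sorted(set(y) | set(p))
            pooled = ev.metrics(ev.confusion(y, p, classes)).weighted_f1
            lo, hi = table["weighted_f1"].min(), table["weighted_f1"].max()
            assert lo - 1e-9 <= pooled <= hi + 1e-9

    def test_weighted_recall_equals_accuracy(self, rng):
        y = rng.choice(list("abcd"), 50)
        p = rng.choice(list("abcd"), 50)
        table = ev.temporal_table(y, p, np.ones(50, int))
        acc = ev.metrics(ev.confusion(y, p, sorted(set(y) | set(p)))).accuracy
        assert table.loc[1, "weighted_recall"] == pytest.approx(acc)


class TestTestRetest:
    def build(self, rng, n=6, per=10, acc=0.7):
        producers = [f"p{i}" for i in range(n)]
        y, pred, rounds = [], [], []
        for rnd in (1, 2):
            for prod in producers:
                for _ in range(per):
                    y.append(prod)
                    pred.append(
                        prod if rng.uniform() < acc else rng.choice(producers)
                    )
                    rounds.append(rnd)
        return np.array(y), np.array(pred), np.array(rounds)

    def test_identical_rounds_give_one(self, rng):
        y, p, r = self.build(rng)
        # make round 2 a copy of round 1
        y2 = np.r_[y[r == 1], y[r == 1]]
        p2 = np.r_[p[r == 1], p[r == 1]]
        r2 = np.r_[np.ones((r == 1).sum(), int), np.full((r == 1).sum(), 2)]
        rep = ev.test_retest(y2, p2, r2)
        assert rep.r12 == pytest.approx(1.0)

    def test_affine_relation_gives_one(self):
        f1 = np.array([0.2, 0.5, 0.8, 0.4])
        assert ev.pearson_r12(f1, 0.1 + 0.5 * f1) == pytest.approx(1.0)

    def test_reversed_three_vector_gives_minus_one(self):
        # hand computation: centered vectors are exact negatives of each other
        assert ev.pearson_r12([0.2, 0.5, 0.8], [0.8, 0.5, 0.2]) == pytest.approx(-1.0)

    def test_formula_matches_scipy_pearson(self, rng):
        for seed in range(5):
            rng2 = np.random.default_rng(seed)
            y, p, r = self.build(rng2, n=8, per=12, acc=0.6)
            try:
                rep = ev.test_retest(y, p, r)
            except UndefinedCorrelationError:
                continue
            ref = pearsonr(rep.f1_round1, rep.f1_round2).statistic
            assert rep.r12 == pytest.approx(ref, abs=1e-12)

    def test_constant_vector_rejected(self, rng):
        y, p, r = self.build(rng, acc=1.0)  # perfect -> constant F1 vectors
        with pytest.raises(UndefinedCorrelationError):
            ev.test_retest(y, p, r)

    def test_missing_producer_in_round_rejected(self):
        y = np.array(["a", "b", "c", "a", "b"])
        p = y.copy()
        r = np.array([1, 1, 1, 2, 2])  # c absent from round 2
        with pytest.raises(ContractError, match="c"):
            ev.test_retest(y, p, r)

    def test_bounded_and_affine_invariant(self, rng):
        for seed in range(10):
            rng2 = np.random.default_rng(100 + seed)
            y, p, r = self.build(rng2, n=10, per=8, acc=0.55)
            try:
                rep = ev.test_retest(y, p, r)
            except UndefinedCorrelationError:
                continue
            assert -1.0 - 1e-12 <= rep.r12 <= 1.0 + 1e-12
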