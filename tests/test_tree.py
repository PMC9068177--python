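"""Information-gain tree: entropy oracles, count equivalence, evaluation."""

import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from bcrisk.errors import DomainError, FitError, ProtocolError, SchemaError
from bcrisk.tree import (
    TreeHyperparams,
    TreeModel,
    ablate,
    cross_validate,
    default_grid,
    entropy,
    evaluate,
    fit_tree,
    gini,
    information_gain,
    report_from_predictions,
    tune,
)
from bcrisk.weighting import WeightProfile

from .conftest import make_dataset, random_tree_fixture


def oracle_entropy(pairs):
    """Independent entropy: plain-python sum over positive masses."""
    tot = sum(pairs)
    return -sum(q * math.log2(q) for p in pairs if (q := p / tot) > 0)


def oracle_best_multiway_split(X, y, counts):
    """Exhaustive search over per-feature multiway splits; lowest index wins."""
    parent = [counts[y == 0].sum(), counts[y == 1].sum()]
    total = sum(parent)
    best_gain, best_j = 0.0, None
    for j in range(X.shape[1]):
        values = sorted(set(X[:, j]))
        if len(values) < 2:
            continue
        gain = oracle_entropy(parent)
        for v in values:
            sel = X[:, j] == v
            child = [counts[sel & (y == 0)].sum(), counts[sel & (y == 1)].sum()]
            gain -= sum(child) / total * oracle_entropy(child)
        if gain > best_gain + 1e-12:
            best_gain, best_j = gain, j
    return best_gain, best_j


class TestEntropy:
    def test_uniform_binary_is_one_bit(self):
        assert entropy((1, 1)) == 1.0

    def test_pure_node_is_zero(self):
        assert entropy((1, 0)) == 0.0

    def test_three_to_one_split(self):
        expected = -0.75 * math.log2(0.75) - 0.25 * math.log2(0.25)
        assert entropy((3, 1)) == pytest.approx(expected)
        assert entropy((3, 1)) == pytest.approx(0.8113, abs=5e-5)

    def test_all_zero_raises(self):
        with pytest.raises(DomainError):
            entropy((0, 0))
        with pytest.raises(DomainError):
            entropy((-1, 2))

    @given(st.lists(st.floats(0, 100), min_size=2, max_size=5).filter(lambda w: sum(w) > 0))
    @settings(max_examples=100, derandomize=True, deadline=None)
    def test_matches_plain_python_oracle(self, weights):
        assert entropy(weights) == pytest.approx(oracle_entropy(weights))

    def test_gini_bounds(self):
        assert gini((1, 1)) == pytest.approx(0.5)
        assert gini((1, 0)) == 0.0


class TestInformationGain:
    def test_perfect_split_is_one_bit(self):
        assert information_gain((2, 2), [(2, 0), (0, 2)]) == 1.0

    def test_uninformative_children_zero_gain(self):
        assert information_gain((4, 2), [(2, 1), (2, 1)]) == pytest.approx(0.0)

    def test_hand_arithmetic_case(self):
        # parent (3,1) split into (1,1) and (2,0): 0.8113 - 0.5*1.0
        got = information_gain((3, 1), [(1, 1), (2, 0)])
        assert got == pytest.approx(entropy((3, 1)) - 0.5, abs=1e-12)
        assert got == pytest.approx(0.3113, abs=5e-5)

    def test_mass_mismatch_raises(self):
        with pytest.raises(DomainError):
            information_gain((3, 1), [(1, 1), (1, 0)])

    @given(st.data())
    @settings(max_examples=100, derandomize=True, deadline=None)
    def test_nonnegative_on_random_partitions(self, data):
        k = data.draw(st.integers(2, 4))
        children = [
            (data.draw(st.integers(0, 5)), data.draw(st.integers(0, 5)))
            for _ in range(k)
        ]
        parent = (sum(c[0] for c in children), sum(c[1] for c in children))
        if sum(parent) == 0:
            return
        assert information_gain(parent, children) >= 0.0


class TestFitAgainstBruteForce:
    @pytest.mark.parametrize("seed", range(25))
    def test_root_split_equals_exhaustive_argmax(self, seed):
        X, y, counts = random_tree_fixture(seed, n_rows=8, n_feats=3)
        gain, j = oracle_best_multiway_split(X, y, counts)
        model = fit_tree(X, y, counts, hp=TreeHyperparams(max_depth=1))
        if j is None:
            assert model.root.is_leaf
        else:
            assert model.root.feature == j

    @pytest.mark.parametrize("seed", range(10))
    def test_count_weighting_equals_row_expansion(self, seed):
        X, y, counts = random_tree_fixture(seed, n_rows=10, n_feats=3)
        rep = np.repeat(np.arange(len(X)), counts.astype(int))
        weighted = fit_tree(X, y, counts)
        expanded = fit_tree(X[rep], y[rep], None)
        assert weighted.to_dict() == expanded.to_dict()
        # evaluation is equivalent too
        ew = evaluate(weighted, X, y, counts)
        ee = evaluate(expanded, X[rep], y[rep], None)
        assert ew.confusion == ee.confusion
        assert ew.accuracy == ee.accuracy


class TestFitBehavior:
    def test_separable_single_feature_depth_one(self):
        X = np.array([[0.0], [1.0], [0.0], [1.0]])
        y = np.array([0, 1, 0, 1])
        model = fit_tree(X, y)
        assert model.depth() == 1
        assert (model.predict(X) == y).all()

    def test_max_depth_zero_is_majority_stump(self):
        X, y = np.array([[0.0], [1.0], [2.0]]), np.array([0, 0, 1])
        model = fit_tree(X, y, hp=TreeHyperparams(max_depth=0))
        assert model.root.is_leaf
        assert (model.predict(X) == 0).all()

    def test_no_positive_gain_becomes_leaf(self):
        X = np.zeros((4, 2))
        y = np.array([0, 1, 0, 1])
        model = fit_tree(X, y)
        assert model.root.is_leaf

    def test_column_scaling_invariant_for_categorical_splits(self):
        X, y, counts = random_tree_fixture(3, n_rows=30, n_feats=4)
        a = fit_tree(X, y, counts, weight_mode="column")
        b = fit_tree(X * np.array([4.0, 1.0, 0.5, 2.0]), y, counts,
                     weight_mode="column")
        assert (a.predict(X) == b.predict(X * np.array([4.0, 1.0, 0.5, 2.0]))).all()

    def test_gain_scale_redirects_equal_gain_tie(self):
        # both features perfectly predict the label (equal gain); the
        # unweighted tie goes to the lowest index, a gain weight flips it
        X = np.array([[0.0, 0.0], [1.0, 1.0], [0.0, 0.0], [1.0, 1.0]])
        y = np.array([0, 1, 0, 1])
        base = fit_tree(X, y, feature_weights=np.array([1.0, 1.0]))
        assert base.root.feature == 0
        tilted = fit_tree(X, y, feature_weights=np.array([1.0, 2.0]))
        assert tilted.root.feature == 1

    def test_random_splitter_is_seeded(self):
        X, y, counts = random_tree_fixture(5, n_rows=40, n_feats=4)
        hp = TreeHyperparams(splitter="random", max_depth=3)
        a = fit_tree(X, y, counts, hp=hp, seed=7)
        b = fit_tree(X, y, counts, hp=hp, seed=7)
        assert a.to_dict() == b.to_dict()

    def test_binary_split_mode_predicts(self):
        X, y, counts = random_tree_fixture(6, n_rows=60, n_feats=3)
        model = fit_tree(X, y, counts, hp=TreeHyperparams(split_mode="binary"))
        acc = ((model.predict(X) == y) * counts).sum() / counts.sum()
        multi = fit_tree(X, y, counts)
        acc_multi = ((multi.predict(X) == y) * counts).sum() / counts.sum()
        assert acc == pytest.approx(acc_multi, abs=0.02)

    def test_empty_input_raises(self):
        with pytest.raises(FitError):
            fit_tree(np.zeros((0, 2)), np.zeros(0, dtype=int))

    def test_unseen_category_falls_back_to_node_majority(self):
        X = np.array([[0.0], [0.0], [1.0]])
        y = np.array([0, 0, 1])
        model = fit_tree(X, y)
        assert model.predict(np.array([[2.0]]))[0] == 0

    def test_json_roundtrip(self, tmp_path):
        X, y, counts = random_tree_fixture(9, n_rows=50, n_feats=4)
        model = fit_tree(X, y, counts, feature_weights=np.array([1.0, 2, 1, 3]))
        path = tmp_path / "model.json"
        model.save(path)
        again = TreeModel.load(path)
        assert (again.predict(X) == model.predict(X)).all()
        assert np.allclose(again.predict_proba(X), model.predict_proba(X))


class TestAgainstSklearn:
    @pytest.mark.parametrize("seed", [0, 1, 2])
    def test_training_accuracy_within_one_point(self, seed):
        from sklearn.tree import DecisionTreeClassifier

        rng = np.random.default_rng(seed)
        X = rng.integers(0, 4, size=(200, 3)).astype(float)
        y = rng.integers(0, 2, size=200)
        counts = rng.integers(1, 5, size=200).astype(float)
        ours = fit_tree(X, y, counts)
        acc = ((ours.predict(X) == y) * counts).sum() / counts.sum()
        sk = DecisionTreeClassifier(criterion="entropy", random_state=0)
        sk.fit(X, y, sample_weight=counts)
        sk_acc = ((sk.predict(X) == y) * counts).sum() / counts.sum()
        assert abs(acc - sk_acc) <= 0.01


class TestEvaluate:
    def test_perfect_predictions(self):
        y = np.array([0, 1, 0, 1])
        rep = report_from_predictions(y, y.copy(), np.ones(4))
        assert rep.accuracy == 1.0
        assert rep.fnr == {0: 0.0, 1: 0.0}
        assert rep.fdr == {0: 0.0, 1: 0.0}

    def test_all_majority_on_90_10(self):
        y = np.concatenate([np.zeros(90, dtype=int), np.ones(10, dtype=int)])
        pred = np.zeros(100, dtype=int)
        rep = report_from_predictions(y, pred, np.ones(100))
        assert rep.accuracy == pytest.approx(0.90)
        assert rep.fnr[0] == 0.0
        assert rep.fnr[1] == 1.0
        assert rep.fdr[0] == pytest.approx(0.1)

    def test_minor_class_rates_from_confusion(self):
        # minor-class confusion TP=90 FN=10 FP=20 TN=880
        y = np.concatenate([np.ones(100, dtype=int), np.zeros(900, dtype=int)])
        pred = np.concatenate(
            [np.ones(90, dtype=int), np.zeros(10, dtype=int),
             np.ones(20, dtype=int), np.zeros(880, dtype=int)]
        )
        rep = report_from_predictions(y, pred, np.ones(1000))
        assert rep.fnr[1] == pytest.approx(0.10)
        assert rep.fdr[1] == pytest.approx(20 / 110)
        assert rep.fdr[1] == pytest.approx(0.182, abs=5e-4)

    def test_count_weighted_confusion(self):
        y = np.array([0, 1])
        pred = np.array([0, 0])
        rep = report_from_predictions(y, pred, np.array([9.0, 1.0]))
        assert rep.accuracy == pytest.approx(0.9)


class TestTuneAndAblate:
    def test_single_point_grid_returns_it(self):
        ds = make_dataset(60, 20, seed=1)
        from bcrisk.schema import normalize

        nm = normalize(ds)
        hp = TreeHyperparams(max_depth=2)
        best, rep = tune(nm.values, ds.labels(), ds.counts(), grid=[hp], folds=3)
        assert best is hp
        assert 0.0 <= rep.accuracy <= 1.0

    def test_tie_prefers_smaller_depth(self):
        X = np.array([[0.0], [1.0]] * 20)
        y = np.array([0, 1] * 20)
        grid = [TreeHyperparams(max_depth=None), TreeHyperparams(max_depth=1)]
        best, rep = tune(X, y, grid=grid, folds=2)
        assert best.max_depth == 1
        assert rep.accuracy == 1.0

    def test_folds_exceeding_minority_raises(self):
        ds = make_dataset(30, 3, seed=2)
        from bcrisk.schema import normalize

        nm = normalize(ds)
        with pytest.raises(ProtocolError):
            cross_validate(nm.values, ds.labels(), ds.counts(), folds=5)

    def test_default_grid_covers_stated_hyperparameters(self):
        grid = default_grid()
        assert {hp.criterion for hp in grid} == {"information-gain", "gini"}
        assert {hp.splitter for hp in grid} == {"best", "random"}
        assert len(grid) == 12

    def test_ablate_rejects_bad_drop_sets(self):
        ds = make_dataset(30, 10, seed=4)
        wp = WeightProfile(stw={f: 1 for f in ds.factor_names})
        with pytest.raises(ProtocolError):
            ablate(ds, wp, list(ds.factor_names))
        with pytest.raises(SchemaError):
            ablate(ds, wp, ["nope"])

    def test_ablate_empty_drop_equals_baseline(self):
        from bcrisk.schema import normalize

        ds = make_dataset(60, 20, seed=5)
        wp = WeightProfile(stw={f: 1 for f in ds.factor_names})
        hp = TreeHyperparams(max_depth=3)
        base = cross_validate(
            normalize(ds).values, ds.labels(), ds.counts(),
            hp=hp, feature_weights=wp.multipliers(ds.factor_names),
            folds=3, seed=0,
        )
        abl = ablate(ds, wp, [], hp=hp, folds=3, seed=0)
        assert abl.accuracy == base.accuracy
        assert abl.confusion == base.confusion

    def test_ablating_only_informative_feature_destroys_signal(self):
        from bcrisk.schema import LABEL_COL, RiskDataset

        rng = np.random.default_rng(0)
        n = 400
        base = make_dataset(n, 0, seed=6)
        df = base.df.copy()
        y = rng.integers(0, 2, size=n)
        df[LABEL_COL] = y
        # make exactly one factor carry the label; all others random
        df["hrt"] = y
        informative = RiskDataset(df=df, schema=base.schema)
        wp = WeightProfile(stw={f: 1 for f in informative.factor_names})
        hp = TreeHyperparams(max_depth=2)
        with_factor = ablate(informative, wp, [], hp=hp, folds=3, seed=0)
        without = ablate(informative, wp, ["hrt"], hp=hp, folds=3, seed=0)
        assert with_factor.accuracy == pytest.approx(1.0)
        majority = max((y == 0).mean(), (y == 1).mean())
        assert without.accuracy <= majority + 0.1
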