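"""Weighted random forest: split criterion vs an exhaustive oracle, weighted
voting arithmetic, OOB machinery, permutation significance and serialization."""

import itertools

import numpy as np
import pytest

import aeegrf as a
from aeegrf.forest import Forest, ForestConfig, _tree_proba


# ---------------------------------------------------------------------------
# Oracles
# ---------------------------------------------------------------------------

def gini_oracle(counts, weights):
    mass = [c * w for c, w in zip(counts, weights)]
    tot = sum(mass)
    return 1.0 - sum((m / tot) ** 2 for m in mass)


def split_oracle(X, y, candidates, weights, min_leaf=1):
    """Exhaustively enumerate every candidate feature × midpoint threshold and
    keep the first strictly best weighted-Gini decrease."""
    n, k = len(y), len(weights)
    parent = [sum(1 for v in y if v == c) for c in range(k)]
    parent_mass = sum(c * w for c, w in zip(parent, weights))
    parent_imp = gini_oracle(parent, weights)
    best = None
    for f in sorted(candidates):
        vals = sorted(set(X[i][f] for i in range(n)))
        for lo, hi in zip(vals, vals[1:]):
            thr = (lo + hi) / 2.0
            left = [i for i in range(n) if X[i][f] <= thr]
            right = [i for i in range(n) if X[i][f] > thr]
            if len(left) < min_leaf or len(right) < min_leaf:
                continue
            lc = [sum(1 for i in left if y[i] == c) for c in range(k)]
            rc = [sum(1 for i in right if y[i] == c) for c in range(k)]
            lm = sum(c * w for c, w in zip(lc, weights))
            rm = sum(c * w for c, w in zip(rc, weights))
            gain = parent_imp - (lm * gini_oracle(lc, weights) + rm * gini_oracle(rc, weights)) / parent_mass
            if gain > 1e-12 and (best is None or gain > best[0] + 1e-12):
                best = (gain, f, thr)
    return None if best is None else (best[1], best[2], best[0])


# ---------------------------------------------------------------------------
# Split criterion
# ---------------------------------------------------------------------------

class TestWeightedGini:
    def test_balanced_two_class(self):
        assert a.weighted_gini([5, 5], [1, 1]) == pytest.approx(0.5)

    def test_pure_node(self):
        assert a.weighted_gini([7, 0], [3, 1]) == pytest.approx(0.0)
        assert a.weighted_gini([0, 4], [5, 2]) == pytest.approx(0.0)

    def test_weighting_shifts_proportions(self):
        # 1 abnormal @ weight 3 vs 2 normal @ weight 1 → p = (0.6, 0.4)
        assert a.weighted_gini([1, 2], [3, 1]) == pytest.approx(0.48)

    def test_all_zero_counts_rejected(self):
        with pytest.raises(ValueError):
            a.weighted_gini([0, 0], [1, 1])


class TestBestSplit:
    def test_matches_exhaustive_oracle(self):
        # every seeded fixture with <= 8 samples and <= 4 features
        for seed in range(40):
            rng = np.random.default_rng(seed)
            n = int(rng.integers(2, 9))
            p = int(rng.integers(1, 5))
            X = np.round(rng.uniform(0, 10, (n, p)), 1)
            y = rng.integers(0, 2, n)
            if len(set(y)) < 2:
                y[0] = 1 - y[0]
            for weights in ([1.0, 1.0], [3.0, 1.0]):
                cands = list(range(p))
                got = a.best_split(X, y, cands, np.array(weights))
                exp = split_oracle(X.tolist(), y.tolist(), cands, weights)
                if exp is None:
                    assert got is None
                else:
                    assert got[0] == exp[0]
                    assert got[1] == pytest.approx(exp[1])
                    assert got[2] == pytest.approx(exp[2], abs=1e-12)

    def test_perfect_separator_gets_full_gain(self):
        X = np.array([[0.0, 5.0], [1.0, 1.0], [0.0, 6.0], [1.0, 2.0]])
        y = np.array([0, 1, 0, 1])
        f, thr, gain = a.best_split(X, y, [0, 1], np.ones(2))
        assert f == 0 and thr == pytest.approx(0.5)
        assert gain == pytest.approx(0.5)  # parent impurity of a 2/2 node

    def test_constant_candidates_give_none(self):
        X = np.ones((6, 2))
        y = np.array([0, 1, 0, 1, 0, 1])
        assert a.best_split(X, y, [0, 1], np.ones(2)) is None

    def test_empty_candidate_set_rejected(self):
        with pytest.raises(ValueError):
            a.best_split(np.ones((4, 2)), np.array([0, 1, 0, 1]), [], np.ones(2))


# ---------------------------------------------------------------------------
# Tree growing and prediction
# ---------------------------------------------------------------------------

def _toy_separable(n=40, seed=0):
    rng = np.random.default_rng(seed)
    X = rng.normal(0, 1, (n, 2))
    labels = np.where(X[:, 0] > 0, "abnormal", "normal")
    X[:, 0] += np.where(X[:, 0] > 0, 2.0, -2.0)  # widen the margin
    return X, list(labels)


class TestGrowAndPredict:
    def test_fully_grown_tree_fits_training_data(self):
        X, labels = _toy_separable()
        f = a.fit(X, labels, ForestConfig(n_tree=5, m_try=2, seed=3))
        pred, _ = a.predict(f, X)
        assert np.mean(pred == np.asarray(labels)) == 1.0

    def test_single_tree_forest(self):
        X, labels = _toy_separable()
        f = a.fit(X, labels, ForestConfig(n_tree=1, seed=0))
        assert len(f.trees) == 1 and len(f.bootstraps[0]) == len(labels)

    def test_determinism(self):
        X, labels = _toy_separable(seed=4)
        cfg = ForestConfig(n_tree=10, seed=9)
        f1, f2 = a.fit(X, labels, cfg), a.fit(X, labels, cfg)
        assert a.to_json(f1) == a.to_json(f2)

    def test_weighted_leaf_vote(self):
        # one abnormal + two normal at weights 3:1 → tree probability (0.6, 0.4)
        forest = Forest(
            trees=[{"probs": [0.6, 0.4]}],
            bootstraps=[np.array([0, 1, 2])],
            config=ForestConfig(n_tree=1),
            classes=("abnormal", "normal"),
            n_samples=3,
        )
        forest._p = 2
        labels, proba = a.predict(forest, np.zeros((1, 2)))
        assert labels[0] == "abnormal"
        assert np.allclose(proba, [[0.6, 0.4]])

    def test_unanimous_trees(self):
        X, labels = _toy_separable()
        f = a.fit(X, labels, ForestConfig(n_tree=20, seed=1))
        _, proba = a.predict(f, X[:1])
        assert proba.sum() == pytest.approx(1.0)
        assert proba.max() == pytest.approx(1.0)

    def test_probabilities_sum_to_one(self):
        X, labels = _toy_separable(seed=7)
        f = a.fit(X, labels, ForestConfig(n_tree=15, seed=2))
        proba = a.predict_proba(f, X)
        assert np.allclose(proba.sum(axis=1), 1.0)

    def test_dimension_mismatch_rejected(self):
        X, labels = _toy_separable()
        f = a.fit(X, labels, ForestConfig(n_tree=2, seed=0))
        with pytest.raises(ValueError, match="features"):
            a.predict(f, np.zeros((1, 3)))

    def test_single_class_rejected(self):
        with pytest.raises(ValueError, match="2 classes"):
            a.fit(np.ones((4, 2)), ["normal"] * 4, ForestConfig(n_tree=1))

    def test_weight_neutrality(self):
        X, labels = _toy_separable(seed=5)
        f_none = a.fit(X, labels, ForestConfig(n_tree=25, class_weights=None, seed=6))
        f_unit = a.fit(
            X, labels, ForestConfig(n_tree=25, class_weights={"abnormal": 1, "normal": 1}, seed=6)
        )
        assert np.array_equal(a.predict(f_none, X)[0], a.predict(f_unit, X)[0])
        assert np.allclose(a.predict_proba(f_none, X), a.predict_proba(f_unit, X))

    def test_agrees_with_reference_forest_on_clean_data(self):
        # independent cross-check: on a wide-margin problem an off-the-shelf
        # unweighted forest must reach the same labels
        from sklearn.ensemble import RandomForestClassifier

        X, labels = _toy_separable(n=60, seed=8)
        ours = a.fit(X, labels, ForestConfig(n_tree=50, class_weights=None, seed=0))
        ref = RandomForestClassifier(n_estimators=50, random_state=0).fit(X, labels)
        assert np.array_equal(a.predict(ours, X)[0], ref.predict(X))


class TestVoteModes:
    def test_hard_vote_runs_and_sums_to_one(self):
        X, labels = _toy_separable(seed=2)
        f = a.fit(X, labels, ForestConfig(n_tree=9, vote="hard", seed=3))
        proba = a.predict_proba(f, X)
        assert np.allclose(proba.sum(axis=1), 1.0)
        assert np.mean(a.predict(f, X)[0] == np.asarray(labels)) == 1.0


# ---------------------------------------------------------------------------
# Out-of-bag machinery
# ---------------------------------------------------------------------------

class TestOOB:
    def test_perfect_forest_has_zero_oob_error(self):
        # duplicated wide-margin rows: every tree classifies them perfectly
        X = np.repeat([[0.0, 0.0], [10.0, 10.0]], 10, axis=0)
        labels = ["normal"] * 10 + ["abnormal"] * 10
        f = a.fit(X, labels, ForestConfig(n_tree=30, m_try=1, seed=0))
        assert a.oob_error(f, X, labels) == 0.0

    def test_single_tree_uses_only_its_oob_rows(self):
        X, labels = _toy_separable(n=30, seed=1)
        f = a.fit(X, labels, ForestConfig(n_tree=1, seed=4))
        _, has = a.oob_predictions(f, X)
        in_bag = np.zeros(len(labels), dtype=bool)
        in_bag[f.bootstraps[0]] = True
        assert np.array_equal(has, ~in_bag)

    def test_oob_requires_training_matrix(self):
        X, labels = _toy_separable()
        f = a.fit(X, labels, ForestConfig(n_tree=3, seed=0))
        with pytest.raises(ValueError):
            a.oob_error(f, X[:-1], labels[:-1])


# ---------------------------------------------------------------------------
# Permutation significance
# ---------------------------------------------------------------------------

class TestPermutationImportance:
    def test_matches_hand_unrolled_two_tree_computation(self):
        X, labels = _toy_separable(n=10, seed=3)
        f = a.fit(X, labels, ForestConfig(n_tree=2, m_try=1, seed=5))
        report = a.permutation_importance(f, X, labels, seed=7)

        # hand-unrolled: per tree, correct OOB vote rate minus the rate after
        # permuting each feature among the OOB cases (same documented stream)
        y = np.array([f.classes.index(l) for l in labels])
        rng = np.random.default_rng(7)
        fi = np.zeros((2, 2))
        for t in range(2):
            mask = np.ones(10, dtype=bool)
            mask[f.bootstraps[t]] = False
            rows = np.nonzero(mask)[0]
            Xo, yo = X[rows], y[rows]
            base = np.mean(np.argmax(_tree_proba(f.trees[t], Xo), axis=1) == yo)
            for i in range(2):
                perm = rng.permutation(rows.size)
                Xp = Xo.copy()
                Xp[:, i] = Xo[perm, i]
                fi[t, i] = base - np.mean(
                    np.argmax(_tree_proba(f.trees[t], Xp), axis=1) == yo
                )
        assert np.allclose(report.importances, fi.mean(axis=0))

    def test_unfitted_forest_rejected(self):
        empty = Forest(trees=[], bootstraps=[], config=ForestConfig(),
                       classes=("abnormal", "normal"), n_samples=0)
        with pytest.raises(ValueError):
            a.permutation_importance(empty, np.zeros((1, 1)), ["normal"])


# ---------------------------------------------------------------------------
# Serialization
# ---------------------------------------------------------------------------

class TestSerialization:
    def test_round_trip_reproduces_predictions(self, tmp_path):
        X, labels = _toy_separable(seed=6)
        f = a.fit(X, labels, ForestConfig(n_tree=12, seed=8), feature_names=["f0", "f1"])
        path = tmp_path / "model.json"
        a.to_json(f, path)
        g = a.from_json(path)
        assert g.classes == f.classes
        assert g.feature_names == ("f0", "f1")
        assert np.allclose(a.predict_proba(g, X), a.predict_proba(f, X))
        assert a.oob_error(g, X, labels) == a.oob_error(f, X, labels)

    def test_unsupported_schema_rejected(self):
        with pytest.raises(ValueError, match="schema"):
            a.from_json('{"schema_version": 99}')


class TestConfig:
    def test_default_m_try(self):
        assert a.default_m_try(119) == 11

    def test_validation(self):
        with pytest.raises(ValueError):
            ForestConfig(n_tree=0).validate()
        with pytest.raises(ValueError):
            ForestConfig(m_try=10).validate(p=5)
        with pytest.raises(ValueError):
            ForestConfig(class_weights={"abnormal": 0.0}).validate()
        with pytest.raises(ValueError):
            ForestConfig(vote="loud").validate()
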