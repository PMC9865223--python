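"""Threshold calibration, the knowledge tree, and the ensemble comparator."""

import numpy as np
import pandas as pd
import pytest

from vegindex import (DataError, EnsembleConfig,
                      KnowledgeDecisionTree, build_knowledge_tree,
                      calibrate_threshold, classify_ensemble, classify_tree,
                      default_profiles, optimal_feature_set, simulate_scene,
                      split_train_verify, train_ensemble)
from vegindex.classify import DEFAULT_HIERARCHY
from vegindex.simulate import SceneConfig


def brute_force_split(target, rest):
    """Independent oracle: try every midpoint and both directions naively."""
    t, r = np.asarray(target, float), np.asarray(rest, float)
    direction = "GE" if t.mean() >= r.mean() else "LE"
    pooled = np.unique(np.concatenate([t, r]))
    best = None
    for lo, hi in zip(pooled[:-1], pooled[1:]):
        cut = (lo + hi) / 2
        if direction == "GE":
            err = sum(1 for v in t if v < cut) + sum(1 for v in r if v >= cut)
        else:
            err = sum(1 for v in t if v > cut) + sum(1 for v in r if v <= cut)
        if best is None or err < best[0]:
            best = (err, cut, direction)
    return best


class TestCalibrateThreshold:
    def test_separated_case(self):
        thr, direction = calibrate_threshold([0.8, 0.9], [0.1, 0.2])
        assert 0.2 < thr < 0.8
        assert direction == "GE"

    def test_symmetric_case_is_le(self):
        _, direction = calibrate_threshold([0.1, 0.2], [0.8, 0.9])
        assert direction == "LE"

    def test_interleaved_case_one_error(self):
        thr, direction = calibrate_threshold([0.1, 0.3], [0.2, 0.4])
        err_oracle, _, _ = brute_force_split([0.1, 0.3], [0.2, 0.4])
        t, r = np.array([0.1, 0.3]), np.array([0.2, 0.4])
        if direction == "LE":
            err = (t > thr).sum() + (r <= thr).sum()
        else:
            err = (t < thr).sum() + (r >= thr).sum()
        assert err == err_oracle == 1

    def test_constant_inseparable_rejected(self):
        with pytest.raises(DataError):
            calibrate_threshold([0.5, 0.5], [0.5, 0.5])

    @pytest.mark.parametrize("seed", range(8))
    def test_matches_brute_force_oracle(self, seed):
        rng = np.random.default_rng(seed)
        n_t, n_r = rng.integers(2, 100, size=2)
        t = rng.normal(rng.uniform(-1, 1), 1.0, n_t)
        r = rng.normal(rng.uniform(-1, 1), 1.0, n_r)
        thr, direction = calibrate_threshold(t, r)
        err_o, thr_o, dir_o = brute_force_split(t, r)
        assert direction == dir_o
        if direction == "GE":
            err = (t < thr).sum() + (r >= thr).sum()
        else:
            err = (t > thr).sum() + (r <= thr).sum()
        assert err == err_o


@pytest.fixture(scope="module")
def trained(small_scene_module):
    stack, _, samples = small_scene_module
    features = optimal_feature_set(stack)
    ss = split_train_verify(samples, 0.6, seed=11)
    tree = build_knowledge_tree(features, ss.subset("train"))
    return stack, features, ss, tree


@pytest.fixture(scope="module")
def small_scene_module():
    cfg = SceneConfig(shape=(80, 80), plots_per_class=4, seed=7)
    return simulate_scene(default_profiles(), cfg)


class TestKnowledgeTree:
    def test_zero_noise_training_is_perfect(self):
        profiles = default_profiles(noise_sd=0.0)
        stack, _, samples = simulate_scene(
            profiles, SceneConfig(shape=(80, 80), plots_per_class=3, seed=2,
                                  noise_multiplier=0.0))
        features = optimal_feature_set(stack)
        tree = build_knowledge_tree(features, samples)
        table = features.sample_table(samples)
        assert (tree.predict(table) == table["class"]).all()

    def test_determinism(self, trained):
        stack, features, ss, tree = trained
        tree2 = build_knowledge_tree(features, ss.subset("train"))
        assert tree.to_dict() == tree2.to_dict()

    def test_rule_order_follows_hierarchy(self, trained):
        _, _, _, tree = trained
        assert [(r.feature, r.assigned_class) for r in tree.rules] == \
            list(DEFAULT_HIERARCHY)
        assert tree.fallback_class == "larix"

    def test_missing_class_rejected(self, trained):
        stack, features, ss, _ = trained
        train = ss.subset("train")
        train.plots = [p for p in train.plots if p.class_label != "shaw"]
        with pytest.raises(DataError, match="shaw"):
            build_knowledge_tree(features, train)

    def test_directions_follow_class_contrasts(self, trained):
        # Pinus takes the high NDVI side in December; Quercus the low
        # MTM-NDQI side; scrub grass the low MTM-DSI side; shaw high MTM-RSI.
        _, _, _, tree = trained
        directions = {r.feature: r.direction for r in tree.rules}
        assert directions["NDVI@DEC"] == "GE"
        assert directions["NDVI@APR"] == "LE"
        assert directions["MTM-NDQI"] == "LE"
        assert directions["MTM-DSI"] == "LE"
        assert directions["MTM-RSI"] == "GE"

    def test_json_roundtrip(self, trained, tmp_path):
        _, _, _, tree = trained
        p = tmp_path / "tree.json"
        tree.to_json(p)
        assert KnowledgeDecisionTree.from_json(p).to_dict() == tree.to_dict()


class TestClassifyTree:
    def test_total_function_on_unmasked_pixels(self, trained):
        stack, features, _, tree = trained
        labels, classes = classify_tree(tree, features)
        assert labels.shape == (stack.nrows, stack.ncols)
        assert (labels >= 0).all()  # nothing masked in the synthetic scene
        assert len(classes) == 7

    def test_first_rule_wins_sequential_masking(self, trained):
        _, features, _, tree = trained
        # a pixel above the Pinus NDVI threshold is Pinus regardless of the
        # later rules' features
        row = {l.name: 0.0 for l in features.layers}
        row["NDVI@DEC"] = tree.rules[0].threshold + 0.5
        out = tree.predict(pd.DataFrame([row]))
        assert out[0] == "pinus"

    def test_failing_all_rules_gives_fallback(self, trained):
        _, _, _, tree = trained
        row = {}
        for r in tree.rules:
            row[r.feature] = (r.threshold - 1.0 if r.direction == "GE"
                              else r.threshold + 1.0)
        assert tree.predict(pd.DataFrame([row]))[0] == tree.fallback_class

    def test_masked_pixel_is_nodata(self, trained):
        _, features, _, tree = trained
        row = {l.name: np.nan for l in features.layers}
        assert tree.predict(pd.DataFrame([row]))[0] == "nodata"

    def test_removing_later_rule_keeps_earlier_assignments(self, trained):
        _, features, _, tree = trained
        full, classes = classify_tree(tree, features)
        pruned = KnowledgeDecisionTree(rules=tree.rules[:-1],
                                       fallback_class=tree.fallback_class)
        part, pclasses = classify_tree(pruned, features)
        for i, cls in enumerate(classes[:-2]):  # classes of surviving rules
            j = pclasses.index(cls)
            np.testing.assert_array_equal(full == i, part == j)


class TestEnsemble:
    def _table(self, rng, n=60, p=6, separable=True):
        X = rng.random((n, p))
        y = np.array(["a", "b"] * (n // 2))
        if separable:
            X[y == "a", 0] += 2.0
        return pd.DataFrame(X, columns=[f"f{i}" for i in range(p)]), y

    def test_sqrt_features_per_split(self, rng):
        X, y = self._table(rng)
        clf = train_ensemble(X, y, EnsembleConfig(n_trees=10, seed=0))
        assert clf.model.n_estimators == 10
        # sqrt rule with p = 6 -> 2 candidate features per split
        assert clf.model.estimators_[0].max_features_ == 2

    def test_separable_training_accuracy(self, rng):
        X, y = self._table(rng)
        clf = train_ensemble(X, y, EnsembleConfig(n_trees=25, seed=0))
        assert (classify_ensemble(clf, X) == y).all()

    def test_seed_determinism(self, rng):
        X, y = self._table(rng, separable=False)
        a = classify_ensemble(train_ensemble(X, y, EnsembleConfig(25, seed=3)), X)
        b = classify_ensemble(train_ensemble(X, y, EnsembleConfig(25, seed=3)), X)
        np.testing.assert_array_equal(a, b)

    def test_single_class_rejected(self, rng):
        X, _ = self._table(rng)
        with pytest.raises(DataError):
            train_ensemble(X, np.array(["a"] * len(X)), EnsembleConfig(5))

    def test_column_mismatch_rejected(self, rng):
        X, y = self._table(rng)
        clf = train_ensemble(X, y, EnsembleConfig(5, seed=0))
        with pytest.raises(DataError):
            classify_ensemble(clf, X.rename(columns={"f0": "zz"}))

    def test_empty_table_empty_output(self, rng):
        X, y = self._table(rng)
        clf = train_ensemble(X, y, EnsembleConfig(5, seed=0))
        assert len(classify_ensemble(clf, X.iloc[:0])) == 0


class TestCalibrationProperties:
    """Calibrated splits are optimal over the midpoint search space."""

    from hypothesis import given, settings, strategies as st

    _vec = st.lists(st.floats(-100, 100), min_size=2, max_size=40)

    @given(t=_vec, r=_vec)
    @settings(max_examples=150, deadline=None, derandomize=True)
    def test_never_worse_than_any_midpoint(self, t, r):
        t, r = np.asarray(t), np.asarray(r)
        if np.unique(np.concatenate([t, r])).size == 1:
            return
        thr, direction = calibrate_threshold(t, r)
        if direction == "GE":
            err = (t < thr).sum() + (r >= thr).sum()
        else:
            err = (t > thr).sum() + (r <= thr).sum()
        assert err == brute_force_split(t, r)[0]
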