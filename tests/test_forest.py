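import numpy as np
import pytest

from _oracles import brute_cart, tree_to_nested
from conftest import separable_set
from plastiscan import (
    LabeledSpectraSet,
    PreprocessConfig,
    RDFConfig,
    WavenumberAxis,
    audit_labels,
    load_model,
    preprocess_spectrum,
    save_model,
    train_rdf,
)

EXACT_CONFIG = RDFConfig(n_trees=1, features_per_split=1.0, bootstrap=False, seed=0)


class TestPreprocess:
    def test_identity_on_matching_axis(self, tiny_axis):
        rng = np.random.default_rng(0)
        spec = rng.normal(size=len(tiny_axis))
        out = preprocess_spectrum(spec, tiny_axis, tiny_axis)
        np.testing.assert_array_equal(out, spec)

    def test_constant_spectrum_derivative_is_zero(self, tiny_axis):
        out = preprocess_spectrum(
            np.full(len(tiny_axis), 3.7), tiny_axis, tiny_axis,
            PreprocessConfig(derivative=True),
        )
        np.testing.assert_allclose(out, 0.0, atol=1e-10)

    def test_two_point_midpoint_is_arithmetic_mean(self):
        raw_axis = WavenumberAxis(np.array([1250.0, 1258.0]))
        target = WavenumberAxis(np.array([1250.0, 1254.0, 1258.0]))
        out = preprocess_spectrum(np.array([0.2, 0.6]), raw_axis, target)
        np.testing.assert_allclose(out, [0.2, 0.4, 0.6])

    def test_descending_axis_resampled_correctly(self):
        raw_axis = WavenumberAxis(np.array([1258.0, 1254.0, 1250.0]))
        target = WavenumberAxis(np.array([1250.0, 1254.0, 1258.0]))
        out = preprocess_spectrum(np.array([0.6, 0.4, 0.2]), raw_axis, target)
        np.testing.assert_allclose(out, [0.2, 0.4, 0.6])

    def test_insufficient_overlap_raises(self):
        raw_axis = WavenumberAxis(np.array([1250.0, 1400.0]))
        target = WavenumberAxis(np.array([1250.0, 3594.0]))
        with pytest.raises(ValueError, match="overlap|covers"):
            preprocess_spectrum(np.array([0.1, 0.2]), raw_axis, target)

    def test_out_of_range_bands_take_edge_values(self):
        raw_axis = WavenumberAxis(np.array([1300.0, 3500.0]))
        target = WavenumberAxis(np.array([1250.0, 1300.0, 3500.0, 3594.0]))
        out = preprocess_spectrum(np.array([0.3, 0.8]), raw_axis, target)
        np.testing.assert_allclose(out, [0.3, 0.3, 0.8, 0.8])

    def test_unit_normalization(self, tiny_axis):
        spec = np.arange(len(tiny_axis), dtype=float)
        out = preprocess_spectrum(spec, tiny_axis, tiny_axis,
                                  PreprocessConfig(normalize=True))
        assert np.linalg.norm(out) == pytest.approx(1.0)


class TestTraining:
    def test_separable_classes_training_accuracy_is_one(self):
        data = separable_set(n_classes=2, n_per_class=10, seed=1)
        model = train_rdf(data, RDFConfig(n_trees=15, seed=0))
        assert np.array_equal(model.predict(data.spectra), data.labels)

    def test_single_class_rejected(self, tiny_axis):
        data = LabeledSpectraSet(np.zeros((5, 16)), np.zeros(5, dtype=int), tiny_axis)
        with pytest.raises(ValueError, match="two classes"):
            train_rdf(data)

    def test_empty_data_rejected(self, tiny_axis):
        data = LabeledSpectraSet(np.zeros((0, 16)), np.zeros(0, dtype=int), tiny_axis)
        with pytest.raises(ValueError):
            train_rdf(data)

    def test_deterministic_given_seed(self):
        data = separable_set(n_classes=3, n_per_class=8, seed=2)
        probe = np.random.default_rng(0).normal(size=(10, 16)) + 0.3
        p1 = train_rdf(data, RDFConfig(n_trees=10, seed=4)).predict_proba(probe)
        p2 = train_rdf(data, RDFConfig(n_trees=10, seed=4)).predict_proba(probe)
        np.testing.assert_array_equal(p1, p2)

    def test_prediction_invariant_to_training_row_order(self):
        data = separable_set(n_classes=3, n_per_class=8, seed=3)
        perm = np.random.default_rng(1).permutation(len(data))
        shuffled = LabeledSpectraSet(
            data.spectra[perm], data.labels[perm], data.axis)
        probe = np.random.default_rng(2).normal(size=(20, 16))
        cfg = RDFConfig(n_trees=10, seed=7)
        p1 = train_rdf(data, cfg).predict_proba(probe)
        p2 = train_rdf(shuffled, cfg).predict_proba(probe)
        np.testing.assert_array_equal(p1, p2)


class TestCartOracle:
    """Single-tree, all-features, no-bootstrap forest vs exhaustive greedy CART."""

    @pytest.mark.parametrize("trial", range(60))
    def test_matches_bruteforce_greedy_gini_tree(self, trial):
        rng = np.random.default_rng(1000 + trial)
        n = int(rng.integers(2, 9))
        n_bands = int(rng.integers(1, 5))
        # coarse values so exact split ties actually occur
        X = np.round(rng.normal(size=(n, n_bands)), 1)
        y = rng.integers(0, 3, size=n)
        if len(np.unique(y)) < 2:
            y[0] = (y[1] + 1) % 3
        axis = WavenumberAxis(1250.0 + 4.0 * np.arange(n_bands))
        data = LabeledSpectraSet(X, y, axis)
        model = train_rdf(data, EXACT_CONFIG)
        # oracle sees the same canonical row order the trainer uses
        from plastiscan.forest import _canonical_order
        order = _canonical_order(X.astype(float), y)
        expected = brute_cart(X[order], y[order])
        assert tree_to_nested(model.trees[0]) == expected

    def test_min_leaf_respected(self):
        rng = np.random.default_rng(5)
        X = np.round(rng.normal(size=(8, 3)), 1)
        y = np.array([0, 0, 0, 0, 1, 1, 1, 1])
        cfg = RDFConfig(n_trees=1, features_per_split=1.0, bootstrap=False,
                        min_leaf=3, seed=0)
        model = train_rdf(LabeledSpectraSet(
            X, y, WavenumberAxis(1250.0 + 4.0 * np.arange(3))), cfg)
        from plastiscan.forest import _canonical_order
        order = _canonical_order(X.astype(float), y)
        assert tree_to_nested(model.trees[0]) == brute_cart(X[order], y[order], min_leaf=3)


class TestPrediction:
    def test_vote_fractions_are_valid_probabilities(self):
        data = separable_set(n_classes=4, n_per_class=10, seed=4)
        model = train_rdf(data, RDFConfig(n_trees=7, seed=0))
        probe = np.random.default_rng(3).normal(size=(100, 16))
        p = model.predict_proba(probe)
        np.testing.assert_allclose(p.sum(axis=1), 1.0, atol=1e-9)
        # vote fractions live on the grid {0, 1/T, ..., 1}
        np.testing.assert_allclose(p * 7, np.round(p * 7), atol=1e-9)

    def test_separated_class_wins_all_votes(self):
        # trees grow until pure, so with every row in-bag each training
        # spectrum of a separated class draws a unanimous vote
        data = separable_set(n_classes=3, n_per_class=10, seed=5)
        model = train_rdf(data, RDFConfig(n_trees=25, bootstrap=False, seed=0))
        p = model.predict_proba(data.spectra)
        assert np.all(p.max(axis=1) == 1.0)
        assert np.array_equal(np.argmax(p, axis=1), data.labels)

    def test_held_out_accuracy_on_separable_data_is_one(self):
        train = separable_set(n_classes=4, n_per_class=15, seed=20)
        test = separable_set(n_classes=4, n_per_class=10, seed=21)
        model = train_rdf(train, RDFConfig(n_trees=30, seed=0))
        assert np.array_equal(model.predict(test.spectra), test.labels)

    def test_row_permutation_equivariance(self):
        data = separable_set(n_classes=3, n_per_class=10, seed=6)
        model = train_rdf(data, RDFConfig(n_trees=10, seed=0))
        probe = np.random.default_rng(4).normal(size=(12, 16))
        perm = np.random.default_rng(5).permutation(12)
        np.testing.assert_array_equal(
            model.predict_proba(probe)[perm], model.predict_proba(probe[perm]))

    def test_length_mismatch_raises(self):
        data = separable_set(n_classes=2, n_per_class=5, seed=7)
        model = train_rdf(data, RDFConfig(n_trees=3, seed=0))
        with pytest.raises(ValueError, match="length"):
            model.predict_proba(np.zeros((2, 11)))

    def test_agrees_with_sklearn_on_held_out_data(self):
        """Independent cross-check: a standard random-forest implementation
        reaches the same (perfect) held-out accuracy on separable data."""
        sklearn = pytest.importorskip("sklearn.ensemble")
        train = separable_set(n_classes=4, n_per_class=15, seed=8)
        test = separable_set(n_classes=4, n_per_class=10, seed=9)
        model = train_rdf(train, RDFConfig(n_trees=30, seed=0))
        ours = (model.predict(test.spectra) == test.labels).mean()
        rf = sklearn.RandomForestClassifier(n_estimators=30, random_state=0)
        rf.fit(train.spectra, train.labels)
        theirs = (rf.predict(test.spectra) == test.labels).mean()
        assert ours == theirs == 1.0


class TestPersistence:
    def test_save_load_round_trip(self, tmp_path):
        data = separable_set(n_classes=3, n_per_class=8, seed=10)
        model = train_rdf(data, RDFConfig(n_trees=5, seed=0))
        path = tmp_path / "model.json"
        save_model(model, path)
        back = load_model(path)
        probe = np.random.default_rng(6).normal(size=(10, 16))
        np.testing.assert_array_equal(
            model.predict_proba(probe), back.predict_proba(probe))
        assert back.class_order == model.class_order

    def test_incompatible_version_refused(self, tmp_path):
        import json
        data = separable_set(n_classes=2, n_per_class=5, seed=11)
        model = train_rdf(data, RDFConfig(n_trees=2, seed=0))
        path = tmp_path / "model.json"
        save_model(model, path)
        doc = json.loads(path.read_text())
        doc["version"] = 999
        path.write_text(json.dumps(doc))
        with pytest.raises(ValueError, match="version"):
            load_model(path)

    def test_foreign_json_refused(self, tmp_path):
        path = tmp_path / "junk.json"
        path.write_text('{"hello": 1}')
        with pytest.raises(ValueError):
            load_model(path)


class TestLabelAudit:
    CFG = RDFConfig(n_trees=15, seed=0)

    def _sets(self, flip_one: bool):
        sets = []
        for k in range(4):
            sets.append(separable_set(
                n_classes=5, n_per_class=12, seed=100 + k,
                flip_fraction=0.05 if (flip_one and k == 0) else 0.0,
            ))
        return sets

    def test_clean_sets_produce_no_flags(self):
        report = audit_labels(self._sets(flip_one=False), self.CFG)
        assert not any(r["flagged"] for r in report)

    def test_flipped_labels_are_flagged(self):
        sets = self._sets(flip_one=True)
        flipped = set(sets[0].flipped_indices.tolist())
        assert flipped
        report = audit_labels(sets, self.CFG)
        flags0 = {r["index"] for r in report if r["set"] == 0 and r["flagged"]}
        assert len(flags0 & flipped) / len(flipped) >= 0.8
        clean_flags = [r for r in report
                       if r["flagged"] and not (r["set"] == 0 and r["index"] in flipped)]
        n_clean = sum(1 for r in report
                      if not (r["set"] == 0 and r["index"] in flipped))
        assert len(clean_flags) / n_clean <= 0.05

    def test_two_sets_single_crossmodel_rule(self):
        sets = [separable_set(n_classes=3, n_per_class=10, seed=200 + k)
                for k in range(2)]
        report = audit_labels(sets, self.CFG, majority_fraction=0.5)
        for r in report:
            assert r["flagged"] == (r["cross_labels"][0] != r["own_label"])

    def test_fewer_than_two_sets_rejected(self):
        with pytest.raises(ValueError):
            audit_labels([separable_set(seed=1)], self.CFG)
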