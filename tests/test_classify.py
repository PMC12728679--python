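"""SMOTE oversampling and the SVS stacking ensemble."""

import numpy as np
import pytest

from respifuse import (SvsConfig, SVSClassifier, cross_validate_svs,
                       smote_oversample)
from respifuse.classify import _default_learners, cross_validate_single
from respifuse.errors import ConfigurationError, InputError, SchemaError

FAST2 = SvsConfig(base_learner_names=("logistic", "knn"), fast=True,
                  cv_folds=5, inner_folds=3)


def blobs(n_per_class, d, separation, seed=0):
    rng = np.random.default_rng(seed)
    X = np.vstack([rng.standard_normal((n_per_class, d)),
                   rng.standard_normal((n_per_class, d)) + separation / np.sqrt(d)])
    y = np.r_[np.ones(n_per_class, int), np.zeros(n_per_class, int)]
    return X, y


class TestSmote:
    def test_balanced_input_unchanged(self, rng, table_factory):
        t = table_factory(rng.standard_normal((10, 3)),
                          np.r_[np.ones(5, int), np.zeros(5, int)])
        assert smote_oversample(t, k=2) is t

    def test_imbalanced_cohort_counts_balanced(self, rng, table_factory):
        labels = np.r_[np.ones(282, int), np.zeros(78, int)]
        t = table_factory(rng.standard_normal((360, 3)), labels)
        out = smote_oversample(t, k=5, seed=0)
        counts = np.bincount(out.labels)
        assert counts[0] == counts[1] == 282

    def test_synthetic_rows_lie_on_minority_segments(self, rng, table_factory):
        """Brute-force geometric oracle: every synthetic row is a convex
        combination of two original minority rows."""
        labels = np.r_[np.ones(7, int), np.zeros(3, int)]
        X = rng.standard_normal((10, 2))
        t = table_factory(X, labels)
        out = smote_oversample(t, k=2, seed=1)
        minority = X[labels == 0]
        synthetic = out.values[10:]
        for s in synthetic:
            on_segment = False
            for i in range(len(minority)):
                for j in range(len(minority)):
                    if i == j:
                        continue
                    d = minority[j] - minority[i]
                    denom = float(d @ d)
                    if denom == 0:
                        continue
                    u = float((s - minority[i]) @ d) / denom
                    if -1e-9 <= u <= 1 + 1e-9 and np.allclose(
                            minority[i] + u * d, s, atol=1e-9):
                        on_segment = True
            assert on_segment

    def test_k_exceeding_minority_rejected(self, rng, table_factory):
        labels = np.r_[np.ones(8, int), np.zeros(3, int)]
        t = table_factory(rng.standard_normal((11, 2)), labels)
        with pytest.raises(ConfigurationError):
            smote_oversample(t, k=3)

    def test_single_class_rejected(self, rng, table_factory):
        t = table_factory(rng.standard_normal((6, 2)), np.ones(6, int))
        with pytest.raises(InputError):
            smote_oversample(t, k=2)


class TestSvsFit:
    def test_separable_blobs_high_accuracy(self, table_factory):
        X, y = blobs(150, 10, 3.0, seed=2)
        t = table_factory(X, y)
        result = cross_validate_svs(t, SvsConfig(fast=True, seed=2))
        assert result.pooled.acc >= 0.95

    def test_null_labels_stay_at_chance(self, table_factory):
        """With labels independent of features, mean CV accuracy (at the
        0.5 score cut) stays in the chance band — this doubles as the
        SMOTE-leakage check, since leaking oversampling inflates it."""
        accs = []
        for rep in range(50):
            rng = np.random.default_rng(1000 + rep)
            X = rng.standard_normal((60, 5))
            y = np.r_[np.ones(40, int), np.zeros(20, int)]  # imbalanced
            rng.shuffle(y)
            t = table_factory(X, y)
            cfg = SvsConfig(base_learner_names=("logistic", "knn"),
                            fast=True, seed=rep)
            result = cross_validate_svs(t, cfg)
            accs.append(np.mean((result.scores >= 0.5) == y))
        assert 0.40 <= float(np.mean(accs)) <= 0.60

    def test_identical_base_learners_share_weight(self, monkeypatch,
                                                  table_factory):
        from sklearn.linear_model import LogisticRegression
        from respifuse import classify as mod

        def identical(seed, fast):
            est = LogisticRegression(max_iter=500, random_state=seed)
            return {name: (est, {}) for name in mod.BASE_LEARNER_NAMES}

        monkeypatch.setattr(mod, "_default_learners", identical)
        X, y = blobs(30, 4, 2.0, seed=3)
        clf = SVSClassifier(SvsConfig(fast=True, seed=3)).fit(
            table_factory(X, y))
        weights = np.array(list(clf.bundle_.weights.values()))
        assert np.allclose(weights, 0.2, atol=1e-9)

    def test_determinism_under_fixed_seed(self, table_factory):
        X, y = blobs(40, 5, 2.0, seed=4)
        t = table_factory(X, y)
        a = SVSClassifier(FAST2).fit(t)
        b = SVSClassifier(FAST2).fit(t)
        assert a.bundle_.weights == b.bundle_.weights
        assert a.bundle_.threshold == b.bundle_.threshold
        assert np.array_equal(a.predict_scores(t), b.predict_scores(t))

    def test_too_few_subjects_per_class_rejected(self, rng, table_factory):
        t = table_factory(rng.standard_normal((8, 2)),
                          np.r_[np.ones(6, int), np.zeros(2, int)])
        with pytest.raises(InputError):
            SVSClassifier(FAST2).fit(t)


class TestSvsPredict:
    def test_separable_training_data_reproduced(self, table_factory):
        X, y = blobs(30, 6, 5.0, seed=5)
        t = table_factory(X, y)
        clf = SVSClassifier(FAST2).fit(t)
        labels, scores = clf.predict(t)
        assert np.array_equal(labels, y)
        assert np.all((scores >= 0) & (scores <= 1))

    def test_single_subject_scored(self, table_factory):
        X, y = blobs(30, 4, 3.0, seed=6)
        t = table_factory(X, y)
        clf = SVSClassifier(FAST2).fit(t)
        one = t.subset_rows([0])
        _, scores = clf.predict(one)
        assert scores.shape == (1,) and 0.0 <= scores[0] <= 1.0

    def test_scores_equal_manual_weight_blended_meta_output(self, table_factory):
        """Recompute the stacked score by hand for a 3-subject slice:
        base probabilities x accuracy weights through the logistic meta."""
        X, y = blobs(25, 4, 2.5, seed=7)
        t = table_factory(X, y)
        clf = SVSClassifier(FAST2).fit(t)
        bundle = clf.bundle_
        sub = t.subset_rows([0, 1, 2])
        probs = np.column_stack([
            bundle.learners[n].predict_proba(sub.values)[:, 1]
            for n in bundle.config.base_learner_names])
        w = np.array([bundle.weights[n]
                      for n in bundle.config.base_learner_names])
        z = (probs * w) @ bundle.meta.coef_[0] + bundle.meta.intercept_[0]
        manual = 1.0 / (1.0 + np.exp(-z))
        assert np.allclose(clf.predict_scores(sub), manual, atol=1e-12)

    def test_schema_mismatch_lists_missing_columns(self, rng, table_factory):
        X, y = blobs(25, 4, 2.5, seed=8)
        clf = SVSClassifier(FAST2).fit(table_factory(X, y))
        other = table_factory(rng.standard_normal((4, 2)),
                              np.r_[1, 1, 0, 0], prefix="g")
        with pytest.raises(SchemaError, match="f2"):
            clf.predict_scores(other)


def test_ensemble_not_dominated_by_single_learners(table_factory):
    """On planted-signal data the stacked ensemble stays within 0.02 of the
    best single base learner across seeds."""
    margins = []
    for seed in range(10):
        X, y = blobs(60, 8, 1.6, seed=100 + seed)
        t = table_factory(X, y)
        cfg = SvsConfig(fast=True, seed=seed)
        svs_acc = cross_validate_svs(t, cfg).pooled.acc
        best = max(cross_validate_single(t, name, cfg).pooled.acc
                   for name in cfg.base_learner_names)
        margins.append(svs_acc - best)
    assert float(np.mean(margins)) >= -0.02
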