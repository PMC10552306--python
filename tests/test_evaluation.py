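"""ROC AUC, CV harness, corrected t-test, learning curve."""

import numpy as np
import pytest

from biosparse import corrected_t_test, learning_curve, repeated_stratified_cv, roc_auc
from biosparse.evaluation import cv_splits, nested_stratified_subsets


def brute_force_auc(scores, labels):
    """Exhaustive concordant-pair counting with ties at 1/2."""
    pos = [s for s, l in zip(scores, labels) if l == 1]
    neg = [s for s, l in zip(scores, labels) if l == 0]
    total = 0.0
    for p in pos:
        for q in neg:
            total += 1.0 if p > q else (0.5 if p == q else 0.0)
    return total / (len(pos) * len(neg))


class TestRocAuc:
    def test_perfect_separation(self):
        assert roc_auc([0.9, 0.8, 0.2, 0.1], [1, 1, 0, 0]) == 1.0

    def test_all_tied_scores(self):
        assert roc_auc([0.5] * 6, [1, 0, 1, 0, 1, 0]) == 0.5

    def test_half_concordant_example(self):
        # 2 concordant of 4 case-control pairs
        assert roc_auc([0.9, 0.2, 0.8, 0.1], [1, 0, 0, 1]) == 0.5

    def test_single_class_rejected(self):
        with pytest.raises(ValueError):
            roc_auc([0.1, 0.2], [1, 1])

    def test_matches_brute_force_on_random_instances(self, rng):
        for _ in range(200):
            n = rng.integers(4, 12)
            labels = np.r_[1, 0, rng.integers(0, 2, size=n - 2)]
            scores = rng.choice([0.1, 0.3, 0.5, 0.7], size=n)  # ties likely
            assert roc_auc(scores, labels) == pytest.approx(
                brute_force_auc(scores, labels), abs=1e-12
            )

    def test_invariant_under_monotone_transform(self, rng):
        scores = rng.normal(size=40)
        labels = rng.integers(0, 2, size=40)
        labels[:2] = [0, 1]
        a = roc_auc(scores, labels)
        assert roc_auc(np.exp(scores), labels) == pytest.approx(a, abs=1e-12)
        assert roc_auc(3 * scores - 7, labels) == pytest.approx(a, abs=1e-12)


class _RecordingEstimator:
    """Scores samples by a fixed hash so folds can be compared across runs."""

    def __init__(self, seed):
        self.seed = seed
        self.seen = []

    def fit(self, X, y):
        self.seen.append((X.shape, int(y.sum())))
        return self

    def predict_proba(self, X):
        return 1 / (1 + np.exp(-X.reshape(len(X), -1).sum(axis=1)))


class TestRepeatedStratifiedCV:
    def setup_method(self):
        rng = np.random.default_rng(7)
        self.X = rng.normal(size=(90, 4)).astype(np.float32)
        self.y = np.r_[np.ones(30, int), np.zeros(60, int)]
        rng.shuffle(self.y)

    def test_fold_class_proportions(self):
        for folds in cv_splits(self.y, 3, 2, base_seed=0):
            for tr, te in folds:
                frac = self.y[te].mean()
                assert abs(frac - self.y.mean()) <= 1.5 / len(te)

    def test_folds_partition_dataset(self):
        for folds in cv_splits(self.y, 3, 2, base_seed=0):
            all_te = np.concatenate([te for _, te in folds])
            assert sorted(all_te) == list(range(90))

    def test_identical_splits_across_factories(self):
        s1 = cv_splits(self.y, 3, 5, base_seed=3)
        s2 = cv_splits(self.y, 3, 5, base_seed=3)
        for f1, f2 in zip(s1, s2):
            for (tr1, te1), (tr2, te2) in zip(f1, f2):
                np.testing.assert_array_equal(tr1, tr2)
                np.testing.assert_array_equal(te1, te2)

    def test_result_shape_and_range(self):
        res = repeated_stratified_cv(
            _RecordingEstimator, self.X, self.y, k=3, reps=2, base_seed=0,
            standardize="columns",
        )
        assert res.aucs.shape == (2, 3)
        assert np.all((res.aucs >= 0) & (res.aucs <= 1))
        assert res.mean == pytest.approx(res.aucs.mean())

    def test_too_small_class_rejected(self):
        y = np.r_[np.ones(2, int), np.zeros(50, int)]
        with pytest.raises(ValueError):
            repeated_stratified_cv(_RecordingEstimator, self.X[:52], y, k=3)


class TestCorrectedTTest:
    def test_zero_differences(self):
        a = np.full((10, 3), 0.7)
        res = corrected_t_test(a, a, n_train=100, n_test=50)
        assert res.t == 0.0 and res.p == 1.0

    def test_formula_against_scalar_oracle(self, rng):
        """k=3 correction factor is 1/m + 1/2 with m = 30."""
        d = rng.normal(0.01, 0.02, size=(10, 3))
        a = np.full((10, 3), 0.7) + d
        b = np.full((10, 3), 0.7)
        res = corrected_t_test(a, b, n_train=200, n_test=100)
        m = 30
        expected_t = d.mean() / np.sqrt((1 / m + 100 / 200) * d.ravel().var(ddof=1))
        assert res.t == pytest.approx(expected_t, rel=1e-12)
        from scipy import stats as sps

        assert res.p == pytest.approx(2 * sps.t.sf(abs(expected_t), df=m - 1), rel=1e-12)

    def test_scale_equivariance_of_t(self, rng):
        """Rescaling all differences leaves t unchanged (mean and sd scale
        together); doubling the mean difference at fixed spread doubles t."""
        b = np.full((5, 3), 0.6)
        d = rng.normal(0.02, 0.01, size=(5, 3))
        t1 = corrected_t_test(b + d, b, 100, 50).t
        t2 = corrected_t_test(b + 2 * d, b, 100, 50).t
        assert t2 == pytest.approx(t1, rel=1e-9)
        t3 = corrected_t_test(b + d + d.mean(), b, 100, 50).t
        assert t3 == pytest.approx(2 * t1, rel=1e-9)

    def test_degenerate_variance_flagged(self):
        a = np.full((4, 3), 0.8)
        b = np.full((4, 3), 0.7)
        res = corrected_t_test(a, b, 100, 50)
        assert res.degenerate and res.p == 0.0

    def test_shape_mismatch_rejected(self):
        with pytest.raises(ValueError):
            corrected_t_test(np.zeros((3, 3)), np.zeros((4, 3)), 10, 5)


class TestLearningCurve:
    def setup_method(self):
        rng = np.random.default_rng(11)
        self.X = rng.normal(size=(120, 5)).astype(np.float32)
        self.y = (self.X[:, 0] + rng.normal(0, 0.5, 120) > 0).astype(int)

    def test_subsets_are_nested_and_stratified(self):
        subsets = nested_stratified_subsets(self.y, [0.2, 0.4, 1.0], base_seed=0)
        assert set(subsets[0.2]) <= set(subsets[0.4]) <= set(subsets[1.0])
        assert len(subsets[1.0]) == 120
        frac = self.y[subsets[0.4]].mean()
        assert abs(frac - self.y.mean()) < 0.1

    def test_full_fraction_reproduces_plain_cv(self):
        lc = learning_curve(
            {"m": _RecordingEstimator}, self.X, self.y,
            fractions=[0.5, 1.0], k=3, reps=2, base_seed=5, standardize="columns",
        )
        direct = repeated_stratified_cv(
            _RecordingEstimator, self.X, self.y, k=3, reps=2, base_seed=5,
            standardize="columns",
        )
        np.testing.assert_allclose(lc.results["m"][1.0].aucs, direct.aucs)

    def test_long_format_serialization(self, tmp_path):
        lc = learning_curve(
            {"m": _RecordingEstimator}, self.X, self.y,
            fractions=[0.5, 1.0], k=3, reps=1, base_seed=0, standardize="columns",
        )
        lc.to_tsv(tmp_path / "lc.tsv")
        import pandas as pd

        frame = pd.read_csv(tmp_path / "lc.tsv", sep="\t")
        assert {"model", "fraction", "rep", "fold", "auc"} <= set(frame.columns)
        assert len(frame) == 2 * 1 * 3

    def test_infeasible_fraction_rejected(self):
        with pytest.raises(ValueError):
            learning_curve(
                {"m": _RecordingEstimator}, self.X, self.y,
                fractions=[0.01, 1.0], k=3, reps=1, base_seed=0,
            )
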