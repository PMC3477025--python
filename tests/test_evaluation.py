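import numpy as np
import pytest

from biosig.cohort import CohortSpec, FeatureTable, ModalitySpec, generate_cohort
from biosig.evaluate import (auc, auc_vs_topT, compare_auc, loo_scores,
                             paired_bootstrap_auc_test)
from biosig.stability import StabilityConfig, selection_profile


def brute_force_auc(scores, labels):
    """Pair enumeration with exact half-credit for ties."""
    scores = np.asarray(scores)
    labels = np.asarray(labels)
    pos = scores[labels == 1]
    neg = scores[labels == -1]
    total = 0.0
    for p in pos:
        for q in neg:
            if p > q:
                total += 1.0
            elif p == q:
                total += 0.5
    return total / (len(pos) * len(neg))


def _table(X, y):
    X = np.atleast_2d(np.asarray(X, dtype=float))
    return FeatureTable([f"s{i}" for i in range(len(y))], np.asarray(y),
                        X, [f"f{j}" for j in range(X.shape[1])],
                        ["cognitive"] * X.shape[1])


class TestAUC:
    def test_enumerated_example(self):
        assert auc([0.9, 0.8, 0.3], [1, -1, 1]) == pytest.approx(0.5)

    def test_all_tied_scores(self):
        assert auc([1.0] * 6, [1, 1, 1, -1, -1, -1]) == 0.5

    def test_label_flip_symmetry(self, rng):
        s = rng.standard_normal(20)
        y = np.where(rng.random(20) < 0.5, 1, -1)
        y[:2] = [1, -1]
        assert auc(s, y) == pytest.approx(1.0 - auc(s, -y))

    def test_negated_scores_identity_exact(self, rng):
        for _ in range(20):
            s = np.round(rng.standard_normal(15), 2)   # induce ties
            y = np.where(rng.random(15) < 0.5, 1, -1)
            y[:2] = [1, -1]
            assert auc(s, y) + auc(-s, y) == 1.0

    def test_matches_brute_force_with_ties(self, rng):
        for _ in range(50):
            n = int(rng.integers(4, 51))
            s = np.round(rng.standard_normal(n), 1)
            y = np.where(rng.random(n) < 0.5, 1, -1)
            y[:2] = [1, -1]
            assert auc(s, y) == pytest.approx(brute_force_auc(s, y), abs=1e-12)

    def test_single_class_rejected(self):
        with pytest.raises(ValueError):
            auc([0.1, 0.2], [1, 1])

    def test_matches_sklearn_roc_auc(self, rng):
        from sklearn.metrics import roc_auc_score
        for _ in range(20):
            n = int(rng.integers(6, 40))
            s = np.round(rng.standard_normal(n), 1)
            y = np.where(rng.random(n) < 0.5, 1, -1)
            y[:2] = [1, -1]
            assert auc(s, y) == pytest.approx(roc_auc_score(y, s), abs=1e-12)


class TestLOOScores:
    def test_label_feature_is_perfectly_separable(self):
        y = np.array([1, 1, -1, -1, 1, -1])
        res = loo_scores(_table(y.astype(float)[:, None], y), ["f0"])
        assert res.auc == 1.0

    def test_null_feature_auc_in_sampling_band(self):
        for seed in (0, 1):
            spec = CohortSpec(n_nonconverter=177, n_converter=142, seed=seed,
                              modalities=(ModalitySpec("lab", 1),))
            table, _ = generate_cohort(spec)
            res = loo_scores(table, [table.feature_names[0]])
            assert 0.35 <= res.auc <= 0.65

    def test_planted_single_feature_band(self):
        # d = 0.8 single feature: pooled LOO AUC lands near the theoretical
        # Phi(d/sqrt(2)) ~ 0.71 for a Gaussian shift
        spec = CohortSpec(n_nonconverter=177, n_converter=142, seed=4,
                          modalities=(ModalitySpec("cognitive", 1,
                                                   planted=((0, 0.8),)),))
        table, _ = generate_cohort(spec)
        res = loo_scores(table, ["cognitive"])
        assert 0.65 <= res.auc <= 0.78

    def test_determinism(self, small_cohort):
        table, _ = small_cohort
        names = table.feature_names[:3]
        r1 = loo_scores(table, names)
        r2 = loo_scores(table, names)
        np.testing.assert_array_equal(r1.loo_scores, r2.loo_scores)

    def test_missing_subjects_dropped_and_counted(self):
        spec = CohortSpec(n_nonconverter=30, n_converter=30, seed=8,
                          modalities=(ModalitySpec("csf", 2, availability=0.8),))
        table, _ = generate_cohort(spec)
        res = loo_scores(table, table.feature_names)
        assert res.n_dropped == 60 - len(res.labels)
        assert res.n_dropped == 12

    def test_empty_feature_set_rejected(self, small_cohort):
        table, _ = small_cohort
        with pytest.raises(ValueError):
            loo_scores(table, [])


class TestCompareAUC:
    def _two_results(self, seed, d=1.0):
        spec = CohortSpec(
            n_nonconverter=60, n_converter=60, seed=seed,
            modalities=(ModalitySpec("cognitive", 2, planted=((0, d),)),))
        table, _ = generate_cohort(spec)
        ra = loo_scores(table, [table.feature_names[0]])   # signal
        rb = loo_scores(table, [table.feature_names[1]])   # noise
        return ra, rb

    def test_identical_scores_give_p_one(self, small_cohort):
        table, _ = small_cohort
        r = loo_scores(table, table.feature_names[:2])
        assert compare_auc(r, r) == 1.0

    def test_signal_vs_noise_detected(self):
        hits = sum(compare_auc(*self._two_results(seed, d=1.2)) < 0.05
                   for seed in range(20))
        assert hits >= 17

    def test_bootstrap_cross_check_agrees_with_delong(self):
        agree = 0
        for seed in range(10):
            ra, rb = self._two_results(seed, d=0.9)
            d1 = compare_auc(ra, rb) < 0.05
            d2 = paired_bootstrap_auc_test(ra, rb, n_resamples=500,
                                           seed=seed) < 0.05
            agree += d1 == d2
        assert agree >= 8

    def test_mismatched_subjects_rejected(self, small_cohort):
        table, _ = small_cohort
        r1 = loo_scores(table, table.feature_names[:1])
        sub = table.complete_cases()
        r2 = loo_scores(
            type(table)(table.subject_ids[:-1], table.labels[:-1],
                        table.X[:-1], table.feature_names,
                        table.modality_tags),
            table.feature_names[:1])
        with pytest.raises(ValueError):
            compare_auc(r1, r2)


class TestTopTCurve:
    def test_single_point_matches_direct_call(self, small_cohort):
        table, _ = small_cohort
        prof = selection_profile(table, StabilityConfig(n_bootstrap=20, seed=3))
        curve = auc_vs_topT(table, prof, t_max=1)
        from biosig.stability import top_features
        direct = loo_scores(table, top_features(prof, 1))
        assert curve.aucs[0] == pytest.approx(direct.auc)
        assert list(curve.t_values) == [1]
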