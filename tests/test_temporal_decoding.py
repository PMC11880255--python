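"""Sliding LDA decoding, bootstrap inference, dummy baseline, patterns."""

import numpy as np
import pytest

from conftest import make_epochs
from robot_erp.cluster_stats import ContrastStack
from robot_erp.temporal_decoding import (
    auc,
    bootstrap_ci,
    dummy_scores,
    finalize_curve,
    group_curve,
    haufe_patterns,
    lda_train,
    ledoit_wolf_cov,
    mask_patterns,
    peak_time,
    sliding_decode,
)


class TestLedoitWolf:
    def test_matches_sklearn_reference(self):
        from sklearn.covariance import ledoit_wolf as sk_lw

        rng = np.random.default_rng(0)
        X = rng.standard_normal((30, 12)) @ rng.standard_normal((12, 12))
        S, d = ledoit_wolf_cov(X)
        S_ref, d_ref = sk_lw(X)
        assert d == pytest.approx(d_ref, abs=1e-12)
        assert np.abs(S - S_ref).max() < 1e-10

    def test_strong_shrinkage_when_n_below_p(self):
        rng = np.random.default_rng(1)
        deltas = [ledoit_wolf_cov(rng.standard_normal((10, 20)))[1]
                  for _ in range(20)]
        assert min(deltas) >= 0 and max(deltas) <= 1
        assert np.mean(deltas) > 0.3

    def test_consistent_at_large_n(self):
        rng = np.random.default_rng(2)
        true = np.array([[1.0, 0.5], [0.5, 1.0]])
        L = np.linalg.cholesky(true)
        X = rng.standard_normal((10000, 2)) @ L.T
        S, d = ledoit_wolf_cov(X)
        assert d < 0.05
        assert np.abs(S - true).max() < 0.05

    def test_single_sample_rejected(self):
        with pytest.raises(ValueError):
            ledoit_wolf_cov(np.ones((1, 3)))


class TestLDA:
    def test_weight_direction_for_isotropic_classes(self):
        rng = np.random.default_rng(3)
        X = rng.standard_normal((400, 6))
        y = np.array([0, 1] * 200)
        X[y == 1, 0] += 4.0
        w, b = lda_train(X, y)
        cos = w[0] / np.linalg.norm(w)
        assert cos > 0.99

    def test_label_swap_negates_weights(self):
        rng = np.random.default_rng(4)
        X = rng.standard_normal((60, 5))
        y = np.array([0, 1] * 30)
        X[y == 1] += 0.5
        w1, b1 = lda_train(X, y)
        w2, b2 = lda_train(X, 1 - y)
        assert np.allclose(w1, -w2, atol=1e-10)

    def test_duplicate_features_still_finite(self):
        rng = np.random.default_rng(5)
        X = rng.standard_normal((40, 3))
        X = np.hstack([X, X])  # exactly collinear
        y = np.array([0, 1] * 20)
        X[y == 1] += 0.3
        w, b = lda_train(X, y)
        assert np.isfinite(w).all() and np.isfinite(b)

    def test_matches_sklearn_lsqr_auto_shrinkage_direction(self):
        from sklearn.discriminant_analysis import LinearDiscriminantAnalysis

        rng = np.random.default_rng(6)
        X = rng.standard_normal((200, 8))
        y = np.array([0, 1] * 100)
        X[y == 1] += 0.8
        w, _ = lda_train(X, y)
        ref = LinearDiscriminantAnalysis(solver="lsqr", shrinkage="auto")
        ref.fit(X, y)
        cos = w @ ref.coef_[0] / np.linalg.norm(w) / np.linalg.norm(ref.coef_[0])
        assert cos > 0.98

    def test_single_class_rejected(self):
        with pytest.raises(ValueError):
            lda_train(np.ones((4, 2)), np.zeros(4))


class TestAUC:
    def test_hand_counted_concordant_pairs(self):
        assert auc(np.array([0.1, 0.4, 0.35, 0.8]),
                   np.array([0, 0, 1, 1])) == pytest.approx(0.75)

    def test_perfect_and_tied_scores(self):
        y = np.array([0, 0, 1, 1])
        assert auc(np.array([1, 2, 3, 4]), y) == 1.0
        assert auc(np.zeros(4), y) == 0.5

    def test_single_class_rejected(self):
        with pytest.raises(ValueError):
            auc(np.ones(3), np.ones(3))


class TestSlidingDecode:
    def test_canonical_fold_and_timepoint_shape(self):
        ep = make_epochs(n_epochs=40, n_channels=4, n_times=220)
        curve = sliding_decode(ep, n_splits=5, n_repeats=20, seed=0)
        assert curve.scores.shape == (100, 220)
        assert (curve.scores >= 0).all() and (curve.scores <= 1).all()

    def test_separable_component_window(self):
        ep = make_epochs(n_epochs=60, n_channels=6, n_times=60, seed=1,
                         effect=6.0, effect_channel=2,
                         effect_window=(0.1, 0.25))
        curve = sliding_decode(ep, n_repeats=5, seed=0)
        dummy = dummy_scores(ep, n_repeats=5, seed=0)
        curve = finalize_curve(curve, dummy, n_boot=500, seed=1)
        times = ep.times
        win = (times >= 0.1) & (times < 0.25)
        assert curve.boot_mean[win].min() > 0.95
        assert abs(curve.boot_mean[~win].mean() - 0.5) < 0.05
        assert curve.sig_mask[win].all()

    def test_label_shuffle_is_at_chance(self):
        ep = make_epochs(n_epochs=80, n_channels=8, n_times=30, seed=2)
        curve = sliding_decode(ep, n_repeats=5, seed=3)
        assert abs(curve.scores.mean() - 0.5) < 0.02

    def test_deterministic_and_class_minimum_enforced(self):
        ep = make_epochs(n_epochs=30, n_channels=3, n_times=10, seed=4)
        a = sliding_decode(ep, n_repeats=2, seed=5)
        b = sliding_decode(ep, n_repeats=2, seed=5)
        assert np.array_equal(a.scores, b.scores)
        small = make_epochs(n_epochs=10, n_channels=3, n_times=10)
        with pytest.raises(ValueError):
            sliding_decode(small)


class TestBootstrap:
    def test_constant_input_degenerate_ci(self):
        m, lo, hi = bootstrap_ci(np.full(50, 0.7), n_boot=200, seed=0)
        assert (m, lo, hi) == pytest.approx((0.7, 0.7, 0.7))

    def test_ordering_invariant(self):
        rng = np.random.default_rng(1)
        m, lo, hi = bootstrap_ci(rng.uniform(size=100), n_boot=500, seed=2)
        assert lo <= m <= hi

    def test_half_width_matches_clt(self):
        rng = np.random.default_rng(3)
        v = rng.normal(0.6, 0.05, size=1600)
        _, lo, hi = bootstrap_ci(v, n_boot=4000, seed=4)
        half = (hi - lo) / 2
        assert half == pytest.approx(1.96 * 0.05 / 40, rel=0.2)

    def test_empty_rejected(self):
        with pytest.raises(ValueError):
            bootstrap_ci(np.array([]))


class TestDummy:
    def test_null_auc_regime_and_determinism(self):
        ep = make_epochs(n_epochs=100, n_channels=4, n_times=10)
        d1 = dummy_scores(ep, n_repeats=40, seed=0)
        d2 = dummy_scores(ep, n_repeats=40, seed=0)
        assert np.array_equal(d1, d2)
        m, lo, hi = bootstrap_ci(d1, n_boot=500, seed=1)
        assert 0.47 < m < 0.53

    def test_ci_shrinks_with_fold_count(self):
        ep = make_epochs(n_epochs=100, n_channels=4, n_times=10)
        few = bootstrap_ci(dummy_scores(ep, n_repeats=3, seed=0),
                           n_boot=500, seed=1)
        many = bootstrap_ci(dummy_scores(ep, n_repeats=30, seed=0),
                            n_boot=500, seed=1)
        assert (many[2] - many[1]) < (few[2] - few[1])


class TestSignificanceAndPeak:
    def test_mask_definition(self):
        ep = make_epochs(n_epochs=40, n_channels=4, n_times=20, seed=6)
        curve = finalize_curve(sliding_decode(ep, n_repeats=3, seed=0),
                               dummy_scores(ep, n_repeats=3, seed=0),
                               n_boot=300, seed=1)
        assert np.array_equal(curve.sig_mask,
                              curve.boot_lo > curve.dummy_hi)

    def test_peak_time_rules(self):
        from robot_erp.temporal_decoding import DecodingCurve

        times = np.array([0.0, 0.1, 0.2, 0.3])
        rising = DecodingCurve(scores=np.array([[0.5, 0.6, 0.7, 0.8]]),
                               times=times)
        assert peak_time(rising) == pytest.approx(0.3)
        flat = DecodingCurve(scores=np.full((1, 4), 0.5), times=times)
        assert peak_time(flat) == pytest.approx(0.0)  # earliest on ties

    def test_group_curve_pools_subject_folds(self):
        eps = [make_epochs(n_epochs=40, n_channels=4, n_times=10, seed=s)
               for s in range(3)]
        curves = [sliding_decode(e, n_repeats=2, seed=s)
                  for s, e in enumerate(eps)]
        dummies = [dummy_scores(e, n_repeats=2, seed=s)
                   for s, e in enumerate(eps)]
        g = group_curve(curves, dummies, n_boot=300, seed=0)
        assert g.scores.shape == (30, 10)
        assert g.boot_mean.shape == (10,)


class TestHaufePatterns:
    def test_single_latent_source_recovered(self):
        # generative model x = a s + noise: the inverted pattern must align
        # with the true topography a
        rng = np.random.default_rng(7)
        n, p = 300, 10
        a = rng.standard_normal(p)
        a /= np.linalg.norm(a)
        labels = np.array(["optimal", "suboptimal"] * (n // 2))
        s = (labels == "suboptimal") * 2.0 - 1.0 + 0.4 * rng.standard_normal(n)
        X = np.outer(s, a) + 0.7 * rng.standard_normal((n, p))
        from robot_erp.montage_io import EpochSet

        ep = EpochSet(data=np.repeat(X[:, :, None], 2, axis=2), srate=100.0,
                      tmin=0.0, labels=labels)
        curve = sliding_decode(ep, n_repeats=2, seed=0)
        pat = haufe_patterns(ep, curve.weights).patterns[:, 0]
        cos = abs(pat @ a) / np.linalg.norm(pat)
        assert cos > 0.95

    def test_whitened_features_pattern_proportional_to_weights(self):
        rng = np.random.default_rng(8)
        n, p = 5000, 6
        X = rng.standard_normal((n, p))  # identity covariance
        from robot_erp.montage_io import EpochSet

        labels = np.array(["optimal", "suboptimal"] * (n // 2))
        ep = EpochSet(data=X[:, :, None], srate=100.0, tmin=0.0,
                      labels=labels)
        w = rng.standard_normal((1, p))
        pat = haufe_patterns(ep, w).patterns[:, 0]
        cos = abs(pat @ w[0]) / np.linalg.norm(pat) / np.linalg.norm(w[0])
        assert cos > 0.99

    def test_scale_invariance_of_direction(self):
        ep = make_epochs(n_epochs=50, n_channels=5, n_times=3, seed=9)
        w = np.random.default_rng(10).standard_normal((3, 5))
        p1 = haufe_patterns(ep, w).patterns
        p2 = haufe_patterns(ep.copy_with(data=ep.data * 10), w).patterns
        for t in range(3):
            cos = p1[:, t] @ p2[:, t] / np.linalg.norm(p1[:, t]) \
                / np.linalg.norm(p2[:, t])
            assert cos > 0.9999


class TestMaskPatterns:
    def _patterns(self, C, T):
        from robot_erp.temporal_decoding import PatternMap

        return PatternMap(patterns=np.ones((C, T)),
                          times=np.arange(T) / 100.0)

    def test_zero_contrast_gives_empty_mask(self):
        cs = ContrastStack(data=np.zeros((10, 4, 6)), srate=100.0, tmin=0.0)
        pm = mask_patterns(self._patterns(4, 6), cs, n_boot=500, seed=0)
        assert not pm.mask.any()

    def test_pure_noise_contrast_flags_near_type_one_rate(self):
        rng = np.random.default_rng(11)
        cs = ContrastStack(data=rng.standard_normal((20, 4, 6)),
                           srate=100.0, tmin=0.0)
        pm = mask_patterns(self._patterns(4, 6), cs, n_boot=500, seed=0)
        assert pm.mask.mean() < 0.3  # only chance-level flags

    def test_strong_contrast_masked_true(self):
        rng = np.random.default_rng(12)
        data = rng.standard_normal((10, 4, 6)) * 0.1
        data[:, 2, 3] += 5.0
        cs = ContrastStack(data=data, srate=100.0, tmin=0.0)
        pm = mask_patterns(self._patterns(4, 6), cs, n_boot=500, seed=0)
        assert pm.mask[2, 3]

    def test_mask_monotone_in_effect_size(self):
        rng = np.random.default_rng(13)
        noise = rng.standard_normal((12, 4, 6))
        effect = np.zeros((4, 6))
        effect[1, 2:5] = 1.0
        masks = []
        for amp in (0.5, 1.0, 2.0):
            cs = ContrastStack(data=noise + amp * effect, srate=100.0,
                               tmin=0.0)
            pm = mask_patterns(self._patterns(4, 6), cs, n_boot=400, seed=1)
            masks.append(pm.mask[1, 2:5].sum())
        assert masks[0] <= masks[1] <= masks[2]
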