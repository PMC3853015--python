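import numpy as np
import pytest

from micsp import csp
from micsp.io_preprocess import Epochs, ValidationError


def random_covset(rng, n=6, n_classes=7, trials=12):
    """CovarianceSet built from random trials (well-conditioned SPD means)."""
    class_means, trial_covs = {}, {}
    for c in range(1, n_classes + 1):
        covs = np.stack([csp.trial_covariance(rng.standard_normal((n, 6 * n))) for _ in range(trials)])
        trial_covs[c] = covs
        class_means[c] = covs.mean(axis=0)
    return csp.CovarianceSet(class_means=class_means, trial_covs=trial_covs)


def diag_toy():
    """Two-class diagonal toy: S1 = diag(2,1), S_rest = diag(1,2)."""
    cm = {1: np.diag([2.0, 1.0]), 2: np.diag([1.0, 2.0])}
    tc = {1: cm[1][None], 2: cm[2][None]}
    return csp.CovarianceSet(class_means=cm, trial_covs=tc)


def row_normalized(W):
    return W / np.linalg.norm(W, axis=1, keepdims=True)


class TestTrialCovariance:
    def test_unit_trace(self, rng):
        C = csp.trial_covariance(rng.standard_normal((5, 100)))
        assert np.trace(C) == pytest.approx(1.0, abs=1e-12)
        np.testing.assert_allclose(C, C.T)

    def test_isotropic_limit(self, rng):
        C = csp.trial_covariance(rng.standard_normal((4, 200_000)))
        np.testing.assert_allclose(C, np.eye(4) / 4, atol=0.01)

    def test_rank_one_trial(self):
        X = np.zeros((3, 50))
        X[1] = np.sin(np.arange(50))
        C = csp.trial_covariance(X)
        assert C[1, 1] == pytest.approx(1.0)
        assert np.abs(C - np.diag([0, 1.0, 0])).max() < 1e-12

    def test_zero_trial_rejected(self):
        with pytest.raises(ValidationError, match="energy"):
            csp.trial_covariance(np.zeros((3, 50)))

    def test_short_trial_warns(self, rng):
        with pytest.warns(UserWarning, match="samples"):
            csp.trial_covariance(rng.standard_normal((10, 8)))


class TestClassCovariances:
    def _epochs(self, rng, n_per=3):
        data = rng.standard_normal((2 * n_per, 4, 64))
        labels = np.repeat([1, 2], n_per)
        return Epochs(data, labels, 128.0, ["a", "b", "c", "d"])

    def test_single_trial_class_mean_is_trial(self, rng):
        e = self._epochs(rng, n_per=1)
        cs = csp.class_covariances(e, shrinkage=0.0)
        np.testing.assert_allclose(cs.class_means[1], csp.trial_covariance(e.data[0]), atol=1e-12)

    def test_identical_trials_composite_scales(self, rng):
        x = rng.standard_normal((4, 64))
        data = np.tile(x[None], (7, 1, 1))
        e = Epochs(data, np.arange(1, 8), 128.0, ["a", "b", "c", "d"])
        cs = csp.class_covariances(e, shrinkage=0.0)
        np.testing.assert_allclose(cs.composite, 7 * cs.class_means[1], atol=1e-12)

    def test_composite_pd_after_shrinkage(self, rng):
        e = self._epochs(rng)
        # CAR-like degenerate data: remove channel mean
        e = Epochs(e.data - e.data.mean(axis=1, keepdims=True), e.labels, e.fs, e.channels)
        cs = csp.class_covariances(e, shrinkage=1e-6)
        assert np.linalg.eigvalsh(cs.composite).min() > 0

    def test_missing_expected_class_rejected(self, rng):
        e = self._epochs(rng)
        with pytest.raises(ValidationError, match="without trials"):
            csp.class_covariances(e, expected_classes=[1, 2, 3])


class TestWhitening:
    def test_identity(self):
        cm = {1: 0.5 * np.eye(3), 2: 0.5 * np.eye(3)}
        cs = csp.CovarianceSet(class_means=cm, trial_covs={1: cm[1][None], 2: cm[2][None]})
        wr = csp.whitening(cs)
        np.testing.assert_allclose(wr.P, np.eye(3), atol=1e-12)

    def test_diagonal_closed_form(self):
        cm = {1: np.diag([2.0, 0.5]), 2: np.diag([2.0, 0.5])}
        cs = csp.CovarianceSet(class_means=cm, trial_covs={1: cm[1][None], 2: cm[2][None]})
        wr = csp.whitening(cs)  # composite = diag(4, 1)
        np.testing.assert_allclose(np.abs(wr.P), np.diag([0.5, 1.0]), atol=1e-12)

    def test_random_spd_whitens(self, rng):
        cs = random_covset(rng)
        wr = csp.whitening(cs)
        err = np.abs(wr.P @ cs.composite @ wr.P.T - np.eye(cs.n_channels)).max()
        assert err < 1e-8

    def test_rank_deficient_advises_shrinkage(self):
        cm = {1: np.diag([1.0, 0.0]), 2: np.diag([1.0, 0.0])}
        cs = csp.CovarianceSet(class_means=cm, trial_covs={1: cm[1][None], 2: cm[2][None]})
        with pytest.raises(ValidationError, match="shrinkage"):
            csp.whitening(cs)


class TestMultiCSP:
    def test_diagonal_toy(self):
        fb = csp.multi_csp(diag_toy())
        np.testing.assert_allclose(fb.eigvals[1], [2 / 3, 1 / 3], atol=1e-12)
        w_top = fb.filters[1][0] / np.linalg.norm(fb.filters[1][0])
        np.testing.assert_allclose(np.abs(w_top), [1.0, 0.0], atol=1e-10)

    def test_indistinguishable_classes(self, rng):
        base = csp.trial_covariance(rng.standard_normal((4, 200)))
        cm = {c: base.copy() for c in range(1, 8)}
        tc = {c: base[None] for c in range(1, 8)}
        fb = csp.multi_csp(csp.CovarianceSet(class_means=cm, trial_covs=tc))
        for c in range(1, 8):
            np.testing.assert_allclose(fb.eigvals[c], 1 / 7, atol=1e-10)

    def test_joint_diagonalization(self, rng):
        cs = random_covset(rng)
        fb = csp.multi_csp(cs)
        for c in cs.classes:
            W = fb.filters[c]
            np.testing.assert_allclose(W @ cs.composite @ W.T, np.eye(cs.n_channels), atol=1e-8)
            D = W @ cs.class_means[c] @ W.T
            assert np.abs(D - np.diag(np.diag(D))).max() < 1e-8
            np.testing.assert_allclose(np.diag(D), fb.eigvals[c], atol=1e-8)

    def test_complementarity(self, rng):
        cs = random_covset(rng)
        fb = csp.multi_csp(cs)
        wr = csp.whitening(cs)
        for c in cs.classes:
            rest = cs.composite - cs.class_means[c]
            lam_rest = np.diag(fb.filters[c] @ rest @ fb.filters[c].T)
            np.testing.assert_allclose(fb.eigvals[c] + lam_rest, 1.0, atol=1e-8)


class TestGECSP:
    def test_diagonal_toy(self):
        fb = csp.gecsp(diag_toy())
        np.testing.assert_allclose(fb.eigvals[1], [2 / 3, 1 / 3], atol=1e-12)
        w_top = fb.filters[1][0] / np.linalg.norm(fb.filters[1][0])
        np.testing.assert_allclose(np.abs(w_top), [1.0, 0.0], atol=1e-10)

    @pytest.mark.parametrize("seed", range(5))
    def test_equivalence_with_multi_csp(self, seed):
        rng = np.random.default_rng(seed)
        cs = random_covset(rng, n=rng.integers(3, 9))
        fm, fg = csp.multi_csp(cs), csp.gecsp(cs)
        for c in cs.classes:
            np.testing.assert_allclose(fm.eigvals[c], fg.eigvals[c], atol=1e-6)
            np.testing.assert_allclose(
                row_normalized(fm.filters[c]), row_normalized(fg.filters[c]), atol=1e-6
            )

    def test_trace_identity(self, rng):
        cs = random_covset(rng)
        fb = csp.gecsp(cs)
        wr = csp.whitening(cs)
        for c in cs.classes:
            Y = wr.P @ cs.class_means[c] @ wr.P.T
            assert fb.eigvals[c].sum() == pytest.approx(np.trace(Y), abs=1e-8)
            assert np.all(fb.eigvals[c] >= -1e-10) and np.all(fb.eigvals[c] <= 1 + 1e-10)


class TestStationarityPenalty:
    def test_stationary_class_zero_penalty(self, rng):
        base = csp.trial_covariance(rng.standard_normal((3, 100)))
        cs = csp.CovarianceSet(
            class_means={1: base, 2: base}, trial_covs={1: np.tile(base, (4, 1, 1)), 2: base[None]}
        )
        np.testing.assert_allclose(csp.stationarity_penalty(cs, 1), 0.0, atol=1e-12)

    def test_sign_flip_toy(self):
        base = np.eye(2)
        delta = np.diag([1.0, -1.0])
        cs = csp.CovarianceSet(
            class_means={1: base, 2: base},
            trial_covs={1: np.stack([base + delta, base - delta]), 2: base[None]},
        )
        np.testing.assert_allclose(csp.stationarity_penalty(cs, 1), 2 * np.eye(2), atol=1e-12)

    def test_random_penalty_psd(self, rng):
        cs = random_covset(rng)
        for c in cs.classes:
            pen = csp.stationarity_penalty(cs, c)
            assert np.linalg.eigvalsh(pen).min() >= -1e-10
            np.testing.assert_allclose(pen, pen.T)

    def test_single_trial_warns_zero(self, rng):
        base = csp.trial_covariance(rng.standard_normal((3, 100)))
        cs = csp.CovarianceSet(class_means={1: base, 2: base}, trial_covs={1: base[None], 2: base[None]})
        with pytest.warns(UserWarning, match="single trial"):
            pen = csp.stationarity_penalty(cs, 1)
        np.testing.assert_allclose(pen, 0.0)

    def test_upper_bounds_variance_deviation(self, rng):
        cs = random_covset(rng, n=4)
        pen = csp.stationarity_penalty(cs, 1)
        mean = cs.trial_covs[1].mean(axis=0)
        for _ in range(20):
            w = rng.standard_normal(4)
            lhs = sum(abs(w @ (Sk - mean) @ w) for Sk in cs.trial_covs[1])
            assert w @ pen @ w >= lhs - 1e-10


class TestSTRCSP:
    def test_zero_regularization_equals_gecsp(self, rng):
        cs = random_covset(rng)
        fg, fs = csp.gecsp(cs), csp.strcsp(cs, 0.0, 0.0)
        for c in cs.classes:
            np.testing.assert_allclose(fs.eigvals[c], fg.eigvals[c], atol=1e-10)
            np.testing.assert_allclose(fs.filters[c], fg.filters[c], atol=1e-10)

    def test_diagonal_toy_with_identity_penalty(self):
        cs = diag_toy()
        fb = csp.strcsp(cs, alpha=1.0, beta=0.0, penalties={1: np.eye(2), 2: np.eye(2)})
        np.testing.assert_allclose(fb.eigvals[1], [0.5, 0.25], atol=1e-12)

    def test_large_beta_limit(self, rng):
        cs = random_covset(rng)
        fb = csp.strcsp(cs, alpha=0.0, beta=1e6)
        for c in cs.classes:
            top = fb.filters[c][0] / np.linalg.norm(fb.filters[c][0])
            vals, vecs = np.linalg.eigh(cs.class_means[c])
            principal = vecs[:, -1]
            assert abs(top @ principal) > 0.999

    def test_monotone_filter_norm_in_beta(self, rng):
        cs = random_covset(rng)
        norms = []
        for beta in [0.0, 0.1, 1.0, 10.0]:
            fb = csp.strcsp(cs, 0.0, beta)
            norms.append(np.linalg.norm(fb.filters[1][0]))
        assert all(a >= b - 1e-12 for a, b in zip(norms, norms[1:]))

    def test_negative_weights_rejected(self, rng):
        cs = random_covset(rng)
        with pytest.raises(ValidationError, match="non-negative"):
            csp.strcsp(cs, -0.1, 0.0)


class TestSpatialPatterns:
    def test_orthonormal_filters_identity_composite(self):
        cm = {1: 0.5 * np.eye(3), 2: 0.5 * np.eye(3)}
        cs = csp.CovarianceSet(class_means=cm, trial_covs={1: cm[1][None], 2: cm[2][None]})
        fb = csp.multi_csp(cs)
        pats = csp.spatial_patterns(fb)
        for c in (1, 2):
            np.testing.assert_allclose(pats[c], fb.filters[c].T, atol=1e-10)

    def test_reconstruction_identity(self, rng):
        cs = random_covset(rng)
        fb = csp.multi_csp(cs)
        pats = csp.spatial_patterns(fb)
        for c in cs.classes:
            np.testing.assert_allclose(fb.filters[c] @ pats[c], np.eye(cs.n_channels), atol=1e-8)

    def test_planted_source_recovered(self, small_synth_csp):
        epochs, gt = small_synth_csp
        cs = csp.class_covariances(epochs)
        fb = csp.multi_csp(cs)
        pats = csp.spatial_patterns(fb)
        # class 2 (right hand) attenuates C3-mu: ERD -> smallest eigenvalue
        col = gt.mixing_column("C3-mu")
        pat = pats[2][:, -1]
        r = np.corrcoef(pat, col)[0, 1]
        assert abs(r) >= 0.95


class TestScaleInvariance:
    def test_filters_invariant_to_global_scaling(self, rng):
        data = rng.standard_normal((8, 4, 64))
        labels = np.repeat([1, 2], 4)
        e1 = Epochs(data, labels, 128.0, list("abcd"))
        e2 = Epochs(500.0 * data, labels, 128.0, list("abcd"))
        f1 = csp.multi_csp(csp.class_covariances(e1))
        f2 = csp.multi_csp(csp.class_covariances(e2))
        for c in (1, 2):
            np.testing.assert_allclose(f1.filters[c], f2.filters[c], atol=1e-8)
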