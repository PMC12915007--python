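"""Multiclass CSP + LDA decoding, Haufe patterns, ROI contrasts."""

import numpy as np
import pytest

from drivemeg.decoding import (CSPModel, PatternMap, _ortho_ajd,
                               crossval_decode, csp_features,
                               fit_multiclass_csp, haufe_patterns,
                               lda_fit, lda_predict, ledoit_wolf_cov,
                               localize_patterns, percentile_roi_contrast,
                               weighted_grand_average)
from drivemeg.source import minimum_norm_operator


def latent_class_data(rng, n_per_class=60, n_ch=12, n_samp=150, snr=3.0,
                      n_classes=4):
    """Epochs where latent source k is amplified in class k."""
    mixing = rng.standard_normal((n_ch, n_classes))
    X, y = [], []
    for c in range(n_classes):
        for _ in range(n_per_class):
            sources = rng.standard_normal((n_classes, n_samp))
            sources[c] *= snr
            X.append(mixing @ sources + 0.5 * rng.standard_normal((n_ch,
                                                                   n_samp)))
            y.append(c)
    return np.stack(X), np.array(y), mixing


class TestLedoitWolf:
    def test_consistency_at_large_n(self, rng):
        true = np.diag([3.0, 1.0, 0.5])
        data = np.diag(np.sqrt(np.diag(true))) @ \
            rng.standard_normal((3, 50000))
        est = ledoit_wolf_cov(data)
        assert np.abs(est - true).max() < 0.1

    def test_small_n_shrinkage_restores_full_rank(self, rng):
        # 10 samples in 20 dimensions: the sample covariance is singular,
        # the shrunk estimate must be positive definite
        data = rng.standard_normal((20, 10))   # 20 channels, 10 samples
        est = ledoit_wolf_cov(data)
        assert np.linalg.eigvalsh(est).min() > 0
        assert np.linalg.matrix_rank(np.cov(data)) < 20

    def test_spherical_stays_spherical(self, rng):
        data = rng.standard_normal((4, 20000))
        est = ledoit_wolf_cov(data)
        assert np.abs(est - np.eye(4)).max() < 0.05


class TestAJD:
    def test_recovers_common_diagonalizer(self, rng):
        q, _ = np.linalg.qr(rng.standard_normal((6, 6)))
        mats = np.stack([q @ np.diag(rng.uniform(0.5, 3.0, 6)) @ q.T
                         for _ in range(4)])
        V = _ortho_ajd(mats)
        for A in mats:
            D = V.T @ A @ V
            off = D - np.diag(np.diag(D))
            assert np.abs(off).max() < 1e-6

    def test_returns_orthogonal(self, rng):
        mats = np.stack([np.cov(rng.standard_normal((5, 100)))
                         for _ in range(3)])
        V = _ortho_ajd(mats)
        assert np.allclose(V.T @ V, np.eye(5), atol=1e-10)


class TestMulticlassCSP:
    def test_recovers_modulated_sources(self, rng):
        X, y, mixing = latent_class_data(rng, snr=4.0)
        model = fit_multiclass_csp(X, y, n_components=4)
        # each latent source's time course should be recovered by some filter
        sources = np.linalg.pinv(mixing) @ X[0]
        recovered = model.filters @ X[0]
        for k in range(4):
            cors = [abs(np.corrcoef(sources[k], r)[0, 1])
                    for r in recovered]
            assert max(cors) > 0.9

    def test_null_data_low_scores(self, rng):
        X = rng.standard_normal((120, 8, 100))
        y = np.repeat(np.arange(4), 30)
        model = fit_multiclass_csp(X, y)
        assert model.scores.max() < 0.05

    def test_label_permutation_preserves_filter_set(self, rng):
        X, y, _ = latent_class_data(rng, n_per_class=40)
        m1 = fit_multiclass_csp(X, y)
        perm = {0: 2, 1: 3, 2: 0, 3: 1}
        m2 = fit_multiclass_csp(X, np.array([perm[c] for c in y]))
        # same filters up to order and sign
        M = np.abs(np.corrcoef(m1.filters, m2.filters)[:4, 4:])
        assert (M.max(axis=1) > 0.99).all()

    def test_insufficient_epochs_rejected(self, rng):
        X = rng.standard_normal((10, 8, 50))
        y = np.repeat(np.arange(4), [3, 3, 2, 2])
        with pytest.raises(ValueError, match="epochs"):
            fit_multiclass_csp(X, y)


class TestCspFeatures:
    def test_amplitude_scaling_law(self, rng):
        X, y, _ = latent_class_data(rng, n_per_class=20)
        model = fit_multiclass_csp(X, y)
        f1 = csp_features(X[:1], model)
        f2 = csp_features(2.0 * X[:1], model)
        assert np.allclose(f2 - f1, np.log(4.0), atol=1e-10)

    def test_constant_epoch_rejected(self, rng):
        X, y, _ = latent_class_data(rng, n_per_class=20)
        model = fit_multiclass_csp(X, y)
        with pytest.raises(ValueError, match="variance"):
            csp_features(np.zeros((1, X.shape[1], 50)), model)


class TestLDA:
    def test_separable_classes(self, rng):
        X = np.concatenate([rng.standard_normal((100, 3)) + m
                            for m in ([0, 0, 0], [5, 0, 0])])
        y = np.repeat([0, 1], 100)
        lda = lda_fit(X, y)
        assert (lda_predict(lda, X) == y).mean() > 0.95

    def test_null_near_chance(self, rng):
        X = rng.standard_normal((400, 3))
        y = np.repeat(np.arange(4), 100)
        lda = lda_fit(X, y)
        acc = (lda_predict(lda, X) == y).mean()
        assert acc < 0.40

    def test_matches_fisher_direction(self, rng):
        cov = np.array([[2.0, 0.5], [0.5, 1.0]])
        chol = np.linalg.cholesky(cov)
        mu = np.array([1.0, 0.5])
        X = np.concatenate([
            (chol @ rng.standard_normal((2, 4000))).T,
            (chol @ rng.standard_normal((2, 4000))).T + mu])
        y = np.repeat([0, 1], 4000)
        lda = lda_fit(X, y)
        w = lda.coef_.ravel()
        fisher = np.linalg.solve(cov, mu)
        angle = np.degrees(np.arccos(
            abs(w @ fisher) / np.linalg.norm(w) / np.linalg.norm(fisher)))
        assert angle < 5.0

    def test_single_class_rejected(self):
        with pytest.raises(ValueError):
            lda_fit(np.zeros((5, 2)), np.zeros(5))


class TestCrossvalDecode:
    def test_thirty_partitions(self, rng):
        X, y, _ = latent_class_data(rng, n_per_class=20, n_ch=6, n_samp=80)
        res = crossval_decode(X, y, k=10, repeats=3, seed=0, n_boot=100)
        assert res.fold_f1.size == 30

    def test_confusion_row_sums_match_counts(self, rng):
        X, y, _ = latent_class_data(rng, n_per_class=20, n_ch=6, n_samp=80)
        res = crossval_decode(X, y, k=10, repeats=3, seed=0, n_boot=100)
        assert res.confusion.sum() == 3 * len(y)
        assert (res.confusion.sum(axis=1) == 60).all()

    def test_separable_data_high_f1(self, rng):
        X, y, _ = latent_class_data(rng, n_per_class=30, snr=5.0)
        res = crossval_decode(X, y, k=10, repeats=1, seed=1, n_boot=100)
        assert res.mean_f1 > 0.9

    def test_shuffled_labels_near_chance(self, rng):
        X = rng.standard_normal((160, 8, 100))
        y = np.repeat(np.arange(4), 40)
        res = crossval_decode(X, y, k=8, repeats=2, seed=2, n_boot=100)
        assert 0.15 <= res.mean_f1 <= 0.35

    def test_bit_identical_rerun(self, rng):
        X, y, _ = latent_class_data(rng, n_per_class=15, n_ch=6, n_samp=60)
        r1 = crossval_decode(X, y, k=5, repeats=1, seed=3, n_boot=100)
        r2 = crossval_decode(X, y, k=5, repeats=1, seed=3, n_boot=100)
        assert np.array_equal(r1.fold_f1, r2.fold_f1)
        assert np.array_equal(r1.patterns, r2.patterns)

    def test_small_class_rejected(self, rng):
        X = rng.standard_normal((12, 4, 50))
        y = np.repeat(np.arange(4), 3)
        with pytest.raises(ValueError, match="smaller k"):
            crossval_decode(X, y, k=10)

    def test_comparable_to_mne_csp_binary(self, rng):
        """Independent cross-check against the reference CSP implementation
        on a two-class problem, where CSP reduces to the canonical
        generalized-eigenvalue form."""
        import mne
        from mne.decoding import CSP as MneCSP
        from sklearn.discriminant_analysis import LinearDiscriminantAnalysis
        from sklearn.model_selection import StratifiedKFold
        mne.set_log_level("error")
        X, y, _ = latent_class_data(rng, n_per_class=40, snr=3.0,
                                    n_classes=2)
        ours = crossval_decode(X, y, k=5, repeats=1, n_components=2,
                               seed=4, n_boot=100)
        accs = []
        for train, test in StratifiedKFold(5, shuffle=True,
                                           random_state=4).split(X, y):
            csp = MneCSP(n_components=2, log=True)
            f_tr = csp.fit_transform(X[train], y[train])
            f_te = csp.transform(X[test])
            lda = LinearDiscriminantAnalysis(solver="lsqr", shrinkage="auto")
            lda.fit(f_tr, y[train])
            accs.append((lda.predict(f_te) == y[test]).mean())
        assert abs(ours.mean_f1 - np.mean(accs)) < 0.1


class TestHaufePatterns:
    def test_orthonormal_filters_identity_cov(self):
        rng = np.random.default_rng(0)
        q, _ = np.linalg.qr(rng.standard_normal((6, 6)))
        model = CSPModel(filters=q[:, :3].T, scores=np.zeros(3),
                         class_covs=np.zeros((2, 6, 6)),
                         classes=np.array([0, 1]), n_components=3)
        A = haufe_patterns(model, np.eye(6))
        assert np.allclose(A, q[:, :3], atol=1e-10)

    def test_single_source_pattern_matches_mixing(self, rng):
        a = rng.standard_normal(10)
        sig = rng.standard_normal(20000)
        data = np.outer(a, sig) + 0.1 * rng.standard_normal((10, 20000))
        Sigma = np.cov(data)
        # any filter extracting the source must map back to pattern ~ a
        w = np.linalg.solve(Sigma, a)
        model = CSPModel(filters=w[None, :], scores=np.zeros(1),
                         class_covs=np.zeros((2, 10, 10)),
                         classes=np.array([0, 1]), n_components=1)
        A = haufe_patterns(model, Sigma)
        corr = np.corrcoef(A[:, 0], a)[0, 1]
        assert abs(corr) > 0.99

    def test_invariant_to_filter_rescaling(self, rng):
        Sigma = np.cov(rng.standard_normal((5, 1000)))
        W = rng.standard_normal((2, 5))
        m1 = CSPModel(W, np.zeros(2), np.zeros((2, 5, 5)),
                      np.array([0, 1]), 2)
        m2 = CSPModel(np.diag([2.0, 0.5]) @ W, np.zeros(2),
                      np.zeros((2, 5, 5)), np.array([0, 1]), 2)
        A1 = haufe_patterns(m1, Sigma)
        A2 = haufe_patterns(m2, Sigma)
        for k in range(2):
            ratio = A2[:, k] / A1[:, k]
            assert np.allclose(ratio, ratio[0])


class TestLocalizePatterns:
    def test_leadfield_column_peaks_at_vertex(self, model32):
        inv = minimum_norm_operator(model32.lead_field.gain,
                                    model32.noise_cov, snr=3.0)
        v = 77
        pmap = localize_patterns(model32.lead_field.gain[:, [v]], inv)
        peak = int(np.argmax(pmap.values[0]))
        assert peak in set(model32.grid.adjacency[v].indices) | {v}

    def test_zero_pattern_zero_map(self, model32):
        inv = minimum_norm_operator(model32.lead_field.gain,
                                    model32.noise_cov, snr=3.0)
        pmap = localize_patterns(np.zeros((32, 2)), inv)
        assert np.allclose(pmap.values, 0.0)


class TestWeightedGrandAverage:
    def test_equal_weights_plain_average(self):
        maps = [PatternMap(values=np.array([[0.0, 1.0, 4.0]])),
                PatternMap(values=np.array([[2.0, 1.0, 0.0]]))]
        avg = weighted_grand_average(maps, [0.5, 0.5])
        plain = np.array([[1.0, 1.0, 2.0]])          # unweighted mean
        rescaled = (plain - plain.min()) / np.ptp(plain)
        assert np.allclose(avg.values, rescaled)

    def test_constant_average_rejected(self):
        maps = [PatternMap(values=np.array([[1.0, 1.0]]))] * 2
        with pytest.raises(ValueError, match="constant"):
            weighted_grand_average(maps, [0.5, 0.5])

    def test_degenerate_weights_single_subject(self):
        maps = [PatternMap(values=np.array([[0.0, 2.0, 4.0]])),
                PatternMap(values=np.array([[5.0, 5.0, 5.0]]))]
        avg = weighted_grand_average(maps, [1.0, 0.0])
        assert np.allclose(avg.values, [[0.0, 0.5, 1.0]])

    def test_weights_normalized(self):
        maps = [PatternMap(values=np.array([[0.0, 1.0]])),
                PatternMap(values=np.array([[1.0, 0.0]]))]
        avg = weighted_grand_average(maps, [0.8, 0.4])
        assert avg.f1_weights.sum() == pytest.approx(1.0)


class TestPercentileROI:
    def _cohort(self, rng, reversal=True):
        """Synthetic pattern map + per-condition power with a cross-over."""
        n_subj, n_vert = 10, 50
        patch = np.arange(5)
        pattern = np.zeros((1, n_vert))
        pattern[0, patch] = 1.0
        noise = lambda: 0.05 * rng.standard_normal((n_subj, n_vert))
        base = np.ones((n_subj, n_vert))
        eff = np.zeros((n_subj, n_vert))
        eff[:, patch] = 0.3
        power = {
            "LW/LV": base + eff + noise(), "LW/HV": base - eff + noise(),
            "HW/LV": base - eff + noise(), "HW/HV": base + eff + noise(),
        }
        return PatternMap(values=pattern), power

    def test_q_zero_is_global_mean(self, rng):
        pmap, power = self._cohort(rng)
        out = percentile_roi_contrast(pmap, power, q=0)
        assert np.allclose(out["roi_means"]["LW/LV"],
                           power["LW/LV"].mean(axis=1))

    def test_crossover_sign_reversal_recovered(self, rng):
        pmap, power = self._cohort(rng)
        out = percentile_roi_contrast(pmap, power, q=90, seed=0)
        diffs = {(c["a"], c["b"]): c["mean_diff"] for c in out["contrasts"]}
        lw = diffs.get(("LW/LV", "LW/HV"), -diffs.get(("LW/HV", "LW/LV"), 0))
        hw = diffs.get(("HW/LV", "HW/HV"), -diffs.get(("HW/HV", "HW/LV"), 0))
        assert lw > 0 > hw

    def test_uniform_pattern_rejected(self, rng):
        _, power = self._cohort(rng)
        with pytest.raises(ValueError, match="uniform"):
            percentile_roi_contrast(PatternMap(values=np.ones((1, 50))),
                                    power, q=90)
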