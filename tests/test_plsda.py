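import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

import sers_chemo as sc
from sers_chemo.plsda import band_jaccard, extract_vip_bands_from_scores


def _random_fit(seed, n=20, p=8, A=2):
    rng = np.random.default_rng(seed)
    X = rng.normal(size=(n, p))
    y = np.zeros(n)
    y[: n // 2] = 1.0
    return sc.fit_plsda(X, y, A), X, y


class TestFit:
    def test_weight_concentrates_on_informative_column(self):
        """One column equals 2*y_c; noise columns orthogonal to y_c."""
        rng = np.random.default_rng(3)
        n, p = 40, 6
        y = np.r_[np.ones(20), np.zeros(20)]
        yc = y - y.mean()
        noise = rng.normal(size=(n, p - 1))
        # orthogonalize noise columns against y_c
        noise -= np.outer(yc, yc @ noise) / (yc @ yc)
        X = np.column_stack([2.0 * yc, noise])
        res = sc.fit_plsda(X, y, 1)
        assert res.weights[0, 0] ** 2 > 0.9

    def test_full_rank_fit_equals_least_squares_projection(self):
        rng = np.random.default_rng(4)
        X = rng.normal(size=(6, 3))
        y = np.array([1.0, 1, 1, 0, 0, 0])
        res = sc.fit_plsda(X, y, 3)
        Xc = X - X.mean(axis=0)
        beta, *_ = np.linalg.lstsq(Xc, y - y.mean(), rcond=None)
        assert np.abs(res.fittedvalues - (Xc @ beta + y.mean())).max() < 1e-8

    def test_score_orthogonality_on_random_matrix(self):
        rng = np.random.default_rng(5)
        X = rng.normal(size=(20, 50))
        y = np.r_[np.ones(10), np.zeros(10)]
        res = sc.fit_plsda(X, y, 5)
        G = res.scores.T @ res.scores
        off = G - np.diag(np.diag(G))
        assert np.abs(off).max() < 1e-8

    def test_weights_unit_norm(self):
        res, _, _ = _random_fit(6, A=4)
        assert np.abs(np.linalg.norm(res.weights, axis=0) - 1.0).max() < 1e-10

    def test_residual_covariance_exhausted(self):
        """After deflation, residual X scores carry no covariance with residual y."""
        rng = np.random.default_rng(7)
        X = rng.normal(size=(15, 10))
        y = np.r_[np.ones(8), np.zeros(7)]
        A = 4
        Xd = X - X.mean(axis=0)
        yd = y - y.mean()
        for _ in range(A):
            w = Xd.T @ yd
            w /= np.linalg.norm(w)
            t = Xd @ w
            tt = t @ t
            pl = Xd.T @ t / tt
            q = yd @ t / tt
            Xd = Xd - np.outer(t, pl)
            yd = yd - q * t
            assert abs((Xd @ w) @ yd) < 1e-8

    def test_matches_reference_pls_on_small_instances(self):
        sklearn = pytest.importorskip("sklearn.cross_decomposition")
        rng = np.random.default_rng(8)
        for trial in range(5):
            n, p = rng.integers(6, 13), rng.integers(3, 13)
            X = rng.normal(size=(n, p))
            y = (rng.random(n) > 0.5).astype(float)
            y[0], y[1] = 1.0, 0.0
            A = int(min(3, n - 1, p))
            res = sc.fit_plsda(X, y, A)
            ref = sklearn.PLSRegression(n_components=A, scale=False).fit(X, y)
            assert np.abs(res.fittedvalues - ref.predict(X).ravel()).max() < 1e-6

    def test_single_class_rejected(self):
        X = np.random.default_rng(9).normal(size=(8, 4))
        with pytest.raises(ValueError, match="single class"):
            sc.fit_plsda(X, np.ones(8), 1)

    def test_components_beyond_rank_named(self):
        rng = np.random.default_rng(10)
        base = rng.normal(size=(8, 1))
        X = base @ rng.normal(size=(1, 6))  # rank 1
        y = np.r_[np.ones(4), np.zeros(4)]
        with pytest.raises(ValueError, match="rank"):
            sc.fit_plsda(X, y, 3)


class TestPredict:
    def test_training_rows_reproduce_fitted_values(self):
        res, X, _ = _random_fit(11)
        scores, labels = sc.predict_plsda(res, X)
        assert np.allclose(scores, res.fittedvalues)
        assert set(labels) <= {0, 1}

    def test_rows_at_training_mean_score_mean_y(self):
        res, X, y = _random_fit(12)
        scores = res.predict(np.tile(X.mean(axis=0), (3, 1)))
        assert np.allclose(scores, y.mean())

    def test_monotone_along_first_weight_direction(self):
        res, X, _ = _random_fit(13)
        direction = res.weights[:, 0] * np.sign(res.y_loadings[0])
        base = res.predict(X[0])
        bumped = res.predict(X[0] + 0.5 * direction)
        assert bumped > base

    def test_column_mismatch_rejected(self):
        res, X, _ = _random_fit(14)
        with pytest.raises(ValueError, match="columns"):
            res.predict(X[:, :-1])


class TestVip:
    def test_uniform_weights_give_unit_vip(self):
        # A=1 with all |w_1j| equal => VIP_j = 1 for every j
        p = 16
        X = np.tile(np.r_[np.ones(5), -np.ones(5)][:, None], (1, p))
        y = np.r_[np.ones(5), np.zeros(5)]
        res = sc.fit_plsda(X, y, 1)
        vip = res.vip()
        assert np.abs(vip.scores - 1.0).max() < 1e-8

    @pytest.mark.parametrize("seed", [0, 1, 2])
    def test_mean_square_identity(self, seed):
        res, _, _ = _random_fit(seed, A=3)
        vip = res.vip()
        assert np.mean(vip.scores**2) == pytest.approx(1.0, abs=1e-8)

    def test_matches_scalar_loop_oracle(self):
        res, _, _ = _random_fit(21, n=20, p=8, A=2)
        W, T, q = res.weights, res.scores, res.y_loadings
        p, A = W.shape
        ss = [q[a] ** 2 * float(T[:, a] @ T[:, a]) for a in range(A)]
        expected = np.empty(p)
        for j in range(p):
            num = sum(ss[a] * (W[j, a] / np.linalg.norm(W[:, a])) ** 2 for a in range(A))
            expected[j] = np.sqrt(p * num / sum(ss))
        assert np.abs(res.vip().scores - expected).max() < 1e-10


class TestBands:
    def test_all_below_threshold_gives_no_bands(self):
        grid = np.arange(900.0, 1000.0)
        assert extract_vip_bands_from_scores(grid, np.full(100, 0.5)) == []

    def test_single_run_reported_as_closed_interval(self):
        grid = np.arange(990.0, 1021.0)
        scores = np.where((grid >= 1000) & (grid <= 1010), 1.5, 0.2)
        assert extract_vip_bands_from_scores(grid, scores) == [(1000.0, 1010.0)]

    def test_min_width_drops_narrow_runs(self):
        grid = np.arange(0.0, 30.0)
        scores = np.zeros(30)
        scores[5] = 2.0          # single point, width 1
        scores[10:15] = 2.0      # width 5
        bands = extract_vip_bands_from_scores(grid, scores, min_width=3.0)
        assert bands == [(10.0, 14.0)]

    def test_injected_bands_recovered_with_good_overlap(self):
        """Case-1 scenario: VIP>1 intervals localize the injected effects."""
        cfg = sc.SimConfig(n_subjects_per_class=10, spectra_per_subject=20, seed=7)
        ds, truth = sc.generate_dataset(cfg)
        pp = sc.preprocess_pipeline(ds)
        res = sc.PLSDA.from_dataset(pp, ["lung_cancer"]).fit(2)
        recovered = res.vip().bands
        injected = [(b.start_cm1, b.end_cm1) for b in truth]
        assert band_jaccard(recovered, injected, edge_tol=5.0) >= 0.5


def test_mean_normalization_closure_makes_neutral_bands_discriminative():
    """Row-mean normalization closes the data: an intensity effect at one
    band depresses every other signal-bearing channel of the affected
    class, so even a class-neutral band becomes (anti-)discriminative.
    This is a documented property of closed spectral data, and the reason
    the default scenarios place effects on every simulated band."""
    peaks = [sc.PeakSpec(1002.0, 12.0, 400.0, {"lung_cancer": 1.6}),
             sc.PeakSpec(1432.0, 12.0, 400.0)]  # neutral band
    cfg = sc.SimConfig(n_subjects_per_class=2, spectra_per_subject=2, peaks=peaks,
                       noise_sd=0.0, spike_rate=0.0, subject_sd=0.0,
                       baseline_amplitude=0.0, seed=0)
    ds, _ = sc.generate_dataset(cfg)
    pp = sc.normalize_mean(sc.crop(ds))
    out = sc.group_mean_difference(pp, "lung_cancer", "control")
    at = lambda w: out.loc[(out["wavenumber_cm1"] - w).abs().idxmin(), "difference"]
    assert at(1002.0) > 0          # injected effect survives normalization
    assert at(1432.0) < 0          # neutral band picks up the closure echo
    assert abs(at(1432.0)) > 1e-6  # and it is not numerically negligible


class TestBandJaccard:
    def test_identical_sets(self):
        assert band_jaccard([(1.0, 5.0)], [(1.0, 5.0)]) == pytest.approx(1.0)

    def test_disjoint_sets(self):
        assert band_jaccard([(0.0, 1.0)], [(10.0, 11.0)]) == 0.0

    def test_edge_tolerance_bridges_small_offsets(self):
        a, b = [(100.0, 110.0)], [(103.0, 113.0)]
        assert band_jaccard(a, b, edge_tol=5.0) > band_jaccard(a, b, edge_tol=0.0)


class TestGroupMeanDifference:
    def test_identical_classes_give_zero_difference(self, clean_dataset):
        ds, _, _ = clean_dataset
        same = ds.copy()
        same.X = np.tile(ds.X[0], (ds.n_spectra, 1))
        out = sc.group_mean_difference(same, "lung_cancer", "control")
        assert np.abs(out["difference"]).max() == 0.0

    def test_antisymmetry(self, clean_dataset):
        ds, _, _ = clean_dataset
        ab = sc.group_mean_difference(ds, "lung_cancer", "control")
        ba = sc.group_mean_difference(ds, "control", "lung_cancer")
        assert np.allclose(ab["difference"], -ba["difference"])

    def test_difference_peaks_at_injected_band(self):
        peaks = [sc.PeakSpec(1002.0, 12.0, 300.0, {"lung_cancer": 1.5}),
                 sc.PeakSpec(1400.0, 12.0, 300.0)]
        cfg = sc.SimConfig(n_subjects_per_class=2, spectra_per_subject=2, peaks=peaks,
                           noise_sd=0.0, spike_rate=0.0, subject_sd=0.0,
                           baseline_amplitude=0.0, seed=0)
        ds, _ = sc.generate_dataset(cfg)
        out = sc.group_mean_difference(ds, "lung_cancer", "control")
        peak_at = out.loc[out["difference"].abs().idxmax(), "wavenumber_cm1"]
        assert peak_at == 1002.0

    def test_missing_class_rejected(self, clean_dataset):
        ds, _, _ = clean_dataset
        with pytest.raises(ValueError, match="other_cancer"):
            sc.group_mean_difference(ds, "other_cancer", "control")


class TestPcaLda:
    def test_separable_clouds_classified_perfectly(self):
        rng = np.random.default_rng(30)
        X1 = rng.normal(0, 0.3, size=(50, 5)) + np.r_[3.0, np.zeros(4)]
        X0 = rng.normal(0, 0.3, size=(50, 5))
        X = np.vstack([X1, X0])
        y = np.r_[np.ones(50), np.zeros(50)]
        scores, labels = sc.pca_lda_classify(X, y, X, n_pcs=2)
        assert np.array_equal(labels, y.astype(int))

    def test_permuted_labels_give_chance_accuracy(self):
        rng = np.random.default_rng(31)
        X = rng.normal(size=(100, 10))
        y = rng.permutation(np.r_[np.ones(50), np.zeros(50)])
        accs = []
        for s in range(5):
            perm = np.random.default_rng(s).permutation(100)
            tr, te = perm[:70], perm[70:]
            if np.unique(y[tr]).size < 2:
                continue
            _, labels = sc.pca_lda_classify(X[tr], y[tr], X[te], n_pcs=3)
            accs.append(np.mean(labels == y[te]))
        assert abs(np.mean(accs) - 0.5) < 0.15

    def test_projection_variance_matches_eigendecomposition(self):
        rng = np.random.default_rng(32)
        X = rng.normal(size=(60, 6)) @ np.diag([3.0, 2.0, 1.0, 0.5, 0.2, 0.1])
        y = np.r_[np.ones(30), np.zeros(30)]
        mu = X.mean(axis=0)
        Xc = X - mu
        _, s, Vt = np.linalg.svd(Xc, full_matrices=False)
        evals = np.linalg.eigvalsh(Xc.T @ Xc / (60 - 1))[::-1]
        proj_var = (s**2) / (60 - 1)
        assert np.abs(proj_var[:3] - evals[:3]).max() < 1e-8

    def test_single_class_training_rejected(self):
        X = np.random.default_rng(33).normal(size=(10, 4))
        with pytest.raises(ValueError, match="single class"):
            sc.pca_lda_classify(X, np.ones(10), X, 2)


@settings(deadline=None, max_examples=20, derandomize=True)
@given(st.integers(0, 2**31 - 1), st.integers(1, 4))
def test_vip_sum_of_squares_equals_p(seed, A):
    """Sum_j VIP_j^2 = p holds for every fitted model."""
    rng = np.random.default_rng(seed)
    n, p = 16, 10
    X = rng.normal(size=(n, p))
    y = np.r_[np.ones(8), np.zeros(8)]
    res = sc.fit_plsda(X, y, A)
    assert np.sum(res.vip().scores ** 2) == pytest.approx(p, abs=1e-8)
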