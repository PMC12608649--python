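import numpy as np
import pytest
from hypothesis import given, settings, strategies as st
from scipy import stats

import aromapls as ap
from aromapls.opls import _r2_q2, assign_folds


def signal_data(seed, n=60, p=20, noise=0.5):
    rng = np.random.default_rng(seed)
    X = rng.normal(size=(n, p))
    beta = rng.normal(size=p)
    y = X @ beta + noise * rng.normal(size=n)
    return X, y


class TestPls1:
    def test_single_proportional_column_fits_exactly(self):
        rng = np.random.default_rng(0)
        y = rng.normal(size=30)
        X = (2.5 * y)[:, None]
        m = ap.fit_pls1(X, y, 1)
        assert m.r2y == pytest.approx(1.0)
        assert np.allclose(m.predict(X), y)

    def test_first_weight_is_normalized_covariance(self):
        X, y = signal_data(1)
        m = ap.fit_pls1(X, y, 1)
        w = (X - X.mean(0)).T @ (y - y.mean())
        w /= np.linalg.norm(w)
        assert np.allclose(m.weights[:, 0], w)

    @pytest.mark.parametrize("n_comp", [1, 2, 4])
    def test_matches_reference_implementation(self, n_comp):
        """Predictions agree with an independent NIPALS implementation."""
        from sklearn.cross_decomposition import PLSRegression

        X, y = signal_data(7, n=20, p=6)
        mine = ap.fit_pls1(X, y, n_comp).predict(X)
        ref = PLSRegression(n_components=n_comp, scale=False).fit(X, y)
        assert np.allclose(mine, ref.predict(X).ravel(), atol=1e-8)

    def test_r2_nondecreasing_in_components(self):
        X, y = signal_data(3, p=8)
        r2 = [ap.fit_pls1(X, y, k).r2y for k in range(1, 6)]
        assert np.all(np.diff(r2) >= -1e-12)

    def test_constant_y_rejected(self):
        X, _ = signal_data(0)
        with pytest.raises(ValueError, match="constant"):
            ap.fit_pls1(X, np.ones(60), 1)

    def test_rank_exceeded_rejected(self):
        rng = np.random.default_rng(2)
        X = np.tile(rng.normal(size=(10, 1)), (1, 3))  # rank 1
        y = X[:, 0] + 0.01 * rng.normal(size=10)
        with pytest.raises(ValueError, match="rank"):
            ap.fit_pls1(X, y, 3)


class TestOpls:
    def test_zero_orth_reduces_to_pls1(self):
        X, y = signal_data(4)
        opls_pred = ap.fit_opls(X, y, 0).predict(X)
        pls_pred = ap.fit_pls1(X, y, 1).predict(X)
        assert np.allclose(opls_pred, pls_pred, atol=1e-10)

    def test_orthogonal_filtering_concentrates_weight(self):
        """X = [y + small noise, z orthogonal to y]: one orthogonal
        component leaves the predictive weight on column 1."""
        rng = np.random.default_rng(5)
        y = rng.normal(size=80)
        z = rng.normal(size=80)
        z -= z @ y / (y @ y) * y  # exactly orthogonal in sample
        X = np.column_stack([y + 0.05 * rng.normal(size=80), z])
        m = ap.fit_opls(X, y, 1)
        assert abs(m.w_pred[0]) > 0.99

    def test_orthogonal_scores_orthogonal_to_response(self):
        X, y = signal_data(6)
        m = ap.fit_opls(X, y, 3)
        yc = y - y.mean()
        for k in range(m.n_orth):
            t = m.t_orth[:, k]
            assert abs(t @ yc) < 1e-8 * np.linalg.norm(t) * np.linalg.norm(yc)
        assert abs(m.t_pred @ m.t_orth).max() < 1e-8

    def test_r2y_nondecreasing_in_n_orth(self):
        X, y = signal_data(8)
        r2 = [ap.fit_opls(X, y, k).r2y for k in range(4)]
        assert np.all(np.diff(r2) >= -1e-12)

    def test_early_stop_when_no_orthogonal_variation(self):
        rng = np.random.default_rng(9)
        y = rng.normal(size=30)
        X = (3.0 * y)[:, None]  # single column: nothing orthogonal to strip
        with pytest.warns(UserWarning, match="orthogonal"):
            m = ap.fit_opls(X, y, 2)
        assert m.n_orth == 0

    def test_coefficients_reproduce_pipeline_predictions(self):
        X, y = signal_data(10)
        m = ap.fit_opls(X, y, 2)
        via_b = (X - m.x_center) @ m.b + m.y_center
        assert np.allclose(via_b, m.predict(X), atol=1e-10)


class TestCrossValidate:
    def test_noiseless_model_has_high_q2(self):
        # y = Xb exactly; with enough orthogonal components the single
        # predictive component recovers the full linear map
        rng = np.random.default_rng(0)
        X = rng.normal(size=(60, 5))
        y = X @ rng.normal(size=5)
        cv = ap.cross_validate(X, y, 4, n_folds=7, seed=0)
        assert cv.q2 >= 0.99

    @pytest.mark.parametrize("seed", range(5))
    def test_null_data_has_low_q2(self, seed):
        rng = np.random.default_rng(seed)
        X = rng.normal(size=(40, 10))
        y = rng.normal(size=40)
        cv = ap.cross_validate(X, y, 0, seed=seed)
        assert cv.q2 <= 0.2

    def test_press_matches_explicit_leave_fold_out_loop(self):
        X, y = signal_data(12)
        cv = ap.cross_validate(X, y, 1, n_folds=5, seed=3)
        press = 0.0
        for f in range(5):
            test = cv.folds == f
            m = ap.fit_opls(X[~test], y[~test], 1)
            press += float(np.sum((y[test] - m.predict(X[test])) ** 2))
        assert cv.press == pytest.approx(press)
        assert cv.q2 == pytest.approx(1 - press / np.sum((y - y.mean()) ** 2))

    def test_every_sample_predicted_once(self):
        X, y = signal_data(13)
        cv = ap.cross_validate(X, y, 0, n_folds=7, seed=1)
        assert np.bincount(cv.folds, minlength=7).sum() == 60
        assert np.isfinite(cv.y_hat_cv).all()

    def test_stratified_folds_keep_both_levels(self):
        side = np.array([0] * 30 + [1] * 30)
        folds = assign_folds(60, 7, seed=0, stratify=side)
        for f in range(7):
            assert set(side[folds == f]) == {0, 1}

    def test_fold_losing_a_level_raises(self):
        rng = np.random.default_rng(0)
        X = rng.normal(size=(8, 3))
        side = np.array([0] * 7 + [1])  # the single 1 fills one whole fold
        y = side.astype(float)
        with pytest.raises(ValueError, match="stratification"):
            ap.cross_validate(X, y, 0, n_folds=4, seed=0, stratify=side)

    def test_q2_not_above_r2_across_seeds(self):
        for seed in range(10):
            X, y = signal_data(seed, n=40, p=10, noise=1.0)
            r2, q2 = _r2_q2(X, y, 1, 7, seed, None)
            assert q2 <= r2 + 1e-12

    def test_pure_noise_column_barely_moves_predictions(self):
        """Adding a variable orthogonal to y changes cross-validated
        predictions by less than the clean model's CV standard error."""
        rng = np.random.default_rng(21)
        y = rng.normal(size=80)
        z = rng.normal(size=80)
        z -= z @ y / (y @ y) * y
        X = np.column_stack([y + 0.1 * rng.normal(size=80), z])
        cv0 = ap.cross_validate(X, y, 1, seed=0)
        noise = rng.normal(size=80)
        noise -= noise @ y / (y @ y) * y
        cv1 = ap.cross_validate(np.column_stack([X, noise]), y, 1, seed=0)
        cv_se = np.std(y - cv0.y_hat_cv)
        assert np.abs(cv1.y_hat_cv - cv0.y_hat_cv).max() < cv_se


class TestFeatureStats:
    def test_single_feature_vip_is_one(self):
        rng = np.random.default_rng(0)
        y = rng.normal(size=30)
        X = (y * 2 + 0.1 * rng.normal(size=30))[:, None]
        m = ap.fit_opls(X, y, 0)
        cv = ap.cross_validate(X, y, 0, seed=0)
        fs = ap.feature_stats(m, cv, X, y)
        assert fs.vip_pred[0] == pytest.approx(1.0)

    @given(st.integers(min_value=0, max_value=10_000))
    @settings(max_examples=25, deadline=None)
    def test_mean_squared_vip_is_one(self, seed):
        X, y = signal_data(seed, n=30, p=12)
        m = ap.fit_opls(X, y, 1)
        cv = ap.cross_validate(X, y, 1, seed=0)
        fs = ap.feature_stats(m, cv, X, y)
        assert np.mean(fs.vip_pred**2) == pytest.approx(1.0)
        finite = ~np.isnan(fs.p_corr)
        assert (np.abs(fs.p_corr[finite]) <= 1.0).all()

    def test_p_corr_matches_direct_correlation(self):
        rng = np.random.default_rng(5)
        y = rng.normal(size=80)
        z = rng.normal(size=80)
        z -= z @ y / (y @ y) * y
        X = np.column_stack([y + 0.05 * rng.normal(size=80), z])
        m = ap.fit_opls(X, y, 1)
        cv = ap.cross_validate(X, y, 1, seed=0)
        fs = ap.feature_stats(m, cv, X, y)
        direct = np.corrcoef(m.t_pred, X[:, 0])[0, 1]
        assert fs.p_corr[0] == pytest.approx(direct)
        assert abs(fs.p_corr[0]) > 0.95

    def test_zero_variance_feature_flagged_and_unselectable(self):
        X, y = signal_data(3, p=5)
        X[:, 2] = 7.0
        m = ap.fit_opls(X, y, 0)
        cv = ap.cross_validate(X, y, 0, seed=0)
        fs = ap.feature_stats(m, cv, X, y)
        assert fs.undefined[2] and np.isnan(fs.p_corr[2])
        assert not fs.jk_pass[2]
        assert 2 not in [j for j, _ in ap.select_features(fs, 0.0, 0.0)]


class TestSelectFeatures:
    def make_stats(self, vip, pcorr, lo, hi):
        return ap.FeatureStats(
            np.array([vip]), np.array([pcorr]), np.array([lo]), np.array([hi]),
            np.array([(lo > 0) or (hi < 0)]), np.array([False]),
        )

    def test_passing_feature_selected_with_sign(self):
        fs = self.make_stats(2.0, 0.7, 0.1, 0.5)
        assert ap.select_features(fs, 1.5, 0.6) == [(0, 1)]

    def test_vip_threshold_is_strict(self):
        fs = self.make_stats(1.4, 0.9, 0.1, 0.5)
        assert ap.select_features(fs, 1.5, 0.6) == []

    def test_jack_knife_gate(self):
        fs = self.make_stats(3.0, -0.65, -0.4, 0.2)  # CI spans zero
        assert ap.select_features(fs, 1.5, 0.6) == []


class TestCvAnova:
    def test_hand_computed_example(self):
        """SS=100, PRESS=20, n=60, 3 components: F = (80/3)/(20/56)."""
        cv = ap.CvResult(
            y_hat_cv=np.zeros(60), press=20.0, ss_total=100.0, q2=0.8,
            folds=np.zeros(60, int), fold_w_pred=np.zeros((7, 1)),
            fold_b=np.zeros((7, 1)), seed=0, n_folds=7,
        )
        F, p = ap.cv_anova(cv, 3)
        assert F == pytest.approx((80 / 3) / (20 / 56))
        assert p == pytest.approx(stats.f.sf(F, 3, 56))

    def test_perfect_prediction_limit(self):
        cv = ap.CvResult(np.zeros(60), 1e-12, 100.0, 1.0, np.zeros(60, int),
                         np.zeros((7, 1)), np.zeros((7, 1)), 0, 7)
        _, p = ap.cv_anova(cv, 2)
        assert p < 1e-30

    def test_no_information_limit(self):
        cv = ap.CvResult(np.zeros(60), 100.0, 100.0, 0.0, np.zeros(60, int),
                         np.zeros((7, 1)), np.zeros((7, 1)), 0, 7)
        F, p = ap.cv_anova(cv, 2)
        assert F == 0.0 and p == 1.0


class TestPermutationTest:
    def test_identity_permutation_reproduces_observed_q2(self):
        X, y = signal_data(1)
        r2_obs, q2_obs = _r2_q2(X, y, 1, 7, 0, None)
        r2_id, q2_id = _r2_q2(X, y[np.arange(60)], 1, 7, 0, None)
        assert q2_id == pytest.approx(q2_obs)
        assert r2_id == pytest.approx(r2_obs)

    def test_strong_signal_dominates_all_permutations(self):
        rng = np.random.default_rng(0)
        X = rng.normal(size=(40, 5))
        y = X @ rng.normal(size=5)
        perm_r2, perm_q2, perm_p, r2_obs, q2_obs = ap.permutation_test(
            X, y, 0, n_perm=20, seed=0
        )
        assert (perm_q2 < q2_obs).all()
        assert perm_p == pytest.approx(1 / 21)

    def test_zero_permutations_rejected(self):
        X, y = signal_data(1)
        with pytest.raises(ValueError, match="n_perm"):
            ap.permutation_test(X, y, 0, n_perm=0, seed=0)

    def test_validate_model_flags_null_data_invalid(self):
        rng = np.random.default_rng(3)
        X = rng.normal(size=(40, 10))
        y = rng.normal(size=40)
        report = ap.validate_model(X, y, 0, n_perm=20, seed=0)
        assert not report.valid


@given(
    st.floats(min_value=-3, max_value=3),
    st.floats(min_value=0.1, max_value=5),
)
@settings(max_examples=25, deadline=None)
def test_cohens_d_affine_equivariance(beta, alpha):
    a = np.array([0.0, 1.0, 2.5, 0.5])
    b = np.array([2.0, 3.0, 4.5])
    d = ap.cohens_d(a, b)
    assert ap.cohens_d(alpha * a + beta, alpha * b + beta) == pytest.approx(d)
    assert ap.cohens_d(-alpha * a + beta, -alpha * b + beta) == pytest.approx(-d)
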