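"""OPLS-DA core: components, diagnostics, validation and variable selection."""

import numpy as np
import pytest
from scipy import stats

from oametab.oplsda import (
    cross_validate,
    cv_anova,
    CvResult,
    fit_oplsda,
    permutation_test,
    predict,
    select_variables,
    vip_scores,
)


def _separated_classes(seed=0, n=20, p=10, delta=5.0):
    rng = np.random.default_rng(seed)
    X = rng.normal(size=(n, p))
    y = np.array([0] * (n // 2) + [1] * (n // 2))
    X[:, 0] += delta * y
    return X, y


def _pls1_oracle(X, y):
    """Single-component PLS1 predictions, written out long-hand."""
    X = np.asarray(X, dtype=float)
    y = np.where(y == np.unique(y)[1], 1.0, -1.0)
    mean, sd = X.mean(axis=0), X.std(axis=0, ddof=1)
    Xs = (X - mean) / sd
    yc = y - y.mean()
    w = Xs.T @ yc
    w = w / np.linalg.norm(w)
    t = Xs @ w
    q = (yc @ t) / (t @ t)
    return t * q + y.mean()


class TestFit:
    def test_no_orthogonal_components_reduces_to_pls1(self):
        X, y = _separated_classes(seed=1)
        model = fit_oplsda(X, y, n_ortho=0)
        np.testing.assert_allclose(predict(model, X), _pls1_oracle(X, y), atol=1e-10)

    def test_strong_separation_gives_high_r2y_and_correct_signs(self):
        r2s = []
        for seed in range(5):
            X, y = _separated_classes(seed=seed)
            model = fit_oplsda(X, y, n_ortho=2)
            r2s.append(model.r2y)
            y_hat = predict(model, X)
            assert np.all(np.sign(y_hat - model.y_mean) == np.where(y == 1, 1, -1))
        assert np.median(r2s) > 0.9

    def test_column_permutation_equivariance(self):
        X, y = _separated_classes(seed=3)
        rng = np.random.default_rng(0)
        perm = rng.permutation(X.shape[1])
        base = fit_oplsda(X, y, n_ortho=1)
        permuted = fit_oplsda(X[:, perm], y, n_ortho=1)
        np.testing.assert_allclose(permuted.scores, base.scores, atol=1e-10)
        np.testing.assert_allclose(permuted.weights, base.weights[perm], atol=1e-10)

    def test_orthogonal_scores_uncorrelated_with_y(self):
        X, y = _separated_classes(seed=4, p=15)
        for n_ortho in (1, 2, 3):
            model = fit_oplsda(X, y, n_ortho=n_ortho)
            yc = np.where(y == 1, 1.0, -1.0)
            for k in range(n_ortho):
                corr = np.corrcoef(model.ortho_scores[:, k], yc)[0, 1]
                assert abs(corr) < 1e-8

    def test_input_validation(self):
        X, y = _separated_classes()
        with pytest.raises(ValueError):
            fit_oplsda(X, np.zeros(len(y)))  # single class
        with pytest.raises(ValueError):
            fit_oplsda(X, y, n_ortho=50)  # exceeds rank bound
        X_const = X.copy()
        X_const[:, 3] = 1.0
        with pytest.raises(ValueError):
            fit_oplsda(X_const, y)  # zero-variance variable
        X_nan = X.copy()
        X_nan[0, 0] = np.nan
        with pytest.raises(ValueError):
            fit_oplsda(X_nan, y)


class TestCrossValidation:
    def test_noiseless_linear_signal_gives_q2_near_one(self):
        y = np.array([0] * 10 + [1] * 10)
        yc = np.where(y == 1, 1.0, -1.0)
        X = np.column_stack([yc, 0.5 * yc + 1.0])  # y exactly linear in X
        cv = cross_validate(X, y, n_ortho=0, folds=7, seed=1)
        assert cv.q2y > 0.99

    def test_null_data_median_q2_nonpositive(self, null_xy):
        q2s = [
            cross_validate(*null_xy(seed), n_ortho=0, folds=7, seed=seed).q2y
            for seed in range(10)
        ]
        assert np.median(q2s) <= 0.0

    def test_q2_invariant_to_sample_order_given_same_folds(self):
        X, y = _separated_classes(seed=6)
        cv = cross_validate(X, y, n_ortho=1, folds=7, seed=2)
        perm = np.random.default_rng(1).permutation(len(y))
        # reuse the same partition, relabelled by the permutation
        cv_perm = cross_validate(X[perm], y[perm], n_ortho=1, folds=7, seed=2)
        manual = _oracle_q2(X[perm], y[perm], cv_perm.fold_assignment, n_ortho=1)
        assert cv_perm.q2y == pytest.approx(manual, abs=1e-10)

    def test_matches_no_leakage_oracle(self):
        """Q2 equals an independent recomputation that rescales inside every
        training fold; scaling on the full data gives a different number."""
        X, y = _separated_classes(seed=7, delta=1.5)
        cv = cross_validate(X, y, n_ortho=1, folds=7, seed=3)
        assert cv.q2y == pytest.approx(
            _oracle_q2(X, y, cv.fold_assignment, n_ortho=1), abs=1e-10
        )
        leaky = _oracle_q2(X, y, cv.fold_assignment, n_ortho=1, leak_scaling=True)
        assert cv.q2y != pytest.approx(leaky, abs=1e-12)


from tests_oracle import oracle_q2 as _oracle_q2


class TestCvAnova:
    def _cv_result(self, press, ss_tot):
        return CvResult(q2y=1 - press / ss_tot, y_pred=np.zeros(20), press=press,
                        ss_tot=ss_tot, fold_assignment=np.zeros(20, dtype=int),
                        n_ortho=1)

    def test_no_predictive_ability_gives_f_zero_p_one(self):
        X, y = _separated_classes()
        model = fit_oplsda(X, y, n_ortho=1)
        res = cv_anova(self._cv_result(press=20.0, ss_tot=20.0), y, model)
        assert res.f_statistic == 0.0
        assert res.p_value == 1.0

    def test_press_to_zero_drives_p_to_zero(self):
        X, y = _separated_classes()
        model = fit_oplsda(X, y, n_ortho=1)
        p_prev = 1.0
        for press in (10.0, 1.0, 1e-4, 1e-12):
            res = cv_anova(self._cv_result(press=press, ss_tot=20.0), y, model)
            assert res.p_value <= p_prev
            p_prev = res.p_value
        assert p_prev < 1e-12

    def test_degrees_of_freedom_follow_component_count(self):
        X, y = _separated_classes()
        model = fit_oplsda(X, y, n_ortho=2)
        res = cv_anova(self._cv_result(press=5.0, ss_tot=20.0), y, model)
        assert res.df_model == 3  # predictive + 2 orthogonal
        assert res.df_residual == len(y) - 3 - 1

    def test_strong_signal_significant(self):
        X, y = _separated_classes(seed=8)
        model = fit_oplsda(X, y, n_ortho=1)
        cv = cross_validate(X, y, n_ortho=1, folds=7, seed=4)
        assert cv_anova(cv, y, model).p_value < 0.01

    def test_too_few_samples_error(self):
        X, y = _separated_classes(seed=9, n=6, p=4)
        model = fit_oplsda(X, y, n_ortho=3)
        with pytest.raises(ValueError):
            cv_anova(self._cv_result(press=1.0, ss_tot=6.0), y[:4], model)


class TestPermutation:
    def test_observed_above_all_permuted_gives_add_one_p(self):
        X, y = _separated_classes(seed=10)
        summary = permutation_test(X, y, n_ortho=0, n_iterations=99, seed=5)
        assert summary.p_q2 == pytest.approx(1.0 / 100.0)
        assert len(summary.permuted_q2y) == 99
        assert np.all(summary.permuted_q2y < summary.observed_q2y)

    def test_p_never_zero_and_reproducible(self, null_xy):
        X, y = null_xy(0)
        a = permutation_test(X, y, n_ortho=0, n_iterations=49, seed=6)
        b = permutation_test(X, y, n_ortho=0, n_iterations=49, seed=6)
        assert a.p_q2 >= 1.0 / 50.0
        assert a.p_q2 == b.p_q2
        np.testing.assert_array_equal(a.permuted_q2y, b.permuted_q2y)

    def test_few_iterations_warn(self):
        X, y = _separated_classes(seed=11)
        with pytest.warns(UserWarning):
            permutation_test(X, y, n_ortho=0, n_iterations=10, seed=7)

    def test_intercepts_below_observed_for_real_signal(self):
        X, y = _separated_classes(seed=12)
        summary = permutation_test(X, y, n_ortho=0, n_iterations=49, seed=8)
        assert summary.q2_intercept < summary.observed_q2y
        assert summary.r2_intercept < summary.observed_r2y


class TestVipSelection:
    def test_weight_vector_one_zero_gives_vip_sqrt2_zero(self):
        # second variable constructed exactly orthogonal to y, so w = (1, 0)
        rng = np.random.default_rng(13)
        y = np.array([0] * 10 + [1] * 10)
        yc = np.where(y == 1, 1.0, -1.0)
        z = rng.normal(size=20)
        z = z - z.mean() - (z @ yc) / (yc @ yc) * yc
        X = np.column_stack([yc, z])
        model = fit_oplsda(X, y, n_ortho=0)
        np.testing.assert_allclose(np.abs(model.weights), [1.0, 0.0], atol=1e-12)
        vip = vip_scores(X, y, model, folds=5, seed=9)
        assert vip["vip"].loc["0"] == pytest.approx(np.sqrt(2.0), abs=1e-9)
        assert vip["vip"].loc["1"] == pytest.approx(0.0, abs=1e-9)

    def test_equal_weights_give_unit_vip(self):
        y = np.array([0] * 6 + [1] * 6)
        signal = np.where(y == 1, 1.0, -1.0)
        rng = np.random.default_rng(14)
        X = np.column_stack([signal + rng.normal(0, 1e-9, 12) for _ in range(4)])
        model = fit_oplsda(X, y, n_ortho=0)
        np.testing.assert_allclose(np.sqrt(4) * np.abs(model.weights),
                                   np.ones(4), atol=1e-6)

    def test_sum_of_squared_vip_equals_variable_count(self, strong_design):
        X, y, ids = strong_design
        keep = X.std(axis=0) > 0
        X = X[:, keep]
        model = fit_oplsda(X, y, n_ortho=0)
        vip = vip_scores(X, y, model, folds=7, seed=10)
        assert vip["vip"].pow(2).sum() == pytest.approx(X.shape[1], abs=1e-6)
        assert sorted(vip["rank"]) == list(range(1, X.shape[1] + 1))

    def test_selection_rules(self):
        import pandas as pd

        vip = pd.DataFrame(
            {
                "vip": [3.0, 2.5, 2.0, 1.5, 1.0],
                "ci_lower": [1.0, -0.2, 0.5, 0.1, 0.4],
                "ci_upper": [4.0, 3.1, 3.0, 2.0, 1.5],
                "rank": [1, 2, 3, 4, 5],
            },
            index=["a", "b", "c", "d", "e"],
        )
        # rank 5 with tight CI passes when top_n covers it, b fails on CI
        assert select_variables(vip, top_n=30) == ["a", "c", "d", "e"]
        # a variable ranked outside top_n is dropped however tight its CI
        assert select_variables(vip, top_n=3) == ["a", "c"]

    def test_planted_variables_dominate_top_ranks(self, strong_study, strong_design):
        """>=90% of planted discriminant features appear in the top-30/CI
        selection when fitted on the volcano-selected subset."""
        from oametab.qc import cv_filter, normalize_to_istd
        from oametab.volcano import volcano as volcano_table

        pos, neg, sheet, truth = strong_study
        selected_sets = {}
        frames = []
        import pandas as pd

        for table, mode in ((pos, "pos"), (neg, "neg")):
            normed = normalize_to_istd(table, sheet, truth.istd_ids[mode])
            kept = cv_filter(normed, sheet).apply(normed)
            frames.append(kept.intensities)
        stacked = pd.concat(frames)
        pairs = sheet.pairs("T0", "T28")
        sample_ids = list(pairs["early"]) + list(pairs["late"])
        from oametab.volcano import impute_half_min

        X = np.log10(impute_half_min(stacked[sample_ids]).to_numpy(dtype=float)).T
        y = np.array([-1.0] * 6 + [1.0] * 6)
        ids = list(stacked.index)

        # volcano screen feeding the model, as in the pipeline
        vt_mask = []
        from scipy import stats as sps

        for j, fid in enumerate(ids):
            e, l = X[:6, j], X[6:, j]
            fc = (10.0 ** l).mean() / (10.0 ** e).mean()
            _, p = sps.ttest_rel(l, e)
            vt_mask.append((fc >= 2 or fc <= 0.5) and p < 0.05)
        sub = np.flatnonzero(vt_mask)
        model = fit_oplsda(X[:, sub], y, n_ortho=0,
                           variable_ids=[ids[j] for j in sub])
        vip = vip_scores(X[:, sub], y, model, folds=7, seed=11)
        chosen = set(select_variables(vip, top_n=30))
        planted = set(truth.discriminant_ids())
        assert len(chosen & planted) / len(planted) >= 0.9
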