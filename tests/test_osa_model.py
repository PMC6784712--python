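"""Two-stage classifier: regression closed form, severity mapping,
detection tree, and leave-one-patient-out fitting."""
import hashlib

import numpy as np
import pytest

from lcsleep.errors import DataError, ValidationError
from lcsleep.osa_model import (PUBLISHED_S2LR, S2LRCoefficients, fit_lopo,
                               fit_pipeline, predict_study, s1dt_classify,
                               s2lr_predict, severity_from_ahi)
from lcsleep.types import Category, Severity


def polynomial_oracle(x, c=PUBLISHED_S2LR):
    """Independent evaluation path for the regression closed form."""
    terms = [c.intercept, c.coef_x2sq * x[1] * x[1], c.coef_x3 * x[2],
             c.coef_x5 * x[4]]
    return float(np.sum(terms))


class TestS2LR:
    def test_intercept_only(self):
        x = np.zeros(6)
        assert s2lr_predict(x) == pytest.approx(11.94)

    def test_unit_features(self):
        x = np.array([0.0, 1.0, 1.0, 0.0, 1.0, 0.0])
        assert s2lr_predict(x) == pytest.approx(11.94 + 23.06 + 8.74 - 15.04)
        assert s2lr_predict(x) == pytest.approx(28.70)

    def test_squared_term_is_sign_symmetric(self, rng):
        x = rng.normal(size=6)
        x_neg = x.copy()
        x_neg[1] = -x[1]
        assert s2lr_predict(x) == pytest.approx(s2lr_predict(x_neg), abs=1e-12)

    def test_matches_polynomial_oracle(self, rng):
        for _ in range(200):
            x = rng.normal(scale=5.0, size=6)
            assert s2lr_predict(x) == pytest.approx(polynomial_oracle(x), abs=1e-12)

    def test_non_finite_feature_rejected(self):
        x = np.zeros(6)
        x[2] = np.nan
        with pytest.raises(DataError):
            s2lr_predict(x)

    def test_coefficients_must_be_finite(self):
        with pytest.raises(ValidationError):
            S2LRCoefficients(np.inf, 0.0, 0.0, 0.0)


class TestSeverityMapping:
    @pytest.mark.parametrize("ahi,expected", [
        (0.0, Severity.NORMAL),
        (4.999999, Severity.NORMAL),
        (5.0, Severity.MILD),
        (9.92, Severity.MILD),          # a mild-range prediction
        (15.0, Severity.MILD),          # boundary belongs to mild
        (15.000001, Severity.MODERATE_SEVERE),
        (20.06, Severity.MODERATE_SEVERE),
        (73.43, Severity.MODERATE_SEVERE),
    ])
    def test_boundaries(self, ahi, expected):
        assert severity_from_ahi(ahi) is expected

    def test_negative_ahi_rejected(self):
        with pytest.raises(ValidationError):
            severity_from_ahi(-0.1)


def separable_features(rng, n_per_class=20, gap=3.0):
    """Synthetic cohort where X1 separates normal from abnormal by `gap` SD."""
    n = 2 * n_per_class
    X = rng.normal(size=(n, 6))
    abnormal = np.zeros(n, dtype=bool)
    abnormal[n_per_class:] = True
    X[abnormal, 0] += gap
    ahi = np.where(abnormal, rng.uniform(6, 40, n), rng.uniform(0, 4, n))
    return X, abnormal, ahi


class TestDetectionTree:
    def test_separable_cohort_high_heldout_accuracy(self):
        correct = total = 0
        for seed in range(20):
            rng = np.random.default_rng(seed)
            Xtr, ytr, ahitr = separable_features(rng, n_per_class=60)
            Xte, yte, _ = separable_features(rng)
            pipe = fit_pipeline(Xtr, ytr, ahitr, seed=0)
            pred = [s1dt_classify(x, pipe) is Category.ABNORMAL for x in Xte]
            correct += np.sum(np.array(pred) == yte)
            total += len(yte)
        assert correct / total >= 0.90

    def test_reproduces_training_labels_on_separable_data(self, rng):
        X, y, ahi = separable_features(rng, gap=6.0)
        pipe = fit_pipeline(X, y, ahi, seed=0)
        pred = np.array([s1dt_classify(x, pipe) is Category.ABNORMAL for x in X])
        assert (pred == y).mean() >= 0.95

    def test_identical_features_give_constant_prediction(self, rng):
        X = np.tile(rng.normal(size=6), (20, 1))
        y = np.zeros(20, dtype=bool)
        y[:10] = True
        pipe = fit_pipeline(X, y, np.where(y, 10.0, 2.0), seed=0)
        preds = {s1dt_classify(x, pipe) for x in X}
        assert len(preds) == 1

    def test_untrained_pipeline_rejected(self):
        from lcsleep.osa_model import TrainedPipeline

        with pytest.raises(ValidationError):
            s1dt_classify(np.zeros(6), TrainedPipeline(tree=None))

    def test_tree_ignores_stage2_features(self, rng):
        """Perturbing X2/X3/X5 never changes the stage-one gate."""
        X, y, ahi = separable_features(rng)
        pipe = fit_pipeline(X, y, ahi, seed=0)
        for x in X[:10]:
            perturbed = x.copy()
            perturbed[[1, 2, 4]] += rng.normal(scale=10.0, size=3)
            assert s1dt_classify(x, pipe) is s1dt_classify(perturbed, pipe)


class TestPredictStudy:
    def test_normal_gate_yields_censored_output(self, rng):
        X, y, ahi = separable_features(rng, gap=6.0)
        pipe = fit_pipeline(X, y, ahi, seed=0)
        normal_x = X[~y][0]
        pred = predict_study(normal_x, pipe)
        assert pred.category is Category.NORMAL
        assert pred.ahi.is_censored and str(pred.ahi) == "<5"
        assert pred.severity is Severity.NORMAL

    def test_abnormal_gate_with_low_regression_is_clamped(self, rng):
        X, y, ahi = separable_features(rng, gap=6.0)
        pipe = fit_pipeline(X, y, ahi, seed=0)
        pipe.coeffs = S2LRCoefficients(0.0, 0.0, 0.0, 0.0)  # forces estimate 0
        pred = predict_study(X[y][0], pipe)
        assert pred.category is Category.ABNORMAL
        assert pred.ahi.value == 5.0 and pred.severity is Severity.MILD

    def test_prediction_invariant_holds(self, trained_pipeline, cohort_df):
        """category=normal <=> censored <=> severity=normal; abnormal => >= 5."""
        X = cohort_df[[f"X{i}" for i in range(1, 7)]].to_numpy()
        for x in X:
            p = predict_study(x, trained_pipeline)
            if p.category is Category.NORMAL:
                assert p.ahi.is_censored and p.severity is Severity.NORMAL
            else:
                assert p.ahi.value >= 5.0
                assert p.severity in (Severity.MILD, Severity.MODERATE_SEVERE)


class TestLopo:
    def lopo_inputs(self, rng, n_subjects=5, nights=2):
        rows = []
        for s in range(n_subjects):
            for night in range(nights):
                rows.append(f"S{s}")
        subjects = np.array(rows)
        X, y, ahi = separable_features(rng, n_per_class=len(subjects) // 2)
        order = rng.permutation(len(subjects))
        return subjects, X[order], y[order], ahi[order]

    def test_every_study_predicted_exactly_once(self, rng):
        subjects, X, y, ahi = self.lopo_inputs(rng)
        res = fit_lopo(subjects, X, y, ahi, seed=0)
        assert len(res.predictions) + sum(
            (subjects == s).sum() for s in res.fold_errors) == len(subjects)
        keys = list(res.predictions)
        assert len(set(keys)) == len(keys)

    def test_no_leakage_fold_hash_matches_independent_recount(self, rng):
        subjects, X, y, ahi = self.lopo_inputs(rng)
        res = fit_lopo(subjects, X, y, ahi, seed=0)
        for subj, fold_hash in res.fold_hashes.items():
            hold = subjects == subj
            h = hashlib.sha256()
            for a in (X[~hold], y[~hold], ahi[~hold]):
                h.update(np.ascontiguousarray(a, dtype=float).tobytes())
            assert fold_hash == h.hexdigest()
            assert fold_hash != res.final_pipeline.training_hash

    def test_deterministic_under_seed(self, rng):
        subjects, X, y, ahi = self.lopo_inputs(rng)
        r1 = fit_lopo(subjects, X, y, ahi, seed=3)
        r2 = fit_lopo(subjects, X, y, ahi, seed=3)
        assert r1.final_pipeline.coeffs == r2.final_pipeline.coeffs
        for k in r1.predictions:
            assert str(r1.predictions[k].ahi) == str(r2.predictions[k].ahi)

    def test_parameter_recovery_with_known_linear_law(self, rng):
        """Refit regression recovers planted coefficients within 2 SE."""
        n = 400
        X = rng.normal(size=(n, 6))
        design = np.column_stack([X[:, 1] ** 2, X[:, 2], X[:, 4]])
        truth = np.array([20.0, 23.06, 8.74, -15.04])
        ahi_latent = truth[0] + design @ truth[1:] + rng.normal(0, 2.0, n)
        abnormal = ahi_latent >= 5
        ahi = np.clip(ahi_latent, 0, None)
        subjects = np.array([f"S{i // 4}" for i in range(n)])
        res = fit_lopo(subjects, X, abnormal, ahi, seed=0)
        c = res.final_pipeline.coeffs
        # standard errors from the OLS normal equations on the abnormal subset
        A = np.column_stack([np.ones(abnormal.sum()), design[abnormal]])
        resid = ahi[abnormal] - A @ np.array([c.intercept, c.coef_x2sq, c.coef_x3,
                                              c.coef_x5])
        sigma2 = resid @ resid / (len(A) - 4)
        se = np.sqrt(np.diag(sigma2 * np.linalg.inv(A.T @ A)))
        fitted = np.array([c.intercept, c.coef_x2sq, c.coef_x3, c.coef_x5])
        assert np.all(np.abs(fitted - truth) <= 2 * se + 0.5)

    def test_permuted_labels_fall_to_majority_rate(self):
        """With labels shuffled there is nothing to learn: held-out accuracy
        hovers at the majority-class rate."""
        accs = []
        for seed in range(20):
            rng = np.random.default_rng(1000 + seed)
            subjects, X, y, ahi = self.lopo_inputs(rng, n_subjects=10)
            perm = rng.permutation(len(y))
            y_perm, ahi_perm = y[perm], ahi[perm]
            res = fit_lopo(subjects, X, y_perm, ahi_perm, seed=0)
            # with night_keys defaulted, the second key element is the row index
            hits = sum(
                (res.predictions[k].category is Category.ABNORMAL) == y_perm[k[1]]
                for k in res.predictions
            )
            accs.append(hits / len(res.predictions))
        majority = 0.5
        assert abs(np.mean(accs) - majority) <= 0.10

    def test_too_few_subjects_rejected(self, rng):
        X, y, ahi = separable_features(rng, n_per_class=2)
        with pytest.raises(ValidationError):
            fit_lopo(np.array(["A", "A", "B", "B"]), X, y, ahi)

    def test_single_class_training_set_rejected(self, rng):
        X = rng.normal(size=(6, 6))
        with pytest.raises(ValidationError):
            fit_pipeline(X, np.ones(6, dtype=bool), np.full(6, 10.0))
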