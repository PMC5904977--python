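"""Logistic confirmation model, zero-FP calibration and evaluation."""

import json
import math
import warnings

import numpy as np
import pytest
from hypothesis import given
from hypothesis import strategies as st
from scipy.special import expit

from vartriage import (
    ConfidenceModel,
    ConfusionTable,
    InputError,
    SchemaError,
    accuracy_ci,
    calibrate_threshold,
    classify,
    confusion_from_predictions,
    cross_validate,
    fit_logistic,
    roc_auc,
    split_dataset,
    train_confidence_model,
)
from vartriage.callsignals import FEATURE_NAMES, FeatureVector


def _gaussian_classes(n=1200, p=4, seed=0, shift=1.0):
    rng = np.random.default_rng(seed)
    y = (rng.random(n) < 0.5).astype(int)
    X = rng.normal(0, 1, (n, p)) + shift * y[:, None] * np.linspace(0.5, 1.5, p)
    return X, y


class TestSplitDataset:
    def test_fraction_sizes_exact_at_n100(self):
        y = np.array([0] * 20 + [1] * 80)
        tr, dev, te = split_dataset(y, (0.7, 0.15, 0.15), seed=1)
        assert (len(tr), len(dev), len(te)) == (70, 15, 15)
        assert sorted(np.concatenate([tr, dev, te]).tolist()) == list(range(100))

    def test_reproducible_for_fixed_seed(self):
        y = np.array([0, 1] * 50)
        assert all(
            np.array_equal(a, b)
            for a, b in zip(split_dataset(y, seed=9), split_dataset(y, seed=9))
        )

    def test_stratification_preserves_prevalence_within_one(self):
        y = (np.random.default_rng(3).random(400) < 0.10).astype(int)
        n1 = int(y.sum())
        for part, frac in zip(split_dataset(y, seed=3), (0.7, 0.15, 0.15)):
            assert abs(y[part].sum() - frac * n1) <= 1

    def test_tiny_stratum_falls_back_with_warning(self):
        y = np.array([1] * 30 + [0] * 2)
        with pytest.warns(UserWarning, match="unstratified"):
            split_dataset(y, seed=0)

    def test_bad_fractions_rejected(self):
        with pytest.raises(InputError):
            split_dataset(np.array([0, 1] * 10), (0.5, 0.2, 0.2))


class TestFitLogistic:
    def test_single_class_rejected(self):
        with pytest.raises(InputError):
            fit_logistic(np.random.default_rng(0).normal(size=(20, 3)), np.ones(20))

    def test_matches_statsmodels_on_well_conditioned_data(self):
        import statsmodels.api as sm

        X, y = _gaussian_classes(n=2500, seed=4)
        model = fit_logistic(X, y, l2_strength=1e-6, schema=("a", "b", "c", "d"))
        Z = (X - X.mean(0)) / X.std(0)
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            ref = sm.Logit(y, sm.add_constant(Z)).fit(disp=0)
        assert model.intercept == pytest.approx(ref.params[0], abs=2e-3)
        np.testing.assert_allclose(model.coef, ref.params[1:], rtol=5e-3, atol=2e-3)

    def test_separable_data_stays_finite_under_l2(self):
        X = np.linspace(-1, 1, 40).reshape(-1, 1)
        y = (X[:, 0] > 0).astype(int)
        model = fit_logistic(X, y, l2_strength=1.0, schema=("x",))
        assert np.isfinite(model.coef).all()

    def test_irrelevant_feature_shrinks_with_penalty(self):
        rng = np.random.default_rng(8)
        X, y = _gaussian_classes(n=2000, seed=8)
        X = np.column_stack([X, rng.normal(size=2000)])  # label-independent column
        schema = ("a", "b", "c", "d", "noise")
        weak = fit_logistic(X, y, l2_strength=0.1, schema=schema)
        strong = fit_logistic(X, y, l2_strength=500.0, schema=schema)
        assert abs(strong.coef[-1]) < abs(weak.coef[-1]) + 1e-9
        assert abs(strong.coef[-1]) < 0.05


class TestPredictProba:
    def _model(self, coef, intercept=0.0, tau=0.5, p=None):
        p = p or len(coef)
        return ConfidenceModel(
            schema=tuple(f"f{i}" for i in range(p)),
            center=np.zeros(p),
            scale=np.ones(p),
            impute=np.zeros(p),
            coef=np.asarray(coef, dtype=float),
            intercept=intercept,
            tau=tau,
        )

    def test_zero_model_gives_half(self):
        model = self._model([0.0, 0.0])
        assert model.predict_proba(np.zeros(2))[0] == 0.5

    def test_matches_direct_sigmoid_recomputation(self):
        rng = np.random.default_rng(2)
        model = self._model(rng.normal(size=6), intercept=0.3)
        for _ in range(100):
            v = rng.normal(size=6)
            want = expit(model.coef @ v + 0.3)
            assert model.predict_proba(v)[0] == pytest.approx(want, rel=1e-12)

    def test_monotone_in_positively_weighted_feature(self):
        model = self._model([1.0, -2.0])
        grid = [model.predict_proba(np.array([x, 0.7]))[0] for x in np.linspace(-3, 3, 9)]
        assert all(a < b for a, b in zip(grid, grid[1:]))

    def test_schema_mismatch_rejected(self):
        model = self._model([1.0, 1.0])
        with pytest.raises(SchemaError):
            model.predict_proba(np.zeros(3))


class TestCalibrateThreshold:
    def test_separable_scores_keep_all_confirmed_high(self):
        tau = calibrate_threshold([0.9, 0.8, 0.2, 0.1], [1, 1, 0, 0])
        high = np.array([0.9, 0.8, 0.2, 0.1]) >= tau
        ct = confusion_from_predictions(high, [1, 1, 0, 0])
        assert (ct.fp, ct.fn) == (0, 0) and ct.tp == 2

    def test_interleaved_scores_sacrifice_a_confirmed_call(self):
        probas, labels = np.array([0.9, 0.6, 0.7, 0.1]), np.array([1, 1, 0, 0])
        tau = calibrate_threshold(probas, labels)
        assert tau == pytest.approx(0.8)  # midpoint of the straddling pair
        ct = confusion_from_predictions(probas >= tau, labels)
        assert (ct.tp, ct.fp, ct.fn, ct.tn) == (1, 0, 1, 2)

    def test_all_unconfirmed_classifies_nothing_high(self):
        probas = np.array([0.3, 0.9, 0.5])
        tau = calibrate_threshold(probas, np.zeros(3))
        assert (probas >= tau).sum() == 0

    def test_no_unconfirmed_falls_back_to_floor(self):
        assert calibrate_threshold([0.9, 0.8], [1, 1], floor=0.42) == 0.42

    def test_empty_input_rejected(self):
        with pytest.raises(InputError):
            calibrate_threshold([], [])

    @given(
        st.lists(st.floats(0, 1, allow_nan=False), min_size=2, max_size=60),
        st.integers(0, 2**30),
    )
    def test_zero_fp_on_any_calibration_set(self, probas, label_seed):
        rng = np.random.default_rng(label_seed)
        labels = (rng.random(len(probas)) < 0.5).astype(int)
        tau = calibrate_threshold(probas, labels)
        fp = sum(1 for p, l in zip(probas, labels) if l == 0 and p >= tau)
        assert fp == 0

    def test_threshold_monotonicity_of_fp_and_fn(self):
        rng = np.random.default_rng(5)
        probas = rng.random(300)
        labels = (rng.random(300) < 0.4).astype(int)
        grid = np.unique(np.concatenate([[0.0, 1.0], probas]))
        fps, fns = [], []
        for t in grid:
            ct = confusion_from_predictions(probas >= t, labels)
            fps.append(ct.fp)
            fns.append(ct.fn)
        assert all(a >= b for a, b in zip(fps, fps[1:]))
        assert all(a <= b for a, b in zip(fns, fns[1:]))


class TestClassify:
    def _calibrated(self):
        model = TestPredictProba()._model([1.0] * 14, tau=0.5)
        model.schema = FEATURE_NAMES
        return model

    def test_boundary_probability_is_high(self):
        model = self._calibrated()
        model.tau = float(model.predict_proba(np.zeros(14))[0])
        assert classify(model, np.zeros(14))[0] == "HIGH"

    def test_hard_missing_feature_forces_low(self):
        model = self._calibrated()
        values = np.full(14, 10.0)
        values[FEATURE_NAMES.index("whr")] = math.nan
        cls, reason = classify(model, values)
        assert (cls, reason) == ("LOW", "undefined_feature")

    def test_soft_missing_feature_still_scored(self):
        model = self._calibrated()
        vec = FeatureVector(values=np.full(14, 3.0), mask=frozenset({"fs"}))
        assert classify(model, vec)[0] == "HIGH"

    def test_uncalibrated_model_rejected(self):
        model = self._calibrated()
        model.tau = math.nan
        with pytest.raises(InputError):
            classify(model, np.zeros(14))


class TestChallengingCalls:
    def test_low_fraction_clean_site_call_can_be_high_despite_low_qual(self):
        """A ~25% AF call at a deep, clean site (balanced GC, no homopolymer,
        no strand bias) is classifiable HIGH even though its QUAL is low —
        site-level evidence compensates for a weak single quality score."""
        from vartriage import SimulationConfig, simulate_feature_table

        frame, labels, _ = simulate_feature_table(SimulationConfig(seed=1))
        model, _ = train_confidence_model(frame.to_numpy(), labels, seed=1)
        call = {
            "dp": 175.0, "ad": 44.0, "af": 44 / 175, "gc5": 0.4, "gc20": 0.45,
            "gc50": 0.48, "mq": 60.0, "gq": 99.0, "whr": 1.8, "hpl_d": 8.0,
            "hpl_l": 2.0, "qual": 683.77, "qd": 683.77 / 175, "fs": 0.5,
        }
        x = np.array([call[n] for n in FEATURE_NAMES])
        assert classify(model, x)[0] == "HIGH"


class TestCrossValidate:
    def test_leave_one_out_matches_hand_rolled_loop(self):
        X, y = _gaussian_classes(n=20, p=2, seed=6, shift=2.0)
        with pytest.warns(UserWarning, match="unstratified"):
            got = cross_validate(X, y, k=20, seed=6)

        from sklearn.model_selection import KFold

        total = ConfusionTable()
        for tr, te in KFold(20, shuffle=True, random_state=6).split(X):
            m = fit_logistic(X[tr], y[tr], seed=6, schema=("a", "b"))
            tau = calibrate_threshold(m.predict_proba(X[tr]), y[tr])
            total = total + confusion_from_predictions(
                m.predict_proba(X[te]) >= tau, y[te]
            )
        assert got.as_dict() == total.as_dict()

    def test_permuted_labels_collapse_high_fraction(self, cohort):
        frame, labels, _ = cohort
        rng = np.random.default_rng(0)
        permuted = rng.permutation(labels)
        ct = cross_validate(frame.to_numpy(), permuted, k=5, seed=0)
        assert (ct.tp + ct.fp) / ct.n < 0.2

    def test_invalid_k_rejected(self):
        X, y = _gaussian_classes(n=30)
        with pytest.raises(InputError):
            cross_validate(X, y, k=1)
        with pytest.raises(InputError):
            cross_validate(X, y, k=31)

    def test_global_tau_mode_runs(self, cohort):
        frame, labels, _ = cohort
        ct = cross_validate(frame.to_numpy(), labels, k=4, seed=1, per_fold_tau=False)
        assert ct.n == len(labels)


class TestRocAuc:
    def test_perfect_separation_gives_one(self):
        _, auc = roc_auc([0.1, 0.2, 0.8, 0.9], [0, 0, 1, 1])
        assert auc == 1.0

    def test_identical_scores_give_half(self):
        _, auc = roc_auc([0.5] * 6, [0, 1, 0, 1, 0, 1])
        assert auc == 0.5

    def test_single_class_rejected(self):
        with pytest.raises(InputError):
            roc_auc([0.1, 0.9], [1, 1])

    def test_equals_pairwise_concordance_brute_force(self):
        rng = np.random.default_rng(9)
        for _ in range(20):
            n = int(rng.integers(10, 60))
            probas = rng.random(n)
            labels = (rng.random(n) < 0.5).astype(int)
            if labels.min() == labels.max():
                continue
            _, auc = roc_auc(probas, labels)
            pos, neg = probas[labels == 1], probas[labels == 0]
            wins = (pos[:, None] > neg[None, :]).sum() + 0.5 * (pos[:, None] == neg[None, :]).sum()
            assert auc == pytest.approx(wins / (len(pos) * len(neg)), rel=1e-9)


class TestAccuracyCI:
    def test_cohort_scale_confusion_counts(self):
        ct = ConfusionTable(tp=6622, fp=0, fn=44, tn=513)
        acc, (lo, hi) = accuracy_ci(ct)
        assert acc == pytest.approx(7135 / 7179)
        assert acc == pytest.approx(0.9939, abs=5e-5)
        assert lo < acc < hi

    def test_all_correct_degenerates_to_point(self):
        acc, (lo, hi) = accuracy_ci(ConfusionTable(tp=50, tn=50))
        assert (acc, lo, hi) == (1.0, 1.0, 1.0)

    def test_width_shrinks_like_inverse_sqrt_n(self):
        w = []
        for scale in (1, 4):
            ct = ConfusionTable(tp=90 * scale, fp=5 * scale, fn=5 * scale, tn=0)
            _, (lo, hi) = accuracy_ci(ct)
            w.append(hi - lo)
        assert w[0] / w[1] == pytest.approx(2.0, rel=1e-9)

    def test_wilson_interval_contains_accuracy(self):
        ct = ConfusionTable(tp=80, fp=10, fn=5, tn=5)
        acc, (lo, hi) = accuracy_ci(ct, method="wilson")
        assert lo < acc < hi

    def test_empty_rejected(self):
        with pytest.raises(InputError):
            accuracy_ci(ConfusionTable())


class TestDeterminismAndSerialization:
    def test_identical_inputs_yield_byte_identical_models(self, cohort):
        frame, labels, _ = cohort
        X = frame.to_numpy()
        a, _ = train_confidence_model(X, labels, seed=3)
        b, _ = train_confidence_model(X, labels, seed=3)
        assert a.to_json() == b.to_json()

    def test_json_round_trip_is_lossless(self, cohort):
        frame, labels, _ = cohort
        model, _ = train_confidence_model(frame.to_numpy(), labels, seed=3)
        back = ConfidenceModel.from_json(model.to_json())
        assert back.to_json() == model.to_json()
        v = frame.to_numpy()[:5]
        np.testing.assert_array_equal(model.predict_proba(v), back.predict_proba(v))

    def test_train_pipeline_has_zero_fp_on_dev_split(self, cohort):
        frame, labels, _ = cohort
        X = frame.to_numpy()
        model, report = train_confidence_model(X, labels, seed=5)
        _, dev_idx, _ = split_dataset(labels, seed=5)
        high = model.predict_proba(X[dev_idx]) >= model.tau
        assert confusion_from_predictions(high, labels[dev_idx]).fp == 0
        assert report["test_confusion"]["fp"] == 0
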