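"""Stable-vs-decliner machinery: residualization algebra, the AUC /
Mann-Whitney identity, prevalence cutoffs, and cross-validated
classification behaviour."""

import numpy as np
import pandas as pd
import pytest
from scipy.stats import norm

from braingap import CohortSpec, generate_cohort
from braingap.progression import (
    cv_single_feature_auc,
    derive_cutoff,
    residualize,
    roc_auc,
    sensitivity_specificity,
    validate_external,
)


class TestResidualize:
    def test_exact_linear_reference_residuals_are_zero(self, rng):
        Z = rng.normal(size=(30, 2))
        v = Z @ np.array([2.0, -1.0]) + 5.0
        ref = np.zeros(30, dtype=bool)
        ref[:20] = True
        out = residualize(v, Z, ref)
        assert np.allclose(out[ref], 0.0, atol=1e-9)

    def test_intercept_only_reduces_to_z_score(self, rng):
        v = rng.normal(10, 3, size=40)
        ref = np.ones(40, dtype=bool)
        out = residualize(v, None, ref)
        np.testing.assert_allclose(out, (v - v.mean()) / (v - v.mean()).std(ddof=1))

    def test_matches_two_step_oracle(self):
        for seed in range(10):
            rng = np.random.default_rng(seed)
            Z = rng.normal(size=(50, 3))
            v = Z @ rng.normal(size=3) + rng.normal(size=50)
            ref = rng.random(50) < 0.6
            ref[:5] = True
            out = residualize(v, Z, ref)
            # oracle: normal equations on reference rows, then scaling
            D = np.column_stack([np.ones(50), Z])
            beta = np.linalg.solve(D[ref].T @ D[ref], D[ref].T @ v[ref])
            resid = v - D @ beta
            expected = resid / resid[ref].std(ddof=1)
            np.testing.assert_allclose(out, expected, atol=1e-10)

    def test_reference_residuals_decorrelated_from_covariates(self, rng):
        Z = rng.normal(size=(200, 3))
        v = Z @ np.array([1.0, 0.5, -2.0]) + rng.normal(size=200)
        ref = np.zeros(200, dtype=bool)
        ref[:120] = True
        out = residualize(v, Z, ref)
        assert abs(out[ref].mean()) < 1e-10
        for j in range(3):
            r = np.corrcoef(out[ref], Z[ref, j])[0, 1]
            assert abs(r) < 1e-10

    def test_singular_reference_design_errors(self, rng):
        Z = np.column_stack([np.ones(20)])
        with pytest.raises(ValueError, match="singular"):
            residualize(rng.normal(size=20), Z, np.ones(20, dtype=bool))


class TestRocAuc:
    def test_perfect_ranking(self):
        assert roc_auc([0.1, 0.2, 0.8, 0.9], [0, 0, 1, 1]) == 1.0

    def test_all_ties_give_half(self):
        assert roc_auc(np.ones(10), [0] * 5 + [1] * 5) == 0.5

    def test_equals_pairwise_mann_whitney_oracle(self, rng):
        scores = rng.normal(size=30).round(1)  # rounding forces ties
        labels = rng.integers(0, 2, 30)
        labels[:2] = [0, 1]
        pos, neg = scores[labels == 1], scores[labels == 0]
        wins = sum((p > n) + 0.5 * (p == n) for p in pos for n in neg)
        assert roc_auc(scores, labels) == pytest.approx(wins / (len(pos) * len(neg)), abs=1e-15)

    def test_single_class_errors(self):
        with pytest.raises(ValueError, match="both classes"):
            roc_auc([0.1, 0.9], [1, 1])


class TestCutoff:
    def test_prevalence_is_the_cutoff(self):
        assert derive_cutoff([0] * 75 + [1] * 25) == 0.25
        assert derive_cutoff([0, 1] * 10) == 0.5

    def test_single_class_fold_errors(self):
        with pytest.raises(ValueError, match="both"):
            derive_cutoff(np.zeros(10))

    def test_threshold_monotonicity(self, rng):
        probs = rng.random(200)
        labels = rng.random(200) < probs  # well-calibrated scores
        sens, spec = [], []
        for cut in np.linspace(0.05, 0.95, 19):
            se, sp = sensitivity_specificity(probs, labels, cut)
            sens.append(se)
            spec.append(sp)
        assert all(a >= b - 1e-12 for a, b in zip(sens, sens[1:]))
        assert all(a <= b + 1e-12 for a, b in zip(spec, spec[1:]))

    def test_zero_cutoff_calls_everyone_a_decliner(self, rng):
        probs = rng.random(50)
        labels = np.array([True] * 20 + [False] * 30)
        sens, spec = sensitivity_specificity(probs, labels, 0.0)
        assert sens == 1.0 and spec == 0.0


class TestCrossValidation:
    def test_near_separable_signal_gives_high_auc(self, rng):
        n = 400
        y = np.array([0] * 300 + [1] * 100)
        x = y + 0.01 * rng.normal(size=n)
        res = cv_single_feature_auc(x, y, None, n_folds=10, seed=0)
        assert res.mean_auc > 0.95
        assert res.mean_cutoff == pytest.approx(0.25, abs=0.01)

    def test_null_feature_gives_chance_auc(self, rng):
        n = 2000
        y = (rng.random(n) < 0.3).astype(int)
        x = rng.normal(size=n)
        res = cv_single_feature_auc(x, y, None, n_folds=10, seed=1)
        assert abs(res.mean_auc - 0.5) < 0.03

    def test_fixed_seed_is_deterministic(self, rng):
        n = 200
        y = (rng.random(n) < 0.3).astype(int)
        x = y * 0.8 + rng.normal(size=n)
        Z = rng.normal(size=(n, 2))
        a = cv_single_feature_auc(x, y, Z, n_folds=10, seed=7)
        b = cv_single_feature_auc(x, y, Z, n_folds=10, seed=7)
        assert a.fold_aucs == b.fold_aucs
        assert a.cutoff_per_fold == b.cutoff_per_fold

    def test_small_minority_class_errors(self, rng):
        y = np.array([1] * 5 + [0] * 95)
        with pytest.raises(ValueError, match="fewer"):
            cv_single_feature_auc(rng.normal(size=100), y, None, n_folds=10, seed=0)

    def test_string_labels_accepted(self, rng):
        n = 200
        y = np.where(rng.random(n) < 0.3, "decliner", "stable")
        x = (y == "decliner") * 1.0 + rng.normal(size=n)
        res = cv_single_feature_auc(x, y, None, n_folds=5, seed=0)
        assert 0.5 < res.mean_auc <= 1.0


class TestNormalTheoryRecovery:
    def test_cv_auc_tracks_phi_of_d_over_sqrt2(self):
        # two-Gaussian predictor with standardized separation d:
        # theoretical AUC = Phi(d / sqrt(2))
        aucs, theory = [], []
        for seed in range(5):
            rng = np.random.default_rng(1000 + seed)
            n = 400
            y = (rng.random(n) < 0.25).astype(int)
            x = 0.8 * y + rng.normal(size=n)
            pooled = np.sqrt(
                ((y == 1).sum() - 1) * x[y == 1].var(ddof=1)
                + ((y == 0).sum() - 1) * x[y == 0].var(ddof=1)
            ) / np.sqrt(n - 2)
            d = (x[y == 1].mean() - x[y == 0].mean()) / pooled
            theory.append(norm.cdf(d / np.sqrt(2)))
            aucs.append(cv_single_feature_auc(x, y, None, n_folds=10, seed=seed).mean_auc)
        assert abs(np.mean(aucs) - np.mean(theory)) < 0.05


class TestExternalValidation:
    def test_perfect_separation(self, rng):
        n = 300
        y_int = (rng.random(n) < 0.3).astype(int)
        x_int = y_int * 5.0 + 0.01 * rng.normal(size=n)
        res = cv_single_feature_auc(x_int, y_int, None, n_folds=10, seed=0)
        y_ext = np.array([0] * 60 + [1] * 20)
        x_ext = y_ext * 5.0 + 0.01 * np.random.default_rng(5).normal(size=80)
        out = validate_external(res, x_ext, y_ext, None)
        assert out["sensitivity"] == 1.0 and out["specificity"] == 1.0

    def test_unknown_labels_rejected(self, rng):
        y = np.array(["stable"] * 30 + ["decliner"] * 10 + ["unknown"])
        x = rng.normal(size=41)
        res = cv_single_feature_auc(
            np.r_[np.zeros(30), np.ones(10)], ["stable"] * 30 + ["decliner"] * 10,
            None, n_folds=5, seed=0,
        )
        with pytest.raises(ValueError, match="unknown"):
            validate_external(res, x, y, None)

    def test_synthetic_external_cohort_matches_internal_rates(self):
        spec = dict(
            n_subjects=400, group="MCI", bag_shift_mean=2.0, bag_shift_sd=3.0,
            progression_base_rate=0.15, progression_logodds_per_bag_year=0.5,
        )
        internal = generate_cohort(CohortSpec(seed=31, **spec))
        external = generate_cohort(CohortSpec(seed=32, **spec))

        def parts(c):
            y = (c.phenotype["progression_status"] == "decliner").to_numpy().astype(int)
            x = c.phenotype["latent_bag_true"].to_numpy()
            Z = np.column_stack([
                c.phenotype["age"],
                (c.phenotype["sex"] == "male").astype(float),
                c.phenotype["education"],
            ])
            return x, y, Z

        x, y, Z = parts(internal)
        res = cv_single_feature_auc(x, y, Z, n_folds=10, seed=0)
        xe, ye, Ze = parts(external)
        out = validate_external(res, xe, ye, Ze)
        assert abs(out["sensitivity"] - res.sensitivity) < 0.1
        assert abs(out["specificity"] - res.specificity) < 0.1
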