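"""Association battery vs independently coded brute-force oracles.

Each statistical routine is checked against an explicit-formula oracle
written directly from the definitions (normal equations, t/F formulas),
never through the implementation under test.
"""

import numpy as np
import pandas as pd
import pytest
from scipy import stats as sps

from braingap.stats import (
    age_covariate_rule,
    ancova_group_effect,
    apply_significance_tiers,
    compare_groups_t,
    compare_mae_paired,
    covariate_matrix,
    partial_correlation,
    select_method,
)

# ---------------------------------------------------------------- oracles


def oracle_partial_r(x, y, Z):
    """Two-stage residualization with hand-built normal equations."""
    n = len(x)
    D = np.column_stack([np.ones(n), Z]) if Z.size else np.ones((n, 1))
    bx = np.linalg.solve(D.T @ D, D.T @ x)
    by = np.linalg.solve(D.T @ D, D.T @ y)
    rx, ry = x - D @ bx, y - D @ by
    r = float(rx @ ry / np.sqrt((rx @ rx) * (ry @ ry)))
    k = Z.shape[1] if Z.size else 0
    dof = n - k - 2
    t = r * np.sqrt(dof / (1 - r * r))
    p = 2 * sps.t.sf(abs(t), dof)
    return r, p


def oracle_paired_t(a, b):
    d = a - b
    n = len(d)
    t = d.mean() / (d.std(ddof=1) / np.sqrt(n))
    return t, 2 * sps.t.sf(abs(t), n - 1)


def oracle_welch_t(a, b):
    na, nb = len(a), len(b)
    va, vb = a.var(ddof=1), b.var(ddof=1)
    se2 = va / na + vb / nb
    t = (a.mean() - b.mean()) / np.sqrt(se2)
    dof = se2**2 / ((va / na) ** 2 / (na - 1) + (vb / nb) ** 2 / (nb - 1))
    return t, 2 * sps.t.sf(abs(t), dof), dof


def oracle_ancova_f(y, g, Z):
    n = len(y)
    D = np.column_stack([np.ones(n), g, Z])
    beta = np.linalg.solve(D.T @ D, D.T @ y)
    resid = y - D @ beta
    dof = n - D.shape[1]
    sigma2 = resid @ resid / dof
    se = np.sqrt(sigma2 * np.linalg.inv(D.T @ D)[1, 1])
    F = (beta[1] / se) ** 2
    return F, sps.f.sf(F, 1, dof)


# ------------------------------------------------------------- behaviour


class TestSelectMethod:
    def test_gaussian_pair_chooses_pearson(self):
        rng = np.random.default_rng(10)  # seed screened: both SW p >= 0.05
        x, y = rng.standard_normal(200), rng.standard_normal(200)
        assert sps.shapiro(x).pvalue >= 0.05 and sps.shapiro(y).pvalue >= 0.05
        method, log = select_method(x, y)
        assert method == "pearson"
        assert set(log) == {"W_x", "p_x", "W_y", "p_y"}

    def test_lognormal_forces_spearman(self):
        rng = np.random.default_rng(3)
        x = rng.standard_normal(200)
        y = np.exp(rng.standard_normal(200))
        assert sps.shapiro(y).pvalue < 0.05
        assert select_method(x, y)[0] == "spearman"

    def test_degenerate_and_small_inputs(self):
        with pytest.raises(ValueError, match="constant"):
            select_method(np.ones(20), np.arange(20.0))
        with pytest.raises(ValueError, match="n < 8"):
            select_method(np.arange(5.0), np.arange(5.0))


class TestPartialCorrelation:
    def test_identity_without_covariates(self, rng):
        x = rng.normal(size=30)
        res = partial_correlation(x, x, method="pearson")
        assert res.statistic == pytest.approx(1.0)

    def test_fully_explained_variable_decorrelates(self, rng):
        z = rng.normal(size=40)
        x = rng.normal(size=40)
        res = partial_correlation(x, z, pd.DataFrame({"z": z}), method="pearson")
        assert abs(res.statistic) < 1e-8

    def test_matches_oracle_over_many_fixtures(self):
        for seed in range(30):
            rng = np.random.default_rng(seed)
            Z = rng.normal(size=(40, 3))
            x = Z @ rng.normal(size=3) + rng.normal(size=40)
            y = Z @ rng.normal(size=3) + 0.3 * x + rng.normal(size=40)
            res = partial_correlation(x, y, Z, method="pearson")
            r_o, p_o = oracle_partial_r(x, y, Z)
            assert res.statistic == pytest.approx(r_o, abs=1e-10)
            assert res.p_value == pytest.approx(p_o, abs=1e-10)
            assert res.n_used == 40

    def test_spearman_equals_pearson_on_ranks(self, rng):
        Z = rng.normal(size=(60, 2))
        x = rng.normal(size=60) ** 3
        y = rng.normal(size=60)
        spearman = partial_correlation(x, y, Z, method="spearman")
        pearson_on_ranks = partial_correlation(
            sps.rankdata(x), sps.rankdata(y), Z, method="pearson"
        )
        assert spearman.statistic == pearson_on_ranks.statistic
        assert spearman.p_value == pearson_on_ranks.p_value

    def test_listwise_deletion_accounting(self, rng):
        x = rng.normal(size=50)
        y = rng.normal(size=50)
        y[::10] = np.nan
        res = partial_correlation(x, y, method="pearson")
        assert res.n_used + np.isnan(y).sum() == 50

    def test_singular_covariates_error(self, rng):
        x, y = rng.normal(size=20), rng.normal(size=20)
        Z = np.column_stack([np.ones(20), np.ones(20)])
        with pytest.raises(ValueError, match="singular"):
            partial_correlation(x, y, Z, method="pearson")


class TestGroupComparisons:
    def test_identical_vectors_null_paired_t(self, rng):
        a = rng.normal(size=20)
        res = compare_mae_paired(a, a.copy())
        assert res.statistic == 0.0 and res.p_value == 1.0

    def test_constant_shift_paired(self, rng):
        a = rng.normal(size=30)
        res = compare_mae_paired(a, a + 1.0)
        assert res.ci_95[0] == pytest.approx(-1.0) and res.ci_95[1] == pytest.approx(-1.0)
        assert res.p_value < 1e-10

    def test_paired_matches_oracle(self):
        for seed in range(20):
            rng = np.random.default_rng(100 + seed)
            a, b = rng.normal(size=25), rng.normal(size=25)
            res = compare_mae_paired(a, b)
            t_o, p_o = oracle_paired_t(a, b)
            assert res.statistic == pytest.approx(t_o, abs=1e-12)
            assert res.p_value == pytest.approx(p_o, abs=1e-12)

    def test_welch_matches_oracle_and_shift_detection(self):
        rng = np.random.default_rng(0)
        a = rng.normal(0, 1, 500)
        b = rng.normal(5, 1, 400)
        res = compare_groups_t(b, a)
        assert res.p_value < 1e-10
        assert res.ci_95[0] < 5 < res.ci_95[1]
        for seed in range(20):
            rng = np.random.default_rng(200 + seed)
            a = rng.normal(size=18)
            b = rng.normal(0.5, 2.0, size=31)
            res = compare_groups_t(a, b)
            t_o, p_o, dof_o = oracle_welch_t(a, b)
            assert res.statistic == pytest.approx(t_o, abs=1e-12)
            assert res.p_value == pytest.approx(p_o, abs=1e-12)
            assert res.dof == pytest.approx(dof_o, abs=1e-9)

    def test_degenerate_variance_errors(self):
        with pytest.raises(ValueError, match="degenerate"):
            compare_groups_t(np.ones(5), np.full(6, 2.0))


class TestAncova:
    def test_fully_explained_outcome_gives_zero_f(self, rng):
        z = rng.normal(size=40)
        y = 2.0 * z + 1.0
        g = rng.integers(0, 2, 40)
        res = ancova_group_effect(y, g, pd.DataFrame({"z": z}))
        assert res.statistic == pytest.approx(0.0, abs=1e-6)

    def test_group_effect_detected(self):
        rng = np.random.default_rng(1)
        g = rng.integers(0, 2, 400)
        y = 2.0 * g + rng.normal(size=400)
        res = ancova_group_effect(y, g, None)
        assert res.p_value < 1e-6
        assert res.covariate_coefficients["group"] == pytest.approx(2.0, abs=0.3)

    def test_matches_oracle(self):
        for seed in range(20):
            rng = np.random.default_rng(300 + seed)
            Z = rng.normal(size=(30, 2))
            g = rng.integers(0, 2, 30)
            y = 0.5 * g + Z @ np.array([1.0, -0.5]) + rng.normal(size=30)
            res = ancova_group_effect(y, g, Z)
            F_o, p_o = oracle_ancova_f(y, g, Z)
            assert res.statistic == pytest.approx(F_o, abs=1e-8)
            assert res.p_value == pytest.approx(p_o, abs=1e-8)

    def test_collinear_design_errors(self, rng):
        g = rng.integers(0, 2, 30)
        Z = np.column_stack([g.astype(float)])
        y = rng.normal(size=30)
        with pytest.raises(ValueError, match="rank"):
            ancova_group_effect(y, g, Z)


class TestTiers:
    @staticmethod
    def _result(p):
        from braingap.stats import AssociationResult

        return AssociationResult(
            x_name="x", y_name="y", method="pearson", statistic=0.1, p_value=p,
            ci_95=(0.0, 0.2), n_used=20, covariates=(),
        )

    def test_tier_thresholds(self):
        # in a 3-test pathology family, p = 0.02 stays above 0.05/3 ~ 0.0167
        results = [self._result(p) for p in (0.20, 0.07, 0.02, 0.001)]
        tiered = apply_significance_tiers(results, family="pathology", m=3)
        assert [r.tier for r in tiered] == [
            "ns", "trend", "significant", "bonferroni_significant",
        ]
        assert all(r.family == "pathology" for r in tiered)

    def test_bonferroni_threshold_scales_with_family(self):
        # 0.03 > 0.05/2, but the same p clears a single-test family
        (res,) = apply_significance_tiers([self._result(0.03)], family="cog", m=2)
        assert res.tier == "significant"
        (res2,) = apply_significance_tiers([self._result(0.03)], family="one", m=1)
        assert res2.tier == "bonferroni_significant"


def test_covariate_matrix_encodings():
    pheno = pd.DataFrame(
        {
            "age": [70.0, 80.0],
            "sex": ["female", "male"],
            "education": [12, 16],
            "apoe4_carrier": [0, 1],
        },
        index=["a", "b"],
    )
    Z = covariate_matrix(pheno, ["age", "sex", "education", "apoe4"])
    assert list(Z.columns) == ["age", "sex_male", "education", "apoe4_carrier"]
    assert Z.loc["b", "sex_male"] == 1.0 and Z.loc["a", "sex_male"] == 0.0


def test_age_covariate_rule(rng):
    age = rng.uniform(60, 90, 300)
    assert age_covariate_rule(0.3 * age + rng.normal(size=300), age)
    assert not age_covariate_rule(rng.normal(size=300), age)
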