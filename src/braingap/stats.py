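"""Covariate-adjusted association battery and group comparisons.

Associations between BAG and cognition/pathology are partial correlations
adjusted for age, sex, education, and APOE-e4 carriership: both focal
variables are residualized on the covariates (with intercept) by least
squares and the residuals are correlated.  The method is chosen per pair by
Shapiro-Wilk normality of the two focal variables (Pearson if both pass at
alpha 0.05, Spearman otherwise); the Spearman variant rank-transforms the
focal variables first (average ranks for ties) and then runs the identical
partial-Pearson machinery.

Significance is tiered: p < 0.1 trend, p < 0.05 significant, and
Bonferroni-significant against alpha = 0.05/m within a named family of m
tests.

Group comparisons use a paired t-test (per-subject absolute errors across
modalities), Welch's two-sample t-test (unequal group sizes and variances
are the norm here), and ANCOVA: a linear model of the outcome on a binary
group indicator plus covariates, F-tested on the group term.
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np
import pandas as pd
from scipy import stats

__all__ = [
    "AssociationResult",
    "GroupComparisonResult",
    "select_method",
    "partial_correlation",
    "compare_mae_paired",
    "compare_groups_t",
    "ancova_group_effect",
    "apply_significance_tiers",
    "covariate_matrix",
    "age_covariate_rule",
]


@dataclass(frozen=True)
class AssociationResult:
    x_name: str
    y_name: str
    method: str  # pearson | spearman
    statistic: float
    p_value: float
    ci_95: tuple[float, float]
    n_used: int
    covariates: tuple[str, ...]
    tier: str = "untiered"
    family: str = ""

    def __post_init__(self) -> None:
        if not -1.0 - 1e-12 <= self.statistic <= 1.0 + 1e-12:
            raise ValueError(f"correlation statistic out of [-1, 1]: {self.statistic}")


@dataclass(frozen=True)
class GroupComparisonResult:
    groups: tuple[str, str]
    test: str  # paired_t | two_sample_t | ancova
    statistic: float
    dof: float | tuple[float, float]
    p_value: float
    ci_95: tuple[float, float] | None
    covariates: tuple[str, ...] = ()
    covariate_coefficients: dict | None = None


def covariate_matrix(phenotype: pd.DataFrame, names: list[str]) -> pd.DataFrame:
    """Build a numeric covariate matrix from a phenotype table.

    sex -> male indicator (0/1), apoe/apoe4 -> carrier indicator (0/1),
    education in years untransformed, anything else passed through as float.
    """
    cols = {}
    for name in names:
        if name == "sex":
            cols["sex_male"] = (phenotype["sex"].astype(str) == "male").astype(float)
        elif name in ("apoe", "apoe4", "apoe4_carrier"):
            cols["apoe4_carrier"] = phenotype["apoe4_carrier"].astype(float)
        else:
            cols[name] = phenotype[name].astype(float)
    return pd.DataFrame(cols, index=phenotype.index)


def select_method(x: np.ndarray, y: np.ndarray, alpha: float = 0.05) -> tuple[str, dict]:
    """Choose pearson vs spearman by Shapiro-Wilk normality of both
    variables; Pearson iff both p >= alpha.  Returns (method, log) where the
    log carries both W statistics and p-values."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.size < 8 or y.size < 8:
        raise ValueError("n < 8: too small for Shapiro-Wilk, choose the method explicitly")
    if np.ptp(x) == 0 or np.ptp(y) == 0:
        raise ValueError("constant variable: normality test degenerate")
    wx, px = stats.shapiro(x)
    wy, py = stats.shapiro(y)
    method = "pearson" if (px >= alpha and py >= alpha) else "spearman"
    return method, {"W_x": float(wx), "p_x": float(px), "W_y": float(wy), "p_y": float(py)}


def _residualize(v: np.ndarray, Z: np.ndarray) -> np.ndarray:
    """Residuals of v after least-squares projection on [1, Z]."""
    design = np.column_stack([np.ones(len(v)), Z]) if Z.size else np.ones((len(v), 1))
    coef, *_ = np.linalg.lstsq(design, v, rcond=None)
    return v - design @ coef


def partial_correlation(
    x: np.ndarray | pd.Series,
    y: np.ndarray | pd.Series,
    covariates: pd.DataFrame | np.ndarray | None = None,
    method: str = "auto",
    x_name: str = "x",
    y_name: str = "y",
) -> AssociationResult:
    """Covariate-adjusted correlation between x and y.

    Listwise deletion over x, y, and the covariates; p from the t
    distribution with n - k - 2 degrees of freedom (k covariates); 95% CI by
    Fisher z with standard error 1/sqrt(n - k - 3).
    """
    x = pd.Series(np.asarray(x, dtype=float))
    y = pd.Series(np.asarray(y, dtype=float))
    if covariates is None:
        Z = pd.DataFrame(index=x.index)
        cov_names: tuple[str, ...] = ()
    else:
        Z = pd.DataFrame(np.asarray(covariates, dtype=float))
        if isinstance(covariates, pd.DataFrame):
            cov_names = tuple(map(str, covariates.columns))
            Z.columns = list(cov_names)
        else:
            cov_names = tuple(f"cov_{i}" for i in range(Z.shape[1]))

    frame = pd.concat([x.rename("_x"), y.rename("_y"), Z.reset_index(drop=True)], axis=1)
    frame = frame.dropna()
    n = len(frame)
    k = Z.shape[1]
    if n <= k + 3:
        raise ValueError(f"insufficient n after listwise deletion: n={n}, covariates={k}")
    xv = frame["_x"].to_numpy()
    yv = frame["_y"].to_numpy()
    Zv = frame.iloc[:, 2:].to_numpy()
    if k and np.linalg.matrix_rank(np.column_stack([np.ones(n), Zv])) < k + 1:
        raise ValueError("singular covariate matrix")

    if method == "auto":
        method, _ = select_method(xv, yv)
    if method == "spearman":
        xv = stats.rankdata(xv)
        yv = stats.rankdata(yv)
    elif method != "pearson":
        raise ValueError(f"method must be auto/pearson/spearman, got {method!r}")

    rx = _residualize(xv, Zv)
    ry = _residualize(yv, Zv)
    # a focal variable fully explained by the covariates leaves only
    # round-off in its residual: the adjusted correlation is zero
    tiny_x = float(rx @ rx) <= 1e-20 * max(float(xv @ xv), 1.0)
    tiny_y = float(ry @ ry) <= 1e-20 * max(float(yv @ yv), 1.0)
    denom = np.sqrt(float(rx @ rx) * float(ry @ ry))
    if denom == 0 or tiny_x or tiny_y:
        r = 0.0
    else:
        r = float(rx @ ry / denom)
    dof = n - k - 2
    if abs(r) >= 1.0:
        p = 0.0
    else:
        t = r * np.sqrt(dof / (1.0 - r * r))
        p = float(2.0 * stats.t.sf(abs(t), dof))
    if n - k - 3 > 0 and abs(r) < 1.0:
        z = np.arctanh(r)
        half = stats.norm.ppf(0.975) / np.sqrt(n - k - 3)
        ci = (float(np.tanh(z - half)), float(np.tanh(z + half)))
    else:
        ci = (float(r), float(r))
    return AssociationResult(
        x_name=x_name,
        y_name=y_name,
        method=method,
        statistic=r,
        p_value=p,
        ci_95=ci,
        n_used=n,
        covariates=cov_names,
    )


def compare_mae_paired(abs_err_a: np.ndarray, abs_err_b: np.ndarray) -> GroupComparisonResult:
    """Paired two-sided t-test on per-subject absolute errors, with 95% CI
    of the mean difference a - b."""
    a = np.asarray(abs_err_a, dtype=float)
    b = np.asarray(abs_err_b, dtype=float)
    if a.shape != b.shape:
        raise ValueError(f"length mismatch: {a.shape} vs {b.shape}")
    if a.size < 3:
        raise ValueError("need at least 3 pairs")
    d = a - b
    n = d.size
    if np.all(d == d[0]) and d[0] == 0.0:  # identical inputs: no difference
        return GroupComparisonResult(
            groups=("a", "b"), test="paired_t", statistic=0.0,
            dof=float(n - 1), p_value=1.0, ci_95=(0.0, 0.0),
        )
    res = stats.ttest_rel(a, b)
    se = d.std(ddof=1) / np.sqrt(n)
    half = stats.t.ppf(0.975, n - 1) * se
    mean_d = float(d.mean())
    return GroupComparisonResult(
        groups=("a", "b"),
        test="paired_t",
        statistic=float(res.statistic),
        dof=float(n - 1),
        p_value=float(res.pvalue),
        ci_95=(mean_d - float(half), mean_d + float(half)),
    )


def compare_groups_t(values_a: np.ndarray, values_b: np.ndarray) -> GroupComparisonResult:
    """Welch two-sample t-test with Welch-Satterthwaite degrees of freedom
    and a 95% CI of the mean difference a - b."""
    a = np.asarray(values_a, dtype=float)
    a = a[~np.isnan(a)]
    b = np.asarray(values_b, dtype=float)
    b = b[~np.isnan(b)]
    if a.size < 3 or b.size < 3:
        raise ValueError("each group needs at least 3 values")
    va, vb = a.var(ddof=1), b.var(ddof=1)
    if va == 0 and vb == 0:
        raise ValueError("both groups degenerate (zero variance)")
    res = stats.ttest_ind(a, b, equal_var=False)
    se2 = va / a.size + vb / b.size
    dof = se2**2 / ((va / a.size) ** 2 / (a.size - 1) + (vb / b.size) ** 2 / (b.size - 1))
    half = stats.t.ppf(0.975, dof) * np.sqrt(se2)
    mean_d = float(a.mean() - b.mean())
    return GroupComparisonResult(
        groups=("a", "b"),
        test="two_sample_t",
        statistic=float(res.statistic),
        dof=float(dof),
        p_value=float(res.pvalue),
        ci_95=(mean_d - float(half), mean_d + float(half)),
    )


def ancova_group_effect(
    outcome: np.ndarray | pd.Series,
    group: np.ndarray | pd.Series,
    covariates: pd.DataFrame | np.ndarray | None = None,
) -> GroupComparisonResult:
    """Linear model outcome ~ group + covariates; F test on the binary
    group term (equivalent to the squared t of its coefficient), with the
    covariate coefficients reported."""
    y = pd.Series(np.asarray(outcome, dtype=float)).rename("_y")
    g = pd.Series(np.asarray(group)).rename("_g")
    if covariates is None or (hasattr(covariates, "shape") and np.size(covariates) == 0):
        Z = pd.DataFrame(index=y.index)
        cov_names: tuple[str, ...] = ()
    else:
        Z = pd.DataFrame(np.asarray(covariates, dtype=float))
        if isinstance(covariates, pd.DataFrame):
            cov_names = tuple(map(str, covariates.columns))
            Z.columns = list(cov_names)
        else:
            cov_names = tuple(f"cov_{i}" for i in range(Z.shape[1]))
    frame = pd.concat([y, g, Z.reset_index(drop=True)], axis=1).dropna()
    levels = sorted(pd.unique(frame["_g"]))
    if len(levels) != 2:
        raise ValueError(f"group must be binary after listwise deletion, got levels {levels}")
    gnum = (frame["_g"] == levels[1]).astype(float).to_numpy()
    yv = frame["_y"].to_numpy()
    Zv = frame.iloc[:, 2:].to_numpy()
    n = len(frame)
    k = Zv.shape[1]
    design = np.column_stack([np.ones(n), gnum, Zv])
    rank = np.linalg.matrix_rank(design)
    if rank < design.shape[1]:
        raise ValueError("rank-deficient ANCOVA design (collinear group/covariates)")
    coef, _, _, _ = np.linalg.lstsq(design, yv, rcond=None)
    resid = yv - design @ coef
    dof_resid = n - design.shape[1]
    sigma2 = float(resid @ resid) / dof_resid
    if float(resid @ resid) <= 1e-20 * max(float(yv @ yv), 1.0):
        F = 0.0  # covariates explain the outcome exactly
    else:
        xtx_inv = np.linalg.inv(design.T @ design)
        se_g = np.sqrt(sigma2 * xtx_inv[1, 1])
        t_g = coef[1] / se_g
        F = float(t_g**2)
    p = float(stats.f.sf(F, 1, dof_resid))
    cov_coefs = {name: float(c) for name, c in zip(cov_names, coef[2:])}
    return GroupComparisonResult(
        groups=(str(levels[0]), str(levels[1])),
        test="ancova",
        statistic=F,
        dof=(1.0, float(dof_resid)),
        p_value=p,
        ci_95=None,
        covariates=cov_names,
        covariate_coefficients={"group": float(coef[1]), **cov_coefs},
    )


def apply_significance_tiers(
    results: list[AssociationResult], family: str, m: int
) -> list[AssociationResult]:
    """Tier each result: ns, trend (p<0.1), significant (p<0.05),
    bonferroni_significant (p < 0.05/m within the family of m tests)."""
    if m < 1:
        raise ValueError("family size m must be >= 1")
    out = []
    for res in results:
        p = res.p_value
        if p < 0.05 / m:
            tier = "bonferroni_significant"
        elif p < 0.05:
            tier = "significant"
        elif p < 0.1:
            tier = "trend"
        else:
            tier = "ns"
        out.append(replace(res, tier=tier, family=family))
    return out


def age_covariate_rule(bag: np.ndarray, age: np.ndarray, alpha: float = 0.05) -> bool:
    """Whether age must enter the ANCOVA covariate set: True when the
    BAG-age correlation remains significant after bias correction."""
    mask = ~(np.isnan(np.asarray(bag, float)) | np.isnan(np.asarray(age, float)))
    r, p = stats.pearsonr(np.asarray(bag, float)[mask], np.asarray(age, float)[mask])
    return bool(p < alpha)
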