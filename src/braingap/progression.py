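"""Stable-vs-decliner progression prediction.

A single candidate predictor (e.g. BAG, a memory composite, hippocampal
volume) is assessed by stratified 10-fold cross-validated single-feature
logistic regression.  In each training fold the predictor is first
residualized on the covariates (age, sex, education, APOE) using a linear
model fit on the *stable* subjects of that training fold only; residuals are
computed for all subjects against that fit and standardized by the stable
subjects' residual SD.  Anchoring on the stable group means a predictor
whose covariate relationship differs in decliners keeps that signal.

The classification threshold is not 0.5: each training fold contributes a
cutoff equal to its a-priori decliner prevalence, and the mean cutoff is
applied to pooled validation-fold probabilities (internal) or to an external
cohort (with the residualization refit on the external stable group but the
internally derived cutoff kept fixed).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from sklearn.linear_model import LogisticRegression
from sklearn.metrics import roc_auc_score
from sklearn.model_selection import StratifiedKFold

__all__ = [
    "ProgressionCVResult",
    "residualize",
    "roc_auc",
    "derive_cutoff",
    "cv_single_feature_auc",
    "classify_at_cutoff",
    "sensitivity_specificity",
    "validate_external",
]


@dataclass
class ProgressionCVResult:
    predictor_name: str
    fold_aucs: list[float]
    mean_auc: float
    cutoff_per_fold: list[float]
    mean_cutoff: float
    cutoff_range: tuple[float, float]
    sensitivity: float
    specificity: float
    n_folds: int
    seed: int
    covariates: tuple[str, ...]
    # final model refit on all rows for external validation
    final_coef: tuple[float, float] = (0.0, 0.0)  # (intercept, slope)
    pooled_scores: pd.Series | None = field(default=None, repr=False)


def residualize(
    values: np.ndarray,
    covariates: np.ndarray | pd.DataFrame | None,
    reference_mask: np.ndarray,
) -> np.ndarray:
    """Standardized residuals of ``values`` against a covariate model fit on
    the reference rows only.

    The linear model (with intercept) is fit by least squares on the
    reference subset; residuals are computed for ALL rows against that fit
    and divided by the reference-group residual standard deviation (ddof=1).
    Reference residuals therefore have mean 0 and SD 1.
    """
    v = np.asarray(values, dtype=float)
    ref = np.asarray(reference_mask, dtype=bool)
    if covariates is None:
        Z = np.empty((len(v), 0))
    else:
        Z = np.asarray(covariates, dtype=float)
        if Z.ndim == 1:
            Z = Z[:, None]
    n_ref = int(ref.sum())
    if n_ref <= Z.shape[1] + 2:
        raise ValueError(f"reference subset too small: {n_ref} rows for {Z.shape[1]} covariates")
    design = np.column_stack([np.ones(len(v)), Z])
    d_ref = design[ref]
    if np.linalg.matrix_rank(d_ref) < design.shape[1]:
        raise ValueError("singular covariate design on the reference rows")
    coef, *_ = np.linalg.lstsq(d_ref, v[ref], rcond=None)
    resid = v - design @ coef
    ref_ss = float(resid[ref] @ resid[ref])
    if ref_ss <= 1e-20 * max(float(v[ref] @ v[ref]), 1.0):
        # reference fit is exact up to round-off: scaling by the (noise)
        # SD would amplify junk, so leave the residuals unscaled
        return resid
    return resid / resid[ref].std(ddof=1)


def roc_auc(scores: np.ndarray, labels: np.ndarray) -> float:
    """Area under the ROC curve; equals the Mann-Whitney probability that a
    random positive outscores a random negative, ties counted one half."""
    y = np.asarray(labels)
    if len(np.unique(y)) < 2:
        raise ValueError("roc_auc needs both classes present")
    return float(roc_auc_score(y, np.asarray(scores, dtype=float)))


def derive_cutoff(training_labels: np.ndarray) -> float:
    """A-priori-probability cutoff: the decliner fraction of the training
    fold.  A subject is classified decliner iff predicted probability >=
    this cutoff."""
    y = np.asarray(training_labels, dtype=float)
    frac = float(y.mean())
    if frac <= 0.0 or frac >= 1.0:
        raise ValueError("training fold must contain both stable and decliner subjects")
    return frac


def classify_at_cutoff(probabilities: np.ndarray, cutoff: float) -> np.ndarray:
    return np.asarray(probabilities, dtype=float) >= cutoff


def sensitivity_specificity(
    probabilities: np.ndarray, labels: np.ndarray, cutoff: float
) -> tuple[float, float]:
    """(true decliner rate among decliners, true stable rate among stables)
    at the given probability cutoff."""
    y = np.asarray(labels, dtype=bool)
    if y.all() or not y.any():
        raise ValueError("need both classes to compute sensitivity and specificity")
    called = classify_at_cutoff(probabilities, cutoff)
    sens = float(called[y].mean())
    spec = float((~called[~y]).mean())
    return sens, spec


def _fit_logistic(x: np.ndarray, y: np.ndarray) -> LogisticRegression:
    # Essentially unpenalized: a real penalty would shrink probabilities
    # and distort the prevalence-based cutoff.  The tiny ridge only guards
    # against separable folds.
    clf = LogisticRegression(C=1e8, solver="lbfgs", max_iter=2000)
    clf.fit(x[:, None], y)
    return clf


def cv_single_feature_auc(
    feature: np.ndarray | pd.Series,
    labels: np.ndarray | pd.Series,
    covariates: pd.DataFrame | np.ndarray | None = None,
    n_folds: int = 10,
    seed: int = 0,
    predictor_name: str = "predictor",
) -> ProgressionCVResult:
    """Stratified k-fold single-feature logistic classification of
    stable vs decliner, with per-training-fold stable-anchored
    residualization; returns fold AUCs, the prevalence cutoffs, and
    sensitivity/specificity of pooled validation predictions at the mean
    cutoff."""
    x = np.asarray(feature, dtype=float)
    lab = np.asarray(labels)
    if lab.dtype.kind in "UOS":
        y = (lab == "decliner").astype(int)
        if not set(np.unique(lab)) <= {"stable", "decliner"}:
            raise ValueError("labels must be 'stable'/'decliner' (or 0/1)")
    else:
        y = np.asarray(lab, dtype=int)
    if covariates is not None:
        Z = np.asarray(covariates, dtype=float)
        cov_names = (
            tuple(map(str, covariates.columns))
            if isinstance(covariates, pd.DataFrame)
            else tuple(f"cov_{i}" for i in range(Z.shape[1]))
        )
    else:
        Z = None
        cov_names = ()
    counts = np.bincount(y, minlength=2)
    if counts.min() < n_folds:
        raise ValueError(
            f"minority class has {counts.min()} members, fewer than n_folds={n_folds}; "
            "use fewer folds"
        )

    skf = StratifiedKFold(n_splits=n_folds, shuffle=True, random_state=seed % (2**31 - 1))
    fold_aucs: list[float] = []
    cutoffs: list[float] = []
    pooled_probs = np.full(len(y), np.nan)
    for tr, va in skf.split(x[:, None], y):
        stable_ref = np.zeros(len(y), dtype=bool)
        stable_ref[tr] = y[tr] == 0
        resid = residualize(x, Z, stable_ref)
        clf = _fit_logistic(resid[tr], y[tr])
        probs = clf.predict_proba(resid[va][:, None])[:, 1]
        fold_aucs.append(roc_auc(probs, y[va]))
        cutoffs.append(derive_cutoff(y[tr]))
        pooled_probs[va] = probs

    mean_cutoff = float(np.mean(cutoffs))
    sens, spec = sensitivity_specificity(pooled_probs, y.astype(bool), mean_cutoff)

    # refit on all rows (stable-anchored residualization over the full
    # sample) so the model can be carried to an external cohort
    resid_all = residualize(x, Z, y == 0)
    final = _fit_logistic(resid_all, y)
    return ProgressionCVResult(
        predictor_name=predictor_name,
        fold_aucs=[float(a) for a in fold_aucs],
        mean_auc=float(np.mean(fold_aucs)),
        cutoff_per_fold=cutoffs,
        mean_cutoff=mean_cutoff,
        cutoff_range=(float(np.min(cutoffs)), float(np.max(cutoffs))),
        sensitivity=sens,
        specificity=spec,
        n_folds=n_folds,
        seed=seed,
        covariates=cov_names,
        final_coef=(float(final.intercept_[0]), float(final.coef_[0, 0])),
        pooled_scores=pd.Series(pooled_probs),
    )


def validate_external(
    result: ProgressionCVResult,
    feature: np.ndarray | pd.Series,
    labels: np.ndarray | pd.Series,
    covariates: pd.DataFrame | np.ndarray | None = None,
) -> dict:
    """Apply an internally trained classifier and its mean cutoff to an
    external cohort.

    The covariate residualization is refit on the external stable group (the
    covariate-predictor relationship is cohort-specific) but the logistic
    coefficients and the internally derived mean cutoff are carried over
    unchanged.
    """
    x = np.asarray(feature, dtype=float)
    lab = np.asarray(labels)
    if lab.dtype.kind in "UOS":
        known = np.isin(lab, ("stable", "decliner"))
        if not known.all():
            raise ValueError("external cohort has subjects with unknown progression labels")
        y = (lab == "decliner").astype(int)
    else:
        y = np.asarray(lab, dtype=int)
    Z = None if covariates is None else np.asarray(covariates, dtype=float)
    resid = residualize(x, Z, y == 0)
    b0, b1 = result.final_coef
    probs = 1.0 / (1.0 + np.exp(-(b0 + b1 * resid)))
    auc = roc_auc(probs, y)
    sens, spec = sensitivity_specificity(probs, y.astype(bool), result.mean_cutoff)
    return {"auc": auc, "sensitivity": sens, "specificity": spec, "n": int(len(y)),
            "cutoff": result.mean_cutoff}
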