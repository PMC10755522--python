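"""Nested cross-validated brain age estimation.

The estimator is trained on cognitively normal subjects to predict
chronological age from regional features, with an outer/inner
cross-validation:

1. split training subjects into ``n_outer_folds`` outer folds;
2. per outer fold, remove multivariate outliers from the outer-train
   portion only (Tukey fences, IQR multiplier 6, per feature);
3. run an inner cross-validation over every candidate
   (algorithm, hyperparameters) pair — support vector regression and
   relevance vector regression — and select the pair with the lowest mean
   inner-validation MAE;
4. refit the winner on the full cleaned outer-train set and predict the
   outer-validation fold;
5. estimate age-bias correction parameters from those outer-validation
   predictions.

Brain-age predictions regress to the mean: young subjects are over- and old
subjects under-estimated, so the uncorrected brain-age gap (BAG = predicted
minus chronological age) correlates negatively with age.  The correction
fits BAG = alpha * age + beta by ordinary least squares on validation-fold
predictions and subtracts the fitted trend, which for a perfect predictor
gives (alpha, beta) = (0, 0).

Inference on an external cohort applies each fold model, corrects each
prediction with that fold's (alpha, beta), and averages the five corrected
estimates (ensemble averaging).  On the training cohort itself, each subject
instead receives the single prediction from the one fold model that did not
train on it (held-out mode).
"""

from __future__ import annotations

import hashlib
import pickle
import warnings
from dataclasses import dataclass
from pathlib import Path
from typing import Any

import numpy as np
import pandas as pd
from sklearn.exceptions import ConvergenceWarning
from sklearn.metrics import r2_score
from sklearn.model_selection import KFold
from sklearn.pipeline import Pipeline
from sklearn.preprocessing import StandardScaler
from sklearn.svm import SVR

from .rvm import RVR
from .synthetic import Cohort

__all__ = [
    "BAEConfig",
    "FoldModel",
    "BAEEnsemble",
    "EvalMetrics",
    "detect_outliers",
    "estimate_bias_params",
    "apply_bias_correction",
    "fit_nested",
    "predict_cohort",
    "save_ensemble",
    "load_ensemble",
]


def default_grid() -> dict[str, list[dict[str, Any]]]:
    """Candidate hyperparameter grids per algorithm.

    Small grids: kernel methods on ~90 standardized features need little
    tuning, and linear kernels dominate in practice for monotone aging
    signal.
    """
    svr = [
        {"kernel": k, "C": float(c), "epsilon": e}
        for k in ("linear", "rbf")
        for c in 10.0 ** np.arange(-3, 4)
        for e in (0.01, 0.1, 1.0)
    ]
    rvr = [{"kernel": k} for k in ("linear", "rbf")]
    return {"SVR": svr, "RVR": rvr}


@dataclass(frozen=True)
class BAEConfig:
    n_outer_folds: int = 5
    n_inner_folds: int = 5
    candidate_algorithms: tuple[str, ...] = ("SVR", "RVR")
    hyperparameter_grid: dict[str, list[dict[str, Any]]] | None = None
    outlier_iqr_multiplier: float = 6.0
    pooled_bias: bool = False  # sensitivity variant: one (alpha, beta) for all folds
    seed: int = 0

    def validate(self) -> None:
        if self.n_outer_folds < 2 or self.n_inner_folds < 2:
            raise ValueError("n_outer_folds and n_inner_folds must both be >= 2")
        if self.outlier_iqr_multiplier <= 0:
            raise ValueError("outlier_iqr_multiplier must be > 0")
        bad = set(self.candidate_algorithms) - {"SVR", "RVR"}
        if bad:
            raise ValueError(f"unknown candidate algorithms: {sorted(bad)}")
        if not self.candidate_algorithms:
            raise ValueError("candidate_algorithms must be non-empty")
        grid = self.resolved_grid()
        for algo in self.candidate_algorithms:
            if not grid.get(algo):
                raise ValueError(f"empty hyperparameter grid for {algo}")

    def resolved_grid(self) -> dict[str, list[dict[str, Any]]]:
        return self.hyperparameter_grid if self.hyperparameter_grid is not None else default_grid()

    def fingerprint(self) -> str:
        payload = repr(
            (
                self.n_outer_folds,
                self.n_inner_folds,
                self.candidate_algorithms,
                sorted((a, sorted(map(sorted_items, g))) for a, g in self.resolved_grid().items()),
                self.outlier_iqr_multiplier,
                self.pooled_bias,
                self.seed,
            )
        )
        return hashlib.sha256(payload.encode()).hexdigest()[:16]


def sorted_items(d: dict) -> tuple:
    return tuple(sorted(d.items()))


@dataclass
class FoldModel:
    fold_index: int
    chosen_algorithm: str
    chosen_hyperparameters: dict[str, Any]
    estimator: Pipeline
    bias_alpha: float
    bias_beta: float
    inner_validation_mae: float
    outer_validation_mae: float
    outlier_ids: list[str]
    validation_ids: list[str]
    train_ids: list[str]


@dataclass
class BAEEnsemble:
    fold_models: list[FoldModel]
    modality_tag: str
    config: BAEConfig
    region_names: list[str]
    fingerprint: str = ""

    def __post_init__(self) -> None:
        if len(self.fold_models) != self.config.n_outer_folds:
            raise ValueError("ensemble must hold exactly n_outer_folds fold models")

    @property
    def training_ids(self) -> list[str]:
        out: list[str] = []
        for fm in self.fold_models:
            out.extend(fm.validation_ids)
        return out

    @property
    def outlier_ids(self) -> set[str]:
        ids: set[str] = set()
        for fm in self.fold_models:
            ids.update(fm.outlier_ids)
        return ids


@dataclass(frozen=True)
class EvalMetrics:
    mae: float
    r_squared: float
    bag_range: tuple[float, float]
    mean_bag: float
    n: int

    def __post_init__(self) -> None:
        if self.mae < 0 or self.n <= 0:
            raise ValueError("invalid metrics: mae must be >= 0 and n > 0")


def detect_outliers(train_features: np.ndarray | pd.DataFrame, multiplier: float = 6.0) -> np.ndarray:
    """Flag subjects with ANY feature outside the per-feature Tukey fences
    [Q1 - m*IQR, Q3 + m*IQR], quartiles computed over these subjects only.

    Zero-spread features flag only values that differ from the common value
    by more than 1e-12 absolute.
    """
    X = np.asarray(train_features, dtype=float)
    if X.ndim != 2 or X.shape[0] < 5:
        raise ValueError("outlier detection needs a 2-D matrix with at least 5 subjects")
    if multiplier <= 0:
        raise ValueError("multiplier must be > 0")
    q1 = np.percentile(X, 25, axis=0)
    q3 = np.percentile(X, 75, axis=0)
    iqr = q3 - q1
    lo = np.where(iqr > 0, q1 - multiplier * iqr, q1 - 1e-12)
    hi = np.where(iqr > 0, q3 + multiplier * iqr, q3 + 1e-12)
    return ((X < lo) | (X > hi)).any(axis=1)


def estimate_bias_params(
    validation_ages: np.ndarray, validation_predictions: np.ndarray
) -> tuple[float, float]:
    """OLS fit of uncorrected BAG (prediction - age) on age.

    Returns (alpha, beta) with BAG = alpha*age + beta; a perfect predictor
    yields (0, 0).
    """
    age = np.asarray(validation_ages, dtype=float)
    pred = np.asarray(validation_predictions, dtype=float)
    if age.shape != pred.shape or age.size < 3:
        raise ValueError("need at least 3 matched (age, prediction) pairs")
    if np.var(age) == 0:
        raise ValueError("zero age variance: bias parameters unidentifiable")
    bag = pred - age
    alpha, beta = np.polyfit(age, bag, 1)
    return float(alpha), float(beta)


def apply_bias_correction(
    raw_prediction: np.ndarray | float,
    age: np.ndarray | float,
    alpha: float,
    beta: float,
) -> np.ndarray | float:
    """corrected = raw - (alpha*age + beta)."""
    raw = np.asarray(raw_prediction, dtype=float)
    age = np.asarray(age, dtype=float)
    if not (np.all(np.isfinite(raw)) and np.all(np.isfinite(age)) and np.isfinite(alpha) and np.isfinite(beta)):
        raise ValueError("non-finite input to bias correction")
    out = raw - (alpha * age + beta)
    return float(out) if out.ndim == 0 else out


def _make_estimator(algorithm: str, params: dict[str, Any]) -> Pipeline:
    # z-standardization uses outer-train statistics only (fit inside the
    # pipeline) so there is no validation leakage.
    if algorithm == "SVR":
        # iteration cap: libsvm crawls for heavily under-regularized linear
        # fits on noisy data; those candidates lose the inner CV anyway
        reg = SVR(max_iter=5_000, **params)
    elif algorithm == "RVR":
        reg = RVR(**params)
    else:
        raise ValueError(f"unknown algorithm {algorithm!r}")
    return Pipeline([("scale", StandardScaler()), ("reg", reg)])


def _candidates(config: BAEConfig) -> list[tuple[str, dict[str, Any]]]:
    """Deterministic candidate order: SVR before RVR, then lexicographic
    hyperparameters — this is also the tie-break order."""
    grid = config.resolved_grid()
    out: list[tuple[str, dict[str, Any]]] = []
    order = [a for a in ("SVR", "RVR") if a in config.candidate_algorithms]
    for algo in order:
        for params in sorted(grid[algo], key=sorted_items):
            out.append((algo, params))
    return out


def fit_nested(train_cohort: Cohort, config: BAEConfig | None = None) -> BAEEnsemble:
    """Train the full nested-CV ensemble on a (typically CN) cohort."""
    config = config or BAEConfig()
    config.validate()
    n = train_cohort.n_subjects
    if n < 5 * config.n_outer_folds:
        raise ValueError(
            f"need at least {5 * config.n_outer_folds} subjects for "
            f"{config.n_outer_folds} outer folds, got {n}"
        )
    X = train_cohort.features.to_numpy(dtype=float)
    age = train_cohort.phenotype["age"].to_numpy(dtype=float)
    ids = np.asarray(train_cohort.subject_ids)
    base_seed = config.seed % (2**31 - 1)

    outer = KFold(config.n_outer_folds, shuffle=True, random_state=base_seed)
    candidates = _candidates(config)
    fold_models: list[FoldModel] = []
    for fold_index, (tr_idx, va_idx) in enumerate(outer.split(X), start=1):
        X_tr, age_tr = X[tr_idx], age[tr_idx]
        if np.var(age_tr) == 0 or np.var(age[va_idx]) == 0:
            raise ValueError(f"degenerate fold {fold_index}: constant ages")
        mask = detect_outliers(X_tr, config.outlier_iqr_multiplier)
        keep = ~mask
        X_clean, age_clean = X_tr[keep], age_tr[keep]

        inner = KFold(
            config.n_inner_folds,
            shuffle=True,
            random_state=(base_seed + 7919 * fold_index) % (2**31 - 1),
        )
        inner_splits = list(inner.split(X_clean))
        maes = np.empty(len(candidates))
        with warnings.catch_warnings():
            warnings.filterwarnings("ignore", category=ConvergenceWarning)
            for ci, (algo, params) in enumerate(candidates):
                errs = []
                for itr, iva in inner_splits:
                    est = _make_estimator(algo, params)
                    est.fit(X_clean[itr], age_clean[itr])
                    pred = est.predict(X_clean[iva])
                    errs.append(float(np.mean(np.abs(pred - age_clean[iva]))))
                maes[ci] = np.mean(errs)
            best = int(np.argmin(maes))  # first minimum respects tie-break order
            algo, params = candidates[best]

            est = _make_estimator(algo, params)
            est.fit(X_clean, age_clean)
            va_pred = est.predict(X[va_idx])
        alpha, beta = estimate_bias_params(age[va_idx], va_pred)
        outer_mae = float(np.mean(np.abs(va_pred - age[va_idx])))
        fold_models.append(
            FoldModel(
                fold_index=fold_index,
                chosen_algorithm=algo,
                chosen_hyperparameters=dict(params),
                estimator=est,
                bias_alpha=alpha,
                bias_beta=beta,
                inner_validation_mae=float(maes[best]),
                outer_validation_mae=outer_mae,
                outlier_ids=[str(s) for s in ids[tr_idx][mask]],
                validation_ids=[str(s) for s in ids[va_idx]],
                train_ids=[str(s) for s in ids[tr_idx][keep]],
            )
        )

    if config.pooled_bias:
        ages_all = np.concatenate([age[np.isin(ids, fm.validation_ids)] for fm in fold_models])
        preds_all = np.concatenate(
            [fm.estimator.predict(X[np.isin(ids, fm.validation_ids)]) for fm in fold_models]
        )
        alpha, beta = estimate_bias_params(ages_all, preds_all)
        for fm in fold_models:
            fm.bias_alpha, fm.bias_beta = alpha, beta

    return BAEEnsemble(
        fold_models=fold_models,
        modality_tag=train_cohort.modality_tag,
        config=config,
        region_names=list(train_cohort.features.columns),
        fingerprint=config.fingerprint(),
    )


def _metrics(pred_table: pd.DataFrame) -> EvalMetrics:
    sub = pred_table.dropna(subset=["corrected_predicted_age", "chronological_age"])
    age = sub["chronological_age"].to_numpy(dtype=float)
    corr = sub["corrected_predicted_age"].to_numpy(dtype=float)
    bag = sub["bag"].to_numpy(dtype=float)
    return EvalMetrics(
        mae=float(np.mean(np.abs(corr - age))),
        r_squared=float(r2_score(age, corr)),
        bag_range=(float(bag.min()), float(bag.max())),
        mean_bag=float(bag.mean()),
        n=int(len(sub)),
    )


def predict_cohort(
    ensemble: BAEEnsemble, cohort: Cohort, mode: str = "ensemble_average"
) -> tuple[pd.DataFrame, EvalMetrics]:
    """Predict brain age for a cohort.

    ``held_out`` (training cohort only): each non-outlier subject gets the
    one prediction from the fold whose model never saw it, corrected with
    that fold's bias parameters.  ``ensemble_average``: every fold model
    predicts every subject; each prediction is corrected per fold and the
    corrected estimates are averaged.
    """
    if cohort.modality_tag != ensemble.modality_tag:
        raise ValueError(
            f"modality mismatch: ensemble is {ensemble.modality_tag}, cohort is {cohort.modality_tag}"
        )
    if list(cohort.features.columns) != ensemble.region_names:
        raise ValueError("cohort feature columns do not match the ensemble's atlas regions")
    X = cohort.features.to_numpy(dtype=float)
    age = cohort.phenotype["age"].to_numpy(dtype=float)
    ids = cohort.subject_ids

    if mode == "held_out":
        known = set(ensemble.training_ids)
        unknown = [s for s in ids if s not in known]
        if unknown:
            raise ValueError(
                "held_out mode is only valid for the training cohort; "
                f"{len(unknown)} subjects were never in a validation fold"
            )
        rows = []
        pos = {s: i for i, s in enumerate(ids)}
        outliers = ensemble.outlier_ids
        for fm in ensemble.fold_models:
            keep = [s for s in fm.validation_ids if s in pos and s not in outliers]
            if not keep:
                continue
            idx = np.asarray([pos[s] for s in keep])
            raw = fm.estimator.predict(X[idx])
            corrected = apply_bias_correction(raw, age[idx], fm.bias_alpha, fm.bias_beta)
            for s, a, r, c in zip(keep, age[idx], raw, corrected):
                rows.append((s, a, r, c))
        table = pd.DataFrame(
            rows,
            columns=["subject_id", "chronological_age", "raw_predicted_age", "corrected_predicted_age"],
        ).set_index("subject_id")
        table = table.loc[[s for s in ids if s in table.index]]
        table["bag"] = table["corrected_predicted_age"] - table["chronological_age"]
        table["source"] = "held_out"
    elif mode == "ensemble_average":
        raw_all = np.stack([fm.estimator.predict(X) for fm in ensemble.fold_models])
        corr_all = np.stack(
            [
                apply_bias_correction(raw_all[i], age, fm.bias_alpha, fm.bias_beta)
                for i, fm in enumerate(ensemble.fold_models)
            ]
        )
        final = corr_all.mean(axis=0)
        table = pd.DataFrame(
            {
                "chronological_age": age,
                "raw_predicted_age": raw_all.mean(axis=0),
                "corrected_predicted_age": final,
            },
            index=ids,
        )
        table["bag"] = table["corrected_predicted_age"] - table["chronological_age"]
        for i in range(corr_all.shape[0]):
            table[f"fold_{i + 1}"] = corr_all[i]
        table["source"] = "ensemble"
    else:
        raise ValueError(f"mode must be 'held_out' or 'ensemble_average', got {mode!r}")

    return table, _metrics(table)


def save_ensemble(ensemble: BAEEnsemble, path: str | Path) -> None:
    """Serialize the ensemble (fold models + config + atlas fingerprint)."""
    with open(path, "wb") as fh:
        pickle.dump(ensemble, fh, protocol=4)


def load_ensemble(path: str | Path) -> BAEEnsemble:
    with open(path, "rb") as fh:
        obj = pickle.load(fh)
    if not isinstance(obj, BAEEnsemble):
        raise ValueError(f"{path} does not contain a BAEEnsemble")
    return obj
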