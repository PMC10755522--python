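"""Permutation feature importance of the trained ensembles.

The importance of a region (delta) is the increase in mean absolute error,
in years, when that region's feature column is randomly permuted across the
evaluation subjects — higher delta means the model leans on the region more.
Each fold model is evaluated on its own outer-validation subjects (never
in-sample), repeats are averaged, and fold maps are averaged into one map
per modality.  Maps can then be summarized anatomically (median per lobe,
hemisphere, or lobe-by-hemisphere) and compared across modalities with a
Pearson correlation over regions.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .model import BAEEnsemble, FoldModel
from .synthetic import Cohort

__all__ = [
    "ImportanceMap",
    "permutation_importance",
    "ensemble_importance",
    "summarize_by_anatomy",
    "compare_maps",
]


@dataclass
class ImportanceMap:
    delta: pd.Series  # one value per region, units: years of MAE increase
    n_repeats: int
    seed: int
    fold_indices: list[int]

    def __post_init__(self) -> None:
        if self.delta.index.has_duplicates:
            raise ValueError("duplicate regions in importance map")


def permutation_importance(
    fold_model: FoldModel,
    eval_features: pd.DataFrame,
    eval_ages: np.ndarray,
    n_repeats: int = 10,
    seed: int = 0,
) -> pd.Series:
    """Per-region MAE increase on an evaluation set disjoint from training.

    Corrected predictions are used throughout: the bias term is a function
    of age only, so it shifts the baseline and permuted errors identically
    in expectation but keeps delta in the model's operational output scale.
    """
    if n_repeats < 1:
        raise ValueError("n_repeats must be >= 1")
    X = eval_features.to_numpy(dtype=float)
    age = np.asarray(eval_ages, dtype=float)
    n_features = len(fold_model.estimator.named_steps["scale"].mean_)
    if X.shape[1] != n_features:
        raise ValueError(
            f"region count mismatch: model expects {n_features}, got {X.shape[1]}"
        )
    overlap = set(eval_features.index) & set(fold_model.train_ids)
    if overlap:
        raise ValueError(f"evaluation set overlaps the model's training subjects: {sorted(overlap)[:3]}...")

    def corrected_mae(mat: np.ndarray) -> float:
        pred = fold_model.estimator.predict(mat)
        corrected = pred - (fold_model.bias_alpha * age + fold_model.bias_beta)
        return float(np.mean(np.abs(corrected - age)))

    baseline = corrected_mae(X)
    rng = np.random.default_rng(seed)
    delta = np.zeros(X.shape[1])
    for _ in range(n_repeats):
        for j in range(X.shape[1]):
            perm = rng.permutation(X.shape[0])
            Xp = X.copy()
            Xp[:, j] = X[perm, j]
            delta[j] += corrected_mae(Xp) - baseline
    delta /= n_repeats
    return pd.Series(delta, index=eval_features.columns, name="delta")


def ensemble_importance(
    ensemble: BAEEnsemble,
    train_cohort: Cohort,
    n_repeats: int = 10,
    seed: int = 0,
) -> ImportanceMap:
    """Average the per-fold importance maps, each fold evaluated on its own
    outer-validation subjects of the training cohort."""
    maps = []
    for fm in ensemble.fold_models:
        ids = [s for s in fm.validation_ids if s in train_cohort.subject_ids]
        feats = train_cohort.features.loc[ids]
        ages = train_cohort.phenotype.loc[ids, "age"].to_numpy(dtype=float)
        maps.append(
            permutation_importance(fm, feats, ages, n_repeats=n_repeats, seed=seed + fm.fold_index)
        )
    delta = pd.concat(maps, axis=1).mean(axis=1)
    delta.name = "delta"
    return ImportanceMap(
        delta=delta,
        n_repeats=n_repeats,
        seed=seed,
        fold_indices=[fm.fold_index for fm in ensemble.fold_models],
    )


def summarize_by_anatomy(
    imap: ImportanceMap, atlas: pd.DataFrame, grouping: str = "lobe"
) -> pd.Series:
    """Median delta per anatomical group.

    ``grouping`` is 'lobe', 'hemisphere', or 'lobe_by_hemisphere'.
    """
    if grouping not in ("lobe", "hemisphere", "lobe_by_hemisphere"):
        raise ValueError(f"unknown grouping {grouping!r}")
    mapped = atlas.set_index("region_name")
    unmapped = [r for r in imap.delta.index if r not in mapped.index]
    if unmapped:
        raise ValueError(f"regions not in atlas map: {unmapped}")
    df = pd.DataFrame({"delta": imap.delta})
    df["lobe"] = mapped.loc[df.index, "lobe"].to_numpy()
    df["hemisphere"] = mapped.loc[df.index, "hemisphere"].to_numpy()
    if grouping == "lobe_by_hemisphere":
        keys = [df["lobe"], df["hemisphere"]]
    else:
        keys = [df[grouping]]
    return df.groupby(keys, observed=True)["delta"].median()


def compare_maps(map_a: ImportanceMap, map_b: ImportanceMap) -> dict:
    """Pearson correlation of two importance maps over regions, with
    two-sided p and Fisher-z 95% CI."""
    if not map_a.delta.index.equals(map_b.delta.index):
        raise ValueError("importance maps are on different atlases")
    a = map_a.delta.to_numpy(dtype=float)
    b = map_b.delta.to_numpy(dtype=float)
    if np.std(a) == 0 or np.std(b) == 0:
        raise ValueError("zero variance in an importance map; correlation undefined")
    r, p = stats.pearsonr(a, b)
    n = len(a)
    z = np.arctanh(np.clip(r, -1 + 1e-15, 1 - 1e-15))
    half = stats.norm.ppf(0.975) / np.sqrt(n - 3)
    return {
        "r": float(r),
        "p": float(p),
        "ci_95": (float(np.tanh(z - half)), float(np.tanh(z + half))),
        "n": n,
    }
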