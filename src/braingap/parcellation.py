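"""Atlas-based feature extraction and tabular I/O.

Turns a labeled 3D volume into the 90-region feature table the pipeline
consumes, and reads/writes the tabular artifacts.  Volumes are treated in
voxel space only: spatial normalization, smoothing, and segmentation are
assumed to have happened upstream.

The default atlas is a 90-region cortical + subcortical parcellation in the
automated-anatomic-labeling tradition; its region -> lobe/hemisphere map
ships as an editable TSV resource (``resources/aal90.tsv``) because the
anatomical grouping is data, not code.
"""

from __future__ import annotations

from importlib import resources as _resources
from pathlib import Path
from typing import Iterable

import nibabel as nib
import numpy as np
import pandas as pd

__all__ = [
    "load_atlas",
    "parcellate_volume",
    "parcellate_image",
    "suvr_normalize",
    "read_feature_table",
    "write_feature_table",
    "read_phenotype",
]

LOBES = frozenset({"frontal", "temporal", "limbic", "subcortical", "occipital", "parietal"})
HEMISPHERES = frozenset({"left", "right"})


def load_atlas(path: str | Path | None = None) -> pd.DataFrame:
    """Load an atlas map (columns: region_id, region_name, lobe, hemisphere).

    Without ``path`` the bundled 90-region default is returned.  Validates
    uniqueness of region ids/names and the lobe/hemisphere vocabularies.
    """
    if path is None:
        with _resources.files("braingap.resources").joinpath("aal90.tsv").open() as fh:
            atlas = pd.read_csv(fh, sep="\t")
    else:
        atlas = pd.read_csv(path, sep="\t")
    required = {"region_id", "region_name", "lobe", "hemisphere"}
    missing = required - set(atlas.columns)
    if missing:
        raise ValueError(f"atlas map missing columns: {sorted(missing)}")
    if atlas["region_id"].duplicated().any() or atlas["region_name"].duplicated().any():
        raise ValueError("atlas region ids and names must be unique")
    if (atlas["region_id"] <= 0).any():
        raise ValueError("atlas region_id values must be positive integers")
    bad_lobes = set(atlas["lobe"]) - LOBES
    if bad_lobes:
        raise ValueError(f"unknown lobes in atlas map: {sorted(bad_lobes)}")
    bad_hemis = set(atlas["hemisphere"]) - HEMISPHERES
    if bad_hemis:
        raise ValueError(f"unknown hemispheres in atlas map: {sorted(bad_hemis)}")
    return atlas.reset_index(drop=True)


def parcellate_volume(
    image: np.ndarray,
    labels: np.ndarray,
    atlas: pd.DataFrame,
    reduction: str = "mean",
) -> pd.Series:
    """Reduce voxel values to one number per atlas region.

    Voxels labeled 0 (background) are ignored.  Every atlas region must be
    present in the label volume — a silent zero for an absent region would
    corrupt downstream models.
    """
    image = np.asarray(image, dtype=float)
    labels = np.asarray(labels)
    if image.shape != labels.shape:
        raise ValueError(f"image shape {image.shape} != labels shape {labels.shape}")
    if reduction not in ("mean", "median"):
        raise ValueError(f"reduction must be 'mean' or 'median', got {reduction!r}")
    reduce = np.mean if reduction == "mean" else np.median
    values = {}
    flat_labels = labels.ravel()
    flat_image = image.ravel()
    for rid, rname in zip(atlas["region_id"], atlas["region_name"]):
        mask = flat_labels == rid
        if not mask.any():
            raise ValueError(f"atlas region {rid} ({rname}) absent from label volume")
        values[rname] = float(reduce(flat_image[mask]))
    return pd.Series(values, name=reduction)


def parcellate_image(
    image_path: str | Path,
    labels_path: str | Path,
    atlas: pd.DataFrame,
    reduction: str = "mean",
) -> pd.Series:
    """NIfTI wrapper around :func:`parcellate_volume`."""
    img = nib.load(str(image_path))
    lab = nib.load(str(labels_path))
    return parcellate_volume(
        np.asanyarray(img.dataobj, dtype=float),
        np.asanyarray(lab.dataobj).astype(int),
        atlas,
        reduction,
    )


def suvr_normalize(values: pd.Series, reference_region_ids: Iterable[int], atlas: pd.DataFrame) -> pd.Series:
    """Convert regional uptake values to SUV ratios.

    Each value is divided by the unweighted mean over the reference regions.
    There is no default reference: PET pipelines differ (pons, cerebellum,
    whole brain) and a silent choice would be irreproducible, so the caller
    must name one.  The choice is recorded in ``result.attrs``.
    """
    ref_ids = sorted(set(int(r) for r in reference_region_ids))
    if not ref_ids:
        raise ValueError("reference_region_ids must be non-empty")
    id_to_name = dict(zip(atlas["region_id"], atlas["region_name"]))
    missing = [r for r in ref_ids if r not in id_to_name]
    if missing:
        raise ValueError(f"reference regions not in atlas: {missing}")
    ref_names = [id_to_name[r] for r in ref_ids]
    absent = [n for n in ref_names if n not in values.index]
    if absent:
        raise ValueError(f"reference regions absent from values: {absent}")
    ref_mean = float(values.loc[ref_names].mean())
    if ref_mean <= 0:
        raise ValueError(f"reference mean must be > 0, got {ref_mean}")
    out = values / ref_mean
    out.attrs["reference_region_ids"] = ref_ids
    out.attrs["reference_mean"] = ref_mean
    return out


def write_feature_table(table: pd.DataFrame, path: str | Path, modality_tag: str | None = None) -> None:
    """Write a feature table (subject_id index + one column per region)."""
    out = table.copy()
    tag = modality_tag or out.attrs.get("modality_tag")
    if tag is not None:
        out.insert(0, "modality_tag", tag)
    out.to_csv(path, index_label="subject_id")


def read_feature_table(path: str | Path, atlas: pd.DataFrame | None = None) -> pd.DataFrame:
    """Read a feature table and canonicalize columns to atlas order.

    Raises on missing or extra region columns (listing them) and on any
    non-numeric feature cell (naming row and column).
    """
    if atlas is None:
        atlas = load_atlas()
    df = pd.read_csv(path, index_col="subject_id")
    modality = None
    if "modality_tag" in df.columns:
        modality = str(df.pop("modality_tag").iloc[0])
    expected = list(atlas["region_name"])
    missing = sorted(set(expected) - set(df.columns))
    extra = sorted(set(df.columns) - set(expected))
    if missing or extra:
        raise ValueError(
            f"feature table columns do not match atlas; missing={missing}, extra={extra}"
        )
    df = df[expected]
    for col in expected:
        numeric = pd.to_numeric(df[col], errors="coerce")
        bad = numeric.isna() & df[col].notna()
        if bad.any() or df[col].isna().any():
            row = df.index[bad | df[col].isna()][0]
            raise ValueError(f"non-numeric or missing feature cell at row {row!r}, column {col!r}")
        df[col] = numeric.astype(float)
    df.attrs["modality_tag"] = modality
    return df


def read_phenotype(path: str | Path) -> pd.DataFrame:
    """Read a phenotype table; requires the demographic columns that the
    downstream statistics cannot run without."""
    df = pd.read_csv(path, index_col="subject_id")
    required = ["age", "sex", "education", "apoe4_carrier"]
    missing = [c for c in required if c not in df.columns]
    if missing:
        raise ValueError(f"phenotype table missing required columns: {missing}")
    return df
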