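"""ROI-level feature tables for the classification tasks.

Eleven voxelwise maps feed the classifiers: four DTI scalars (AD, RD, MD,
FA), five single-shell HARDI scalars (ODI, density, diameter, ICVF,
ODF_energy) and two tractography maps (FDi, FTi).  Every ROI sample is the
mean of each map over the ROI's voxels.  For the core-vs-shell task the two
tractography maps are excluded (streamlines are too sparsely represented
in such small sub-ROIs), leaving 9 features.
"""

from __future__ import annotations

import warnings

import numpy as np
import pandas as pd

FEATURE_NAMES = [
    "AD",
    "RD",
    "MD",
    "FA",
    "ODI",
    "density",
    "diameter",
    "ICVF",
    "ODF_energy",
    "FDi",
    "FTi",
]
CORE_SHELL_FEATURES = [f for f in FEATURE_NAMES if f not in ("FDi", "FTi")]

META_COLUMNS = ["subject_id", "roi_id", "label"]

__all__ = [
    "FEATURE_NAMES",
    "CORE_SHELL_FEATURES",
    "extract_features",
    "minmax_normalize",
]


def _values(m) -> np.ndarray:
    return m.values if hasattr(m, "values") else np.asarray(m)


def extract_features(
    maps: dict[str, np.ndarray],
    roi_samples: list[tuple[np.ndarray, int, str, int]],
    feature_names: list[str] | None = None,
) -> pd.DataFrame:
    """Build a FeatureTable: one row per ROI sample, one column per map mean.

    Parameters
    ----------
    maps : dict
        Feature name -> ScalarMap or 3D array; must cover ``feature_names``.
    roi_samples : list of (mask, label, subject_id, roi_id)
        Binary ROI masks with their binary class label and identifiers.
        Empty masks are skipped with a warning.
    feature_names : list, optional
        Column subset and order; defaults to all 11 features present.
    """
    if feature_names is None:
        feature_names = [f for f in FEATURE_NAMES if f in maps]
    missing = [f for f in feature_names if f not in maps]
    if missing:
        raise ValueError(f"missing maps for features: {missing}")

    rows = []
    for mask, label, subject_id, roi_id in roi_samples:
        mask = np.asarray(mask).astype(bool)
        if not mask.any():
            warnings.warn(f"empty ROI {subject_id}/{roi_id}; row skipped")
            continue
        row = {"subject_id": subject_id, "roi_id": roi_id, "label": int(label)}
        for f in feature_names:
            row[f] = float(_values(maps[f])[mask].mean())
        rows.append(row)
    df = pd.DataFrame(rows, columns=META_COLUMNS + feature_names)
    if df[feature_names].isna().any().any():
        raise ValueError("missing values after feature assembly")
    return df


def minmax_normalize(
    table: pd.DataFrame, feature_names: list[str] | None = None
) -> pd.DataFrame:
    """Rescale every feature column to [0, 1] over the whole table.

    Constant columns map to 0 with a warning.  Normalizing an already
    [0, 1]-spanning column is a no-op.  Note this is the whole-dataset
    normalization applied before cross-validation; see
    :func:`minmax_normalize_fold` for a leakage-free per-fold variant.
    """
    if len(table) < 2:
        raise ValueError("normalization needs >= 2 rows")
    if feature_names is None:
        feature_names = [c for c in table.columns if c not in META_COLUMNS]
    out = table.copy()
    for c in feature_names:
        lo, hi = out[c].min(), out[c].max()
        if hi > lo:
            out[c] = (out[c] - lo) / (hi - lo)
        else:
            warnings.warn(f"constant feature column {c!r} normalized to 0")
            out[c] = 0.0
    return out


def minmax_normalize_fold(
    train: pd.DataFrame, test: pd.DataFrame, feature_names: list[str] | None = None
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Strict per-fold variant: ranges learned on the training rows only."""
    if feature_names is None:
        feature_names = [c for c in train.columns if c not in META_COLUMNS]
    tr, te = train.copy(), test.copy()
    for c in feature_names:
        lo, hi = tr[c].min(), tr[c].max()
        scale = (hi - lo) if hi > lo else 1.0
        tr[c] = (tr[c] - lo) / scale
        te[c] = (te[c] - lo) / scale
    return tr, te
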