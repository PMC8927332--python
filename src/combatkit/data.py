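"""Input validation and design-matrix construction.

The canonical in-memory containers are plain pandas objects:

* a *feature matrix* is a ``DataFrame`` of shape (n_samples, n_features),
  index = sample identifiers, columns = feature names, all values finite
  floats;
* a *batch assignment* is a ``Series`` of categorical labels aligned to the
  feature-matrix index, whose ``name`` identifies the batch effect;
* a *covariate table* is a ``DataFrame`` of clinical covariates (categorical
  or continuous) aligned to the same index.

The helpers here validate those invariants once, at the model boundary, and
produce the reference-coded covariate design used by the ComBat fit.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

__all__ = [
    "validate_feature_matrix",
    "validate_batch",
    "validate_covariates",
    "encode_covariates",
    "check_design_rank",
]

MIN_SAMPLES = 4
MIN_PER_LEVEL = 2


def validate_feature_matrix(features: pd.DataFrame, min_samples: int = MIN_SAMPLES) -> pd.DataFrame:
    """Validate and coerce a feature matrix to float64.

    Raises ``ValueError`` on duplicated identifiers, non-numeric columns,
    missing or non-finite entries, or fewer than ``min_samples`` samples.
    """
    if not isinstance(features, pd.DataFrame):
        raise TypeError("features must be a pandas DataFrame (samples x features)")
    if features.shape[1] < 1:
        raise ValueError("feature matrix needs at least one feature column")
    if features.shape[0] < min_samples:
        raise ValueError(
            f"feature matrix has {features.shape[0]} samples; at least {min_samples} required"
        )
    if features.index.duplicated().any():
        dups = features.index[features.index.duplicated()].unique().tolist()
        raise ValueError(f"duplicated sample identifiers: {dups}")
    if features.columns.duplicated().any():
        dups = features.columns[features.columns.duplicated()].unique().tolist()
        raise ValueError(f"duplicated feature names: {dups}")
    try:
        values = features.astype(np.float64)
    except (TypeError, ValueError) as exc:
        bad = [c for c in features.columns if not np.issubdtype(features[c].dtype, np.number)]
        raise ValueError(f"non-numeric feature columns: {bad}") from exc
    if not np.isfinite(values.to_numpy()).all():
        mask = ~np.isfinite(values.to_numpy())
        rows = values.index[mask.any(axis=1)].tolist()[:5]
        raise ValueError(
            f"feature matrix contains missing or non-finite values (e.g. samples {rows}); "
            "no imputation is performed — clean the input first"
        )
    return values


def validate_batch(
    batch: pd.Series,
    index: pd.Index,
    min_per_level: int = MIN_PER_LEVEL,
) -> pd.Series:
    """Validate a batch assignment against a sample index.

    Labels are coerced to strings; levels are ordered alphabetically for
    reproducible parameter indexing. Requires >= 2 levels with
    ``min_per_level`` samples each.
    """
    name = batch.name or "batch"
    if not batch.index.equals(index):
        try:
            batch = batch.loc[index]
        except KeyError as exc:
            missing = index.difference(batch.index).tolist()[:5]
            raise ValueError(
                f"batch effect {name!r} is missing labels for samples {missing}"
            ) from exc
    if batch.isna().any():
        rows = batch.index[batch.isna()].tolist()[:5]
        raise ValueError(f"batch effect {name!r} has missing labels for samples {rows}")
    batch = batch.astype(str)
    counts = batch.value_counts()
    if len(counts) < 2:
        raise ValueError(
            f"batch effect {name!r} has a single level {counts.index[0]!r}; "
            "harmonization needs at least two levels"
        )
    small = counts[counts < min_per_level]
    if len(small):
        raise ValueError(
            f"batch effect {name!r}: level(s) {small.index.tolist()} have fewer than "
            f"{min_per_level} samples"
        )
    return batch


def validate_covariates(covariates: pd.DataFrame | None, index: pd.Index) -> pd.DataFrame | None:
    """Align covariates to the sample index and reject constant columns."""
    if covariates is None or covariates.shape[1] == 0:
        return None
    if not covariates.index.equals(index):
        missing = index.difference(covariates.index).tolist()[:5]
        if missing:
            raise ValueError(f"covariates are missing rows for samples {missing}")
        covariates = covariates.loc[index]
    if covariates.isna().any().any():
        bad = covariates.columns[covariates.isna().any()].tolist()
        raise ValueError(f"covariate column(s) {bad} contain missing values")
    for col in covariates.columns:
        if covariates[col].nunique() < 2:
            raise ValueError(f"covariate {col!r} is constant and cannot be protected")
    return covariates


def encode_covariates(covariates: pd.DataFrame | None) -> tuple[np.ndarray, list[str]]:
    """Reference-code covariates into a design block (no intercept).

    Categorical columns are dummy-coded against the alphabetically first
    level; numeric columns are used as-is. Returns the (n, p) design block
    and the encoded column names.
    """
    if covariates is None or covariates.shape[1] == 0:
        return np.empty((0, 0)), []
    blocks: list[np.ndarray] = []
    names: list[str] = []
    for col in covariates.columns:
        series = covariates[col]
        if np.issubdtype(series.dtype, np.number) and series.nunique() > 2:
            blocks.append(series.to_numpy(dtype=np.float64)[:, None])
            names.append(str(col))
        elif np.issubdtype(series.dtype, np.number) and series.nunique() == 2:
            # binary numeric: treat as categorical with the smaller value as reference
            levels = np.sort(series.unique())
            blocks.append((series.to_numpy() == levels[1]).astype(np.float64)[:, None])
            names.append(f"{col}[{levels[1]}]")
        else:
            labels = series.astype(str)
            levels = sorted(labels.unique())
            for level in levels[1:]:
                blocks.append((labels.to_numpy() == level).astype(np.float64)[:, None])
                names.append(f"{col}[{level}]")
    design = np.hstack(blocks) if blocks else np.empty((len(covariates), 0))
    return design, names


def check_design_rank(design: np.ndarray, column_names: list[str]) -> None:
    """Raise on a rank-deficient design, naming the aliased column(s).

    Uses a pivoted QR: columns pivoted past the numerical rank are linearly
    dependent on the preceding ones (e.g. a covariate confounded with batch).
    """
    from scipy.linalg import qr

    if design.shape[1] == 0:
        return
    _, r, piv = qr(design, mode="economic", pivoting=True)
    diag = np.abs(np.diag(r))
    tol = diag.max() * max(design.shape) * np.finfo(np.float64).eps if diag.size else 0.0
    rank = int((diag > tol).sum())
    if rank < design.shape[1]:
        aliased = [column_names[i] for i in piv[rank:]]
        raise ValueError(
            f"design matrix is singular: column(s) {aliased} are confounded with the "
            "batch indicators or with other covariates"
        )
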