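"""CSV readers/writers and run manifests.

File conventions (bit-exact reproducibility, no dialect sniffing):

* feature table — comma-separated UTF-8, header row, first column the sample
  identifier, remaining columns numeric features;
* metadata table — same layout, remaining columns batch-effect labels and
  clinical covariates;
* the two are joined on the sample identifier; mismatches are errors, never
  silent subsetting (unless explicitly allowed).
"""

from __future__ import annotations

import json
from datetime import datetime, timezone
from pathlib import Path

import pandas as pd

from . import __version__
from .data import validate_feature_matrix

__all__ = ["load_dataset", "read_features", "write_features", "write_manifest"]


def read_features(path: str | Path) -> pd.DataFrame:
    """Read and validate a feature CSV (first column = sample identifier)."""
    df = pd.read_csv(path, index_col=0)
    df.index = df.index.astype(str)
    try:
        return validate_feature_matrix(df)
    except ValueError as exc:
        raise ValueError(f"{path}: {exc}") from exc


def load_dataset(
    features_path: str | Path,
    metadata_path: str | Path,
    allow_subset: bool = False,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Read features + metadata CSVs and align them on the sample identifier.

    Every feature-table sample must appear in the metadata; metadata rows for
    unknown samples are an error unless ``allow_subset=True``, in which case
    the metadata are subset to the feature table's samples. The returned
    metadata are reordered to the feature table's sample order.
    """
    features = read_features(features_path)
    metadata = pd.read_csv(metadata_path, index_col=0)
    metadata.index = metadata.index.astype(str)
    if metadata.index.duplicated().any():
        dups = metadata.index[metadata.index.duplicated()].unique().tolist()
        raise ValueError(f"{metadata_path}: duplicated sample identifiers {dups}")
    missing = features.index.difference(metadata.index)
    if len(missing):
        raise ValueError(
            f"{metadata_path}: no metadata for sample(s) {missing.tolist()[:5]}"
        )
    extra = metadata.index.difference(features.index)
    if len(extra) and not allow_subset:
        raise ValueError(
            f"{metadata_path}: metadata contain sample(s) {extra.tolist()[:5]} absent "
            "from the feature table; pass allow_subset to drop them"
        )
    return features, metadata.loc[features.index]


def write_features(features: pd.DataFrame, path: str | Path) -> None:
    features.to_csv(path, index_label="sample_id")


def write_manifest(path: str | Path, subcommand: str, config: dict, **extra) -> dict:
    """Write a JSON run manifest tying outputs to inputs, parameters, seeds."""
    manifest = {
        "tool": "combatkit",
        "version": __version__,
        "subcommand": subcommand,
        "written_at": datetime.now(timezone.utc).isoformat(),
        "config": config,
        **extra,
    }
    Path(path).write_text(json.dumps(manifest, indent=2, default=str) + "\n")
    return manifest
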