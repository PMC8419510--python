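"""Delimited-text feature tables and JSON report helpers."""

from __future__ import annotations

import json
from pathlib import Path
from typing import Tuple

import numpy as np
import pandas as pd

from .wrapper_selection import FeatureMatrix, LabelVector

__all__ = [
    "read_feature_table",
    "write_feature_table",
    "write_json",
    "read_json",
]


def read_feature_table(
    path, label_col: str = "label"
) -> Tuple[FeatureMatrix, LabelVector]:
    """Read a delimited table (comma or tab, sniffed) with a header row and
    a binary label column."""
    df = pd.read_csv(path, sep=None, engine="python")
    if label_col not in df.columns:
        raise ValueError(f"label column {label_col!r} not found in {path}")
    labels = LabelVector(df[label_col].to_numpy())
    features = df.drop(columns=[label_col])
    matrix = FeatureMatrix(features.to_numpy(dtype=float), list(features.columns))
    return matrix, labels


def write_feature_table(
    path, matrix: FeatureMatrix, labels: LabelVector, label_col: str = "label"
) -> None:
    df = pd.DataFrame(matrix.values, columns=matrix.feature_names)
    df[label_col] = labels.labels
    df.to_csv(path, index=False)


def write_json(path, payload: dict) -> None:
    Path(path).write_text(json.dumps(payload, indent=2, sort_keys=True) + "\n")


def read_json(path) -> dict:
    return json.loads(Path(path).read_text())
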