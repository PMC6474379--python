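"""Dataset I/O, affine feature scaling, and model-file helpers.

Training features are affinely mapped onto [0, 1] per coordinate; the same
transform is stored with the model and applied to new data, whose scaled
values may leave [0, 1] (saturating evaluation handles that, so nothing is
clipped).
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd

from .measures import SplineModel

__all__ = [
    "ScaledDesign",
    "scale_fit_transform",
    "scale_apply",
    "read_dataset",
    "write_model",
    "read_model",
    "write_predictions",
    "write_path_summary",
]


@dataclass
class ScaledDesign:
    X_scaled: np.ndarray
    transforms: np.ndarray  # (D, 2): shift, range
    feature_names: list[str]


def _report_nonfinite(X: np.ndarray, names: list[str]) -> None:
    bad = ~np.isfinite(X)
    if bad.any():
        r, c = np.argwhere(bad)[0]
        raise ValueError(
            f"nonfinite value at row {int(r)}, column {names[int(c)]!r}"
        )


def scale_fit_transform(X_raw: np.ndarray, feature_names: list[str] | None = None) -> ScaledDesign:
    """Fit per-coordinate (x - min) / (max - min) scaling on training data.

    Constant columns map to the constant 0.5 and are recorded with a zero
    range; they can never acquire knots, which is the correct
    feature-selection behaviour for degenerate features.
    """
    X = np.asarray(X_raw, dtype=float)
    if X.ndim == 1:
        X = X.reshape(-1, 1)
    n, D = X.shape
    names = feature_names if feature_names is not None else [f"x{d}" for d in range(D)]
    _report_nonfinite(X, names)
    transforms = np.zeros((D, 2))
    Xs = np.empty_like(X)
    for d in range(D):
        lo = X[:, d].min()
        rng = X[:, d].max() - lo
        transforms[d] = (lo, rng)
        Xs[:, d] = 0.5 if rng == 0.0 else (X[:, d] - lo) / rng
    return ScaledDesign(X_scaled=Xs, transforms=transforms, feature_names=list(names))


def scale_apply(transforms: np.ndarray, X_new: np.ndarray) -> np.ndarray:
    """Apply stored transforms to new raw data; outputs are not clipped."""
    transforms = np.asarray(transforms, dtype=float)
    X = np.asarray(X_new, dtype=float)
    if X.ndim == 1:
        X = X.reshape(-1, 1)
    D = transforms.shape[0]
    if X.shape[1] != D:
        raise ValueError(f"expected {D} columns, got {X.shape[1]}")
    out = np.empty_like(X)
    for d in range(D):
        shift, rng = transforms[d]
        out[:, d] = 0.5 if rng == 0.0 else (X[:, d] - shift) / rng
    return out


def read_dataset(path: str | Path, response_column: str):
    """Read a headered CSV into ``(X_raw, y, feature_names)``.

    Column order is preserved; non-numeric cells and missing values are
    reported with their location.
    """
    df = pd.read_csv(path, float_precision="round_trip")
    if response_column not in df.columns:
        raise ValueError(
            f"response column {response_column!r} not found; "
            f"available: {list(df.columns)}"
        )
    for col in df.columns:
        coerced = pd.to_numeric(df[col], errors="coerce")
        bad = coerced.isna() & ~df[col].isna()
        if bad.any():
            row = int(bad.idxmax())
            raise ValueError(
                f"non-numeric cell in column {col!r}, row {row}: {df[col][row]!r}"
            )
        if coerced.isna().any():
            row = int(coerced.isna().idxmax())
            raise ValueError(f"missing value in column {col!r}, row {row}")
        df[col] = coerced
    y = df[response_column].to_numpy(dtype=float)
    feats = [c for c in df.columns if c != response_column]
    X = df[feats].to_numpy(dtype=float)
    return X, y, feats


def write_model(model: SplineModel, path: str | Path) -> None:
    model.save(path)


def read_model(path: str | Path) -> SplineModel:
    return SplineModel.load(path)


def write_predictions(preds: np.ndarray, path: str | Path) -> None:
    pd.DataFrame({"prediction": np.asarray(preds, dtype=float)}).to_csv(
        path, index=False, float_format="%.17g"
    )


def write_path_summary(summary: pd.DataFrame, path: str | Path) -> None:
    summary.to_csv(path, index=False)
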