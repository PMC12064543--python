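"""Core in-memory containers shared across the pipeline.

Images are plain numpy arrays with physical pixel spacing attached; feature
tables wrap a pandas DataFrame indexed by subject id.  NIfTI is the on-disk
interchange format for images and masks (via nibabel), CSV for tables.
"""

from __future__ import annotations

import dataclasses
from pathlib import Path
from typing import Sequence

import nibabel as nib
import numpy as np
import pandas as pd


@dataclasses.dataclass
class ImageVolume:
    """Gridded intensity data (2D slice or 3D stack) with physical spacing.

    Parameters
    ----------
    data
        Intensity array, float; 2D ``(rows, cols)`` or 3D
        ``(rows, cols, slices)``.
    spacing
        Physical size of one pixel per axis, in millimetres.
    """

    data: np.ndarray
    spacing: tuple[float, ...] = None  # type: ignore[assignment]

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data, dtype=float)
        if self.data.ndim not in (2, 3):
            raise ValueError(f"image must be 2D or 3D, got ndim={self.data.ndim}")
        if self.spacing is None:
            self.spacing = (1.0,) * self.data.ndim
        self.spacing = tuple(float(s) for s in self.spacing)
        if len(self.spacing) != self.data.ndim:
            raise ValueError("spacing length must match image dimensionality")
        if any(s <= 0 for s in self.spacing):
            raise ValueError("spacing must be positive")

    @property
    def ndim(self) -> int:
        return self.data.ndim

    @property
    def shape(self) -> tuple[int, ...]:
        return self.data.shape


@dataclasses.dataclass
class ROIMask:
    """Binary region-of-interest (tumor) mask aligned with an ImageVolume."""

    data: np.ndarray
    spacing: tuple[float, ...] = None  # type: ignore[assignment]

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data).astype(bool)
        if self.data.ndim not in (2, 3):
            raise ValueError(f"mask must be 2D or 3D, got ndim={self.data.ndim}")
        if self.spacing is None:
            self.spacing = (1.0,) * self.data.ndim
        self.spacing = tuple(float(s) for s in self.spacing)
        if len(self.spacing) != self.data.ndim:
            raise ValueError("spacing length must match mask dimensionality")

    @property
    def n_pixels(self) -> int:
        return int(self.data.sum())

    def is_empty(self) -> bool:
        return not bool(self.data.any())


def save_nifti(path: str | Path, arr: np.ndarray, spacing: Sequence[float]) -> None:
    """Write a 2D/3D array as NIfTI with a diagonal affine from spacing."""
    arr = np.asarray(arr)
    if arr.ndim == 2:
        arr = arr[:, :, None]
        spacing = tuple(spacing) + (1.0,)
    affine = np.diag(list(spacing) + [1.0])
    nib.save(nib.Nifti1Image(arr.astype(np.float32), affine), str(path))


def load_nifti(path: str | Path) -> tuple[np.ndarray, tuple[float, ...]]:
    """Read a NIfTI file; trailing singleton axes are squeezed to 2D."""
    img = nib.load(str(path))
    arr = np.asanyarray(img.dataobj).astype(float)
    spacing = tuple(float(z) for z in img.header.get_zooms()[: arr.ndim])
    if arr.ndim == 3 and arr.shape[2] == 1:
        arr = arr[:, :, 0]
        spacing = spacing[:2]
    return arr, spacing


class FeatureTable:
    """Subjects-by-features numeric table with an optional batch label.

    Wraps a pandas DataFrame whose index holds subject ids and whose columns
    hold feature names.  Feature names must be unique; values must be finite
    unless explicitly flagged.
    """

    def __init__(
        self,
        values: pd.DataFrame,
        batch: pd.Series | None = None,
    ) -> None:
        if values.columns.duplicated().any():
            dups = values.columns[values.columns.duplicated()].tolist()
            raise ValueError(f"duplicate feature names: {dups}")
        if values.index.duplicated().any():
            raise ValueError("duplicate subject ids")
        self.values = values.astype(float)
        self.values.index.name = "subject_id"
        if batch is not None:
            batch = batch.reindex(values.index)
            if batch.isna().any():
                missing = batch.index[batch.isna()].tolist()
                raise ValueError(f"batch labels missing for subjects: {missing}")
        self.batch = batch

    @property
    def subjects(self) -> list:
        return list(self.values.index)

    @property
    def feature_names(self) -> list[str]:
        return list(self.values.columns)

    @property
    def matrix(self) -> np.ndarray:
        return self.values.to_numpy()

    def require_finite(self) -> None:
        if not np.isfinite(self.values.to_numpy()).all():
            bad = self.values.columns[~np.isfinite(self.values).all(axis=0)].tolist()
            raise ValueError(f"non-finite values in features: {bad}")

    def copy(self) -> "FeatureTable":
        return FeatureTable(
            self.values.copy(),
            None if self.batch is None else self.batch.copy(),
        )

    def to_csv(self, path: str | Path, batch_col: str = "batch") -> None:
        out = self.values.copy()
        if self.batch is not None:
            out.insert(0, batch_col, self.batch)
        out.to_csv(path, index_label="subject_id")

    @classmethod
    def from_csv(cls, path: str | Path, batch_col: str | None = "batch") -> "FeatureTable":
        df = pd.read_csv(path, index_col="subject_id")
        batch = None
        if batch_col is not None and batch_col in df.columns:
            batch = df.pop(batch_col)
        return cls(df, batch)

    def __repr__(self) -> str:  # pragma: no cover - cosmetic
        nb = "none" if self.batch is None else f"{self.batch.nunique()} batches"
        return f"FeatureTable({self.values.shape[0]} subjects x {self.values.shape[1]} features, {nb})"
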