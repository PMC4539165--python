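"""Scalar volumes on a shared case grid.

A :class:`ScalarVolume` is a thin container around a 2-D or 3-D numpy array
plus its voxel spacing in millimetres.  All images of one case (DWI, T2-w,
MTT, derived maps, masks) live on a single grid, so most of the pipeline
passes bare arrays around internally and only wraps them at module
boundaries and for NIfTI I/O.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import nibabel as nib
import numpy as np

__all__ = ["ScalarVolume", "load_nifti", "save_nifti", "save_mask", "load_mask"]


@dataclass
class ScalarVolume:
    """A scalar field sampled on a regular grid.

    Parameters
    ----------
    data:
        2-D or 3-D float array.
    spacing:
        Voxel size in mm along each axis; length equals ``data.ndim``.
    """

    data: np.ndarray
    spacing: tuple[float, ...] = field(default=None)  # type: ignore[assignment]

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data, dtype=float)
        if self.data.ndim not in (2, 3):
            raise ValueError(f"expected a 2-D or 3-D array, got ndim={self.data.ndim}")
        if self.spacing is None:
            self.spacing = (1.0,) * self.data.ndim
        self.spacing = tuple(float(s) for s in self.spacing)
        if len(self.spacing) != self.data.ndim:
            raise ValueError("spacing length must match array dimensionality")
        if any(s <= 0 for s in self.spacing):
            raise ValueError("voxel spacing must be positive")

    @property
    def shape(self) -> tuple[int, ...]:
        return self.data.shape

    @property
    def ndim(self) -> int:
        return self.data.ndim

    @property
    def cell_volume(self) -> float:
        """Volume (or area, in 2-D) of one voxel in mm^ndim."""
        return float(np.prod(self.spacing))

    def same_grid(self, other: "ScalarVolume") -> bool:
        return self.shape == other.shape and self.spacing == other.spacing

    def copy(self) -> "ScalarVolume":
        return ScalarVolume(self.data.copy(), self.spacing)


def _affine(spacing: tuple[float, ...]) -> np.ndarray:
    diag = list(spacing) + [1.0] * (3 - len(spacing)) + [1.0]
    return np.diag(diag)


def save_nifti(volume: ScalarVolume, path) -> None:
    """Write a volume as NIfTI; 2-D grids are stored with a trailing singleton axis."""
    data = volume.data
    if data.ndim == 2:
        data = data[:, :, None]
    img = nib.Nifti1Image(np.asarray(data, dtype=np.float64), _affine(volume.spacing))
    nib.save(img, str(path))


def load_nifti(path, squeeze: bool = True) -> ScalarVolume:
    img = nib.load(str(path))
    data = np.asarray(img.dataobj, dtype=float)
    zooms = img.header.get_zooms()[: data.ndim]
    if squeeze and data.ndim == 3 and data.shape[2] == 1:
        data = data[:, :, 0]
        zooms = zooms[:2]
    return ScalarVolume(data, tuple(float(z) for z in zooms))


def save_mask(mask: np.ndarray, spacing, path) -> None:
    save_nifti(ScalarVolume(np.asarray(mask, dtype=float), tuple(spacing)), path)


def load_mask(path) -> np.ndarray:
    vol = load_nifti(path)
    data = vol.data
    uniq = np.unique(data)
    if not np.all(np.isin(uniq, (0.0, 1.0))):
        raise ValueError(f"mask at {path} is not binary (values {uniq[:5]}...)")
    return data.astype(bool)


def as_binary_mask(arr: np.ndarray, name: str = "mask") -> np.ndarray:
    """Validate that an array is strictly binary and return it as bool."""
    a = np.asarray(arr)
    if a.dtype == bool:
        return a
    uniq = np.unique(a)
    if not np.all(np.isin(uniq, (0, 1))):
        raise ValueError(f"{name} is not binary: found values {uniq[:6]}")
    return a.astype(bool)
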