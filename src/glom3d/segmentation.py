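"""Binarization, isolated-voxel suppression and connected-component labeling."""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import numpy as np
import tifffile
from scipy import ndimage

__all__ = [
    "BinaryStack",
    "LabelStack",
    "binarize",
    "median_filter_3d",
    "label_components",
    "write_binary",
    "write_labels",
    "read_labels",
]


@dataclass(frozen=True)
class BinaryStack:
    """A {0,1} mask congruent with its source stack."""

    mask: np.ndarray
    spacing: tuple[float, float, float]

    def __post_init__(self) -> None:
        arr = np.asarray(self.mask)
        if arr.ndim != 3:
            raise ValueError(f"mask must be 3D, got ndim={arr.ndim}")
        if not np.isin(arr, (0, 1)).all():
            raise ValueError("mask values must be 0 or 1")
        spacing = tuple(float(s) for s in self.spacing)
        if any(s <= 0 for s in spacing):
            raise ValueError(f"spacing must be positive, got {self.spacing}")
        object.__setattr__(self, "mask", arr.astype(np.uint8, copy=False))
        object.__setattr__(self, "spacing", spacing)

    @property
    def voxel_volume(self) -> float:
        dz, dy, dx = self.spacing
        return dz * dy * dx


@dataclass(frozen=True)
class LabelStack:
    """Connected components labeled 1..n_objects over a 0 background."""

    labels: np.ndarray
    n_objects: int
    spacing: tuple[float, float, float]

    def __post_init__(self) -> None:
        arr = np.asarray(self.labels)
        if arr.ndim != 3:
            raise ValueError(f"labels must be 3D, got ndim={arr.ndim}")
        if arr.max(initial=0) != self.n_objects or arr.min(initial=0) < 0:
            raise ValueError(
                f"labels must span 0..{self.n_objects} (max found {arr.max(initial=0)})"
            )
        spacing = tuple(float(s) for s in self.spacing)
        object.__setattr__(self, "labels", arr.astype(np.int32, copy=False))
        object.__setattr__(self, "spacing", spacing)

    @property
    def voxel_volume(self) -> float:
        dz, dy, dx = self.spacing
        return dz * dy * dx


def binarize(stack, threshold: float) -> BinaryStack:
    """Mask = 1 where voxel grey is strictly greater than the threshold.

    Strict inequality lets the continuous mean + 3.29·SD cut exclude its own
    boundary bin.
    """
    if stack.bit_depth != 8:
        raise ValueError("binarize expects an 8-bit stack")
    return BinaryStack((stack.voxels > threshold).astype(np.uint8), stack.spacing)


def median_filter_3d(binary: BinaryStack, window: int = 3) -> BinaryStack:
    """Majority vote over a window³ neighborhood (median of a binary image).

    Suppresses artefactual isolated voxels. Borders use edge replication.
    The window is in index space (one value per axis), matching ImageJ
    behavior on anisotropic stacks.
    """
    if window < 1 or window % 2 == 0:
        raise ValueError(f"window must be an odd integer >= 1, got {window}")
    if window > min(binary.mask.shape):
        raise ValueError(
            f"window {window} exceeds the smallest stack dimension {min(binary.mask.shape)}"
        )
    filtered = ndimage.median_filter(binary.mask, size=window, mode="nearest")
    return BinaryStack(filtered, binary.spacing)


_STRUCTURES = {
    6: ndimage.generate_binary_structure(3, 1),
    26: ndimage.generate_binary_structure(3, 3),
}


def label_components(binary: BinaryStack, connectivity: int = 26) -> LabelStack:
    """Label maximal connected components under 6- or 26-connectivity."""
    if connectivity not in _STRUCTURES:
        raise ValueError(f"connectivity must be 6 or 26, got {connectivity}")
    labels, n = ndimage.label(binary.mask, structure=_STRUCTURES[connectivity])
    return LabelStack(labels, int(n), binary.spacing)


def write_binary(binary: BinaryStack, path: str | Path) -> None:
    """Write a mask as an 8-bit TIFF (0/255 for viewer visibility)."""
    tifffile.imwrite(str(path), binary.mask * np.uint8(255), photometric="minisblack")


def write_labels(labels: LabelStack, path: str | Path) -> None:
    tifffile.imwrite(
        str(path), labels.labels.astype(np.uint16), photometric="minisblack"
    )


def read_labels(path: str | Path, spacing: tuple[float, float, float]) -> LabelStack:
    arr = tifffile.imread(str(path)).astype(np.int32)
    if arr.ndim == 2:
        arr = arr[np.newaxis, ...]
    return LabelStack(arr, int(arr.max(initial=0)), spacing)
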