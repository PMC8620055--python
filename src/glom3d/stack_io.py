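"""Reading, writing and bit-depth conversion of 3D greyscale stacks.

Stacks are stored in (z, y, x) axis order, matching page-major TIFF layout;
the physical voxel spacing ``(dz, dy, dx)`` in micrometres travels with the
array because every downstream measurement (volumes, surfaces, densities)
is reported in physical units.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import tifffile

__all__ = ["VoxelStack", "read_stack", "write_stack", "to_8bit"]

_ALLOWED_DTYPES = {np.dtype(np.uint8): 8, np.dtype(np.uint16): 16}


@dataclass(frozen=True)
class VoxelStack:
    """A 3D greyscale volume with per-axis physical voxel spacing.

    Parameters
    ----------
    voxels
        3D array of grey values in (z, y, x) order, dtype uint8 or uint16.
    spacing
        Physical voxel edge lengths ``(dz, dy, dx)`` in micrometres.
    """

    voxels: np.ndarray
    spacing: tuple[float, float, float]

    def __post_init__(self) -> None:
        arr = np.asarray(self.voxels)
        if arr.ndim != 3:
            raise ValueError(f"expected a 3D (z, y, x) array, got ndim={arr.ndim}")
        if arr.dtype not in _ALLOWED_DTYPES:
            raise ValueError(
                f"unsupported dtype {arr.dtype}; greyscale stacks must be uint8 or uint16"
            )
        spacing = tuple(float(s) for s in self.spacing)
        if len(spacing) != 3 or any(s <= 0 for s in spacing):
            raise ValueError(f"spacing must be three positive lengths, got {self.spacing}")
        object.__setattr__(self, "voxels", arr)
        object.__setattr__(self, "spacing", spacing)

    @property
    def bit_depth(self) -> int:
        return _ALLOWED_DTYPES[self.voxels.dtype]

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.voxels.shape

    @property
    def voxel_volume(self) -> float:
        """Physical volume of one voxel in µm³ (dz·dy·dx)."""
        dz, dy, dx = self.spacing
        return dz * dy * dx


def read_stack(path: str | Path, spacing: tuple[float, float, float]) -> VoxelStack:
    """Read a single- or multi-page greyscale TIFF as a :class:`VoxelStack`.

    Page order maps to the z axis. RGB(A) and other non-greyscale layouts
    are rejected; spacing is supplied by the caller because acquisition
    metadata does not survive TIFF export reliably.
    """
    with tifffile.TiffFile(str(path)) as tif:
        page = tif.pages[0]
        if page.samplesperpixel != 1:
            raise ValueError(
                f"{path}: {page.samplesperpixel} samples per pixel "
                "(RGB/multichannel TIFFs are not supported)"
            )
        arr = tif.asarray()
    if arr.ndim == 2:
        arr = arr[np.newaxis, ...]
    if arr.ndim != 3:
        raise ValueError(
            f"{path}: expected greyscale pages, got array of shape {arr.shape}"
        )
    if arr.dtype not in _ALLOWED_DTYPES:
        raise ValueError(f"{path}: unsupported sample format {arr.dtype}")
    return VoxelStack(arr, spacing)


def write_stack(stack: VoxelStack, path: str | Path) -> None:
    """Write a stack as an uncompressed multi-page greyscale TIFF."""
    tifffile.imwrite(str(path), stack.voxels, photometric="minisblack")


def to_8bit(stack: VoxelStack, fixed_range: tuple[float, float] | None = None) -> VoxelStack:
    """Convert a stack to 8-bit (256 grey levels).

    16-bit input is linearly rescaled so that the observed minimum maps to 0
    and the observed maximum to 255 (rounded to nearest); 8-bit input is
    returned unchanged. ``fixed_range`` substitutes an explicit (low, high)
    display range for the observed min/max.

    A constant 16-bit stack has zero dynamic range: it maps to all zeros
    with a warning.
    """
    if stack.bit_depth == 8:
        return stack
    data = stack.voxels.astype(np.float64)
    if fixed_range is not None:
        lo, hi = (float(fixed_range[0]), float(fixed_range[1]))
        if hi <= lo:
            raise ValueError(f"fixed_range must satisfy low < high, got {fixed_range}")
    else:
        lo, hi = float(data.min()), float(data.max())
        if hi == lo:
            warnings.warn(
                "constant 16-bit stack has zero dynamic range; mapping all voxels to 0",
                stacklevel=2,
            )
            return VoxelStack(np.zeros(stack.shape, dtype=np.uint8), stack.spacing)
    scaled = np.clip((data - lo) / (hi - lo), 0.0, 1.0) * 255.0
    return VoxelStack(np.rint(scaled).astype(np.uint8), stack.spacing)
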