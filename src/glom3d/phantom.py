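"""Synthetic cleared-kidney-cortex stacks with known ground truth.

A phantom emulates the three voxel populations of a lectin-labelled cleared
kidney — dark mounting medium, self-fluorescent tissue with Gaussian grey
statistics, and bright labelled structures — plus the object classes the
screening stages must separate: globular glomeruli with irregular
(lobulated) surfaces, thin bright tubules, glomerulus-volume bright tube
decoys, and isolated bright artifact voxels. Every planted glomerulus is
recorded in a label stack with its rasterized voxel volume, so pipeline
recovery can be scored without any external data.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import tifffile
from scipy import ndimage

from .segmentation import LabelStack
from .stack_io import VoxelStack
from .threshold_stats import LECTIN_SD_FACTOR, FrequencyCurve

__all__ = [
    "PhantomSpec",
    "GroundTruth",
    "generate_phantom",
    "histogram_of_truth",
    "save_phantom",
    "load_truth",
    "CLASS_CODES",
]

CLASS_CODES = {
    "background": 0,
    "tissue": 1,
    "glomerulus": 2,
    "tubule": 3,
    "large_tube": 4,
    "artifact": 5,
}


class PlacementError(RuntimeError):
    """Raised when non-overlapping object placement fails (phantom too dense)."""


@dataclass(frozen=True)
class PhantomSpec:
    """Parameters of a synthetic stack.

    Grey levels are (mean, sd) pairs on the 8-bit scale; lengths are in µm.
    Defaults produce a 64×256×256-voxel stack (128³ µm at light-sheet
    spacing (2, 0.5, 0.5)) with 40 lobulated glomeruli, 500 thin tubules,
    5 glomerulus-volume tube decoys and sparse bright artifact voxels.
    """

    shape: tuple[int, int, int] = (64, 256, 256)  # (z, y, x) voxels
    spacing: tuple[float, float, float] = (2.0, 0.5, 0.5)
    background_level: tuple[float, float] = (5.0, 2.0)
    tissue_level: tuple[float, float] = (80.0, 10.0)
    glomerulus_count: int = 40
    glomerulus_radius: tuple[float, float] = (9.0, 0.8)  # µm mean, sd
    lobulation: float = 0.12
    glomerulus_grey: tuple[float, float] = (180.0, 20.0)
    tubule_count: int = 500
    tubule_radius: float = 2.5
    tubule_length: tuple[float, float] = (12.0, 28.0)  # µm uniform range
    large_tube_count: int = 5
    large_tube_radius: float = 4.0
    large_tube_length: float = 45.0
    artifact_voxel_rate: float = 0.2  # bright isolated voxels per 10³ voxels
    margin_fraction: float = 0.08  # dark mounting-medium band on each y/x side
    seed: int = 1

    def __post_init__(self) -> None:
        if any(n <= 0 for n in self.shape) or any(s <= 0 for s in self.spacing):
            raise ValueError("shape and spacing must be positive")
        if (
            self.glomerulus_count < 0
            or self.tubule_count < 0
            or self.large_tube_count < 0
        ):
            raise ValueError("object counts must be non-negative")
        if self.glomerulus_radius[0] <= 0 or self.tubule_radius <= 0:
            raise ValueError("radii must be positive")
        if not 0 <= self.lobulation < 1:
            raise ValueError(f"lobulation must lie in [0, 1), got {self.lobulation}")
        t_mean, t_sd = self.tissue_level
        if self.glomerulus_count > 0 and self.glomerulus_grey[0] <= (
            t_mean + LECTIN_SD_FACTOR * t_sd
        ):
            raise ValueError(
                "glomerulus grey mean must exceed tissue mean + "
                f"{LECTIN_SD_FACTOR}·sd = {t_mean + LECTIN_SD_FACTOR * t_sd:.1f} "
                "so planted objects survive the lectin threshold"
            )

    def to_dict(self) -> dict:
        return asdict(self)


@dataclass(frozen=True)
class GroundTruth:
    """Planted-object reference for scoring pipeline output.

    ``label_stack`` labels planted glomeruli only; ``class_map`` codes every
    voxel by its generating class (see :data:`CLASS_CODES`);
    ``planted_params`` records per-glomerulus center (µm), equivalent radius
    and the true voxel volume measured from the rasterization.
    """

    label_stack: LabelStack
    object_class: dict[int, str]
    planted_params: list[dict]
    class_map: np.ndarray = field(repr=False, default=None)


def _angular_modulation(rel: np.ndarray, coeffs: np.ndarray) -> np.ndarray:
    """Smooth angular surface modulation g(u) ∈ [−1, 1] from direction vectors."""
    norms = np.linalg.norm(rel, axis=-1, keepdims=True)
    u = np.divide(rel, norms, out=np.zeros_like(rel), where=norms > 0)
    z, y, x = u[..., 0], u[..., 1], u[..., 2]
    basis = np.stack(
        [x, y, z, x * y, y * z, z * x, x * x - y * y, 2 * z * z - x * x - y * y],
        axis=-1,
    )
    g = basis @ coeffs
    peak = np.abs(g).max()
    if peak > 0:
        g = g / peak
    return g


def _rasterize_glomerulus(
    shape: tuple[int, int, int],
    spacing: np.ndarray,
    center_um: np.ndarray,
    radius: float,
    lobulation: float,
    rng: np.random.Generator,
) -> tuple[tuple[slice, ...], np.ndarray]:
    """Boolean sub-mask of a radius-modulated spheroid, with its bbox slices."""
    r_max = radius * (1.0 + lobulation)
    lo = np.maximum(np.floor((center_um - r_max) / spacing - 1), 0).astype(int)
    hi = np.minimum(
        np.ceil((center_um + r_max) / spacing + 2), np.asarray(shape)
    ).astype(int)
    sl = tuple(slice(int(a), int(b)) for a, b in zip(lo, hi))
    axes = [
        (np.arange(a, b) + 0.5) * s - c
        for a, b, s, c in zip(lo, hi, spacing, center_um)
    ]
    rel = np.stack(np.meshgrid(*axes, indexing="ij"), axis=-1)
    rho = np.linalg.norm(rel, axis=-1)
    coeffs = rng.standard_normal(8)
    local_r = radius * (1.0 + lobulation * _angular_modulation(rel, coeffs))
    return sl, rho <= local_r


def _rasterize_cylinder(
    shape: tuple[int, int, int],
    spacing: np.ndarray,
    a_um: np.ndarray,
    b_um: np.ndarray,
    radius: float,
) -> tuple[tuple[slice, ...], np.ndarray]:
    """Boolean sub-mask of a capsule (cylinder with hemispherical caps)."""
    lo = np.maximum(
        np.floor((np.minimum(a_um, b_um) - radius) / spacing - 1), 0
    ).astype(int)
    hi = np.minimum(
        np.ceil((np.maximum(a_um, b_um) + radius) / spacing + 2), np.asarray(shape)
    ).astype(int)
    sl = tuple(slice(int(a), int(b)) for a, b in zip(lo, hi))
    axes = [(np.arange(a, b) + 0.5) * s for a, b, s in zip(lo, hi, spacing)]
    pts = np.stack(np.meshgrid(*axes, indexing="ij"), axis=-1)
    ab = b_um - a_um
    denom = float(ab @ ab)
    t = np.clip(((pts - a_um) @ ab) / denom, 0.0, 1.0) if denom > 0 else 0.0
    nearest = a_um + np.multiply.outer(t, ab)
    dist = np.linalg.norm(pts - nearest, axis=-1)
    return sl, dist <= radius


def _place_spheres(
    rng: np.random.Generator,
    count: int,
    radii: np.ndarray,
    lo_um: np.ndarray,
    hi_um: np.ndarray,
    min_gap: float,
    max_attempts: int = 1000,
) -> np.ndarray:
    """Rejection-sample non-overlapping sphere centers inside a box."""
    centers = np.empty((count, 3))
    for i in range(count):
        r = radii[i]
        if np.any(hi_um - r <= lo_um + r):
            raise PlacementError(
                f"glomerulus radius {r:.1f} µm does not fit in the tissue box "
                f"{(hi_um - lo_um).round(1)} µm (density limit)"
            )
        placed = False
        for _ in range(max_attempts):
            c = rng.uniform(lo_um + r, hi_um - r)
            if i == 0:
                centers[0] = c
                placed = True
                break
            d = np.linalg.norm(centers[:i] - c, axis=1)
            if np.all(d > radii[:i] + r + min_gap):
                centers[i] = c
                placed = True
                break
        if not placed:
            raise PlacementError(
                f"could not place glomerulus {i + 1}/{count} without overlap after "
                f"{max_attempts} attempts; reduce count or radius (density limit)"
            )
    return centers


def generate_phantom(spec: PhantomSpec) -> tuple[VoxelStack, GroundTruth]:
    """Generate a synthetic stack and its ground truth (deterministic per seed)."""
    rng = np.random.default_rng(spec.seed)
    shape = tuple(int(n) for n in spec.shape)
    spacing = np.asarray(spec.spacing, dtype=np.float64)
    extent_um = np.asarray(shape) * spacing

    grey = rng.normal(*spec.background_level, size=shape)
    class_map = np.zeros(shape, dtype=np.uint8)

    # self-fluorescent tissue block, inset in y and x by the mounting margin
    my = int(round(spec.margin_fraction * shape[1]))
    mx = int(round(spec.margin_fraction * shape[2]))
    tissue = np.zeros(shape, dtype=bool)
    tissue[:, my : shape[1] - my, mx : shape[2] - mx] = True
    grey[tissue] = rng.normal(*spec.tissue_level, size=int(tissue.sum()))
    class_map[tissue] = CLASS_CODES["tissue"]

    tissue_lo_um = np.array([0.0, my * spacing[1], mx * spacing[2]])
    tissue_hi_um = np.array(
        [extent_um[0], (shape[1] - my) * spacing[1], (shape[2] - mx) * spacing[2]]
    )

    labels = np.zeros(shape, dtype=np.int32)
    planted: list[dict] = []
    object_class: dict[int, str] = {}

    # glomeruli: lobulated spheroids, pairwise non-overlapping
    if spec.glomerulus_count > 0:
        radii = np.clip(
            rng.normal(*spec.glomerulus_radius, size=spec.glomerulus_count),
            0.25 * spec.glomerulus_radius[0],
            None,
        )
        eff = radii * (1.0 + spec.lobulation)
        centers = _place_spheres(
            rng,
            spec.glomerulus_count,
            eff,
            tissue_lo_um + 2.0,
            tissue_hi_um - 2.0,
            min_gap=3.0,
        )
        for k in range(spec.glomerulus_count):
            sl, sub = _rasterize_glomerulus(
                shape, spacing, centers[k], radii[k], spec.lobulation, rng
            )
            n_vox = int(sub.sum())
            grey[sl][sub] = rng.normal(*spec.glomerulus_grey, size=n_vox)
            labels[sl][sub] = k + 1
            class_map[sl][sub] = CLASS_CODES["glomerulus"]
            object_class[k + 1] = "glomerulus"
            planted.append(
                {
                    "label": k + 1,
                    "center_um": centers[k].tolist(),
                    "equivalent_radius_um": float(radii[k]),
                    "true_voxel_volume_um3": n_vox * float(np.prod(spacing)),
                    "true_voxel_count": n_vox,
                }
            )

    # keep-out zone so bright tubes never touch a glomerulus label: dilation
    # must use the full 26-neighborhood, else diagonal contacts slip through
    forbidden = ndimage.binary_dilation(
        labels > 0, structure=ndimage.generate_binary_structure(3, 3), iterations=2
    )

    def _paint_tube(a: np.ndarray, b: np.ndarray, radius: float, code: int) -> None:
        sl, sub = _rasterize_cylinder(shape, spacing, a, b, radius)
        sub = sub & ~forbidden[sl]
        n_vox = int(sub.sum())
        if n_vox == 0:
            return
        grey[sl][sub] = rng.normal(*spec.glomerulus_grey, size=n_vox)
        class_map[sl][sub] = code

    # thin tubules (peritubular-capillary analogues)
    for _ in range(spec.tubule_count):
        length = rng.uniform(*spec.tubule_length)
        a = rng.uniform(tissue_lo_um, tissue_hi_um)
        direction = rng.standard_normal(3)
        direction /= np.linalg.norm(direction)
        b = np.clip(a + direction * length, tissue_lo_um, tissue_hi_um)
        _paint_tube(a, b, spec.tubule_radius, CLASS_CODES["tubule"])

    # glomerulus-volume bright tubes (shape-screen decoys)
    for _ in range(spec.large_tube_count):
        a = rng.uniform(tissue_lo_um, tissue_hi_um)
        direction = rng.standard_normal(3)
        direction /= np.linalg.norm(direction)
        b = np.clip(a + direction * spec.large_tube_length, tissue_lo_um, tissue_hi_um)
        _paint_tube(a, b, spec.large_tube_radius, CLASS_CODES["large_tube"])

    # isolated bright artifact voxels in the tissue
    n_artifacts = int(round(spec.artifact_voxel_rate * grey.size / 1000.0))
    if n_artifacts > 0:
        candidates = np.flatnonzero((class_map == CLASS_CODES["tissue"]).ravel())
        chosen = rng.choice(candidates, size=min(n_artifacts, candidates.size), replace=False)
        idx = np.unravel_index(chosen, shape)
        grey[idx] = rng.normal(*spec.glomerulus_grey, size=chosen.size)
        class_map[idx] = CLASS_CODES["artifact"]

    stack = VoxelStack(
        np.clip(np.rint(grey), 0, 255).astype(np.uint8), tuple(spec.spacing)
    )
    truth = GroundTruth(
        label_stack=LabelStack(labels, spec.glomerulus_count, tuple(spec.spacing)),
        object_class=object_class,
        planted_params=planted,
        class_map=class_map,
    )
    return stack, truth


def histogram_of_truth(
    stack: VoxelStack, truth: GroundTruth
) -> dict[str, FrequencyCurve]:
    """Per-class 256-level grey histograms keyed by class name.

    Classes absent from the phantom yield an all-zero curve.
    """
    if truth.class_map is None or truth.class_map.shape != stack.shape:
        raise ValueError("ground-truth class map is missing or not congruent with stack")
    out = {}
    for name, code in CLASS_CODES.items():
        sel = stack.voxels[truth.class_map == code]
        counts = np.bincount(sel, minlength=256).astype(np.float64)
        out[name] = FrequencyCurve(np.arange(256, dtype=np.float64), counts)
    return out


def save_phantom(
    stack: VoxelStack, truth: GroundTruth, spec: PhantomSpec, out_dir: str | Path
) -> dict[str, Path]:
    """Write stack TIFF, truth-label TIFF and a JSON manifest to a directory."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    paths = {
        "stack": out / "phantom.tif",
        "truth": out / "truth_labels.tif",
        "manifest": out / "manifest.json",
    }
    tifffile.imwrite(str(paths["stack"]), stack.voxels, photometric="minisblack")
    tifffile.imwrite(
        str(paths["truth"]),
        truth.label_stack.labels.astype(np.uint16),
        photometric="minisblack",
    )
    manifest = {
        "spec": spec.to_dict(),
        "object_class": {str(k): v for k, v in truth.object_class.items()},
        "planted_params": truth.planted_params,
    }
    paths["manifest"].write_text(json.dumps(manifest, indent=2))
    return paths


def load_truth(
    truth_tiff: str | Path,
    manifest_json: str | Path,
    spacing: tuple[float, float, float],
) -> GroundTruth:
    """Rebuild a :class:`GroundTruth` from saved TIFF + manifest (no class map)."""
    arr = tifffile.imread(str(truth_tiff)).astype(np.int32)
    if arr.ndim == 2:
        arr = arr[np.newaxis, ...]
    manifest = json.loads(Path(manifest_json).read_text())
    return GroundTruth(
        label_stack=LabelStack(arr, int(arr.max(initial=0)), spacing),
        object_class={int(k): v for k, v in manifest["object_class"].items()},
        planted_params=manifest["planted_params"],
        class_map=None,
    )
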