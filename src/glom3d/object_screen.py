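"""Volume- and shape-based screening of labelled objects.

Grey-level segmentation of a lectin-labelled kidney yields thousands of
objects, most of them small non-glomerular fragments. Two successive
screens remove them: first on physical object volume, then on the shape
score Vobj/Vell — the object's volume divided by the volume of the smallest
ellipsoid enclosing it. Globular objects score near 1, tubes score low.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import ndimage
from scipy.spatial import ConvexHull, QhullError

from .segmentation import LabelStack
from .threshold_stats import FrequencyCurve, NoValleyError, find_inflexion

__all__ = [
    "ScreenedObjects",
    "object_voxel_counts",
    "volume_distribution",
    "ratio_distribution",
    "auto_volume_threshold",
    "auto_ratio_threshold",
    "screen_by_volume",
    "minimum_volume_ellipsoid",
    "enclosing_ellipsoid_volume",
    "shape_ratio",
    "shape_table",
    "screen_by_shape",
]


@dataclass(frozen=True)
class ScreenedObjects:
    """Labels surviving one screening stage, with the threshold that was applied."""

    kept_labels: np.ndarray
    threshold_used: float
    stage: str

    def __post_init__(self) -> None:
        if self.stage not in ("volume", "shape"):
            raise ValueError(f"stage must be 'volume' or 'shape', got {self.stage!r}")
        object.__setattr__(
            self, "kept_labels", np.asarray(self.kept_labels, dtype=np.int64)
        )


def object_voxel_counts(labels: LabelStack) -> np.ndarray:
    """Voxel count per label; index 0 is background and index i is label i."""
    return np.bincount(labels.labels.ravel(), minlength=labels.n_objects + 1)


def _object_volumes(labels: LabelStack) -> np.ndarray:
    return object_voxel_counts(labels)[1:] * labels.voxel_volume


def volume_distribution(labels: LabelStack, n_bins: int = 40) -> FrequencyCurve:
    """Histogram of object physical volumes on a logarithmic volume axis.

    Objects span several decades (single-voxel artifacts to whole
    glomeruli), so bins are equal-width in log10(volume); curve positions
    are the geometric bin centers in µm³.
    """
    if labels.n_objects < 1:
        raise ValueError("no objects to build a volume distribution from")
    volumes = _object_volumes(labels)
    log_v = np.log10(volumes)
    lo, hi = log_v.min(), log_v.max()
    if hi - lo < 1e-9:  # all volumes identical: pad so bins are well-formed
        lo, hi = lo - 0.5, hi + 0.5
    n_bins = max(int(n_bins), 3)
    counts, edges = np.histogram(log_v, bins=n_bins, range=(lo, hi))
    centers = 10 ** ((edges[:-1] + edges[1:]) / 2.0)
    return FrequencyCurve(centers, counts.astype(np.float64))


def ratio_distribution(ratios: np.ndarray, n_bins: int = 25) -> FrequencyCurve:
    """Histogram of Vobj/Vell shape scores on linear bins spanning [0, 1]."""
    ratios = np.asarray(ratios, dtype=np.float64)
    counts, edges = np.histogram(ratios, bins=max(int(n_bins), 3), range=(0.0, 1.0))
    centers = (edges[:-1] + edges[1:]) / 2.0
    return FrequencyCurve(centers, counts.astype(np.float64))


def _auto_threshold(curve: FrequencyCurve, strategy: str, smoothing_window: int) -> float:
    """Resolve an inflexion-point threshold, falling back from valley to knee."""
    if strategy == "auto":
        try:
            return find_inflexion(curve, "valley", smoothing_window)
        except NoValleyError:
            return find_inflexion(curve, "knee", smoothing_window)
    return find_inflexion(curve, strategy, smoothing_window)


def auto_volume_threshold(
    labels: LabelStack,
    n_bins: int = 40,
    strategy: str = "auto",
    smoothing_window: int = 5,
) -> float:
    """Volume cut-off at the inflexion point of the log-binned volume curve."""
    return _auto_threshold(volume_distribution(labels, n_bins), strategy, smoothing_window)


def auto_ratio_threshold(
    ratios: np.ndarray,
    n_bins: int = 25,
    strategy: str = "auto",
    smoothing_window: int = 5,
) -> float:
    """Shape-score cut-off at the inflexion point of the ratio curve."""
    return _auto_threshold(ratio_distribution(ratios, n_bins), strategy, smoothing_window)


def screen_by_volume(labels: LabelStack, min_volume: float | None = None) -> ScreenedObjects:
    """Keep objects with physical volume strictly greater than ``min_volume``.

    With ``min_volume=None`` the cut-off is derived automatically from the
    inflexion point of the object-volume distribution.
    """
    if min_volume is None:
        min_volume = auto_volume_threshold(labels)
    elif min_volume < 0:
        raise ValueError(f"min_volume must be non-negative, got {min_volume}")
    volumes = _object_volumes(labels)
    kept = np.where(volumes > min_volume)[0] + 1
    if kept.size == 0 and labels.n_objects > 0:
        warnings.warn(
            f"volume screen at {min_volume:.3g} µm³ removed all {labels.n_objects} objects",
            stacklevel=2,
        )
    return ScreenedObjects(kept, float(min_volume), "volume")


def minimum_volume_ellipsoid(
    points: np.ndarray, tol: float = 1e-3, max_iter: int = 10000
) -> tuple[np.ndarray, np.ndarray]:
    """Minimum-volume enclosing ellipsoid of a point set (Khachiyan iteration).

    Returns ``(A, c)`` with the ellipsoid {x : (x−c)ᵀ A (x−c) ≤ 1}. The
    result is scaled by (1 + tol) per semi-axis so inclusion holds despite
    the finite iteration tolerance. Points must span full 3D rank.
    """
    P = np.asarray(points, dtype=np.float64)
    if P.ndim != 2 or P.shape[1] != 3:
        raise ValueError(f"expected an (n, 3) point array, got shape {P.shape}")
    n, d = P.shape
    if n < 4 or np.linalg.matrix_rank(P - P.mean(axis=0)) < 3:
        raise ValueError("point set is degenerate (collinear/coplanar); inflate first")
    Q = np.column_stack([P, np.ones(n)]).T  # (d+1, n)
    u = np.full(n, 1.0 / n)
    for _ in range(max_iter):
        X = (Q * u) @ Q.T
        M = np.einsum("ij,ji->i", Q.T, np.linalg.solve(X, Q))
        j = int(np.argmax(M))
        maximum = M[j]
        step = (maximum - d - 1.0) / ((d + 1.0) * (maximum - 1.0))
        new_u = (1.0 - step) * u
        new_u[j] += step
        if np.linalg.norm(new_u - u) < tol / 10.0:
            u = new_u
            break
        u = new_u
    c = P.T @ u
    cov = (P * u[:, None]).T @ P - np.outer(c, c)
    A = np.linalg.inv(cov) / d
    A /= (1.0 + tol) ** 2  # guarantee inclusion at finite tolerance
    return A, c


_CORNER_OFFSETS = np.array(
    [[sz, sy, sx] for sz in (-0.5, 0.5) for sy in (-0.5, 0.5) for sx in (-0.5, 0.5)]
)


def _inflated_hull_points(
    centers_um: np.ndarray, spacing: tuple[float, float, float]
) -> np.ndarray:
    """Corners of the half-voxel inflation of a voxel-center set, hull-reduced.

    conv(S ⊕ box) = conv(vertices(conv S) ⊕ corners(box)), so only hull
    vertices need expanding; degenerate center sets (hull undefined) are
    expanded wholesale.
    """
    centers_um = np.asarray(centers_um, dtype=np.float64).reshape(-1, 3)
    try:
        hull = ConvexHull(centers_um)
        base = centers_um[hull.vertices]
    except QhullError:
        base = centers_um
    offsets = _CORNER_OFFSETS * np.asarray(spacing)
    corners = (base[:, None, :] + offsets[None, :, :]).reshape(-1, 3)
    hull2 = ConvexHull(corners)
    return corners[hull2.vertices]


def _is_degenerate(pts: np.ndarray) -> bool:
    return pts.shape[0] < 4 or np.linalg.matrix_rank(pts - pts.mean(axis=0)) < 3


def enclosing_ellipsoid_volume(
    object_voxels_um: np.ndarray,
    spacing: tuple[float, float, float] = (1.0, 1.0, 1.0),
    tol: float = 1e-3,
    inflate: str = "auto",
) -> float:
    """Volume (µm³) of the smallest ellipsoid enclosing an object's voxels.

    ``object_voxels_um`` are voxel centers in µm. ``inflate`` controls the
    half-voxel expansion of the centers along every axis:

    - ``"auto"`` (default): expand only degenerate sets (single voxels,
      collinear/coplanar objects), so Vell > 0 always;
    - ``"always"``: expand unconditionally, guaranteeing Vell covers the
      full voxelized solid (used by :func:`shape_ratio` so Vobj/Vell <= 1);
    - ``"never"``: raise on degenerate sets.
    """
    pts = np.asarray(object_voxels_um, dtype=np.float64).reshape(-1, 3)
    if pts.shape[0] == 0:
        raise ValueError("empty voxel set")
    if inflate not in ("auto", "always", "never"):
        raise ValueError(f"inflate must be 'auto', 'always' or 'never', got {inflate!r}")
    if inflate == "always" or (inflate == "auto" and _is_degenerate(pts)):
        pts = _inflated_hull_points(pts, spacing)
    A, _ = minimum_volume_ellipsoid(pts, tol=tol)
    det = np.linalg.det(A)
    if det <= 0:
        raise ValueError("enclosing ellipsoid degenerated (non-positive determinant)")
    return float(4.0 / 3.0 * np.pi / np.sqrt(det))


def _voxel_centers_um(
    mask: np.ndarray, spacing: tuple[float, float, float], origin: tuple[int, int, int]
) -> np.ndarray:
    idx = np.argwhere(mask)
    return (idx + np.asarray(origin)) * np.asarray(spacing)


def shape_ratio(
    object_mask: np.ndarray, spacing: tuple[float, float, float], tol: float = 1e-3
) -> float:
    """Vobj/Vell of a single object given as a boolean mask.

    Lies in (0, 1]: Vell encloses the half-voxel-inflated object, whose
    convex hull volume is at least the object volume.
    """
    mask = np.asarray(object_mask).astype(bool)
    count = int(mask.sum())
    if count == 0:
        raise ValueError("object mask is empty")
    vobj = count * float(np.prod(spacing))
    vell = enclosing_ellipsoid_volume(
        _voxel_centers_um(mask, spacing, (0, 0, 0)),
        spacing=spacing,
        tol=tol,
        inflate="always",
    )
    return vobj / vell


def shape_table(
    labels: LabelStack,
    candidate_labels: np.ndarray | None = None,
    tol: float = 1e-3,
) -> pd.DataFrame:
    """Per-object Vobj, Vell and Vobj/Vell for the candidate labels.

    Returns a DataFrame indexed by label with columns ``voxel_count``,
    ``volume_um3``, ``vell_um3`` and ``ratio``.
    """
    if candidate_labels is None:
        candidate_labels = np.arange(1, labels.n_objects + 1)
    candidate_labels = np.asarray(candidate_labels, dtype=np.int64)
    counts = object_voxel_counts(labels)
    slices = ndimage.find_objects(labels.labels)
    spacing = labels.spacing
    rows = []
    for lab in candidate_labels:
        sl = slices[lab - 1]
        if sl is None:
            raise ValueError(f"label {lab} not present in the label stack")
        sub = labels.labels[sl] == lab
        origin = tuple(s.start for s in sl)
        vobj = counts[lab] * labels.voxel_volume
        vell = enclosing_ellipsoid_volume(
            _voxel_centers_um(sub, spacing, origin),
            spacing=spacing,
            tol=tol,
            inflate="always",
        )
        rows.append(
            {
                "label": int(lab),
                "voxel_count": int(counts[lab]),
                "volume_um3": float(vobj),
                "vell_um3": float(vell),
                "ratio": float(vobj / vell),
            }
        )
    return pd.DataFrame(rows).set_index("label")


def screen_by_shape(
    table: pd.DataFrame, min_ratio: float | None = None, n_bins: int = 25
) -> ScreenedObjects:
    """Keep objects with Vobj/Vell strictly greater than ``min_ratio``.

    ``table`` is the output of :func:`shape_table`. With ``min_ratio=None``
    the cut-off is derived from the inflexion point of the ratio
    distribution.
    """
    ratios = table["ratio"].to_numpy()
    if min_ratio is None:
        min_ratio = auto_ratio_threshold(ratios, n_bins=n_bins)
    elif not 0 <= min_ratio < 1:
        raise ValueError(f"min_ratio must lie in [0, 1), got {min_ratio}")
    kept = table.index.to_numpy()[ratios > min_ratio]
    if kept.size == 0 and len(table) > 0:
        warnings.warn(
            f"shape screen at ratio {min_ratio:.3g} removed all {len(table)} objects",
            stacklevel=2,
        )
    return ScreenedObjects(kept, float(min_ratio), "shape")
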