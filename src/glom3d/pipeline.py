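"""End-to-end pipeline orchestration and ground-truth validation.

``run_pipeline`` chains the three successive segmentations (greyscale →
volume → shape) with fully automatic threshold derivation, then computes
morphometrics and population statistics. Every derived threshold and
per-stage object count is logged into the run report so the
operator-independence of the result can be audited.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import pandas as pd
from scipy import ndimage

from . import __version__
from .morphometrics import (
    ObjectMorphometry,
    SampleSummary,
    measure_objects,
    morphometry_table,
    sample_summary,
)
from .object_screen import (
    auto_ratio_threshold,
    screen_by_shape,
    screen_by_volume,
    shape_table,
)
from .phantom import GroundTruth
from .population_stats import ParameterDistribution, parameter_distribution
from .segmentation import (
    BinaryStack,
    LabelStack,
    binarize,
    label_components,
    median_filter_3d,
)
from .stack_io import VoxelStack, to_8bit
from .threshold_stats import (
    LECTIN_SD_FACTOR,
    GaussianFit,
    GaussianFitError,
    NoValleyError,
    ThresholdSet,
    background_threshold,
    fit_gaussian,
    gaussian_fit_range,
    grey_histogram,
    lectin_threshold,
)

__all__ = [
    "PipelineConfig",
    "PipelineResult",
    "RunReport",
    "ValidationReport",
    "run_pipeline",
    "validate",
]


@dataclass(frozen=True)
class PipelineConfig:
    """Settings for one pipeline run; ``None`` thresholds are auto-derived."""

    background_grey: float | None = None
    lectin_grey: float | None = None
    min_volume: float | None = None
    min_ratio: float | None = None
    sd_factor: float = LECTIN_SD_FACTOR
    smoothing_window: int = 5
    median_window: int = 3
    connectivity: int = 26
    surface_method: str = "mesh"
    volume_bins: int = 40
    ratio_bins: int = 25
    volume_strategy: str = "auto"
    ratio_strategy: str = "auto"
    n_parameter_bins: int = 15

    def to_dict(self) -> dict:
        return asdict(self)


@dataclass
class RunReport:
    """Serializable record of one run: thresholds, stage counts, summaries."""

    thresholds: ThresholdSet | None
    stage_counts: dict[str, int]
    summary: SampleSummary | None
    tissue_fit: GaussianFit | None
    distributions: dict[str, ParameterDistribution]
    provenance: dict
    diagnostics: list[str] = field(default_factory=list)

    @property
    def n_glomeruli(self) -> int:
        return self.stage_counts.get("shape_screened", 0)

    def to_dict(self) -> dict:
        return {
            "thresholds": self.thresholds.to_dict() if self.thresholds else None,
            "stage_counts": self.stage_counts,
            "summary": self.summary.to_dict() if self.summary else None,
            "tissue_fit": self.tissue_fit.to_dict() if self.tissue_fit else None,
            "distributions": {k: d.to_dict() for k, d in self.distributions.items()},
            "provenance": self.provenance,
            "diagnostics": self.diagnostics,
        }

    def to_json(self, path: str | Path) -> None:
        Path(path).write_text(json.dumps(self.to_dict(), indent=2))


@dataclass
class PipelineResult:
    """Run report plus the intermediate arrays needed for scoring and export."""

    report: RunReport
    label_stack: LabelStack | None = None
    kept_labels: np.ndarray = field(default_factory=lambda: np.empty(0, dtype=np.int64))
    tissue_mask: BinaryStack | None = None
    objects: list[ObjectMorphometry] = field(default_factory=list)
    object_table: pd.DataFrame | None = None
    screening_table: pd.DataFrame | None = None


def _empty_result(stage_counts: dict, provenance: dict, diagnostics: list[str]) -> PipelineResult:
    report = RunReport(
        thresholds=None,
        stage_counts=stage_counts,
        summary=None,
        tissue_fit=None,
        distributions={},
        provenance=provenance,
        diagnostics=diagnostics,
    )
    return PipelineResult(report)


def run_pipeline(stack: VoxelStack, config: PipelineConfig = PipelineConfig()) -> PipelineResult:
    """Run the full identification + morphometry pipeline on one stack.

    Stage order: 8-bit conversion, grey histogram, background threshold,
    tissue Gaussian fit, lectin threshold (mean + k·SD), binarization, 3D
    median filter, connected components, volume screen, shape screen,
    morphometrics, parameter distributions. An empty final object set
    yields a zero-glomerulus report, not an error.
    """
    provenance = {"config": config.to_dict(), "version": __version__, "spacing": stack.spacing}
    diagnostics: list[str] = []
    stack8 = to_8bit(stack)
    curve = grey_histogram(stack8)

    # --- greyscale thresholds -------------------------------------------------
    if config.background_grey is not None:
        bg = float(config.background_grey)
        diagnostics.append(f"background_grey overridden to {bg}")
    else:
        try:
            bg = background_threshold(curve, config.smoothing_window)
            diagnostics.append(f"background_grey auto-derived (valley) = {bg}")
        except NoValleyError as exc:
            diagnostics.append(f"no valley in grey histogram: {exc}")
            return _empty_result({"grey_segmented": 0}, provenance, diagnostics)

    tissue_fit = None
    if config.lectin_grey is not None:
        lectin = float(config.lectin_grey)
        diagnostics.append(f"lectin_grey overridden to {lectin}")
    else:
        try:
            fit_range = gaussian_fit_range(curve, bg)
            tissue_fit = fit_gaussian(curve, fit_range)
            lectin = lectin_threshold(tissue_fit, k=config.sd_factor)
            diagnostics.append(
                f"tissue fit over {fit_range}: mean={tissue_fit.mean:.2f} "
                f"sd={tissue_fit.sd:.2f} r2={tissue_fit.r_squared:.4f}; "
                f"lectin_grey = mean + {config.sd_factor}*sd = {lectin:.2f}"
            )
        except GaussianFitError as exc:
            diagnostics.append(f"tissue Gaussian fit failed: {exc}")
            return _empty_result({"grey_segmented": 0}, provenance, diagnostics)

    tissue_mask = binarize(stack8, bg)
    lectin_mask = binarize(stack8, lectin)
    filtered = median_filter_3d(lectin_mask, config.median_window)
    labels = label_components(filtered, config.connectivity)
    stage_counts = {"grey_segmented": labels.n_objects}
    if labels.n_objects == 0:
        diagnostics.append("no objects after greyscale segmentation and filtering")
        report = RunReport(None, stage_counts, None, tissue_fit, {}, provenance, diagnostics)
        return PipelineResult(report, labels, tissue_mask=tissue_mask)

    # --- volume screen --------------------------------------------------------
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        vol_screen = screen_by_volume(labels, config.min_volume)
    stage_counts["volume_screened"] = int(vol_screen.kept_labels.size)
    diagnostics.append(
        f"volume screen at {vol_screen.threshold_used:.4g} µm³ kept "
        f"{vol_screen.kept_labels.size}/{labels.n_objects}"
    )

    # --- shape screen ---------------------------------------------------------
    kept = np.empty(0, dtype=np.int64)
    min_ratio_used = config.min_ratio
    table = None
    if vol_screen.kept_labels.size:
        table = shape_table(labels, vol_screen.kept_labels)
        if min_ratio_used is None:
            try:
                min_ratio_used = auto_ratio_threshold(
                    table["ratio"].to_numpy(),
                    n_bins=config.ratio_bins,
                    strategy=config.ratio_strategy,
                    smoothing_window=config.smoothing_window,
                )
            except (NoValleyError, ValueError) as exc:
                min_ratio_used = 0.5
                diagnostics.append(
                    f"shape-ratio inflexion not found ({exc}); fell back to 0.5"
                )
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            shape_screen = screen_by_shape(table, min_ratio_used)
        kept = shape_screen.kept_labels
        min_ratio_used = shape_screen.threshold_used
    else:
        min_ratio_used = min_ratio_used if min_ratio_used is not None else 0.5
    stage_counts["shape_screened"] = int(kept.size)
    diagnostics.append(
        f"shape screen at ratio {min_ratio_used:.3g} kept {kept.size}"
    )

    thresholds = ThresholdSet(
        background_grey=bg,
        lectin_grey=lectin,
        min_volume=max(vol_screen.threshold_used, np.finfo(float).tiny),
        min_ratio=float(np.clip(min_ratio_used, np.finfo(float).tiny, 1 - 1e-12)),
    )

    # --- morphometrics and population statistics ------------------------------
    objects = measure_objects(
        labels, kept, surface_method=config.surface_method, shape_metrics=table
    )
    summary = sample_summary(objects, tissue_mask)
    interior = [o for o in objects if not o.edge_touching]
    distributions: dict[str, ParameterDistribution] = {}
    values = {
        "surface": np.array([o.surface for o in interior]),
        "volume": np.array([o.volume for o in interior]),
        "compactness": np.array([o.compactness for o in interior]),
    }
    for name, vals in values.items():
        try:
            distributions[name] = parameter_distribution(
                vals, name, config.n_parameter_bins
            )
        except (ValueError, GaussianFitError) as exc:
            diagnostics.append(f"{name} distribution not fitted: {exc}")

    report = RunReport(
        thresholds=thresholds,
        stage_counts=stage_counts,
        summary=summary,
        tissue_fit=tissue_fit,
        distributions=distributions,
        provenance=provenance,
        diagnostics=diagnostics,
    )
    screening = _screening_table(labels, vol_screen.kept_labels, table, kept)
    return PipelineResult(
        report=report,
        label_stack=labels,
        kept_labels=kept,
        tissue_mask=tissue_mask,
        objects=objects,
        object_table=morphometry_table(objects),
        screening_table=screening,
    )


def _screening_table(
    labels: LabelStack,
    volume_kept: np.ndarray,
    shape_metrics: pd.DataFrame | None,
    shape_kept: np.ndarray,
) -> pd.DataFrame:
    """Per-object audit table across both screening stages."""
    from .object_screen import object_voxel_counts

    counts = object_voxel_counts(labels)[1:]
    table = pd.DataFrame(
        {
            "label": np.arange(1, labels.n_objects + 1),
            "voxel_count": counts,
            "volume_um3": counts * labels.voxel_volume,
            "vell_um3": np.nan,
            "ratio": np.nan,
            "kept_volume": False,
            "kept_shape": False,
        }
    ).set_index("label")
    table.loc[volume_kept, "kept_volume"] = True
    if shape_metrics is not None:
        table.loc[shape_metrics.index, "vell_um3"] = shape_metrics["vell_um3"]
        table.loc[shape_metrics.index, "ratio"] = shape_metrics["ratio"]
    table.loc[shape_kept, "kept_shape"] = True
    return table.reset_index()


@dataclass(frozen=True)
class ValidationReport:
    """Detection scored against a reference, normalized to the reference count."""

    n_truth: int
    n_detected: int
    false_positive_pct: float
    false_negative_pct: float
    matches: list[tuple[int, int]]  # (truth label, detected label)

    def to_dict(self) -> dict:
        return {
            "n_truth": self.n_truth,
            "n_detected": self.n_detected,
            "false_positive_pct": self.false_positive_pct,
            "false_negative_pct": self.false_negative_pct,
            "matches": [list(m) for m in self.matches],
        }


def _centroids_um(labels: LabelStack, which: np.ndarray) -> np.ndarray:
    if which.size == 0:
        return np.empty((0, 3))
    coms = ndimage.center_of_mass(
        labels.labels > 0, labels.labels, which.tolist()
    )
    return np.asarray(coms) * np.asarray(labels.spacing)


def validate(
    detected: LabelStack,
    kept_labels: np.ndarray,
    truth: GroundTruth | LabelStack,
    match_radius: float | None = None,
) -> ValidationReport:
    """Score detected objects against reference glomeruli.

    Greedy nearest-centroid matching within ``match_radius`` (µm; default =
    mean planted equivalent radius, or 10 µm when unknown). Each truth and
    each detected label is matched at most once. Unmatched detections are
    false positives, unmatched truths false negatives; both are normalized
    to the truth count and expressed in %.
    """
    if isinstance(truth, GroundTruth):
        truth_stack = truth.label_stack
        if match_radius is None and truth.planted_params:
            match_radius = float(
                np.mean([p["equivalent_radius_um"] for p in truth.planted_params])
            )
    else:
        truth_stack = truth
    if match_radius is None:
        match_radius = 10.0
    if truth_stack.labels.shape != detected.labels.shape:
        raise ValueError(
            f"shape mismatch: truth {truth_stack.labels.shape} vs "
            f"detected {detected.labels.shape}"
        )
    truth_ids = np.unique(truth_stack.labels)
    truth_ids = truth_ids[truth_ids > 0]
    kept_labels = np.asarray(kept_labels, dtype=np.int64)
    n_truth, n_det = truth_ids.size, kept_labels.size
    if n_truth == 0:
        raise ValueError("reference contains no glomeruli to normalize against")

    t_cent = _centroids_um(truth_stack, truth_ids)
    d_cent = _centroids_um(detected, kept_labels)
    if n_det:
        dists = np.linalg.norm(t_cent[:, None, :] - d_cent[None, :, :], axis=-1)
        pairs = np.argwhere(dists <= match_radius)
        order = np.argsort(dists[pairs[:, 0], pairs[:, 1]])
        used_t: set[int] = set()
        used_d: set[int] = set()
        matches = []
        for ti, di in pairs[order]:
            if ti in used_t or di in used_d:
                continue
            used_t.add(int(ti))
            used_d.add(int(di))
            matches.append((int(truth_ids[ti]), int(kept_labels[di])))
    else:
        matches = []
    fp = n_det - len(matches)
    fn = n_truth - len(matches)
    return ValidationReport(
        n_truth=int(n_truth),
        n_detected=int(n_det),
        false_positive_pct=100.0 * fp / n_truth,
        false_negative_pct=100.0 * fn / n_truth,
        matches=matches,
    )
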