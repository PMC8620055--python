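"""Statistical threshold derivation from voxel frequency distributions.

The tissue voxel population of a cleared, non-labelled kidney follows a
Gaussian grey distribution. Fitting that bell and placing the cut at
``mean + 3.29·SD`` excludes a fixed fraction (Φ(3.29) ≈ 99.95%) of tissue
voxels from the labelled-structure mask, independent of any visual
estimate. Frequency curves of object volume and shape ratio are screened
with the same inflexion-point machinery.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import numpy as np
from scipy import optimize, signal, stats

from .stack_io import VoxelStack

__all__ = [
    "LECTIN_SD_FACTOR",
    "FrequencyCurve",
    "GaussianFit",
    "ThresholdSet",
    "NoValleyError",
    "GaussianFitError",
    "ThresholdSaturationError",
    "grey_histogram",
    "find_inflexion",
    "fit_gaussian",
    "gaussian_fit_range",
    "lectin_threshold",
    "background_threshold",
    "normal_fraction_below",
    "normal_coverage",
]

#: Multiplier k in the tissue-exclusion threshold mean + k·SD.
LECTIN_SD_FACTOR = 3.29


class NoValleyError(ValueError):
    """Raised when a curve has no interior valley between two populations."""


class GaussianFitError(RuntimeError):
    """Raised when the Gaussian least-squares fit fails or degenerates."""


class ThresholdSaturationError(ValueError):
    """Raised when a derived grey threshold exceeds the 8-bit dynamic range."""


@dataclass(frozen=True)
class FrequencyCurve:
    """Ordered abscissa positions with non-negative frequencies.

    Positions may be grey levels, object volumes in µm³ or dimensionless
    ratios; frequencies may be counts or relative frequencies.
    """

    positions: np.ndarray
    frequencies: np.ndarray

    def __post_init__(self) -> None:
        pos = np.asarray(self.positions, dtype=np.float64)
        freq = np.asarray(self.frequencies, dtype=np.float64)
        if pos.ndim != 1 or freq.ndim != 1 or pos.size != freq.size:
            raise ValueError("positions and frequencies must be 1D arrays of equal length")
        if pos.size < 3:
            raise ValueError("a frequency curve needs at least 3 positions")
        if np.any(np.diff(pos) <= 0):
            raise ValueError("positions must be strictly increasing")
        if np.any(freq < 0):
            raise ValueError("frequencies must be non-negative")
        object.__setattr__(self, "positions", pos)
        object.__setattr__(self, "frequencies", freq)

    @property
    def total(self) -> float:
        return float(self.frequencies.sum())

    def to_csv(self, path: str | Path) -> None:
        header = "position,frequency"
        np.savetxt(
            str(path),
            np.column_stack([self.positions, self.frequencies]),
            delimiter=",",
            header=header,
            comments="",
        )

    @classmethod
    def from_csv(cls, path: str | Path) -> "FrequencyCurve":
        data = np.loadtxt(str(path), delimiter=",", skiprows=1)
        return cls(data[:, 0], data[:, 1])


@dataclass(frozen=True)
class GaussianFit:
    """Parameters of a fitted bell curve F = amplitude·exp(−0.5·((x−mean)/sd)²)."""

    amplitude: float
    mean: float
    sd: float
    r_squared: float

    def __post_init__(self) -> None:
        if self.sd <= 0:
            raise ValueError(f"sd must be positive, got {self.sd}")
        if self.amplitude <= 0:
            raise ValueError(f"amplitude must be positive, got {self.amplitude}")
        if not 0.0 <= self.r_squared <= 1.0:
            raise ValueError(f"r_squared must lie in [0, 1], got {self.r_squared}")

    def to_dict(self) -> dict:
        return {
            "amplitude": self.amplitude,
            "mean": self.mean,
            "sd": self.sd,
            "r_squared": self.r_squared,
        }


@dataclass(frozen=True)
class ThresholdSet:
    """The four derived cut-offs of the pipeline."""

    background_grey: float
    lectin_grey: float
    min_volume: float
    min_ratio: float

    def __post_init__(self) -> None:
        if not 0 <= self.background_grey < self.lectin_grey <= 255:
            raise ValueError(
                "thresholds must satisfy 0 <= background_grey < lectin_grey <= 255, "
                f"got ({self.background_grey}, {self.lectin_grey})"
            )
        if self.min_volume <= 0:
            raise ValueError(f"min_volume must be positive, got {self.min_volume}")
        if not 0 < self.min_ratio < 1:
            raise ValueError(f"min_ratio must lie in (0, 1), got {self.min_ratio}")

    def to_dict(self) -> dict:
        return {
            "background_grey": self.background_grey,
            "lectin_grey": self.lectin_grey,
            "min_volume": self.min_volume,
            "min_ratio": self.min_ratio,
        }


def grey_histogram(stack: VoxelStack) -> FrequencyCurve:
    """256-level grey histogram of an 8-bit stack; frequencies sum to voxel count."""
    if stack.bit_depth != 8:
        raise ValueError("grey_histogram expects an 8-bit stack; convert with to_8bit first")
    counts = np.bincount(stack.voxels.ravel(), minlength=256)
    return FrequencyCurve(np.arange(256, dtype=np.float64), counts.astype(np.float64))


def _moving_average(values: np.ndarray, window: int) -> np.ndarray:
    if window < 1 or window % 2 == 0:
        raise ValueError(f"smoothing window must be an odd integer >= 1, got {window}")
    values = np.asarray(values, dtype=np.float64)
    if window == 1:
        return values.copy()
    pad = window // 2
    padded = np.pad(values, pad, mode="edge")
    return np.convolve(padded, np.ones(window) / window, mode="valid")


def _candidate_peaks(smoothed: np.ndarray) -> list[int]:
    # peaks must rise 5% of the dynamic range above their surroundings, so
    # counting noise in a unimodal histogram does not fake a second population;
    # zero-padding lets populations sitting at the curve boundary (e.g. a
    # background spike at grey 0) register with their full prominence
    prominence = 0.05 * (smoothed.max() - smoothed.min())
    padded = np.concatenate([[0.0], smoothed, [0.0]])
    peaks = signal.find_peaks(padded, prominence=prominence)[0] - 1
    return sorted(int(p) for p in peaks)


def find_inflexion(
    curve: FrequencyCurve,
    strategy: str = "valley",
    smoothing_window: int = 5,
) -> float:
    """Locate the transition point between two populations of a frequency curve.

    ``valley``: position of the minimum of the moving-average-smoothed
    frequencies between the two largest local maxima. Raises
    :class:`NoValleyError` when no two separated maxima exist, in which case
    the caller may retry with ``knee``.

    ``knee``: position of maximum curvature of the smoothed log(1+frequency)
    curve, for monotone curves with no interior valley. Detection operates
    on the bin index axis, so log-binned curves are treated uniformly.
    """
    n = curve.positions.size
    if n < 2 * smoothing_window:
        raise ValueError(
            f"curve has {n} positions; need at least {2 * smoothing_window} "
            f"for smoothing window {smoothing_window}"
        )
    smoothed = _moving_average(curve.frequencies, smoothing_window)

    if strategy == "valley":
        peaks = _candidate_peaks(smoothed)
        if len(peaks) < 2:
            raise NoValleyError("curve has fewer than two local maxima; no interior valley")
        top_two = sorted(sorted(peaks, key=lambda i: smoothed[i], reverse=True)[:2])
        lo, hi = top_two
        if hi - lo < 2:
            raise NoValleyError("the two dominant maxima are adjacent; no interior valley")
        between = smoothed[lo + 1 : hi]
        ties = np.flatnonzero(between == between.min())
        valley = lo + 1 + int(ties[ties.size // 2])  # midpoint of a flat plateau
        return float(curve.positions[valley])

    if strategy == "knee":
        x = np.arange(n, dtype=np.float64) / (n - 1)
        y = np.log1p(smoothed)
        span = y.max() - y.min()
        if span == 0:
            raise ValueError("constant curve has no knee")
        y = (y - y.min()) / span
        dy = np.gradient(y, x)
        d2y = np.gradient(dy, x)
        curvature = np.abs(d2y) / (1.0 + dy**2) ** 1.5
        interior = slice(1, n - 1)
        knee = 1 + int(np.argmax(curvature[interior]))
        return float(curve.positions[knee])

    raise ValueError(f"unknown strategy {strategy!r}; expected 'valley' or 'knee'")


def _gauss(x: np.ndarray, amplitude: float, mean: float, sd: float) -> np.ndarray:
    return amplitude * np.exp(-0.5 * ((x - mean) / sd) ** 2)


def fit_gaussian(curve: FrequencyCurve, fit_range: tuple[float, float]) -> GaussianFit:
    """Least-squares single-Gaussian fit over a restricted position range.

    The initial guess is derivative-free and deterministic: amplitude = max
    frequency in range, mean = its position, sd = half-width at
    half-maximum / 1.177 (falling back to the weighted SD).
    """
    low, high = fit_range
    mask = (curve.positions >= low) & (curve.positions <= high)
    x = curve.positions[mask]
    f = curve.frequencies[mask]
    if np.count_nonzero(f) < 5:
        raise GaussianFitError(
            f"fit range [{low}, {high}] holds {np.count_nonzero(f)} nonzero "
            "frequencies; need at least 5"
        )
    i_max = int(np.argmax(f))
    a0, m0 = float(f[i_max]), float(x[i_max])
    half = a0 / 2.0
    above = np.where(f >= half)[0]
    hwhm = max((x[above[-1]] - x[above[0]]) / 2.0, np.min(np.diff(x)))
    s0 = hwhm / 1.177
    try:
        popt, _ = optimize.curve_fit(
            _gauss, x, f, p0=(a0, m0, s0), maxfev=20000
        )
    except (RuntimeError, optimize.OptimizeWarning) as exc:
        raise GaussianFitError(
            f"Gaussian fit did not converge on range [{low}, {high}]: {exc}"
        ) from exc
    amplitude, mean, sd = float(popt[0]), float(popt[1]), float(abs(popt[2]))
    if sd <= 0 or not np.isfinite(sd):
        raise GaussianFitError(f"fitted sd degenerated to {sd}")
    if amplitude <= 0 or not np.isfinite(amplitude):
        raise GaussianFitError(f"fitted amplitude degenerated to {amplitude}")
    residuals = f - _gauss(x, amplitude, mean, sd)
    ss_res = float(np.sum(residuals**2))
    ss_tot = float(np.sum((f - f.mean()) ** 2))
    r2 = 1.0 - ss_res / ss_tot if ss_tot > 0 else 0.0
    return GaussianFit(amplitude, mean, sd, float(np.clip(r2, 0.0, 1.0)))


def gaussian_fit_range(
    curve: FrequencyCurve,
    background_grey: float,
    flank_fraction: float = 0.01,
) -> tuple[float, float]:
    """Select the bell-shaped tissue population of a grey histogram.

    The range starts just above the background threshold and ends where the
    right flank first drops below ``flank_fraction`` of the tissue peak, so
    the bright labelled tail does not bias the fit.
    """
    above = curve.positions > background_grey
    x = curve.positions[above]
    f = curve.frequencies[above]
    if x.size < 5:
        raise GaussianFitError("fewer than 5 positions above the background threshold")
    i_peak = int(np.argmax(f))
    cutoff = flank_fraction * f[i_peak]
    right = np.where(f[i_peak:] < cutoff)[0]
    i_end = i_peak + int(right[0]) if right.size else f.size - 1
    return float(x[0]), float(x[i_end])


def lectin_threshold(fit: GaussianFit, k: float = LECTIN_SD_FACTOR) -> float:
    """Grey threshold mean + k·SD of the fitted tissue population (continuous).

    Binarization compares voxel grey strictly greater than this value.
    """
    threshold = fit.mean + k * fit.sd
    if threshold >= 255:
        raise ThresholdSaturationError(
            f"threshold {threshold:.1f} >= 255: tissue population saturates the dynamic range"
        )
    return float(threshold)


def background_threshold(curve: FrequencyCurve, smoothing_window: int = 5) -> float:
    """Grey level separating the dark mounting-medium spike from the tissue bell."""
    return find_inflexion(curve, strategy="valley", smoothing_window=smoothing_window)


def normal_fraction_below(k: float = LECTIN_SD_FACTOR) -> float:
    """Fraction of a Gaussian population at or below mean + k·SD (= Φ(k))."""
    return float(stats.norm.cdf(k))


def normal_coverage(k: float = LECTIN_SD_FACTOR) -> float:
    """Fraction of a Gaussian population within mean ± k·SD."""
    return float(stats.norm.cdf(k) - stats.norm.cdf(-k))
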