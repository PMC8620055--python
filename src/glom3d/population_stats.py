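"""Relative-frequency distributions of per-object parameters with Gaussian fits."""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .threshold_stats import FrequencyCurve, GaussianFit, fit_gaussian

__all__ = ["ParameterDistribution", "parameter_distribution", "POOR_FIT_R2"]

#: Fits with R² below this are flagged as poor (clearly non-Gaussian data).
POOR_FIT_R2 = 0.9


@dataclass(frozen=True)
class ParameterDistribution:
    """Relative-frequency histogram of one morphometric parameter plus its fit."""

    parameter_name: str
    curve: FrequencyCurve  # relative frequencies in %
    fit: GaussianFit
    n_objects: int

    @property
    def poor_fit(self) -> bool:
        return self.fit.r_squared < POOR_FIT_R2

    def to_dict(self) -> dict:
        return {
            "parameter_name": self.parameter_name,
            "n_objects": self.n_objects,
            "fit": self.fit.to_dict(),
            "poor_fit": self.poor_fit,
            "positions": self.curve.positions.tolist(),
            "relative_frequencies_pct": self.curve.frequencies.tolist(),
        }


def parameter_distribution(
    values: np.ndarray, parameter_name: str = "parameter", n_bins: int = 15
) -> ParameterDistribution:
    """Histogram per-object values and fit the relative frequencies with a Gaussian.

    Values are binned over [min, max] with equal-width bins, converted to
    relative frequency (%, summing to 100), and fitted at the bin centers
    with the same least-squares engine as the grey-level stage.
    """
    values = np.asarray(values, dtype=np.float64)
    if values.size < 10:
        raise ValueError(f"need at least 10 values, got {values.size}")
    lo, hi = float(values.min()), float(values.max())
    if hi - lo <= 0:
        raise ValueError("degenerate spread: all values are equal")
    counts, edges = np.histogram(values, bins=max(int(n_bins), 3), range=(lo, hi))
    centers = (edges[:-1] + edges[1:]) / 2.0
    rel = 100.0 * counts / counts.sum()
    curve = FrequencyCurve(centers, rel)
    fit = fit_gaussian(curve, (centers[0], centers[-1]))
    return ParameterDistribution(parameter_name, curve, fit, int(values.size))
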