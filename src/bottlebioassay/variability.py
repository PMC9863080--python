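"""Within-bioassay variability: how far observed points sit from the fit.

For each retained MCMC draw m, the deviation is the average absolute
difference (in percentage points) between each observed response proportion
and the curve of that draw::

    dev_m = mean_i | y_i / n_i - p_i^(m) | * 100

The statistic is the median of dev_m over draws, with the central 95% of the
iteration deviations as its interval at institution scope.  Species-level
aggregation averages institution values and uses their min-max spread as the
interval when more than one institution contributed.

Deviations are computed on the raw probability scale (the fitted line
includes the background parameter Z), so control points are compared
against Z itself.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd

from .data import GroupingError
from .model import PosteriorDraws, log_one_minus_response

__all__ = [
    "VariabilityEstimate",
    "per_iteration_deviation",
    "within_bioassay_variability",
    "aggregate_variability",
]


@dataclass(frozen=True)
class VariabilityEstimate:
    """Median within-bioassay deviation (percentage points) with interval."""

    value: float
    ci_low: float
    ci_high: float
    institution: str
    species: str
    insecticide: str
    endpoint_type: str = "mortality"
    n_locations: int = 1

    def __post_init__(self) -> None:
        if not (0.0 <= self.ci_low <= self.value <= self.ci_high <= 100.0):
            raise ValueError(
                f"interval must satisfy 0 <= {self.ci_low} <= {self.value} "
                f"<= {self.ci_high} <= 100"
            )

    def to_dict(self) -> dict:
        return {
            "institution": self.institution,
            "species": self.species,
            "insecticide": self.insecticide,
            "endpoint_type": self.endpoint_type,
            "variability_pct": self.value,
            "ci_low": self.ci_low,
            "ci_high": self.ci_high,
            "n_locations": self.n_locations,
        }


def per_iteration_deviation(
    draws: PosteriorDraws,
    data: Sequence[tuple[float, int, int]],
    across_points: str = "mean",
) -> np.ndarray:
    """Absolute data-curve deviation per retained draw, in percentage points.

    ``across_points`` selects how the per-point absolute differences are
    combined within one draw: "mean" (default) or "median".  Points with
    n = 0 carry no information and are dropped with a warning.
    """
    if len(data) == 0:
        raise ValueError("data must be nonempty")
    if across_points not in ("mean", "median"):
        raise ValueError(f"across_points must be 'mean' or 'median', got {across_points!r}")
    arr = np.asarray(data, dtype=float)
    keep = arr[:, 1] > 0
    if not keep.all():
        warnings.warn(f"dropping {int((~keep).sum())} data point(s) with n=0", stacklevel=2)
    arr = arr[keep]
    if arr.shape[0] == 0:
        raise ValueError("no data points with n > 0")
    x, n, y = arr[:, 0], arr[:, 1], arr[:, 2]
    observed = y / n

    B = draws.flat("B")[:, None]
    C = draws.flat("C")[:, None]
    E = draws.flat("E")[:, None]
    Z = draws.flat("Z")[:, None]
    p = -np.expm1(log_one_minus_response(B, C, E, Z, x[None, :]))
    abs_dev = np.abs(observed[None, :] - np.clip(p, 0.0, 1.0)) * 100.0
    if across_points == "mean":
        return abs_dev.mean(axis=1)
    return np.median(abs_dev, axis=1)


def within_bioassay_variability(
    draws: PosteriorDraws,
    data: Sequence[tuple[float, int, int]],
    across_points: str = "mean",
    interval: float = 0.95,
) -> VariabilityEstimate:
    """Median over draws of the per-iteration deviation, with its 95% band."""
    devs = per_iteration_deviation(draws, data, across_points=across_points)
    alpha = (1.0 - interval) / 2.0
    lo, med, hi = np.quantile(devs, [alpha, 0.5, 1.0 - alpha])
    scope = draws.fit_scope
    endpoint = "OI" if scope.get("endpoint_type") == "oviposition" else scope.get("endpoint_type", "mortality")
    return VariabilityEstimate(
        value=float(med),
        ci_low=float(lo),
        ci_high=float(hi),
        institution=scope.get("institution", ""),
        species=scope.get("species", ""),
        insecticide=scope.get("insecticide", ""),
        endpoint_type=endpoint,
    )


def aggregate_variability(estimates: Sequence[VariabilityEstimate]) -> VariabilityEstimate:
    """Species-level variability: mean of institutions, min-max interval.

    With a single institution the estimate (and its own 95% interval) passes
    through unchanged.
    """
    if not estimates:
        raise ValueError("need at least one institution estimate")
    keys = {(e.species, e.insecticide, e.endpoint_type) for e in estimates}
    if len(keys) > 1:
        raise GroupingError(f"mixed species/insecticide scopes: {keys}")
    if len(estimates) == 1:
        return estimates[0]
    species, insecticide, endpoint_type = next(iter(keys))
    values = [e.value for e in estimates]
    return VariabilityEstimate(
        value=float(np.mean(values)),
        ci_low=float(np.min(values)),
        ci_high=float(np.max(values)),
        institution="(all)",
        species=species,
        insecticide=insecticide,
        endpoint_type=endpoint_type,
        n_locations=len(estimates),
    )


def variability_frame(estimates: Sequence[VariabilityEstimate]) -> pd.DataFrame:
    return pd.DataFrame([e.to_dict() for e in estimates])
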