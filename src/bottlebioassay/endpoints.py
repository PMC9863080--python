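"""Lethal-concentration / oviposition-inhibition endpoints and aggregation.

LC_q (or OI_q for sterilizing compounds) is defined on the
background-corrected curve: the concentration at which
``(p(x) - Z) / (1 - Z) = q``.  Inverting the logistic form gives the closed
form::

    LC_q = exp(C + ln((1 - q)**(-1/E) - 1) / B)

Point estimates are posterior medians of the pooled fit; uncertainty ranges
are the min and max of per-bioassay fit medians (the study's "Range"
convention).  Species-level summaries average institution estimates, and
discriminating concentrations are a fixed multiple of a high lethal quantile.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .data import GroupingError
from .model import CurveParams, PosteriorDraws

__all__ = [
    "EndpointEstimate",
    "SpeciesSummary",
    "invert_lc",
    "lc_posterior",
    "institution_estimate",
    "species_summary",
    "compute_dc",
    "round_sig",
]


def invert_lc(params: CurveParams, q: float) -> float:
    """Concentration achieving corrected response ``q``; increasing in q."""
    if not (0.0 < q < 1.0):
        raise ValueError(f"quantile q must lie strictly in (0, 1), got {q}")
    return float(np.exp(params.C + np.log((1.0 - q) ** (-1.0 / params.E) - 1.0) / params.B))


def _lc_draws(draws: PosteriorDraws, q: float) -> np.ndarray:
    if not (0.0 < q < 1.0):
        raise ValueError(f"quantile q must lie strictly in (0, 1), got {q}")
    B, C, E = draws.flat("B"), draws.flat("C"), draws.flat("E")
    return np.exp(C + np.log((1.0 - q) ** (-1.0 / E) - 1.0) / B)


def lc_posterior(
    draws: PosteriorDraws, q: float, interval: float = 0.95
) -> tuple[float, tuple[float, float]]:
    """Posterior median and central credible interval of LC_q.

    The quantile is inverted draw by draw, so the summary reflects the full
    posterior of the induced concentration rather than the median curve.
    """
    lc = _lc_draws(draws, q)
    if lc.size == 0:
        raise ValueError("draws are empty")
    alpha = (1.0 - interval) / 2.0
    lo, med, hi = np.quantile(lc, [alpha, 0.5, 1.0 - alpha])
    return float(med), (float(lo), float(hi))


@dataclass(frozen=True)
class EndpointEstimate:
    """An LC_q or OI_q estimate at institution scope.

    ``value`` is the pooled-fit posterior median; ``range_low``/``range_high``
    span the per-bioassay fit medians.  With a single bioassay the range falls
    back to the pooled credible interval and ``single_replicate`` is flagged;
    if no per-bioassay fit converged the range is unavailable (NaN).
    """

    quantile_q: float
    value: float
    range_low: float
    range_high: float
    institution: str
    species: str
    insecticide: str
    endpoint_type: str = "LC"  # "LC" or "OI"
    single_replicate: bool = False
    range_available: bool = True

    def to_dict(self) -> dict:
        return {
            "institution": self.institution,
            "species": self.species,
            "insecticide": self.insecticide,
            "endpoint_type": self.endpoint_type,
            "q": self.quantile_q,
            "value": self.value,
            "range_low": self.range_low,
            "range_high": self.range_high,
            "single_replicate": self.single_replicate,
            "range_available": self.range_available,
        }


def institution_estimate(
    pooled: PosteriorDraws,
    per_replicate: Mapping[str, PosteriorDraws] | Sequence[PosteriorDraws],
    q: float,
    endpoint_type: str = "LC",
) -> EndpointEstimate:
    """Combine the pooled fit with per-bioassay fits into one estimate.

    Only converged per-bioassay fits contribute to the range.
    """
    scope = pooled.fit_scope
    value, (ci_lo, ci_hi) = lc_posterior(pooled, q)
    reps = list(per_replicate.values()) if isinstance(per_replicate, Mapping) else list(per_replicate)
    rep_medians = [lc_posterior(r, q)[0] for r in reps if r.converged]
    if len(rep_medians) >= 2:
        # the range must bracket the pooled point estimate: pooled and
        # per-bioassay fits are separate models, so include the pooled median
        lo = min(*rep_medians, value)
        hi = max(*rep_medians, value)
        single, available = False, True
    elif len(rep_medians) == 1:
        # a single curve: fall back on the pooled credible interval
        lo, hi = ci_lo, ci_hi
        single, available = True, True
    else:
        lo, hi = float("nan"), float("nan")
        single, available = False, False
    return EndpointEstimate(
        quantile_q=q,
        value=value,
        range_low=lo,
        range_high=hi,
        institution=scope.get("institution", ""),
        species=scope.get("species", ""),
        insecticide=scope.get("insecticide", ""),
        endpoint_type=endpoint_type,
        single_replicate=single,
        range_available=available,
    )


@dataclass(frozen=True)
class SpeciesSummary:
    """Mean of institution estimates for one species-insecticide pair."""

    quantile_q: float
    value: float
    range_low: float
    range_high: float
    species: str
    insecticide: str
    endpoint_type: str
    n_locations: int

    def to_dict(self) -> dict:
        return {
            "species": self.species,
            "insecticide": self.insecticide,
            "endpoint_type": self.endpoint_type,
            "q": self.quantile_q,
            "value": self.value,
            "range_low": self.range_low,
            "range_high": self.range_high,
            "n_locations": self.n_locations,
        }


def species_summary(estimates: Sequence[EndpointEstimate]) -> SpeciesSummary:
    """Average institution values; the overall range spans all institutions."""
    if not estimates:
        raise ValueError("need at least one institution estimate")
    keys = {(e.species, e.insecticide, e.endpoint_type, e.quantile_q) for e in estimates}
    if len(keys) > 1:
        raise GroupingError(f"mixed species/insecticide/endpoint scopes: {keys}")
    species, insecticide, endpoint_type, q = next(iter(keys))
    values = [e.value for e in estimates]
    lows = [e.range_low for e in estimates if e.range_available]
    highs = [e.range_high for e in estimates if e.range_available]
    return SpeciesSummary(
        quantile_q=q,
        value=float(np.mean(values)),
        range_low=float(np.min(lows)) if lows else float("nan"),
        range_high=float(np.max(highs)) if highs else float("nan"),
        species=species,
        insecticide=insecticide,
        endpoint_type=endpoint_type,
        n_locations=len(estimates),
    )


def round_sig(value: float, sig_figs: int = 2) -> float:
    """Round to a number of significant figures."""
    if value == 0 or not np.isfinite(value):
        return value
    magnitude = int(np.floor(np.log10(abs(value))))
    return round(value, sig_figs - 1 - magnitude)


def compute_dc(
    lc: EndpointEstimate, multiplier: float = 2.0, sig_figs: int = 2
) -> float:
    """Discriminating concentration: a multiple of a high lethal quantile.

    Conventionally twice LC99.9 (or twice LC99, per the basis chosen),
    rounded to two significant figures for publication.
    """
    if multiplier <= 0:
        raise ValueError(f"multiplier must be positive, got {multiplier}")
    if lc.quantile_q not in (0.99, 0.999):
        raise ValueError(
            f"discriminating concentrations are based on LC99 or LC99.9; got q={lc.quantile_q}"
        )
    return round_sig(multiplier * lc.value, sig_figs)


def endpoint_frame(estimates: Sequence[EndpointEstimate | SpeciesSummary]) -> pd.DataFrame:
    return pd.DataFrame([e.to_dict() for e in estimates])
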