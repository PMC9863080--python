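"""Synthetic multi-laboratory bioassay campaigns with known ground truth.

Emulates the multi-centre study design: each bioassay exposes four replicate
bottles of 25 mosquitoes at each of six concentrations, plus two control
bottles of 25; three bioassays per laboratory give ~300 mosquitoes per
concentration.  Outcomes are binomial draws from a known logistic curve,
optionally with beta-binomial between-replicate overdispersion
(parameterized by the intra-class correlation rho) and between-laboratory
parameter heterogeneity (independent Gaussian perturbations of log B, C and
logit Z).

All randomness flows from a single master seed through
``numpy.random.SeedSequence`` substreams, so identical seeds reproduce
byte-identical datasets and laboratories are statistically independent.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Mapping

import numpy as np
import yaml

from .data import BioassayDataset, BioassayRecord, EndpointType
from .model import CurveParams, mortality_curve

__all__ = [
    "TrueCurve",
    "CampaignDesign",
    "simulate_bioassay",
    "simulate_campaign",
    "simulate_oviposition",
    "perturb_curve",
    "design_from_config",
]


class TrueCurve(CurveParams):
    """Ground-truth curve parameters used to generate synthetic data."""


@dataclass(frozen=True)
class CampaignDesign:
    """Layout of one simulated campaign.

    ``n_per_concentration`` is the bottle (replicate) size;
    ``replicates_per_concentration`` bottles are run per concentration per
    bioassay, and ``n_control`` control bottles of the same size accompany
    every bioassay.  Defaults reproduce the standard two-step design's main
    phase: 6 concentrations x 4 x 25 mosquitoes, 2 x 25 controls, three
    bioassays per laboratory.
    """

    concentrations: tuple[float, ...] = (0.1, 0.3, 1.0, 3.0, 10.0, 30.0)
    n_per_concentration: int = 25
    replicates_per_concentration: int = 4
    n_control: int = 2
    n_bioassays: int = 3
    overdispersion_rho: float = 0.0
    laboratories: tuple[tuple[str, float], ...] = (("lab_1", 0.0),)

    def __post_init__(self) -> None:
        concs = self.concentrations
        if any(c <= 0 for c in concs):
            raise ValueError("concentrations must be positive; controls are added separately")
        if any(b <= a for a, b in zip(concs, concs[1:])):
            raise ValueError("concentrations must be strictly increasing")
        for name in ("n_per_concentration", "replicates_per_concentration", "n_control", "n_bioassays"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")
        if not (0.0 <= self.overdispersion_rho < 1.0):
            raise ValueError("overdispersion_rho must lie in [0, 1)")
        labels = [lab for lab, _ in self.laboratories]
        if len(labels) != len(set(labels)):
            raise ValueError(f"duplicate laboratory labels: {labels}")

    @property
    def rows_per_bioassay(self) -> int:
        return len(self.concentrations) * self.replicates_per_concentration + self.n_control

    @property
    def rows_per_lab(self) -> int:
        return self.rows_per_bioassay * self.n_bioassays


_DEFAULT_LABELS = {
    "institution": "lab_1",
    "country": "SIM",
    "species": "An. gambiae",
    "strain": "Kisumu",
    "insecticide": "clothianidin",
    "recording_time_h": 24,
}


def _replicate_p(p: float, rho: float, rng: np.random.Generator) -> float:
    """Replicate-level response probability under beta overdispersion.

    Beta with mean p and intra-class correlation rho; degenerate p (0 or 1)
    or rho = 0 pass through unchanged.
    """
    if rho <= 0.0 or p <= 0.0 or p >= 1.0:
        return p
    a = p * (1.0 - rho) / rho
    b = (1.0 - p) * (1.0 - rho) / rho
    return float(rng.beta(a, b))


def simulate_bioassay(
    curve: TrueCurve | CurveParams,
    design: CampaignDesign,
    seed: int | np.random.SeedSequence,
    labels: Mapping[str, object] | None = None,
) -> BioassayDataset:
    """Simulate all bioassays of one laboratory from a known curve.

    Controls are drawn with p = Z.  With ``design.overdispersion_rho > 0``
    each bottle's probability is a beta draw around the curve value before
    binomial sampling.
    """
    info = {**_DEFAULT_LABELS, **(labels or {})}
    ss = seed if isinstance(seed, np.random.SeedSequence) else np.random.SeedSequence(seed)
    rho = design.overdispersion_rho
    records: list[BioassayRecord] = []
    for b, child in enumerate(ss.spawn(design.n_bioassays), start=1):
        rng = np.random.Generator(np.random.PCG64(child))
        bioassay_id = f"{info['institution']}-assay{b:02d}"
        n = design.n_per_concentration
        for r in range(1, design.n_control + 1):
            p = _replicate_p(curve.Z, rho, rng)
            y = int(rng.binomial(n, p))
            records.append(
                _record(info, bioassay_id, f"ctrl{r}", 0.0, n, y)
            )
        for x in design.concentrations:
            p_mean = float(mortality_curve(curve, x))
            for r in range(1, design.replicates_per_concentration + 1):
                p = _replicate_p(p_mean, rho, rng)
                y = int(rng.binomial(n, p))
                records.append(
                    _record(info, bioassay_id, f"rep{r}", x, n, y)
                )
    return BioassayDataset(records, provenance=f"simulated from {curve!r}")


def _record(info, bioassay_id, replicate_id, x, n, y, chambered=None, endpoint=EndpointType.mortality):
    return BioassayRecord(
        institution=str(info["institution"]),
        country=str(info["country"]),
        species=str(info["species"]),
        strain=str(info["strain"]),
        insecticide=str(info["insecticide"]),
        endpoint_type=endpoint,
        bioassay_id=bioassay_id,
        replicate_id=replicate_id,
        concentration=float(x),
        n_exposed=int(n),
        n_responded=int(y),
        n_chambered=chambered,
        recording_time_h=int(info["recording_time_h"]),
    )


def perturb_curve(
    curve: TrueCurve | CurveParams, scale: float, rng: np.random.Generator
) -> TrueCurve:
    """Laboratory-specific curve: Gaussian shifts of log B, C and logit Z."""
    if scale <= 0.0:
        return TrueCurve(curve.B, curve.C, curve.E, curve.Z)
    eps = rng.normal(scale=scale, size=3)
    log_b = np.log(curve.B) + eps[0]
    c = curve.C + eps[1]
    if curve.Z > 0.0:
        logit_z = np.log(curve.Z / (1.0 - curve.Z)) + eps[2]
        z = float(1.0 / (1.0 + np.exp(-logit_z)))
    else:
        z = 0.0
    return TrueCurve(float(np.exp(log_b)), float(c), curve.E, z)


def simulate_campaign(
    curves_by_lab: Mapping[str, TrueCurve | CurveParams],
    design: CampaignDesign,
    seed: int,
    labels: Mapping[str, object] | None = None,
) -> BioassayDataset:
    """Concatenate per-laboratory simulations with independent substreams."""
    labs = list(curves_by_lab)
    if len(labs) < 1:
        raise ValueError("at least one laboratory is required")
    if len(labs) != len(set(labs)):
        raise ValueError(f"duplicate laboratory labels: {labs}")
    ss = np.random.SeedSequence(seed)
    children = ss.spawn(len(labs))
    records: list[BioassayRecord] = []
    for lab, child in zip(labs, children):
        lab_labels = {**(labels or {}), "institution": lab}
        ds = simulate_bioassay(curves_by_lab[lab], design, child, labels=lab_labels)
        records.extend(ds.records)
    return BioassayDataset(records, provenance=f"simulated campaign, {len(labs)} laboratories")


def campaign_curves(
    base_curve: TrueCurve | CurveParams, design: CampaignDesign, seed: int
) -> dict[str, TrueCurve]:
    """Per-laboratory true curves from the design's perturbation scales."""
    ss = np.random.SeedSequence((seed, 0xC0FFEE))
    children = ss.spawn(len(design.laboratories))
    curves = {}
    for (lab, scale), child in zip(design.laboratories, children):
        rng = np.random.Generator(np.random.PCG64(child))
        curves[lab] = perturb_curve(base_curve, scale, rng)
    return curves


def simulate_oviposition(
    curve: TrueCurve | CurveParams,
    control_laying_rate: float,
    design: CampaignDesign,
    seed: int,
    survival_rate: float = 0.9,
    labels: Mapping[str, object] | None = None,
) -> BioassayDataset:
    """Simulate a sterilizing-compound campaign with an oviposition endpoint.

    Survivors of the holding period (a binomial thinning of the exposed at
    ``survival_rate``) are individually chambered; the number NOT laying eggs
    is binomial with the logistic curve's probability, whose background is
    pinned to Z = 1 - control_laying_rate so the control non-laying rate
    matches the specified laying rate.
    """
    if not (0.0 < control_laying_rate <= 1.0):
        raise ValueError("control_laying_rate must lie in (0, 1]")
    z = 1.0 - control_laying_rate
    eff = CurveParams(curve.B, curve.C, curve.E, z)
    info = {**_DEFAULT_LABELS, "insecticide": "pyriproxyfen", "recording_time_h": 72, **(labels or {})}
    ss = np.random.SeedSequence(seed)
    rho = design.overdispersion_rho
    records: list[BioassayRecord] = []
    for b, child in enumerate(ss.spawn(design.n_bioassays), start=1):
        rng = np.random.Generator(np.random.PCG64(child))
        bioassay_id = f"{info['institution']}-ovi{b:02d}"
        n = design.n_per_concentration
        cells = [(0.0, f"ctrl{r}") for r in range(1, design.n_control + 1)]
        cells += [
            (x, f"rep{r}")
            for x in design.concentrations
            for r in range(1, design.replicates_per_concentration + 1)
        ]
        for x, replicate_id in cells:
            chambered = int(rng.binomial(n, survival_rate))
            p_mean = float(mortality_curve(eff, x))
            p = _replicate_p(p_mean, rho, rng)
            not_laying = int(rng.binomial(chambered, p)) if chambered > 0 else 0
            records.append(
                _record(
                    info, bioassay_id, replicate_id, x, n, not_laying,
                    chambered=chambered, endpoint=EndpointType.oviposition,
                )
            )
    return BioassayDataset(records, provenance=f"simulated oviposition campaign from {curve!r}")


def design_from_config(path: str | Path) -> CampaignDesign:
    """Read a campaign design from a YAML file whose keys mirror the fields."""
    payload = yaml.safe_load(Path(path).read_text())
    if not isinstance(payload, dict):
        raise ValueError(f"{path}: expected a mapping of design fields")
    kwargs = dict(payload)
    if "concentrations" in kwargs:
        kwargs["concentrations"] = tuple(float(c) for c in kwargs["concentrations"])
    if "laboratories" in kwargs:
        kwargs["laboratories"] = tuple(
            (str(lab), float(scale)) for lab, scale in kwargs["laboratories"]
        )
    return CampaignDesign(**kwargs)
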