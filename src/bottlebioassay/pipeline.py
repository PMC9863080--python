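"""High-level orchestration: QC -> pooled and per-bioassay fits -> endpoints
-> variability, over every (institution, species, insecticide) scope.

This is the programmatic surface behind the command-line ``fit`` command,
the analysis scripts and the acceptance checks.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .data import (
    BioassayDataset,
    EndpointType,
    QCReport,
    apply_qc,
    qc_report_frame,
)
from .endpoints import (
    EndpointEstimate,
    SpeciesSummary,
    compute_dc,
    institution_estimate,
    species_summary,
)
from .model import (
    FitError,
    MCMCConfig,
    PosteriorDraws,
    PriorSpec,
    fit_mcmc,
    fit_per_replicate,
    pooled_triples,
)
from .variability import (
    VariabilityEstimate,
    aggregate_variability,
    within_bioassay_variability,
)

__all__ = ["ScopeResult", "CampaignResult", "analyse_campaign"]


@dataclass
class ScopeResult:
    """Everything fitted for one (institution, species, insecticide) scope."""

    scope: dict[str, str]
    pooled: PosteriorDraws
    per_replicate: dict[str, PosteriorDraws]
    endpoints: list[EndpointEstimate]
    variability: VariabilityEstimate
    data: list[tuple[float, int, int]]


@dataclass
class CampaignResult:
    """All scope fits of one campaign plus species-level aggregation."""

    scopes: list[ScopeResult]
    species_endpoints: list[SpeciesSummary]
    species_variability: list[VariabilityEstimate]
    qc_reports: list[QCReport]
    skipped_scopes: list[tuple[dict[str, str], str]] = field(default_factory=list)

    @property
    def all_converged(self) -> bool:
        return all(s.pooled.converged for s in self.scopes)

    def endpoint_frame(self) -> pd.DataFrame:
        rows = [e.to_dict() | {"level": "institution"} for s in self.scopes for e in s.endpoints]
        rows += [e.to_dict() | {"level": "species"} for e in self.species_endpoints]
        return pd.DataFrame(rows)

    def variability_frame(self) -> pd.DataFrame:
        rows = [s.variability.to_dict() | {"level": "institution"} for s in self.scopes]
        rows += [e.to_dict() | {"level": "species"} for e in self.species_variability]
        return pd.DataFrame(rows)

    def qc_frame(self) -> pd.DataFrame:
        return qc_report_frame(self.qc_reports)


def analyse_campaign(
    ds: BioassayDataset,
    priors: PriorSpec | None = None,
    config: MCMCConfig | None = None,
    quantiles: Sequence[float] = (0.50, 0.99),
    fixed: Mapping[str, float] | None = None,
    fit_replicates: bool = True,
) -> CampaignResult:
    """Run the full analysis over every scope of a campaign dataset.

    One pooled curve is fitted per (institution, species, insecticide); a
    curve per individual bioassay supplies the min-max endpoint ranges.
    Scopes left empty after quality control are skipped and reported.
    """
    priors = priors or PriorSpec()
    config = config or MCMCConfig()
    accepted, qc_reports = apply_qc(ds)
    scopes = accepted.groupby_scope()
    scope_keys = sorted(scopes)
    sub_seeds = np.random.SeedSequence((config.seed, 0xF17)).spawn(max(len(scope_keys), 1))

    results: list[ScopeResult] = []
    skipped: list[tuple[dict[str, str], str]] = []
    all_keys = sorted(ds.groupby_scope())
    for key in all_keys:
        scope = dict(zip(("institution", "species", "insecticide"), key))
        if key not in scopes:
            skipped.append((scope, "all bioassays discarded or unevaluable by QC"))

    for sub_seed, key in zip(sub_seeds, scope_keys):
        records = scopes[key]
        scope = dict(zip(("institution", "species", "insecticide"), key))
        scope["endpoint_type"] = records[0].endpoint_type.value
        triples = pooled_triples(records)
        scope_config = MCMCConfig(
            chains=config.chains,
            iterations=config.iterations,
            warmup_fraction=config.warmup_fraction,
            escalation_iterations=config.escalation_iterations,
            rhat_threshold=config.rhat_threshold,
            seed=int(sub_seed.generate_state(1)[0] % (2**31)),
        )
        try:
            pooled = fit_mcmc(triples, priors, scope_config, dict(fixed or {}), fit_scope=scope)
        except FitError as exc:
            skipped.append((scope, f"pooled fit failed: {exc}"))
            continue
        scope_ds = BioassayDataset(records)
        reps = (
            fit_per_replicate(scope_ds, priors, scope_config, dict(fixed or {}))
            if fit_replicates
            else {}
        )
        endpoint_label = "OI" if records[0].endpoint_type == EndpointType.oviposition else "LC"
        endpoints = [
            institution_estimate(pooled, reps, q, endpoint_type=endpoint_label)
            for q in quantiles
        ]
        variability = within_bioassay_variability(pooled, triples)
        results.append(ScopeResult(scope, pooled, reps, endpoints, variability, triples))

    species_groups: dict[tuple, list[ScopeResult]] = {}
    for s in results:
        key = (s.scope["species"], s.scope["insecticide"])
        species_groups.setdefault(key, []).append(s)
    species_endpoints: list[SpeciesSummary] = []
    species_var: list[VariabilityEstimate] = []
    for group in species_groups.values():
        for qi, q in enumerate(quantiles):
            species_endpoints.append(species_summary([g.endpoints[qi] for g in group]))
        species_var.append(aggregate_variability([g.variability for g in group]))

    return CampaignResult(results, species_endpoints, species_var, qc_reports, skipped)
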