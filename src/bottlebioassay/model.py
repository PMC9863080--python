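"""Bayesian binomial concentration-response model.

The response probability at concentration ``x`` (µg/bottle) follows a
five-parameter logistic curve with the top and bottom asymptotes fixed
(A = 0, D = 1)::

    p(x) = 1 - (1 - Z) / [1 + exp(B * (ln x - C))]**E

* ``B`` — slope on the natural-log concentration scale (B > 0),
* ``C`` — location, ln(µg/bottle),
* ``E`` — asymmetry (E > 0; E = 1 gives the symmetric logistic),
* ``Z`` — background response rate, the limit of p as x -> 0, so control
  bottles (x = 0) contribute to the likelihood with p = Z and the fitted
  curve with Z divided out is the insecticide-attributable response.

The outcome of each pooled data point is binomial: y ~ Binomial(n, p(x)).
Priors are truncated normals, B ~ N(3,1) on (0, inf), C ~ N(3,5)
unconstrained, E ~ N(3,5) on (0, inf) and Z ~ N(0,5) on [0, 1).

Sampling uses four independent adaptive random-walk Metropolis chains on an
unconstrained transform of the free parameters (log B, C, log E, logit Z)
with Jacobian correction, 5000 iterations per chain and the first half
discarded as warm-up.  If the split R-hat of any free parameter exceeds the
convergence threshold the fit is automatically re-run once at 10 000
iterations.  The sampler is cross-checked against an exhaustive grid
posterior (``grid_posterior_oracle``) in the test suite.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import arviz as az
import numpy as np
import pandas as pd
from scipy.special import expit, gammaln, logit, logsumexp

from .data import (
    BioassayDataset,
    BioassayRecord,
    GroupingError,
    pool_replicates,
)

__all__ = [
    "CurveParams",
    "PriorSpec",
    "MCMCConfig",
    "PosteriorDraws",
    "FitError",
    "PARAM_NAMES",
    "mortality_curve",
    "log_one_minus_response",
    "log_likelihood",
    "fit_mcmc",
    "fit_per_replicate",
    "grid_posterior_oracle",
    "GridPosterior",
    "pooled_triples",
]

PARAM_NAMES = ("B", "C", "E", "Z")


class FitError(RuntimeError):
    """Sampler failure; carries the diagnostics of the failed run."""

    def __init__(self, message: str, diagnostics: dict | None = None):
        super().__init__(message)
        self.diagnostics = diagnostics or {}


@dataclass(frozen=True)
class CurveParams:
    """Parameters of one concentration-response curve (A = 0, D = 1 fixed)."""

    B: float
    C: float
    E: float = 1.0
    Z: float = 0.0

    A: float = field(default=0.0, init=False, repr=False)
    D: float = field(default=1.0, init=False, repr=False)

    def __post_init__(self) -> None:
        if not self.B > 0:
            raise ValueError(f"slope B must be positive, got {self.B}")
        if not self.E > 0:
            raise ValueError(f"asymmetry E must be positive, got {self.E}")
        if not (0.0 <= self.Z < 1.0):
            raise ValueError(f"background Z must lie in [0, 1), got {self.Z}")

    def as_array(self) -> np.ndarray:
        return np.array([self.B, self.C, self.E, self.Z], dtype=float)


def log_one_minus_response(
    B: np.ndarray, C: np.ndarray, E: np.ndarray, Z: np.ndarray, x: np.ndarray
) -> np.ndarray:
    """log(1 - p(x)) computed without cancellation.

    ``1 - p = (1 - Z) * [1 + exp(B (ln x - C))]**(-E)`` so the log is
    ``log1p(-Z) - E * softplus(B (ln x - C))``; for x = 0 the softplus term
    vanishes and 1 - p = 1 - Z.
    """
    x = np.asarray(x, dtype=float)
    with np.errstate(divide="ignore"):  # ln(0) -> -inf is the control limit
        t = B * (np.log(x) - C)
    softplus = np.logaddexp(0.0, t)
    softplus = np.where(x == 0.0, 0.0, softplus)
    return np.log1p(-Z) - E * softplus


def mortality_curve(params: CurveParams, x) -> np.ndarray | float:
    """Response probability at concentration ``x`` (µg/bottle; 0 = control).

    Returns Z at x = 0 and approaches 1 as x grows; non-decreasing in x.
    """
    scalar = np.isscalar(x)
    xv = np.atleast_1d(np.asarray(x, dtype=float))
    if np.any(xv < 0):
        raise ValueError("concentration must be non-negative")
    p = -np.expm1(log_one_minus_response(params.B, params.C, params.E, params.Z, xv))
    p = np.clip(p, 0.0, 1.0)
    return float(p[0]) if scalar else p


def _binom_logpmf(y: np.ndarray, n: np.ndarray, logp: np.ndarray, log1mp: np.ndarray) -> np.ndarray:
    """Binomial log-pmf from (log p, log(1-p)); exact at the p in {0,1} edges."""
    coef = gammaln(n + 1) - gammaln(y + 1) - gammaln(n - y + 1)
    with np.errstate(invalid="ignore"):
        term_y = np.where(y > 0, y * logp, 0.0)
        term_ny = np.where(n - y > 0, (n - y) * log1mp, 0.0)
    return coef + term_y + term_ny


def log_likelihood(params: CurveParams, data: Sequence[tuple[float, int, int]]) -> float:
    """Binomial log-likelihood of pooled (x, n, y) data points.

    Control rows enter with p = Z.  A structurally impossible outcome
    (p = 0 with y > 0) yields -inf rather than raising.  Empty trials
    (n = 0) contribute zero.
    """
    if len(data) == 0:
        raise ValueError("data must be nonempty")
    arr = np.asarray(data, dtype=float)
    x, n, y = arr[:, 0], arr[:, 1], arr[:, 2]
    log1mp = log_one_minus_response(params.B, params.C, params.E, params.Z, x)
    with np.errstate(divide="ignore"):
        logp = np.log(-np.expm1(np.minimum(log1mp, -0.0)))
    return float(np.sum(_binom_logpmf(y, n, logp, log1mp)))


@dataclass(frozen=True)
class PriorSpec:
    """Independent truncated-normal priors, as (mean, sd, lower, upper)."""

    B: tuple[float, float, float, float] = (3.0, 1.0, 0.0, np.inf)
    C: tuple[float, float, float, float] = (3.0, 5.0, -np.inf, np.inf)
    E: tuple[float, float, float, float] = (3.0, 5.0, 0.0, np.inf)
    Z: tuple[float, float, float, float] = (0.0, 5.0, 0.0, 1.0)

    def log_prior(self, values: Mapping[str, np.ndarray]) -> np.ndarray:
        """Unnormalized log prior density at natural-scale values.

        Out-of-support values get -inf; the truncation normalisation is a
        constant and is omitted.
        """
        total = 0.0
        for name in PARAM_NAMES:
            mean, sd, lo, hi = getattr(self, name)
            v = np.asarray(values[name], dtype=float)
            inside = (v >= lo) & (v <= hi)
            total = total + np.where(inside, -0.5 * ((v - mean) / sd) ** 2, -np.inf)
        return total


@dataclass(frozen=True)
class MCMCConfig:
    """Sampling schedule: 4 chains x 5000 iterations, half warm-up, with a
    single automatic escalation to 10 000 iterations on non-convergence."""

    chains: int = 4
    iterations: int = 5000
    warmup_fraction: float = 0.5
    escalation_iterations: int = 10000
    rhat_threshold: float = 1.05
    seed: int = 0

    def __post_init__(self) -> None:
        if self.iterations % 2 != 0:
            raise ValueError("iterations must be even")
        if not (0.0 < self.warmup_fraction < 1.0):
            raise ValueError("warmup_fraction must lie in (0, 1)")


@dataclass
class PosteriorDraws:
    """Retained MCMC draws with convergence diagnostics.

    ``samples[name]`` has shape (chains, retained_iterations) on the natural
    parameter scale; fixed parameters are stored as constant arrays so every
    draw is a complete curve.
    """

    samples: dict[str, np.ndarray]
    diagnostics: dict
    converged: bool
    fit_scope: dict[str, str] = field(default_factory=dict)
    runs: list[dict] = field(default_factory=list)

    @property
    def n_chains(self) -> int:
        return next(iter(self.samples.values())).shape[0]

    @property
    def n_retained(self) -> int:
        a = next(iter(self.samples.values()))
        return int(a.shape[0] * a.shape[1])

    def flat(self, name: str) -> np.ndarray:
        return self.samples[name].reshape(-1)

    def curves(self) -> list[CurveParams]:
        """All retained draws as CurveParams, chain-major order."""
        B, C = self.flat("B"), self.flat("C")
        E, Z = self.flat("E"), self.flat("Z")
        return [CurveParams(b, c, e, z) for b, c, e, z in zip(B, C, E, Z)]

    def posterior_median_params(self) -> CurveParams:
        return CurveParams(
            float(np.median(self.flat("B"))),
            float(np.median(self.flat("C"))),
            float(np.median(self.flat("E"))),
            float(np.median(self.flat("Z"))),
        )

    def to_frame(self) -> pd.DataFrame:
        chains, iters = next(iter(self.samples.values())).shape
        out = {
            "chain": np.repeat(np.arange(chains), iters),
            "iteration": np.tile(np.arange(iters), chains),
        }
        for name in PARAM_NAMES:
            out[name] = self.samples[name].reshape(-1)
        return pd.DataFrame(out)

    def save(self, draws_path: str | Path, summary_path: str | Path | None = None) -> None:
        self.to_frame().to_csv(draws_path, index=False, float_format="%.12g")
        if summary_path is not None:
            payload = {
                "fit_scope": self.fit_scope,
                "converged": self.converged,
                "diagnostics": self.diagnostics,
                "runs": self.runs,
                "posterior_median": {
                    name: float(np.median(self.flat(name))) for name in PARAM_NAMES
                },
            }
            Path(summary_path).write_text(json.dumps(payload, indent=2, default=float))

    @classmethod
    def load(cls, draws_path: str | Path, summary_path: str | Path | None = None) -> "PosteriorDraws":
        frame = pd.read_csv(draws_path)
        chains = int(frame["chain"].max()) + 1
        iters = len(frame) // chains
        samples = {
            name: frame[name].to_numpy().reshape(chains, iters) for name in PARAM_NAMES
        }
        diagnostics: dict = {}
        converged = True
        scope: dict[str, str] = {}
        runs: list[dict] = []
        if summary_path is not None:
            payload = json.loads(Path(summary_path).read_text())
            diagnostics = payload.get("diagnostics", {})
            converged = bool(payload.get("converged", True))
            scope = payload.get("fit_scope", {})
            runs = payload.get("runs", [])
        return cls(samples, diagnostics, converged, scope, runs)


# --- transforms between the natural and unconstrained sampling scales -------

def _to_unconstrained(name: str, v: np.ndarray) -> np.ndarray:
    if name in ("B", "E"):
        return np.log(v)
    if name == "Z":
        return logit(np.clip(v, 1e-12, 1 - 1e-12))
    return np.asarray(v, dtype=float)


def _to_natural(name: str, u: np.ndarray) -> np.ndarray:
    if name in ("B", "E"):
        return np.exp(u)
    if name == "Z":
        return expit(u)
    return u


def _log_jacobian(name: str, u: np.ndarray) -> np.ndarray:
    """log |d natural / d unconstrained| for the change of variables."""
    if name in ("B", "E"):
        return u
    if name == "Z":
        return u - 2.0 * np.logaddexp(0.0, u)  # log sigmoid'(u)
    return np.zeros_like(u)


def pooled_triples(
    records: Sequence[BioassayRecord], include_controls: bool = True
) -> list[tuple[float, int, int]]:
    """Pool replicates into (x, n, y) data points, one per bioassay x concentration.

    This is the data-point granularity of the fits: within one bioassay the
    replicate bottles at a concentration are summed, and separate bioassays
    contribute separate points at the same concentration.
    """
    cells: dict[tuple[str, float], list[BioassayRecord]] = {}
    for r in records:
        cells.setdefault((r.bioassay_id, r.concentration), []).append(r)
    triples = []
    for (bioassay_id, conc), group in sorted(cells.items()):
        if conc == 0.0 and not include_controls:
            continue
        n, y = pool_replicates(group)
        triples.append((conc, n, y))
    return triples


def _log_target_factory(data, priors: PriorSpec, free: list[str], fixed: dict[str, float]):
    """Vectorized log posterior density on the unconstrained scale.

    Accepts a (n_walkers, n_free) array; returns (n_walkers,) log densities.
    Empty data gives a prior-only target (used for prior-recovery checks).
    """
    if data is not None and len(data) > 0:
        arr = np.asarray(data, dtype=float)
        x, n, y = arr[:, 0], arr[:, 1], arr[:, 2]
    else:
        x = n = y = None

    def log_target(u: np.ndarray) -> np.ndarray:
        u = np.atleast_2d(u)
        natural: dict[str, np.ndarray] = {}
        log_jac = np.zeros(u.shape[0])
        for j, name in enumerate(free):
            natural[name] = _to_natural(name, u[:, j])
            log_jac = log_jac + _log_jacobian(name, u[:, j])
        for name, v in fixed.items():
            natural[name] = np.full(u.shape[0], v)
        lp = priors.log_prior(natural) + log_jac
        if x is not None:
            B = natural["B"][:, None]
            C = natural["C"][:, None]
            E = natural["E"][:, None]
            Z = natural["Z"][:, None]
            log1mp = log_one_minus_response(B, C, E, Z, x[None, :])
            with np.errstate(divide="ignore", invalid="ignore"):
                logp = np.log(-np.expm1(np.minimum(log1mp, 0.0)))
            ll = _binom_logpmf(y[None, :], n[None, :], logp, log1mp)
            # p == 0 with y > 0 is impossible data, not a numerical error
            ll = np.where(np.isnan(ll), -np.inf, ll)
            lp = lp + ll.sum(axis=1)
        return np.where(np.isfinite(lp), lp, -np.inf)

    return log_target


def _run_chains(
    log_target,
    free: list[str],
    fixed: dict[str, float],
    priors: PriorSpec,
    chains: int,
    iterations: int,
    warmup_fraction: float,
    rng: np.random.Generator,
) -> tuple[dict[str, np.ndarray], float]:
    """Adaptive random-walk Metropolis; returns retained natural-scale draws.

    Per-chain proposal covariance follows the running sample covariance of
    the warm-up draws (scaled by 2.38^2/d), with a Robbins-Monro global
    scale tuned towards a 0.3 acceptance rate.  Adaptation freezes at the
    end of warm-up so the retained draws target the exact posterior.
    """
    d = len(free)
    n_warm = int(round(iterations * warmup_fraction))
    n_keep = iterations - n_warm

    # overdispersed initial points drawn around the prior means
    u0 = np.empty((chains, d))
    for j, name in enumerate(free):
        mean, sd, lo, hi = getattr(priors, name)
        start = np.clip(mean, lo + 0.25 * sd if np.isfinite(lo) else -np.inf, np.inf)
        if name in ("B", "E"):
            start = max(start, 0.5)
        if name == "Z":
            start = min(max(mean, 0.02), 0.5)
        u0[:, j] = _to_unconstrained(name, np.full(chains, float(start)))
    u0 += rng.normal(scale=0.5, size=(chains, d))

    current = u0
    current_lp = log_target(current)
    # restart any chain initialised in a zero-density region
    for attempt in range(50):
        bad = ~np.isfinite(current_lp)
        if not bad.any():
            break
        current[bad] = u0[bad] + rng.normal(scale=0.1, size=(int(bad.sum()), d))
        current_lp = log_target(current)
    if not np.isfinite(current_lp).all():
        raise FitError("could not initialise all chains at finite posterior density")

    log_scale = np.full(chains, np.log(2.38 / np.sqrt(d)))
    chol = np.tile(np.eye(d) * 0.5, (chains, 1, 1))
    mean_acc = np.zeros(chains)
    run_mean = current.copy()
    run_cov = np.tile(np.eye(d) * 0.25, (chains, 1, 1))
    target_accept = 0.3

    kept = np.empty((chains, n_keep, d))
    accepted_post = 0

    for it in range(iterations):
        step = np.einsum("cij,cj->ci", chol, rng.standard_normal((chains, d)))
        proposal = current + np.exp(log_scale)[:, None] * step
        prop_lp = log_target(proposal)
        log_u = np.log(rng.uniform(size=chains))
        accept = log_u < (prop_lp - current_lp)
        current = np.where(accept[:, None], proposal, current)
        current_lp = np.where(accept, prop_lp, current_lp)

        if it < n_warm:
            # Haario-style covariance adaptation + acceptance-rate tuning
            w = 1.0 / (it + 2)
            delta = current - run_mean
            run_mean = run_mean + w * delta
            run_cov = (1 - w) * run_cov + w * np.einsum("ci,cj->cij", delta, delta)
            log_scale = log_scale + w * (accept.astype(float) - target_accept)
            if (it + 1) % 25 == 0 and it > 50:
                for c in range(chains):
                    try:
                        chol[c] = np.linalg.cholesky(
                            run_cov[c] + 1e-9 * np.eye(d)
                        )
                    except np.linalg.LinAlgError:
                        pass
        else:
            kept[:, it - n_warm, :] = current
            accepted_post += int(accept.sum())

    if accepted_post == 0:
        raise FitError("sampler accepted no proposals after warm-up")

    samples: dict[str, np.ndarray] = {}
    for j, name in enumerate(free):
        samples[name] = _to_natural(name, kept[:, :, j])
    for name, v in fixed.items():
        samples[name] = np.full((chains, n_keep), float(v))
    accept_rate = accepted_post / (chains * n_keep)
    return samples, accept_rate


def _diagnose(samples: dict[str, np.ndarray], free: list[str]) -> dict:
    """Split R-hat and bulk ESS of the free parameters via ArviZ."""
    idata = az.from_dict({name: samples[name] for name in free})
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        rhat = az.rhat(idata)
        ess = az.ess(idata)
    out = {
        "rhat": {name: float(rhat[name].values) for name in free},
        "ess_bulk": {name: float(ess[name].values) for name in free},
    }
    out["max_rhat"] = max(out["rhat"].values())
    return out


def fit_mcmc(
    data: Sequence[tuple[float, int, int]] | None,
    priors: PriorSpec | None = None,
    config: MCMCConfig | None = None,
    fixed: dict[str, float] | None = None,
    fit_scope: dict[str, str] | None = None,
) -> PosteriorDraws:
    """Fit the curve to pooled (x, n, y) data points.

    ``fixed`` pins parameters (e.g. ``{"E": 1.0, "Z": 0.0}`` for the reduced
    symmetric model); the remaining parameters are sampled.  ``data=None`` or
    an empty sequence samples the prior alone.  If the first run fails the
    R-hat convergence check, the fit is repeated once at
    ``config.escalation_iterations``; the returned ``converged`` flag and
    diagnostics describe the final run, and ``runs`` records the schedule of
    every run performed.
    """
    priors = priors or PriorSpec()
    config = config or MCMCConfig()
    fixed = dict(fixed or {})
    free = [name for name in PARAM_NAMES if name not in fixed]
    if not free:
        raise ValueError("at least one parameter must be free")
    if data is not None and len(data) > 0:
        treated = {x for x, _, _ in data if x > 0}
        if len(treated) < 2:
            warnings.warn(
                "fewer than 2 distinct treated concentrations; the curve is weakly identified",
                stacklevel=2,
            )

    log_target = _log_target_factory(data, priors, free, fixed)
    seed_seq = np.random.SeedSequence(config.seed)
    runs: list[dict] = []
    schedule = [config.iterations, config.escalation_iterations]
    samples: dict[str, np.ndarray] = {}
    diagnostics: dict = {}
    converged = False
    for run_index, iters in enumerate(schedule):
        rng = np.random.Generator(np.random.PCG64(seed_seq.spawn(1)[0] if run_index else seed_seq))
        samples, accept_rate = _run_chains(
            log_target, free, fixed, priors,
            config.chains, iters, config.warmup_fraction, rng,
        )
        diagnostics = _diagnose(samples, free)
        diagnostics["acceptance_rate"] = accept_rate
        converged = diagnostics["max_rhat"] < config.rhat_threshold
        runs.append(
            {"iterations": iters, "max_rhat": diagnostics["max_rhat"], "converged": converged}
        )
        if converged:
            break
    return PosteriorDraws(samples, diagnostics, converged, fit_scope or {}, runs)


def fit_per_replicate(
    dataset: BioassayDataset,
    priors: PriorSpec | None = None,
    config: MCMCConfig | None = None,
    fixed: dict[str, float] | None = None,
) -> dict[str, PosteriorDraws]:
    """Fit one curve per bioassay (the per-replicate uncertainty convention).

    Each bioassay gets a deterministic sub-seed spawned from ``config.seed``.
    Bioassays whose pooled data cannot be fitted are skipped with a warning.
    """
    config = config or MCMCConfig()
    groups = dataset.groupby_bioassay()
    fits: dict[str, PosteriorDraws] = {}
    keys = sorted(groups)
    children = np.random.SeedSequence(config.seed).spawn(len(keys))
    for sub_seed, key in zip(children, keys):
        institution, species, insecticide, bioassay_id = key
        records = groups[key]
        triples = pooled_triples(records)
        sub_config = MCMCConfig(
            chains=config.chains,
            iterations=config.iterations,
            warmup_fraction=config.warmup_fraction,
            escalation_iterations=config.escalation_iterations,
            rhat_threshold=config.rhat_threshold,
            seed=int(sub_seed.generate_state(1)[0] % (2**31)),
        )
        scope = {
            "institution": institution,
            "species": species,
            "insecticide": insecticide,
            "bioassay_id": bioassay_id,
        }
        try:
            fits[bioassay_id] = fit_mcmc(triples, priors, sub_config, fixed, fit_scope=scope)
        except FitError as exc:
            warnings.warn(f"skipping bioassay {bioassay_id}: {exc}", stacklevel=2)
    return fits


@dataclass
class GridPosterior:
    """Exhaustive posterior over a parameter grid, for oracle comparisons."""

    grids: dict[str, np.ndarray]
    log_mass: np.ndarray  # shape = tuple(len(g) for g in grids.values())

    @property
    def mass(self) -> np.ndarray:
        return np.exp(self.log_mass)

    def marginal(self, name: str) -> tuple[np.ndarray, np.ndarray]:
        names = list(self.grids)
        axis = tuple(i for i, n in enumerate(names) if n != name)
        marg = logsumexp(self.log_mass, axis=axis)
        return self.grids[name], np.exp(marg)

    def marginal_mean(self, name: str) -> float:
        values, mass = self.marginal(name)
        return float(np.sum(values * mass))

    def marginal_sd(self, name: str) -> float:
        values, mass = self.marginal(name)
        mu = np.sum(values * mass)
        return float(np.sqrt(np.sum(mass * (values - mu) ** 2)))

    def marginal_quantile(self, name: str, q: float) -> float:
        values, mass = self.marginal(name)
        cdf = np.cumsum(mass)
        return float(values[int(np.searchsorted(cdf, q))])


def grid_posterior_oracle(
    data: Sequence[tuple[float, int, int]] | None,
    priors: PriorSpec | None = None,
    grid: Mapping[str, Sequence[float]] | None = None,
) -> GridPosterior:
    """Brute-force posterior over a cartesian parameter grid.

    Single-value grid entries pin a parameter.  Masses are normalized to sum
    to one; internal rescaling guards against underflow.  Intended as an
    independent check of ``fit_mcmc`` on small problems (<= ~1e6 cells).
    """
    priors = priors or PriorSpec()
    if grid is None:
        raise ValueError("an explicit per-parameter grid is required")
    grids = {name: np.asarray(grid[name], dtype=float) for name in PARAM_NAMES}
    shape = tuple(len(g) for g in grids.values())
    n_cells = int(np.prod(shape))
    if n_cells > 2_000_000:
        raise ValueError(f"grid too large to enumerate ({n_cells} cells)")

    mesh = np.meshgrid(*grids.values(), indexing="ij")
    flat = {name: m.reshape(-1) for name, m in zip(grids, mesh)}
    logpost = priors.log_prior(flat)
    if data is not None and len(data) > 0:
        arr = np.asarray(data, dtype=float)
        x, n, y = arr[:, 0], arr[:, 1], arr[:, 2]
        log1mp = log_one_minus_response(
            flat["B"][:, None], flat["C"][:, None], flat["E"][:, None], flat["Z"][:, None],
            x[None, :],
        )
        with np.errstate(divide="ignore", invalid="ignore"):
            logp = np.log(-np.expm1(np.minimum(log1mp, 0.0)))
        ll = _binom_logpmf(y[None, :], n[None, :], logp, log1mp)
        ll = np.where(np.isnan(ll), -np.inf, ll)
        logpost = logpost + ll.sum(axis=1)
    total = logsumexp(logpost)
    if not np.isfinite(total):
        raise FitError("grid posterior has zero total mass; data and prior incompatible")
    return GridPosterior(grids, (logpost - total).reshape(shape))
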