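# Methods

## Model and likelihood

Each pooled data point is one bioassay × concentration cell: replicate
bottles within a bioassay are summed (`pool_replicates`), and separate
bioassays contribute separate points, including at the same concentration.
The responder count is binomial, yᵢ ~ Binomial(nᵢ, p(xᵢ)), where the
denominator is the number exposed for mortality endpoints and the number of
chambered survivors for oviposition endpoints. The response probability is
a five-parameter logistic in ln-concentration with fixed asymptotes
(A = 0, D = 1):

p(x) = 1 − (1 − Z) · [1 + exp(B(ln x − C))]^(−E)

Control bottles (x = 0) enter the likelihood at the x → 0 limit p = Z.
This is where background correction lives: rather than applying Abbott's
formula to observed proportions before fitting, the background rate is a
model parameter and the reported curve divides it out. The standalone
`abbott_correct` function is provided for descriptive reporting only.

Numerics: log(1 − p) = log(1 − Z) − E·softplus(B(ln x − C)) is evaluated
directly (no cancellation at either asymptote), and the binomial log-pmf is
assembled from (log p, log(1 − p)) with explicit handling of the p ∈ {0, 1}
edges, so Z = 0 with observed control deaths yields −∞ (impossible data)
rather than NaN.

## Priors

B ~ N(3, 1), C ~ N(3, 5), E ~ N(3, 5), Z ~ N(0, 5), truncated to B, E > 0
and Z ∈ [0, 1); C is unconstrained. The truncation reconciles the normal
prior statements with the positivity the curve requires. Truncation
normalising constants are omitted (they are constant in the parameters).

## Sampling

No gradient-based MCMC engine is part of this package's dependency set; the
sampler is a multi-chain adaptive random-walk Metropolis algorithm written
for this model and validated against an exhaustive grid posterior. The
parameter space is transformed to ℝᵈ (log B, C, log E, logit Z, with the
appropriate Jacobian), and each of the four chains carries its own proposal
covariance, adapted during warm-up from the running sample covariance
(scaled 2.38²/d) together with a Robbins–Monro global scale tuned towards
30% acceptance. Adaptation freezes at the end of warm-up, so retained draws
target the exact posterior. The schedule is 4 chains × 5000 iterations with
the first 50% discarded; convergence is judged by split-R̂ < 1.05 on every
free parameter (computed by ArviZ, which also supplies bulk ESS). A fit
failing the check is re-run once at 10 000 iterations; the final run's
draws, diagnostics and converged flag are returned, with the schedule of
runs recorded. The R̂ threshold of 1.05 and the single-escalation-then-
report policy are design choices of this package.

Parameters can be pinned (e.g. E = 1, Z = 0) to fit reduced models; the
grid oracle (`grid_posterior_oracle`) enumerates the posterior over a
cartesian parameter grid and is the independent correctness gate for the
sampler — the test suite requires MCMC posterior means to fall within 3
Monte-Carlo standard errors of the grid means on the reduced model.

Seed discipline: every source of randomness descends from one integer seed
through `numpy.random.SeedSequence`; per-scope, per-bioassay and
escalation-run substreams are spawned deterministically, so identical
(data, config, seed) reproduce identical draws, and pipeline outputs are
byte-identical across runs.

## Quality control

Applied per bioassay on pooled controls (the design pairs every bioassay
with its own control bottles):

- mortality endpoint — control mortality ≥ 20%: discarded; in (5%, 20%):
  accepted with background correction (via Z); ≤ 5%: accepted as-is.
  Exactly 5% is treated as "no correction needed"; the literal band is
  open at both ends and the boundary choice is recorded in the QC report.
- oviposition endpoint — control laying rate (1 − pooled control
  non-laying proportion) < 30%: discarded.
- a bioassay with no control bottles is unevaluable and excluded.

## Endpoints and aggregation

LC_q is defined on the background-corrected scale and inverted in closed
form per posterior draw; the point estimate is the posterior median of the
laboratory-pooled fit and the 95% interval is the central interval of the
induced LC_q draws. (Inverting the median curve instead is available by
taking `posterior_median_params` and `invert_lc`, but per-draw inversion is
the default since it propagates the full posterior.) The laboratory-level
uncertainty range spans the per-bioassay fit medians; because pooled and
per-bioassay fits are distinct models, the pooled median is included in the
span so the range always brackets the point estimate. With a single
bioassay the range falls back to the pooled credible interval and the
estimate is flagged as a single-curve case. Species-level summaries are
arithmetic means of laboratory values with the overall min/max as the
range. Discriminating concentrations multiply a high lethal quantile (LC₉₉
or LC₉₉.₉) by 2 and round to two significant figures.

## Within-bioassay variability

For each retained draw m, devₘ = meanᵢ |yᵢ/nᵢ − p⁽ᵐ⁾(xᵢ)| × 100 over the
pooled data points (control points compared against Z⁽ᵐ⁾, since the fitted
line includes the background). The statistic is the median of devₘ over
draws; at laboratory scope its interval is the central 95% of the devₘ; at
species scope the value is the mean of laboratory values and the interval
their min/max (single laboratory: pass-through). Whether the within-draw
aggregation over points should be a mean or a median is genuinely
ambiguous; the mean is the default ("average within-bioassay variability")
and a median mode is exposed via `across_points="median"`.

## Synthetic campaigns

The generator emulates the two-step multi-centre design's main phase: six
concentrations tested as 4 replicate bottles × 25 mosquitoes, plus 2 × 25
controls, three bioassays per laboratory (~300 mosquitoes per
concentration per laboratory). Defaults place the curve at B = 3, C = 0,
E = 1 (LC₅₀ = 1 µg/bottle) with Z = 0.03 background mortality and
concentrations {0.1, 0.3, 1, 3, 10, 30} spanning ~0–100% response.
Optional features:

- between-replicate overdispersion — bottle-level probabilities drawn from
  a Beta distribution with mean p(x) and intra-class correlation ρ before
  binomial sampling (ρ = 0 recovers pure binomial);
- between-laboratory heterogeneity — Gaussian perturbation of (log B, C,
  logit Z) at a per-laboratory scale;
- oviposition campaigns — exposed females survive the holding period by
  binomial thinning (default 90%), survivors are chambered, and non-laying
  is binomial under the same curve with Z = 1 − control laying rate.

What the generator does not emulate: concentration-dependent survival
before chambering, bottle-coating degradation or volatility loss over
time, temperature effects, and real between-strain differences. Passing
recovery tests therefore demonstrate correctness of the inference given
the model family, not robustness to those field realities.

## Problem sizes and tolerances

Recovery checks use the standard design (~2000 mosquitoes per laboratory
campaign), 20 seeds for LC₅₀ recovery (±15% and 95%-interval coverage in
≥18/20), and 10 paired seeds for the overdispersion-monotonicity check; the
variability ceiling of 2 percentage points applies at 1000 mosquitoes per
concentration, where binomial noise alone predicts ~1–1.5 pp. Grid-oracle
agreement is asserted at 3 Monte-Carlo standard errors; closed-form LC
inversion is asserted against bracketed root-finding at 10⁻⁸ relative
error. Some unit fixtures shorten chains to 1200–2000 iterations where the
assertion does not depend on full-length mixing; all convergence-sensitive
checks use the full 4 × 5000 schedule.

## Known limitations

- No hierarchical multi-laboratory model: laboratories are fitted
  independently and combined by summary arithmetic, so between-laboratory
  variance is described (min–max ranges), not decomposed.
- The random-walk sampler is adequate for this 4-parameter posterior but
  mixes more slowly than gradient-based samplers; weakly identified fits
  (few concentrations, flat response) may need the escalated schedule or
  fail the R̂ check, which is reported rather than hidden.
- LC_q far outside the tested concentration range (q → 1 with small E·B)
  inherits heavy posterior tails; ranges on LC₉₉ are correspondingly wide.
- Knockdown-at-1-h endpoints and unit conversions (e.g. to mg/m²) are out
  of scope.
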