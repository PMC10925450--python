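# Methods

## The model

`wildfire_opioid` quantifies a hypothesised causal pathway: experiencing a
wildfire raises the incidence and severity of anxiety, and anxiety raises the
risk of opioid misuse. The population is U.S. young adults (ages 18–25),
treated as a single homogeneous cohort described by two baseline prevalences:

| symbol | meaning | default |
| --- | --- | --- |
| `t` | past-year opioid misuse prevalence | 0.053 |
| `q` | past-year anxiety prevalence | 0.066 |
| `OR` | odds ratio for misuse given fire-related anxiety | Lognormal, natural mean 3.04, sd 1.07 |
| `p_fire` | anxiety prevalence among the wildfire-exposed | Beta(10.5, 70), mean 0.1304 |
| `RR` | hypothetical risk ratio for the elevated strata | 5 |

The two probabilistic parameters are drawn 50,000 times; everything else is
propagated deterministically per draw.

### Calibration

Each draw's OR is converted into conditional misuse risks by solving the
mixture constraint

    q·p1 + (1 − q)·p0 = t,    odds(p1)/odds(p0) = OR

for `p0` (risk without anxiety) and `p1` (risk with anxiety). The left side is
strictly increasing in `p0`, so the root is unique; the scalar path uses
Brent's method and the vectorised path a fixed-count bisection (100 halvings,
i.e. to floating-point resolution). The reconstructed overall prevalence must
match `t` to 1e−12 or the run aborts. An alternative dialect (`or_as_rr: true`)
treats the drawn value as a risk ratio, `p1 = min(OR·p0, 1)`; the two dialects
converge as the outcome becomes rare and bracket each other at the 5.3%
baseline. Calibration is re-solved per draw, not once at the mean.

### Scenarios

Per draw, each scenario partitions the exposed population into strata with a
proportion and a misuse probability; the post-fire prevalence is the mixture
mean and the prevalence ratio (PR) is that prevalence over `t`.

* **S1 (base case)** — wildfire only raises anxiety incidence: anxiety at the
  drawn `p_fire` with risk `p1`; remainder at `p0`.
* **S2** — incident fire-related anxiety is an altered phenotype: pre-existing
  anxiety (`q`) keeps `p1`; the incident stratum (`max(p_fire − q, 0)`) gets
  `min(RR·p0, 1)`; remainder `p0`.
* **S3** — wildfire additionally worsens pre-existing anxiety: as S2 but the
  pre-existing stratum is also raised to `min(RR·p0, 1)`.

The hypothetical RR multiplies the calibrated *no-anxiety* risk `p0`
(capped at 1), not `p1` and not the overall prevalence; this is the
assignment that reproduces the published scenario means. The incident
proportion is floored at zero — the framework models anxiety incidence, not
remission — and the pre-existing stratum is never shrunk. PR is reported
unclamped; values below 1 occur for draws whose post-fire anxiety falls below
baseline, consistent with uncertainty intervals whose lower bound prints
as 1.00.

Mixtures are evaluated in delta form `p0 + Σ wᵢ·(pᵢ − p0)`, so a draw with
OR exactly 1 returns the baseline prevalence bit-for-bit and the S1 PR is
exactly 1 (a tested invariant).

### Monte Carlo run and summaries

All scenarios are evaluated on the same draws (common random numbers), which
lowers the variance of scenario contrasts without changing means. Each
probabilistic parameter draws from its own generator substream spawned from
the run seed (`numpy.random.SeedSequence`), so the draw stream is a pure
function of the seed and independent of batch size. Summaries report the
per-scenario mean and the empirical 2.5th/97.5th percentiles ("95% UI")
using numpy's default linear interpolation between order statistics — the
convention matters because interval endpoints are compared at two-decimal
precision. By linearity, the mean PR equals the mean prevalence divided by
`t` exactly, so the two headline outputs are not independent; they are
nevertheless both computed from the draw table. (At the published
parameterisation the printed S3 pair, 7.2% and PR 1.34, disagree beyond
rounding — 0.072/0.053 ≈ 1.36; the package reports both from the same draws
and does not force agreement.)

## The synthetic-data generator

`microsim.simulate_cohort` realises the cohort arithmetic at the individual
level: pre-existing anxiety ~ Bernoulli(`q`); among the previously
non-anxious, incident anxiety ~ Bernoulli(`max(p_fire − q, 0)/(1 − q)`), so
total anxiety targets the beta draw; misuse ~ Bernoulli with the stratum's
scenario-specific risk. This is the minimal individual-level structure
consistent with the cohort mixtures and serves as a brute-force oracle: at
n = 10⁶ the empirical prevalence must match the closed-form mixture within
3 binomial standard errors across a 3×3 grid of (OR, anxiety) quantiles.

What the generator does **not** emulate: longitudinal trajectories, anxiety
remission, correlated risk factors, other mediators (depression, PTSD), or
measurement error in the underlying prevalences. A green oracle test
establishes that the stratum arithmetic and the individual-level model agree
— not that either describes a real exposed population. Because incident
anxiety is generated only among the non-anxious, the cohort realises the S1
stratum proportions exactly only for draws with `p_fire ≥ q` (the regime the
model describes); below that the cohort floors total anxiety at `q` while the
S1 mixture does not.

## Numerical and design choices

* **Lognormal dialect.** "Mean 3.04, sd 1.07" is read as natural-scale
  moments and inverted in closed form (σ² = ln(1 + sd²/mean²),
  μ = ln(mean) − σ²/2 → μ ≈ 1.0535, σ ≈ 0.3418). A log-scale reading would
  put the median OR near 21, grossly inconsistent with the published
  outcomes; it remains available as `dialect: log_scale` for sensitivity
  checks.
* **OR dialect.** Whether the drawn OR was converted exactly to conditional
  risks or treated as a risk ratio is not documented; both are implemented
  behind `or_as_rr` (default: exact odds-ratio conversion, the statistically
  correct reading). The acceptance suite accepts a published target if at
  least one dialect reproduces it; in practice the risk-ratio dialect sits
  slightly closer to the printed means and the odds-ratio dialect to the S1
  interval endpoints.
* **Tolerances.** Calibration residual 1e−12; vectorised/scalar calibration
  agreement 1e−10; microsimulation agreement 3 binomial SEs with fixed
  oracle seeds (deterministic in practice).
* **Degenerate inputs.** `point` distribution specs support pinning either
  probabilistic parameter; `p_group = 1` with a non-unit association is
  rejected (no reference stratum); an association of exactly 1 short-circuits
  to `p0 = p1 = t` rather than passing through the root-finder.
* **Rounding.** The rendered table prints percentages to one decimal and
  ratios to two, matching the publication; all comparisons in tests use the
  unrounded JSON values.

## Known limitations

The model propagates parameter uncertainty only — no sampling variability in
the baseline prevalences, no covariate structure, no age structure, and the
two probabilistic parameters are drawn independently. Scenario ordering
S1 ≤ S2 ≤ S3 holds per draw only while `RR·p0 ≥ p1`; very large OR draws
invert S2 vs S3, though the Monte Carlo means remain strictly ordered at the
default parameterisation.
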