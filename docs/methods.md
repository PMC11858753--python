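# Methods

## Non-parametric circadian rhythm analysis

The NPCRA statistics are computed on a day-aligned binned series. By
default activity is averaged into hourly bins (`bins_per_day = 24`),
the standard convention for IS/IV; the binning is configurable down to
raw epoch resolution because source studies do not always state theirs.
Partial leading and trailing days are trimmed before analysis, with the
day boundary at the local midnight of the recording's start time: the
IS formula compares bin-of-day means across days and is only meaningful
on complete, balanced days.

Definitions (n bins total, p bins/day, grand mean x̄, bin-of-day means
x̄_h):

- `IS = [Σ_h (x̄_h − x̄)²/p] / [Σ_i (x_i − x̄)²/n]`. Between-group sum
  of squares cannot exceed the total, so IS ∈ [0, 1]; the ratio is
  clipped at 1 against float round-off. A constant series makes the
  statistic 0/0 and raises.
- `IV = [Σ_{i≥2} (x_i − x_{i−1})²/(n−1)] / [Σ_i (x_i − x̄)²/n]`, the
  normalized mean squared successive difference. It is ≈0 for a smooth
  sinusoid, ≈2 for white noise, and up to 4 for a perfectly
  anti-correlated (alternating) series.
- M10 and L5 are window means over the *average* 24 h profile with
  circular wrap-around, scanning every window start; `RA = (M10 −
  L5)/(M10 + L5)`, defined as 0 for an identically zero profile (no
  rhythm has no amplitude). Window lengths must be whole numbers of
  bins; at hourly resolution they are 10 and 5 bins.
- `CFI = (IS + IV_inv + RA)/3` with `IV_inv = clip(1 − IV/2, 0, 1)`.
  The inversion maps IV's nominal 0–2 range to 1–0 so that all three
  components point the same way (1 = robust rhythm); values of IV above
  2 clip to 0 rather than going negative.

A minimum of six consecutive nights is enforced by default, the
accepted floor for stable NPCRA estimates; `allow_short=True`
downgrades the rejection to a logged warning for exploratory use.

Missing data: a bin with ≥50% of its epochs missing is itself missing.
IS and IV assume complete balanced days, so any missing bin aborts the
analysis by default; `missing_policy="impute"` fills missing bins with
the bin-of-day mean and logs a warning. The overall missing fraction is
capped (default 20%) regardless of policy.

## Synthetic actigraphy

The simulator writes
`activity(t) = max(0, state(t)·[M + A·cos(2π(t − φ_d)/24)] + night_floor·1[nocturnal] + ε_t)`
at 60 s epochs. Each degradation axis maps onto one NPCRA statistic:

- `phase_jitter_sd_hours` jitters each day's acrophase φ_d, breaking
  day-to-day alignment and lowering IS;
- `fragmentation_rate` is the per-epoch probability of toggling a
  two-state multiplicative process (×1.5 / ×0.5), injecting
  square-edged transitions that raise IV;
- `night_floor` adds counts inside the 8 h window opposite the
  acrophase, raising L5 and lowering RA.

Noise is Gaussian and the signal is rectified at zero, since activity
counts cannot be negative; rectification is negligible at the default
mesor/amplitude ratios.

The two cohort presets draw per-subject parameters from truncated
Gaussians. Their constants were calibrated by simulation against the
full NPCRA pipeline so that cohort CFI moments land on the descriptive
targets for each society type: non-industrial mean ≈ 0.70, industrial
mean ≈ 0.63 with between-subject sd ≈ 0.07. The calibration is part of
the generator's definition and is not revisited per run. What the
presets emulate is the *statistical* signature of each society type —
stability, fragmentation and amplitude levels — not the mechanisms
behind it: there is no photoperiod, no seasonality, no latitude effect,
no light or temperature channel, and real actigraphy has autocorrelated
(non-Gaussian) noise and behavioural artefacts the cosine model lacks.
Passing cohort-level tests therefore shows the pipeline recovers the
intended moments under the model's assumptions, not that those moments
are unbiased in field data.

The study-table simulator mirrors the meta-analytic design: 54 studies
(10 non-industrial) across 21 countries, society scale constant within
a country, covariates drawn on their natural scales and entered as
sample z-scores — exactly the scaling the fitter applies, so generator
truths and fitted coefficients are directly comparable. Default truths
are the published posterior means for the duration model (intercept
7.16 h, society −0.75 h, age −0.19, %male −0.13, country sd 0.73 h) and
the efficiency analogue (intercept 87.91, society −14.01, age −2.80,
%male 0.64, country sd 5.42, over 38 studies). Neither analysis
publishes a residual σ, so the generator defaults (0.5 h duration,
3.0% efficiency) are free choices sized to keep parameter recovery
well-posed; they are labelled as such and matter only for simulation
studies.

## Hierarchical models

All three models use a Gaussian likelihood — deliberately also for the
bounded outcomes (efficiency %, CFI), mirroring common practice for
these analyses; posterior-predictive bound violations are a diagnostic
concern, not an error. Covariate scaling: study-level mean age and
% male are z-scored before fitting, which is the only scaling consistent
with the magnitude of the published age/sex coefficients; this is an
assumption and is recorded as one. "Industrial" is the reference
society-scale level in the sleep models (the coefficient is the
non-industrial offset); the subject-level CFI model uses non-industrial
as reference so its society coefficient is the industrial offset, the
direction that contrast is usually reported in. The CFI model's sex
term is a subject-level male indicator.

Priors: intercepts Normal(8, 1) h (duration), Normal(85, 10) %
(efficiency), Normal(0.58, 0.1) (CFI); slopes Normal(0, 2·sd(y));
group and residual sds half-Normal(2·sd(y)). The slope and sd priors
are weakly informative and dominated by the data at these sample sizes;
a prior-only mode (`prior_only=True`) exists to verify that with an
empty likelihood the intercept posterior returns the prior.

Sampling marginalizes the country random intercepts analytically:
within country c the marginal covariance is σ²I + τ²J, whose inverse
and determinant are closed-form, so the posterior is over at most six
parameters (fixed effects, log τ, log σ). It is explored with an
affine-invariant ensemble sampler using differential-evolution moves
(4 independent 32-walker ensembles; 1200 warm-up steps and 400 kept
steps each, i.e. 51 200 retained draws). Each ensemble's walkers are
pooled in step-major order into one chain: walkers within an ensemble
interact and are not independent chains, whereas the four ensembles
are. Split-R̂ across the ensembles above 1.01 raises a ConvergenceError
(disable with `check_convergence=False`); a collapsed acceptance
fraction — this sampler's analogue of pathological geometry — also
raises. Reported effective sample sizes are approximate for ensemble
samplers; the operative gate is cross-ensemble R̂. Random-intercept
draws are recovered exactly from their conditional Gaussian
`u_c | θ, y ~ N(τ²S_c/(σ² + n_cτ²), τ²σ²/(σ² + n_cτ²))` for the spatial
diagnostic and for conditional pointwise log-likelihoods.

Summaries are equal-tailed percentile intervals (89% and 95%), not HDI;
the 89/95 pair is reported together, and the % of negative draws is
classified as weak (85–90%], support (90–95%], strong (>95%), with
intervals closed on the right.

Model comparison uses leave-one-out expected log predictive density:
PSIS importance sampling (default) on conditional pointwise
log-likelihoods, or exact refits per left-out row (feasible at n ≈ 50;
held-out studies from a country absent in training are scored with the
random intercept integrated over its population distribution).

## Moran's I

Weights are inverse great-circle (haversine) distance,
row-standardized, zero diagonal; no weighting scheme is canonical for
irregular country locations and this one is the least structured
choice. Pairwise distances are floored at 1 km so duplicate coordinates
cannot create infinite weights. The null expectation is exactly
−1/(n−1); inference is a two-sided permutation test (default 9999
seeded permutations, add-one correction), so p-values live on a grid in
(0, 1].

## Problem sizes and numerical choices

The test suite and the acceptance script run everything at the study's
own scales where those are small (54- and 38-row meta-tables, 93- and
200-subject cohorts at 7 days × 1-min epochs) and use 20 seeded
replicates for interval-coverage checks, a size at which the binomial
acceptance band is already sharp. Interval coverage is checked against
Binomial(20, 0.89); the generator's efficiency design has only six
non-industrial countries, so single-table recovery of the society
coefficient is noisy (country effects do not average out of the
contrast) — its posterior sd reflects this correctly, which is what the
2-posterior-sd recovery criterion relies on. Exact-arithmetic claims
(IS of repeated days, RA of a square wave, CFI extremes) are asserted
exactly; Monte-Carlo quantities carry tolerances stated with each test.

## Known limitations

- The cosine-plus-axes simulator cannot represent napping, split sleep,
  or social zeitgebers; cohort CFI targets are matched by construction,
  not discovered.
- Gaussian likelihoods on bounded outcomes can place posterior mass
  outside the feasible range for extreme covariate combinations.
- Subject-level sex enters the CFI model as a binary indicator; data
  sources that only report cohort % male cannot be used there.
- The spatial diagnostic tests country *intercepts*; it says nothing
  about within-country spatial structure.
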