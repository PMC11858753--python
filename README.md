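# circasleep

Cross-cultural comparison of human sleep asks two linked questions: do
people in large-scale industrial societies actually sleep less and worse
than people in small-scale, largely off-grid societies, and do the two
groups differ in how strongly their rest–activity rhythms are entrained
to the 24 h day? `circasleep` implements the complete analytical stack
for both questions — the circadian metrics computed from wrist-worn
actigraphy, the Bayesian hierarchical models fit to study-level sleep
quotas, the spatial diagnostic for country effects, and a synthetic-data
generator so the whole pipeline is testable end to end without any
restricted data. It is aimed at sleep researchers and biological
anthropologists working with actigraphy cohorts and published sleep
meta-tables.

## What it computes

**Non-parametric circadian rhythm analysis (NPCRA).** From a day-binned
activity series `x_1..x_n` (`p` bins/day, `d` complete days, at least
six consecutive nights):

- interdaily stability
  `IS = [Σ_h (x̄_h − x̄)² / p] / [Σ_i (x_i − x̄)² / n]` ∈ [0, 1] —
  how well the daily profile repeats from day to day;
- intradaily variability
  `IV = [Σ_i (x_i − x_{i−1})² / (n−1)] / [Σ_i (x_i − x̄)² / n]` —
  ≈0 for a smooth sinusoid, ≈2 for white noise;
- relative amplitude `RA = (M10 − L5) / (M10 + L5)` where M10/L5 are the
  mean activity of the most/least active 10/5 consecutive hours of the
  average day (circular windows);
- the circadian function index
  `CFI = (IS + clip(1 − IV/2, 0, 1) + RA) / 3` ∈ [0, 1], with 0 meaning
  no circadian rhythmicity and 1 a robust rhythm.

**Bayesian hierarchical sleep models.** Study-level mean outcomes are
modelled as

    y_j = β₀ + β_soc·1[non-industrial_j] + β_age·z(age_j) + β_male·z(%male_j) + u_{country(j)} + ε_j,
    u_c ~ Normal(0, τ),  ε_j ~ Normal(0, σ),

with informative intercept priors — Normal(8 h, 1 h) for sleep duration,
Normal(85, 10) for sleep efficiency (%) — and a fixed-effects analogue
for the subject-level circadian function index with a Normal(0.58, 0.1)
intercept prior. Country random intercepts are marginalized analytically
and the low-dimensional posterior is sampled with an affine-invariant
ensemble sampler, with split-R̂ convergence gating. Posteriors are
reported with dual 89%/95% equal-tailed credible intervals, the % of
draws below zero, and directional support labels
(weak 85–90%, support 90–95%, strong >95%). Models are compared by
leave-one-out expected log predictive density (PSIS or exact refits),
and country intercepts can be screened for spatial clustering with a
permutation-based Moran's I on haversine inverse-distance weights.

**Synthetic data.** A cosine rest–activity simulator with three
independent degradation axes (phase jitter → IS, a two-state
fragmentation process → IV, a nocturnal activity floor → RA), cohort
presets calibrated so the non-industrial / industrial cohorts land on
mean CFI ≈ 0.70 / 0.63 (sd ≈ 0.07), and a hierarchical study-table
simulator whose default truths are the published posterior means.

## Worked example

```python
from circasleep import RhythmParams, generate_recording, npcra

rec = generate_recording(RhythmParams(
    mesor=200, amplitude=170, acrophase_hour=14, noise_sd=50,
    phase_jitter_sd_hours=0.5, fragmentation_rate=0.004,
    night_floor=25, days=7, seed=42))
print(npcra(rec))
```

prints (see `examples/npcra_basics.py`):

```
subject demo: 7 complete days
  IS  = 0.575   (1 = identical days)
  IV  = 0.217   (0 = smooth sinusoid, 2 = white noise)
  RA  = 0.656   (M10 = 327 from 10.0 h, L5 = 68 from 23.0 h)
  CFI = 0.707  (mean of IS, inverted IV, RA)
```

Half an hour of phase wobble and a modest nocturnal floor leave a
clearly rhythmic but imperfect record: the subject keeps about 58% of
day-to-day stability, very low fragmentation, and a strong day–night
contrast, averaging to a CFI of 0.71. Fitting the hierarchical duration
model to a simulated 54-study table (`examples/sleep_meta_model.py`)
recovers the generating society-scale contrast:

```
            parameter  estimate    se  ci89_low  ci89_high  pct_negative support
            intercept     7.385 0.181     7.099      7.674         0.000    none
society_nonindustrial    -0.856 0.310    -1.359     -0.369        99.688  strong
...
industrial - non-industrial sleep duration: 0.86 h (true difference 0.75 h)
```

The other examples cover cohort-level CFI contrasts
(`examples/cohort_cfi.py`) and the Moran's I diagnostic
(`examples/spatial_check.py`). A thin CLI mirrors the library:
`circasleep simulate-studies`, `npcra`, `fit`, `moran`, `report`.

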