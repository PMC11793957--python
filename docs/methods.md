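# Methods

## Threshold utility and certainty equivalents

The utility of holding `r` euros is `sigmoid(u) + slope · u · 1[u > 0]`
with `u = (r − threshold) / scale`.  Defaults: threshold €0, scale €100
per sigmoid unit, slope 1/50 per unit.  The euro scale of the sigmoid
argument is a modelling choice, not a measured quantity: €100 per unit
maps the seven sure amounts of the elicitation ladder (€100–€700) onto
1–7 units and places the switch from risk avoidance to risk taking near
€400 below the threshold, which is where it must sit for the reference
gamble (the gamble's sure-equivalent €400 lands the winner exactly at the
threshold).  The scale is a first-class parameter everywhere.

Certainty equivalents are solved by bisection on `[0, win_amount]` to an
absolute tolerance of €0.01; utility is strictly increasing, so the root
is unique and bracketing cannot fail.  A discrete elicitation ladder is
represented separately by `predicted_bet_count`: the gamble is chosen
against a sure amount under *strict* expected-utility preference.  Under
strict preference a risk-neutral agent accepts exactly 3 of the 7 bets
(the gamble beats €100–€300 and nothing above); deep in the linear regime
the comparison against €400 is an exact utility tie, where the count is
numerically 3 or 4.  Response error is modelled as a trembling hand:
each of the seven choices flips independently with a small probability,
which requires an explicit seeded RNG.

## Synthetic panel generator

The generator emulates a two-country monthly cost-of-living panel: 472
participants, up to 12 waves, per-participant Beta-distributed response
propensity targeting 10.05 completed waves on average.  Persistent
participant state: log-normal income level (log-mean 7.983, between-person
log-s.d. 0.52, within-month 0.22 — total moments match a mean of ~€3437
and s.d. of ~€2117; the implied median, ~€2930, is ~2.5% below the
survey's €3000, the price of using a single log-normal), a Beta(5, 7)
unavoidable-cost fraction with lognormal monthly spikes (s.d. 0.30, which
yields ~1% of months with costs above income), a desperation threshold
drawn Normal(€650, €400) — thresholds plausibly differ between households
— and a Normal(−0.7, 1.2) risk-attitude trait on the count scale.

Behaviour responds to the *standing*: 70% persistent surplus, 30% the
current month's measured surplus, minus the participant's own threshold,
plus €150 of wave noise.  The bet count is the threshold-utility
prediction at that distance (behavioural sigmoid scale €100) plus trait,
an age effect of −0.085 counts per s.d. and −0.19 for women, wave noise
(s.d. 1.0 counts), unbiased stochastic rounding onto 0–7, a cutoff choice
battery, and a 1.5% trembling hand (≈7% inconsistent batteries).  The
three insecurity items are a logistic transform (scale €1500) of the
*perceived* distance to threshold — the true distance plus €400 of
perception noise — with Normal(0, 10) item noise, truncated to [0, 100].
Financial strain bands the same perceived distance at €0/€400/€1000/€2000.
Delay choices come from an independent persistent discount trait that
steepens by 2.2 counts below the threshold.

The decomposition into persistent standing, transient measured surplus
and noisy perception is what gives the synthetic data the measurement
structure the analyses assume: the objective log-ratio is a noisy proxy
of the behavioural state (months with an expense spike land at the bottom
of the objective distribution regardless of the household's standing), and
the subjective measure tracks the behavioural state more closely but
through its own noise.  Both bottom tails therefore contain a mixture of
vulnerable (just-above-threshold) avoiders and desperate (below-threshold)
takers.

Calibration targets (ICC of bet counts ≈ 0.48; Cronbach's alpha ≈ 0.87;
mean bet count ≈ 2.3) fix the free noise knobs; all are exposed on
`GeneratorConfig`.  What the generator does *not* emulate: country-level
income differences, non-random dropout, savings/assets, serially
correlated income shocks, and any feedback from behaviour to resources.
Passing tests on these panels show that the statistics detect (and do not
hallucinate) threshold structure under this measurement model — not that
the real survey satisfies it.

Two planted-truth mechanisms support calibration studies: `piecewise`
(counts linear in the objective resource index with a slope break of
−1.5/+0.15 counts per unit at its 20th percentile, random intercept s.d.
0.9, wave noise 1.0) and `linear` (one slope, no break, latent count
centred mid-scale so the 0–7 clipping stays symmetric and counts remain
homoscedastic under the null).

## Preprocessing

Objective resources: `log2(income + 1) − log2(costs + 1)` (the +1 guards
zeros).  Subjective resources: `sqrt(300 − (item1 + item2 + item3))` —
reverse-coding before the square root; per-item reversal then summing is
algebraically identical.  Bet and immediate-choice counts are plain sums;
a battery is consistent iff its choice vector is non-increasing (no
gamble refused against a small sure amount while accepted against a
larger one).  Rows missing any gamble item are dropped; a missing delay
battery only voids the discount count for that row.  Age is z-scored
within the analysis sample.

## Mixed models and the changepoint search

All confirmatory models are Gaussian random-intercept models (participant
intercepts; fixed age and gender) fitted by maximum likelihood, not REML,
so deviances, AICs (`−2ℓ + 2k`, k counting fixed effects plus both
variance components) and likelihood-ratio tests are comparable across
fixed-effect structures.  Treating a 0–7 count as Gaussian is a
deliberate simplification; ordinal or count families are out of scope.

Fitting uses a profiled-likelihood solver written for this package: for a
single random intercept, conditional on the variance ratio
ψ = σ²_b/σ²_e the GLS problem has a closed form after a within-group
shrinkage transform, leaving a one-dimensional search over ψ (Brent, with
a guard at the ψ → 0 boundary).  Its log-likelihoods agree with
`statsmodels` `MixedLM` to ~1e-8 (tested), and it is fast enough to refit
the model at every candidate changepoint.  Standard errors are
conditional on ψ̂, as is conventional.

The segmented model constrains the two segments to meet at the
changepoint.  Candidates are, by default, a 199-point percentile grid of
the resource variable (every unique observed value is available behind
`grid="observed"`); candidates leaving fewer than 20 observations on
either side are inadmissible.  The minimum-deviance candidate wins; exact
ties break toward the smaller changepoint.  Slope t-tests are conditional
on the selected changepoint — no correction is made for the search, a
known limitation shared with the standard practice this implements.
Polynomial fits use an orthonormal (QR) basis to avoid collinearity;
inflection points are read off the refitted raw-coefficient polynomial
inside the observed resource range.

Holm–Bonferroni is the step-down adjustment with running-maximum
monotonicity and capping at 1.

## Dispersion tests

The family of three (jointly Holm-corrected): (1) a two-sided F test of
bet-count variance for the worst financial-strain answer against everyone
else; (2, 3) for each resource measure, OLS of risk count on resources,
age and gender *without* random effects — person-level spread is the
signal, so absorbing it into random intercepts would defeat the test —
followed by OLS of squared residuals on resources.  Stage-2 inference
uses CR1 cluster-robust standard errors by participant with g − 1
degrees of freedom: repeated observations share a random intercept, and
classical errors are anti-conservative there (empirical type-I ~9–10%
versus ~5–7% cluster-robust, at the nominal 5%).  The variance-ratio
sweep reports per-percentile uncorrected p-values plus a Holm column,
since it is a visualization rather than a confirmatory test.  The ICC is
the between-participant share of variance from the same random-intercept
decomposition; Cronbach's alpha is the standard `k/(k−1)(1 − Σs²ᵢ/s²ₜ)`.

Prevalence tables pool observations across waves (participant-level
aggregation would change the unit of analysis; the tables state n so the
reader can tell).  Chi-squared tests are Pearson 2×2 without continuity
correction.  Extremes: a risk avoider accepts 0 bets; a risk taker more
than 4 — 5+ acceptances necessarily include a gamble taken against a sure
amount above its expected value.

## Problem sizes

Default analyses run on one 472 × ~10 panel (~4 800 observations).  The
calibration studies use 50 replicates of that size for changepoint
recovery and segmented type-I, and 500 replicates at 150 × 4 for the
dispersion-test calibration; these sizes give stable medians and
rejection-rate estimates at desk scale.

## Known limitations

- No confidence interval or search-adjusted inference for the
  changepoint location.
- Gaussian response for a bounded count; no GLMM families.
- The generator's missingness is (participant-heterogeneous) missing at
  random; real attrition may be informative.
- The stability regression needs ≥3 participants with repeated waves
  (a 2-participant fit is saturated and has no error degrees of freedom);
  fewer than 30 triggers a small-sample warning.
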