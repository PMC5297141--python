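# Methods

## Sequential model

Each sampling attempt is a Bernoulli trial; the monitored quantity is the
failure probability `p` of the operator (or institution). The design
quadruple `(p0, p1, alpha, beta)` fixes an SPRT-style test of
`H: p = p0` against `K: p = p1`:

- `P = ln(p1/p0)` and `Q = ln((1-p0)/(1-p1))` are the per-failure and
  per-success log-likelihood-ratio increments (natural logs throughout);
- `s = Q/(P+Q)` is the per-success chart decrement, `1-s` the per-failure
  increment; `s` is invariant to the log base, the decision intervals are
  not;
- `a = ln((1-beta)/alpha)`, `b = ln((1-alpha)/beta)`,
  `H0 = b/(P+Q)`, `H1 = a/(P+Q)`. `alpha = beta` implies `H0 = H1`, and
  `alpha + beta < 1` is required for positive intervals (enforced).

Defaults `(0.1, 0.2, 0.1, 0.1)` give `s = 0.145244`, `1-s = 0.854756`,
`H0 = H1 = 2.709511`. All values are carried at full float precision;
rounding to 2 d.p. is presentation only. A truncated `s = 0.14` /
`1-s = 0.86` appears in some earlier learning-curve literature for the
same design; the formulas give 0.145 at 3 d.p. and the package uses the
formula value.

The chart starts at 0 and is **unrestricted** — no holding barrier at
zero — so sustained success produces the characteristic descending curves
and the chart value may be arbitrarily negative.

## Decision rule

The published convention this implements speaks of crossing "two boundary
lines". Where those lines sit is genuinely open: a fixed lattice of
horizontal lines spaced `H` apart, or an excursion measured from the
chart's own extremum. We implement the **extremum-referenced** reading:

- proficient at the first attempt where `(running max since last signal)
  - C_k >= 2*H0`;
- nonproficient at the first attempt where `C_k - (running min since last
  signal) >= 2*H1`;
- inconclusive before the first signal; a state persists until the
  opposite signal; after *any* signal both extrema reset at the
  signalling value, so repeated signals need fresh excursions.

Rationale: an excursion from the running extremum is translation-
invariant (a lattice rule's output would depend on the arbitrary start
value) and supports re-signalling after recovery. The lattice reading is
not configurable in this version. A single step can never cross a
threshold from reset (`max(s, 1-s) < 2*min(H0,H1)` is asserted), so no
signal can occur at attempt 1 under the default design.

Analytic consequences (brute-force verified in the tests): the shortest
all-success run that signals proficiency is 38 attempts
(`38*s = 5.519 >= 2*H0 = 5.419 > 37*s`); the shortest all-failure run to
nonproficiency is 7 (`7*(1-s) = 5.983 >= 5.419 > 6*(1-s)`).

Each signalling segment also records a **change-point estimate**: the
attempt at which the referenced extremum was attained. The signal itself
lags the true performance change by roughly `2*H/|p - s|` attempts (the
excursion length over the drift rate); the extremum is where the chart
turned, and is the natural estimate of when performance actually changed.

## Interval segmentation

Pooling all operators' attempts in chronological order gives one
institutional chart (a single running sum, no per-operator restart).
State segments are mapped to case-level intervals: spans before
proficiency is first attained (inconclusive or nonproficient) are
*learning*; proficient spans are *proficiency*; nonproficient spans after
proficiency was attained are *worsening*. The case containing a
signalling attempt closes the preceding interval and the next case opens
the new one. Two signals landing in one case would leave an empty
interval, which is dropped.

## Environment regression

The analysis frame has one row per sampled node (default) or per case;
the outcome is membership of a worsening interval. Covariates: assisting
attending, on-site cytopathologist, midazolam dose >= 10 mg and fentanyl
dose >= a configurable threshold (300 ug default; 200 ug is supported as
an alternative dichotomisation, and neither is privileged). Thresholds
are inclusive. Missing covariates are handled complete-case with a
logged drop count; no imputation.

Fitting is joint maximum likelihood (statsmodels) with Wald 95% CIs and
2-tailed Wald p-values. Separation — a covariate level perfectly
predicting the outcome, or a diverged estimate (|log-odds| > 12 or
non-convergence) — sets a per-covariate flag; `method="firth"` (or an ML
fit that fails outright under separation) uses a hand-implemented
Jeffreys-prior penalized Newton fit with step-halving, which yields
finite estimates (on a separated 2x2 table it reproduces the half-cell
corrected cross product exactly, which the tests exploit as an oracle).
Covariates are case-level while nodes are the unit, so within-case rows
are correlated; no cluster adjustment is made and reports carry the
caveat. Mixed-effects/GEE corrections are out of scope.

## Synthetic cohorts

The generator emulates a three-operator institutional training series:
per-operator chronological phases with baseline failure probabilities,
1-3 nodes per case, case-level covariates acting on failure odds through
a logistic link (`logit(p) = logit(p_phase) + sum x_j * effect_j`). Each
operator consumes a `default_rng([seed, 1000+index])` substream so adding
an operator leaves the others' draws unchanged; a separate substream
interleaves the operators' case sequences into one chronology.

The packaged replica scenario fixes the study-scale structure: operators
A/B/C with 84/89/49 nodes over 47/50/34 cases (222 nodes, 131 cases) and
a four-phase institutional profile — learning (p ~ 0.42 for the first
~22% of each operator's attempts), proficient (0.04), worsening (0.5 for
~15% mid-series), proficient (0.04) — aligned in fractional study time
across operators, reflecting the premise that the worsening was an
institution-level environmental episode. Covariate prevalences (attending
0.35, cytopathologist 0.5, high midazolam 0.29, high fentanyl 0.17 — the
dose prevalences match the reported high-dose case fractions 38/131 and
22/131) are constant over time with illustrative effects on failure odds,
so the replica builds in no covariate-worsening association; its
regression output demonstrates the report format, not a target estimate.
The scenario seed (2008) is part of the fixture. What passing tests on
this cohort show is that the machinery recovers structure it can see at
study scale; they cannot validate clinical covariate estimates, node-level
difficulty effects, or secular trends absent from the generator.

## Operating characteristics and recovery experiments

`simulate_operating_characteristics` draws i.i.d. outcome sequences at a
true failure probability and applies the identical reset-aware rule
(vectorised across replicates; verified against the sequential
classifier replicate-by-replicate on common random streams). At the
design points over 200-attempt horizons, the probability of ever being
falsely flagged is ~0.05 in both directions — comfortably below the loose
SPRT-style bound `alpha/(1-beta) + 0.05 = 0.161`; the two-boundary
(`2*H`) excursion makes the rule more conservative than plain SPRT
theory.

`simulate_segmentation_recovery` measures how often a known four-phase
profile (0.35 x 30 / 0.08 x 60 / 0.30 x 40 / 0.08 x 70) is recovered as
learning/proficiency/worsening/proficiency with change-point estimates
within +/-15 attempts of the truth. At this scale the structure emerges
in only ~19% of replicates: a proficient signal needs a `2*H0 = 5.42`
excursion, while a 60-attempt stretch at p = 0.08 drifts down only
`60*(s-p) = 3.9` on average (sd ~1.6), so the signal usually cannot fire
within the phase; the 70-attempt final stretch gives ~4.6. This is a
property of the decision rule at these phase lengths, not of the
change-point estimator — conditional on the structure appearing, the
boundaries are within tolerance in ~90% of replicates, and a
strong-contrast profile (longer, cleaner phases) is recovered in ~99%.
The experiment is reported as measured.

Problem sizes used throughout (10,000 replicates x 200 attempts for
operating characteristics, 200 replicates for recovery experiments,
2,000-row frames x 500 replicates for CI coverage) were chosen to keep
Monte-Carlo standard errors around or below 0.005-0.01 while remaining
quick on a laptop.

## Numerical choices

- Threshold comparisons use `>= threshold - 1e-9` to guard float
  accumulation; chart steps are validated against the supplied constants
  at the same tolerance.
- Logistic collinearity is rejected by pairwise |r| > 1 - 1e-10 and a
  design-rank check, naming the offending pair.
- Firth Newton iterations: penalized log-likelihood
  `ll + 0.5*logdet(X'WX)`, hat-diagonal score correction, step-halving,
  tolerance 1e-10 on the step.
- Empty outcome sequences yield a chart of length 1 and an empty segment
  list; degenerate regression outcomes raise rather than return NaNs.
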