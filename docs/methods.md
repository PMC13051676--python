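# Methods

## Scope and design

The package separates three concerns that are often entangled in
program-evaluation spreadsheets:

1. **Survey statistics** (`swineval.survey`): the inferential models
   applied to respondent-level microdata.
2. **Economic model** (`swineval.impact`): a deterministic cascade from
   an attributable success-rate gain to piglets, income, and
   economy-wide impact. Every quantity is a pure function of the
   configured scalars; randomness never enters this layer.
3. **Synthetic microdata** (`swineval.synth`): a seeded generator that
   emulates the study's structure so the statistical layer can be
   validated against planted truths and the whole pipeline runs
   without access to the original survey data.

`swineval.reporting` composes them and audits the published tables.

## Counterfactual adjustment

The program effect is carried by a single odds ratio from the CAHW
binomial GLM. The baseline success probability p₀ is mapped to
p_adj = expit(logit(p₀) + ln OR); the incremental rate is
Δp = p_adj − p₀. This is the standard "push the baseline through the
fitted odds" construction: it nets out secular change because the GLM's
round coefficient is estimated jointly with district fixed effects and
respondent covariates, while the observed endline rate (74.8%) also
contains system-wide movement that the program cannot claim.

With an OR *estimated* from data, sampling noise can push it below 1;
the incremental scope then goes (slightly) negative and is carried with
its sign rather than rejected, so a genuinely null program yields an
estimated increment scattered around zero. For all configured (as
opposed to estimated) inputs the OR is ≥ 1 and 0 ≤ Δp ≤ p_adj holds.

## Total-scope rate policy

The published totals embed a success rate of 4,489/7,540 ≈ 59.5% that
matches neither the adjusted rate (59.0%) nor the endline rate (74.8%).
Rather than hard-coding the published count, the rate used for the
total cascade is explicit configuration: `adjusted` (default),
`endline`, or `custom`. The reproduction harness recomputes every
published row under the configured policy, flags the rows it cannot
reproduce, and re-checks them under the implied rate (derived at run
time from the published total, which is treated as an input); rows
that reproduce there are labelled *paper-internal discrepancy*. Under
the implied rate, all 25 audited rows agree to within 0.1% (or 2 units
for small-magnitude rows) — the comparison tolerance used throughout,
chosen to absorb the mixed presentation rounding of the source tables.
Full precision is carried internally; rounding is presentation-only.

## Cost ledger and currency

Cost items are USD, or local currency with a mandatory attached
exchange rate (validated at construction; never clamped or defaulted
silently). The prevailing RWF/USD rate behind the published procurement
line is not published; the constant `DERIVED_RWF_PER_USD`
(42,350,000 RWF / $29,312 ≈ 1444.80) is back-solved from that line and
is a documented convenience, not an authoritative rate. No inflation
adjustment is applied; the piglet price is taken as given in 2024 USD.

## Statistical layer

* Fits use maximum likelihood via statsmodels: IRLS for the binomial
  models with relative-deviance tolerance 1e-8 and at most 100
  iterations; OLS for the success-proportion model. Records with zero
  procedures have no defined proportion and are excluded with a
  reported count.
* Contrasts are deterministic: reference levels are district Burera
  (first alphabetically), round baseline, sex female, breed Landrace.
  Covariate columns absent from the input are simply not modelled, so
  aggregated tables (e.g. a 2×2 round-by-outcome layout) fit as
  saturated models and reproduce closed-form odds ratios exactly.
* Degenerate designs: single-level categoricals are dropped (a
  one-district cohort still fits); rank deficiency raises an error
  naming the collinear columns (identified by pivoted QR); an outcome
  with no variation, or a diverging coefficient, raises a separation
  error naming the term.
* Inference is two-sided Wald throughout (the paired t uses the t
  distribution; McNemar uses χ²₁, continuity correction off by default
  with a flag to enable). No multiple-testing adjustment is applied.
* The paired tests match observations by respondent id, which supports
  the linked-cohort reading of the two survey rounds; unlinked data
  can be compared by the descriptive layer.

## Synthetic generator

The generator's defaults are the study conditions: cohort sizes
310/240 (CAHWs) and 257/221 (veterinarians) with MCAR attrition to the
endline roster size; farmer survey n = 233; baseline CAHW success
48.8%; round log odds ln 1.51; veterinarian success stable near
74.5–74.8% with a null round effect; monthly procedure targets 3.2/4.3
(CAHWs) and 3.59/5.34 (veterinarians); farmer success 63.1%, full-term
rate 79.6%, litter mean 7.99 clipped to [1, 16], first-time AI share
80%, sow ages log-normal matched to mean 14.88 / median 12 months and
clipped to [3, 96].

Design choices where the source gives only summaries:

* **Success model.** logit(p) = intercept + district effect +
  (round log-odds + secular shift)·[endline]. The intercept is solved
  numerically (Brent) so the expected baseline population rate equals
  its target to <1e-6; the secular shift, when unset, is solved the
  same way for the endline target. Round effect and secular shift are
  *collinear* — both load on the endline indicator — so a single-round
  GLM estimates their sum. Attribution analyses and estimated-mode
  runs therefore generate with the secular shift at 0; with the shift
  active, the default configuration reproduces the observed
  48.8% → 74.8% trajectory instead.
* **Counts.** Monthly procedures are zero-truncated Poisson with the
  rate solved so the *truncated* mean hits the target. Litter sizes
  are Poisson clipped to the observed range.
* **Sow age.** Log-normal fitted by matching mean and median (μ = ln
  median, σ² = 2 ln(mean/median)), then clipped; clipping pulls the
  realized mean ≈0.5 months below the nominal target, which is within
  the tolerance used for calibration checks.
* **Parity.** A point mass at 0 (share 55.2%) plus a shifted Poisson
  whose mean makes the overall mean 0.70.
* **Breeds.** Landrace 85% / Large White 15%, with the planted breed
  effect ln 0.24 on the logit scale. Only these two breeds are named
  in the source; the mix is a synthetic default.
* **District effects.** The three districts with reported elevated
  success (Nyamagabe, Nyamasheke, Rutsiro) default to +0.30 log odds —
  a synthetic magnitude, as none is published. Farmer district effects
  default to zero (none were significant).
* **Failure causes.** Each record's failures are allocated
  multinomially across six categories with round-specific shares; the
  veterinarian simplex is assembled from reported challenge shares and
  is labelled synthetic.
* **Attrition** is outcome-independent by construction (the retained
  subsample is drawn before outcomes are used anywhere), matching the
  reported non-selective dropout.

What the generator does *not* emulate: calendar time and seasonality,
spatial structure below district level, respondent-level heterogeneity
in success beyond district membership (no random effects), recall
error, and any correlation between attrition and covariates.
Consequently, passing recovery tests show that the estimators are
correct and adequately powered at the study's sizes — not that the
real surveys were free of recall or selection artefacts.

## Validation and known limitations

* The composed economic model is checked against an independent
  straight-line re-derivation (no shared code) on 1,000 random valid
  parameter sets at 1e-9 relative tolerance, and the GLM against
  closed-form 2×2 odds ratios.
* Parameter recovery at the study sizes (200 replicates): the round
  odds ratio is recovered with mean within 3% of 1.51 and ~95% Wald
  coverage. The farmer breed effect is recovered with correct coverage
  (~0.93), but its point estimate shows the classic small-sample bias
  of ML logistic regression away from zero (≈9% on the log-odds
  scale): each replicate has only ~35 Large White sows (~11
  successes) and ~10 model parameters. This is a property of the
  estimator the study itself used, not of the generator; bias-reduced
  (Firth) estimation would remove it but would no longer be the
  specified estimator, so the recovery test documents the bias
  honestly instead of hiding it.
* Sensitivity analysis is one-way (tornado) only; no probabilistic
  uncertainty propagation. Multipliers are inputs, never estimated
  (no input–output table is inverted here).
* Problem sizes in the shipped tests and drivers (e.g. 200 recovery
  replicates, 25–30 calibration replicates) were chosen as the
  smallest designs that make the Monte-Carlo error comfortably smaller
  than each tolerance being checked.
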