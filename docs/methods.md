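# Methods

This note documents the models, rules and numerical choices implemented in
`plirisk`, the assumptions behind the synthetic data, and what the test suite
does and does not establish.

## Outcome definition and residential history

Stay records carry inclusive start/end dates and one of five settings
(nursing home, hospital, emergency department, hospice, outpatient
encounter).  Days are resolved by painting intervals onto a day grid with
priority hospital > ED > NH > hospice > community; encounter records carry no
residential information.  Payer is ignored throughout spell detection: NH
days count whether VA-paid, Medicare-paid or other.

An **LTI spell** opens on an NH day and accumulates NH days.  Days in an
*interrupting* setting (default: hospital, ED, hospice) never break the spell
and never count toward it; a run of community days longer than
`max_community_gap` (default 7) closes it.  A spell **qualifies** when its
cumulative NH days strictly exceed `day_threshold` (default 90; the
alternative 100-day convention that appears in some summaries of this
definition is available through `SpellRule`).  Death closes a spell on the
death date; a spell already past the threshold remains qualifying.  A person
is LTI-positive for the two-year outcome when a qualifying spell *starts*
inside the outcome window; NH-day accumulation may continue past the window
end up to a configurable horizon (default 180 days), since the definition
imposes no truncation at the window boundary.

Hospice handling was genuinely open: here hospice is its own resolved setting
that neither breaks a spell nor contributes NH days, and any baseline-year
hospice stay excludes the person from the cohort.

Cohort-entry exclusions are applied in a fixed order, counting each person
once: (a) qualifying baseline LTI spell or hospice stay, (b) no face-to-face
encounter, (c) baseline-year death, (d) hospital/NH residence on the last
baseline day.

## Covariates

* **Frailty (JFI proxy).**  A transparent count of affected diagnosis groups
  (default map: 13 disjoint groups over the 18 modeled conditions; maximum
  score 13).  The published claims frailty index this stands in for is
  calibrated against functional measures we do not model; only the role of
  the score (thresholds at ≥5 and ≥6) is reproduced, and the group map is
  fully configurable.
* **CAN proxy.**  A logistic model of one-year death-or-hospitalization fit
  on a held-out quarter of the cohort, applied everywhere; 4.5% of scores are
  flagged missing at random and imputed with the cohort median (indicator
  retained; the median avoids giving imputed rows leverage).
* **IAH-Q month flag**: hospitalization AND post-acute SNF stay AND ≥2
  chronic conditions AND frailty ≥ 6, all in the 12 months ending at that
  month.  "Chronic" means all modeled conditions except sepsis and fracture
  (acute events); the set is configurable because no canonical list exists.
  Post-acute care means SNF only (not home health) — a documented default.
* **HNHR month flag**: non-Medicare hospitalization AND VA-data frailty ≥ 5,
  excluding hospice/palliative care, HBPC/CLC enrollment and ESRD.
* **Stratum**: elevated risk (ER) iff either flag is true in any baseline
  month; common risk (CR) otherwise.
* **Race-centered age**: age minus the cohort mean age of the person's
  racial-ethnic group (groups are whatever the data carry; means are
  computed over the analysis cohort).
* **Prior utilization**: hospitalization and SNF flags over the 12-month
  look-back; **prior LTI** is ascertained in months 13–24 before the index
  date in *both* modes, because complete non-VA nursing-home data for the
  most recent year is exactly what the exclusion step consumes — anyone with
  a qualifying spell in the last 12 months is not in the cohort, so a
  12-month prior-LTI flag would be structurally empty.
* **Cost**: prior-year total in $10,000 units (numerical conditioning).

**Production mode** models scoring with a claims lag: the most recent
`lag_months` (default 9) of non-VA records are invisible.  Non-VA look-back
windows shift back by the lag (extending total look-back to 24 months), the
frailty score becomes the maximum of the monthly scores over the baseline
year, and stratum qualification may occur in any of the 24 pre-index months.
With `lag_months=0` and all information inside the baseline year, production
covariates reduce exactly to the complete-data ones; conditions recorded
*only* in months 13–24 can still raise the production frailty score above
the complete one through the monthly maximum — that asymmetry is the point
of the rule.

## Stratified models

One maximum-likelihood binary regression per stratum (logit default, probit
alternative), Newton iterations with score-norm tolerance 1e-8 and at most
100 iterations; rows are sorted by person id before fitting so results do
not depend on input order.  Constant covariates are dropped with a warning.
Binary covariates with an outcome-pure level (quasi-separation — typical for
rare flags in the low-event stratum) are dropped with a warning; a covariate
that separates the outcome in both directions raises an explicit error
naming it.  Station fixed effects are reference-coded dummies with the
largest station as reference; unseen stations score with effect 0.  The
retention rule keeps a covariate when its Wald p-value is below α (default
0.05) in at least one stratum, then refits both strata on the union;
station effects, when requested, are structural and always retained.

Average marginal effects use the counterfactual difference for binary
covariates (mean of p(x, c=1) − p(x, c=0)) and the mean derivative for
continuous ones, with delta-method confidence intervals; both agree with
statsmodels' independent AME machinery in the test suite.  Pseudo-r² is
McFadden's 1 − ℓ/ℓ₀ (the flavor was unspecified in the source design; values
on synthetic data are not comparable to real-data reports).

## Threshold optimization and tiers

Given scores with strata and outcomes, the optimizer maximizes captured LTI
events subject to pooled NNS ≤ `nns_max` (default 8) over the grid of all
distinct observed scores per stratum (flagging is inclusive, p ≥ τ).  The
search is exact without enumeration of all pairs: for each ER candidate the
feasibility constraint reduces to a one-dimensional query
g_CR(j) = flagged_CR − NNS·captured_CR ≤ budget(ER candidate), answered by a
prefix-lexicographic-max structure over the CR curve sorted by g, at
O(n log n) total.  (A percentile-coarsened grid was considered for very
large cohorts but is unnecessary — the exact search is fast at any realistic
size; the test suite asserts equality with brute-force enumeration.)  Ties
break by lower pooled NNS, then fewer flagged, then higher τ_ER, then higher
τ_CR.  Infeasible budgets raise an error reporting the best achievable NNS.

The moderate tier re-runs the optimizer under a laxer budget (default
NNS ≤ 25).  The source design publishes no moderate-tier rule, so this is an
extrapolation, clearly configurable; moderate thresholds are clamped to not
exceed the high ones.

## Evaluation

NNS = flagged/TP (reciprocal of PPV); the c-statistic is the Mann–Whitney
rank-sum concordance with ties at half credit; calibration ranks persons by
score with a stable sort (ties keep person-id order) into ten equal-count
bins.  The FNR equity audit reports, per race group and stratum, the share
of LTI cases not flagged high, plus the between-group gap; cells without
cases report NaN with a logged message rather than being dropped.  K-fold
cross-validation stratifies folds on (stratum × outcome) and re-tunes
thresholds inside each training fold so no information leaks into the
held-out fold.

## Synthetic cohort generator

The generator defines the study conditions the package is tested under:

* ~1.1% two-year LTI among the eligible cohort, ~5 non-LTI deaths per LTI
  event, and a ~9% ER stratum — the latent class prevalence (12%) and the
  per-class logistic intercepts (−5.80 common, −5.42 elevated; mortality
  −3.41) were calibrated once against these margins and then frozen;
* an elevated latent class whose members draw a high number of frailty
  groups (Normal(7.5, 1.5), clipped to [2, 13]) with group choice weighted
  by the elevated-risk prevalence pattern, plus high hospitalization (95%)
  and SNF (45%) rates — so most of them genuinely satisfy the IAH-Q/HNHR
  machinery rather than being labeled ER by fiat;
* condition prevalences patterned on the observed ER/CR contrast
  (e.g. dementia 15.2% vs 2.5%);
* a race-differential age at LTI entry: latent risk depends on age through
  (age − group mean − group shift), so the expected between-group difference
  in mean age at entry equals the difference of (mean + shift) — with the
  default means 64/56 and shift 0/−4, entry is 12 years earlier in the
  comparison group.  The latent class is independent of age and race, which
  keeps this differential exact but means the ER stratum is not older than
  the CR stratum as a real cohort's would be;
* stay records that exercise the spell detector: qualifying NH sequences
  with hospital interludes and ≤7-day home leaves for LTI-positive persons,
  short post-acute SNF stays (cumulative ≤ 90 days, separated by ≥ 30
  community days) for others, and small arms constructed to trip each
  cohort-entry exclusion;
* diagnosis events with onset, recurrence (35%/month) and a guaranteed
  recent contact, each tagged VA (75%) or Medicare — supporting the VA-only
  frailty score and the production-mode lag;
* outcome generation is a two-step draw (LTI Bernoulli from the latent
  per-class logistic, then death, with death dates placed after a realized
  spell qualifies) rather than a competing-risks model — margins match the
  study conditions but death never censors a drawn LTI event.

What the generator does **not** emulate: real claim formats, correlated
comorbidity structure beyond the ER/CR contrast, age-dependent stratum
composition, cost dynamics, Medicare Advantage/Medicaid gaps.  Passing tests
therefore demonstrate that the *machinery* is correct under known truth, not
that real-data performance (c ≈ 0.87, sensitivity 41%) is reproduced — that
requires the restricted data.

## Fairness measurement on synthetic data

With ~150 comparison-group LTI cases in the CR stratum at n = 50,000, a
realized-outcome FNR gap has binomial noise comparable to the effect of
interest.  The paired fairness check therefore evaluates the FNR gap **in
expectation over outcome draws**: each person is weighted by their latent
event probability (known in simulation), while the fitted models, tuned
thresholds and flags are exactly those the pipeline produced from realized
outcomes.  This is the same estimand with the case-sampling noise removed,
and it is only available because the truth is known — on real data one would
need the realized-count version and far larger cohorts.

## Problem sizes used

Module tests run at n ≤ 30,000; marginal-rate checks use one 200,000-person
cohort; parameter-recovery coverage uses 200 replicates at n = 50,000; the
acceptance script simulates 150,000 persons.  These sizes give Monte-Carlo
error well inside every asserted tolerance while keeping the default test
run a few minutes long.

## Known limitations

* The frailty and auxiliary-risk proxies reproduce roles, not calibrations.
* The moderate tier's budget (NNS ≤ 25) is an extrapolation.
* Exclusion-arm persons in the generator have no outcome records at all,
  which is cruder than reality (e.g. someone institutionalized on the last
  baseline day would usually remain so into the outcome window).
* The two-step outcome draw ignores death-censoring of LTI.
* Monthly windows use calendar-month offsets from the index date; stay
  windows use 365/730-day look-backs — a deliberate, documented mix.
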