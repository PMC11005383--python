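# Methods

This note documents the models, conventions and numerical choices behind
`tilscale`: what each stage computes, what the synthetic cohort generator
does and does not emulate, and which design points were genuinely open.

## Scales and scoring

The therapy intensity level (TIL) scale treats ICP-directed management as a
*formative* construct: the daily score is defined by the twelve treatment
items jointly (positioning, sedation, neuromuscular blockade, CSF drainage,
fluid loading, vasopressors, hypocapnia, mannitol, hypertonic saline,
temperature control, intracranial operation, decompressive craniectomy), not
by a latent factor the items reflect. High inter-item correlation is
therefore not required for validity, and Cronbach's α is reported
descriptively, not as a fitness criterion.

Five configurations ship in `data/scale_configs.yaml`, one table per scale:

| scale | aggregation | maximum |
|---|---|---|
| TIL | sum of per-item maxima | 38 |
| uwTIL | sum of per-item ascending rank indices | 21 |
| TILBasic | maximum administered sub-item tier | 4 |
| PILOT | sum of per-item maxima (adapted item set) | 38 |
| TIL1987 | sum of per-item maxima (adapted item set) | 15 |

Each configuration is validated at load time: the all-maximal treatment day
must score exactly its declared maximum. Two cells of the condensed scale
are under-determined by the published table and are config-encoded (hence
overridable): fever control scores TILBasic 1 (basic-care tier) and
neuromuscular blockade is excluded from TILBasic. Items a configuration
excludes contribute 0.

Conventions implemented in the scoring layer rather than at analysis time:

* **Craniectomy carry-forward.** A decompressive craniectomy performed as a
  last resort for refractory intracranial hypertension contributes its score
  on the operation day and on every later recorded day. A craniectomy that
  was not last-resort is not propagated.
* **WLST censoring.** Days on or after a documented decision to withdraw
  life-sustaining therapies are censored, never scored, and never imputed —
  they are structurally absent, not missing. A first-day WLST decision
  removes the patient from the validation population.
* **Day convention.** Days are 1-based, anchored to ICU admission time in
  24 h blocks; "first week" means days 1–7 inclusive. The published
  material does not state whether calendar days follow local midnight or
  admission-anchored windows; admission anchoring was chosen because the
  synthetic physiology is generated on the same clock.
* **Summaries.** Weekly maximum, and weekly median with midpoint
  interpolation for even day counts — half-integer medians are deliberate
  (they make thresholds such as "weekly median ≥ 7.5" expressible).
* **Missing sub-items.** A missing sub-item on an otherwise assessed day
  contributes 0; a day on which *all* items are missing is a missing daily
  score, left to the imputation stage. Daily scores are imputed as
  longitudinal variables; treatment indicators are never re-imputed and
  scores are never re-derived from imputed indicators.

The daily-TIL → TILBasic category mapping ships in two named variants: the
empirically derived ranges (1–2 → 1, 3–6 → 2, 7–8 → 3, ≥9 → 4) and the
earlier consensus ranges (1–3, 4–7, 8–10, ≥11). `derive_ranges` re-derives
boundaries from data as the points where the median condensed score per
daily-TIL value increases (medians rounded half-up to a category).

## Physiology

End-hour (EH) samples carry ICP/SBP/DBP; mean arterial pressure is
MAP = (SBP + 2·DBP)/3 and CPP = MAP − ICP per sample. High-frequency (HR)
samples carry ICP and CPP directly. Daily values (ICP_24, CPP_24) are
arithmetic means over the admission-anchored day; any sample count ≥ 1
yields a mean (no minimum-count rule is published; `n_samples` is recorded
so users can filter). Weekly summaries are max/median of ICP_24 and
min/median of CPP_24. Negative CPP is retained with a warning — artefact
cleaning is out of scope.

## Synthetic cohort generator

The generator is mechanistic-lite: a latent model plus a treatment policy,
not a fit to any real dataset. Its purpose is to give every downstream
estimate a known truth, with the qualitative structure the validation
argument relies on.

* **Severity** (per patient, N(0, 1)) drives baseline GCS negatively, the
  ordinal six-month outcome and the six prognosis probabilities (both via a
  shared latent recovery scale, so the probability block is non-increasing
  across thresholds by construction), and the initial ICP burden.
* **Burden** — untreated ICP elevation in mm Hg — follows a stationary AR(1)
  across days 1–7 (mean 10.5, sd 3.2, autocorrelation 0.55, severity loading
  0.6). Defaults were chosen once so that summary distributions resemble a
  contemporary neuro-ICU cohort (weekly-max daily score median ≈ 10–12,
  daily score median ≈ 5–7, refractory fraction ≈ 15–20%); no equivalence to
  any real cohort is claimed.
* **Policy.** Each day, therapy escalates along a fixed staircase —
  positioning, sedation, CPP management, ventilation, neuromuscular
  blockade, CSF drainage, hyperosmolar therapy, temperature control —
  until modelled ICP (baseline + burden − treatment_effect × TIL) falls to
  the 20 mm Hg target. CSF drainage and decompressive craniectomy are gated
  by center-level random propensities (logit sd 1.0), reproducing the
  finding that these are the most variably applied therapies. Mass-lesion
  patients (Marshall V/VI) receive an intracranial operation once burden
  exceeds 14 mm Hg; last-resort craniectomy triggers once burden exceeds the
  refractory threshold (16 mm Hg) from day 2, is recorded on its index day
  only, and relieves 6 mm Hg of burden on later days.
* **Observed ICP.** Daily mean ICP is generated with a *fixed* within-patient
  coupling: baseline + patient intercept + day trend + coupling_beta × TIL_24
  + noise, with coupling_beta defaulting to 0.22 mm Hg per point. A purely
  mechanistic subtraction form cannot serve here: under the policy, burden
  and TIL move together and the implied within-patient slope is near zero
  rather than the configured coupling, so the recoverable-slope contract
  would be vacuous. The patient intercepts are drawn independent of severity;
  a severity-loaded intercept would correlate with treatment intensity and
  bias the random-intercept estimator (endogeneity). Real cohorts need not
  satisfy this independence — passing recovery tests here shows the
  machinery is correct, not that real-data estimates are unconfounded.
* **Physiology streams.** EH samples every 2 h; an HR stream for ~30% of
  patients. The emulated HR cadence is 10 min (not seconds): the analysis
  consumes daily means, for which a finer grid changes only file size. SBP
  and DBP are reconstructed from a sampled MAP and pulse pressure so the MAP
  formula is exactly invertible.
* **Concerns.** Daily ICP and CPP concerns (1–10) are noisy monotone
  transforms of the same day's ICP and CPP; the CPP concern carries twice
  the noise, making it the discriminant (more weakly coupled) counterpart.
* **Refractory label** is true when burden exceeds the refractory threshold
  on any day — i.e. medical therapy at full escalation cannot reach the ICP
  target. An infinite threshold yields zero refractory patients.
* **WLST** is assigned to the configured fraction (10%) of highest-severity
  patients on a uniform day 2–7; their post-decision days are structurally
  absent from every longitudinal table, and their outcome is death.
* **Missingness** is injected separately and is missing-at-random by
  construction: masking probabilities depend only on center, age and day.
  Whole daily assessments are masked at 2.4% (the reported real-world rate),
  static variables at variable-specific rates (≈1–19%), and day-1 HR
  physiology is dropped for 67% of HR patients (hookup-delay emulation).

What the generator does **not** emulate: waveform-level artefacts, imaging,
informative (MNAR) missingness, inter-rater disagreement, treatment effects
on outcome, or between-center differences beyond the two therapy
propensities. Tests passing on this cohort validate the statistical
machinery and the qualitative orderings, not clinical effect sizes.

## Statistics

* **Spearman ρ** (average-rank ties) for once-per-patient pairings.
* **Repeated-measures correlation r_rm** by the subject-adjusted ANCOVA:
  regress y on subject indicators plus a common slope for x;
  r_rm = sign(b)·√(SS_x/(SS_x+SS_err)), df = N − k − 1. Computed via the
  equivalent within-subject-centered correlation; two independent oracles
  (explicit OLS-with-dummies ANCOVA, and pingouin) pin the implementation to
  1e-10. Subjects with fewer than two complete pairs are dropped and
  counted. Ordinal concern scores are treated as numeric, as in the source
  r_rm method.
* **Mixed-model slope β** from outcome ~ Day_ICU + score with patient random
  intercepts, REML (statsmodels MixedLM; lbfgs with a Powell fallback for
  boundary variance fits). Interpreted as mm Hg change per scale point net
  of time and patient. Random slopes are deliberately not fitted.
* **Component items**: median item score per daily-TIL stratum; adjusted
  item-total r_rm (item subtracted from the total first); per-day Cronbach
  α; and one joint mixed model of daily ICP/CPP on all sub-item dummies plus
  day, with aliased (collinear or never-administered) dummies dropped and
  reported.
* **Known-groups validity**: AUC as the Mann-Whitney pairwise probability
  with ties credited 0.5; thresholds at midpoints between adjacent distinct
  scores, reported as "≥ t" rules; the selected threshold maximizes
  sensitivity + specificity with ties broken toward the lower (more
  sensitive) threshold — the published material does not state a tie-break,
  so this is an explicit convention. Accuracy is reported per threshold at
  sample prevalence. Surgical-control days are labelled after carry-forward.
* **Information coverage** IC = MI(condensed, full)/H(full) with plug-in
  estimators, base-2 logarithms (IC itself is base-invariant; the estimator
  and base are unstated in the published description, so plug-in/bits were
  chosen and the small-sample bias of plug-in MI is accepted and noted —
  each result carries its n). Half-integer medians are distinct categories.

## Imputation

Static variables (GCS, GOSE, prognosis block, Marshall, refractory label)
are completed by independent stochastic predictive mean matching: a linear
model on complete cases, an approximate posterior draw of its coefficients,
and a uniform draw among the k = 5 nearest observed donors by predicted
value (k is a common default; the published setting is unstated). Donor
draws keep every imputed value inside the observed support; the six
prognosis probabilities are taken as a block from a single donor, which
preserves their monotonicity. Predictors are all usable static columns plus
patient-level auxiliaries (observed weekly summaries, a raised-ICP
indicator).

Longitudinal variables (daily scale scores, EH daily ICP/CPP, concerns) are
completed by a ridge-stabilized EM fit of a multivariate normal over the
patient × (day, variable) matrix, with each of the m imputations drawn from
parameters re-estimated on a bootstrap resample of patients — a documented
simplification of the bootstrapped-EM family of time-series imputers, not a
re-implementation of any package's internals. Draws for ordinal/bounded
variables are rounded and clipped (daily scores to their scale range,
concerns to 1–10). HR daily values are imputed only within the
HR-monitored sub-population (for other patients they are structurally
absent); the HR model uses the daily TIL score and EH dailies as
predictors with a stronger ridge (1e-2 vs 1e-3) because that sub-cohort is
small relative to its dimension. Non-convergent EM raises with the
iteration count. m defaults to 20 at desk scale (5 in the shipped pipeline
defaults); 100 reproduces the study-scale setting by flag — the
bootstrap-over-imputations interval only requires that one copy be drawable
per resample.

## Inference

Confidence intervals are percentile bootstrap over B resamples (default
1000; desk-scale runs use 200): each resample draws patients with
replacement — all of a patient's rows travel together, and a patient drawn
twice enters as two distinct subjects — and one imputation copy uniformly at
random. The interval therefore reflects sampling and missing-data
uncertainty jointly; no Rubin's-rules pooling is used. The point estimate
is the statistic averaged across all copies on the original sample (whether
published point estimates pool copies is unstated; this choice is
documented because it affects estimates, not intervals). Undefined
evaluations are counted and excluded; intervals are suppressed with a
diagnostic if more than half the resamples are undefined. BCa and other
variants are out of scope.

Exception for runtime: mixed-model slopes in the pipeline's association
table carry model-based (Wald) intervals pooled across copies, tagged
`reml-wald-pooled` in the output, because refitting a mixed model inside
every resample dominates desk-scale runtime. All other reported statistics
(ρ, r_rm, AUC, IC, α) use the joint bootstrap.

All randomness flows from one master seed through named substreams
(CRC-32-keyed SeedSequence spawns), so stages are independently
reproducible and insensitive to evaluation order; fixed (seed, B, m) yields
byte-identical outputs.

## Problem sizes and defaults

Desk-scale defaults were chosen once as the package's own operating points:
pipeline runs at n = 300 patients, m = 5 imputations, B = 200 resamples
(about two minutes on one CPU); the acceptance script and the recovery
experiments run the study-scale n = 873 with 50 replicate cohorts for
mixed-model CI coverage and 200 replicates for bootstrap coverage of a
known rank correlation. The generator's distributional defaults are fixed
study conditions, not tuning knobs; they are not adjusted per run.

## Known limitations

* The plug-in MI estimator is biased upward in small cells; IC values on
  small strata should be read with their n.
* The EM imputer assumes joint normality of rank-transformed-ish daily
  variables; heavily skewed real variables may need transformation first.
* The escalation policy is an artifact construct — no quantitative policy
  parameters are published — so synthetic thresholds (e.g. the surgical
  detection cut-off) are compared to generator truth, never to published
  cohort values.
* Inter-rater reliability is out of scope (single-rater data).
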