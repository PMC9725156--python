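# Methods

## Pathway encoding and validation

All computation runs on a participant-local integer day axis with psychosis
onset at day 0; calendar-dated CSVs are converted on load. Delays are whole
days throughout — the underlying interview data cannot resolve finer than a
day, and every published delay quantity is a day count. When an interview
yields only a month, the day is imputed to the 15th (`mid`, default) or the
1st (`first`); no principled rule exists for choosing between them, so both
are offered and the imputation is flagged on the encounter so analysts can
stratify by date precision.

The 14 caregiver node types (5 community, 9 clinical) are frozen in a
registry; unknown labels are a load error, not a silent coercion into an
"Other" bucket, because coerced labels would corrupt per-type summary
tables invisibly. Cohorts with genuinely new caregiver types extend the
registry explicitly.

Validation mirrors field practice with irreconcilable interview data: a
pathway that violates an invariant (dates out of order, encounter outside
the onset–enrollment envelope, prescribing-flag/antipsychotic-date
mismatch, naive flag plus an antipsychotic date, functioning score out of
scale bounds) excludes that participant with a recorded reason rather than
aborting the run, and the exclusion rate is reported. Same-day encounters
keep their input sequence order, which is meaningful (a family contact and
the urgent-care visit it triggers can share a date).

## Delay decomposition

`decompose_delays` computes onset delay, per-encounter marginal delays,
and the three global DUP measures, engineered so two identities hold
*exactly* (they are asserted, not approximated):

- onset delay + Σ marginal delays = DUP-total;
- DUP-demand + DUP-supply = DUP-total.

Design choices the definitions force or leave open:

- **Side of the prescribing encounter: supply.** Its marginal delay
  elapses entirely after prescription; any other convention breaks the
  worked example's 4/5 demand/supply split. Node counts follow delay
  attribution (the prescribing encounter is a supply node).
- **Boundary splitting.** If the antipsychotic date falls strictly inside
  an interval (e.g. a prescription phoned in between visits), that
  interval's delay is divided at the antipsychotic date — the only rule
  consistent with both identities. The split is recorded separately
  (`boundary_split`); the demand/supply *sums* carry its two parts, but
  neither part enters any single encounter's marginal-delay statistics,
  since the interval belongs to no one side in full.
- **Zero-encounter pathways** are retained and flagged degenerate: the
  global measures remain well defined even though onset delay does not.
- Antipsychotic-naive pathways have DUP-supply = 0 by definition and every
  encounter demand-side.

## Transition network

Pathways are stacked into a directed graph with explicit `Onset` and
`STEP` terminals — included because the flow-conservation invariants
(every pathway leaves Onset once and enters STEP once; at every caregiver
node, in-flow = out-flow = encounter count) are only checkable with them.
Self-loops (consecutive encounters at the same node type) are kept as
counted edges for the same reason. Edges carry total counts plus a
demand/supply stratification, labelling each transition with the side of
the encounter it enters (source side for edges into STEP). DOT export
scales edge penwidth linearly with count and node width with the square
root of encounter count (area ≈ encounters), with floors so rare nodes
stay visible; the scaling is presentational only, and the CSV exports are
lossless.

## Summaries

Quantiles are linear-interpolation percentiles; rendered tables round to
one decimal but the frames keep full precision so rounding never feeds a
downstream computation. Per-participant node-count medians include
participants with zero encounters in a stratum (the defensible reading
when a summary claims to describe the whole cohort). Node types never
observed produce no row, and empty side strata report NaN rather than a
fabricated zero.

## Association analyses

The bivariate screen tests 14 baseline covariates against each of
DUP-total/-demand/-supply: tie-corrected Spearman correlation for the six
continuous covariates (age at onset, GAF-e, GAF-12, GAF-Δ, GF-r, GF-s)
and tie-corrected Kruskal–Wallis for the categorical rest, with effect
size η² = (H − k + 1)/(n − k) clamped below at zero (the formula can be
negative under the null; published tables print exact zeros, consistent
with clamping). The Bonferroni family is, by default, the covariates
screened against one outcome (m = 14, printed in every row, configurable).
GAF-Δ is always recomputed as GAF-e − GAF-12; the cohort means (GAF-e
well below GAF-12) force this orientation, so a *positive* GAF-Δ
correlation with delay corresponds to less functional decline — mirrored
relative to reports that define the difference the other way. Constant
covariates yield NA rows, never exceptions.

The marginal-delay model is a linear mixed model on log(1 + delay) —
marginal delays are heavily right-skewed with ranges into hundreds of
days, and log1p keeps the many exact-zero community-node delays in the
model; excluding zeros would bias the node-type contrasts. Fixed effects
are node type plus one covariate (unadjusted) or all covariates
(adjusted); one random intercept per participant absorbs
between-participant delay propensity across repeated encounters.
Estimation is REML via Powell's method: the default quasi-Newton
optimizers in statsmodels raised singular-Hessian errors near the
random-effect variance boundary on a substantial fraction of synthetic
fits, while Powell (derivative-free) converged on all of them. Inference
is Wald. Non-convergence and boundary/singular fits (zero variance,
non-positive-definite Hessian, or an optimizer singularity warning) are
reported on the result object; there is no silent fallback.

## Synthetic cohort generator

The generator is a two-phase semi-Markov walk: an initial node drawn from
a community-heavy distribution, demand-phase transitions until a clinical
encounter prescribes the first antipsychotic (probability 0.57 per
clinical encounter), then supply-phase transitions until absorption at
STEP. Inter-node delays are log-normal with node-type- and phase-specific
medians, floored to whole days.

Anchored defaults: 156 participants; 72.4% male; age 21.6 (SD 3.8); GAF-e
31.1 (10.9); GAF-12 53.7 (17.5); GF-r 4.4 (2.2); GF-s 5.1 (1.5);
categorical covariate tables renormalized from published cohort
marginals; onset-delay median 21.5 days; outpatient mental health the
slowest node (medians 36.5/56 days demand/supply), inpatient intermediate
(12/13), community nodes near zero. The prescribing probability is
calibrated so the simulated antipsychotic-naive fraction sits near
12/156 ≈ 7.7%.

Choices the anchors leave open, fixed once:

- **Log-scale spreads**: σ = 1.8 for onset delay, 1.2 for clinical and
  1.5 for community node delays — heavy right skew with plausible extreme
  values (upper ranges of months to a couple of years) without the
  near-unbounded tails a literal fit of published IQRs would imply.
- **Covariate effects** act multiplicatively on all of a participant's
  delay draws through a log-linear predictor, matching the mixed model's
  scale. The default injects β = −0.03 per GAF-12 point (centered at
  53.7), which induces a Spearman correlation of about −0.35 between
  GAF-12 and DUP-total at default noise — the magnitude reported for this
  association in cohorts of this size. Setting
  `covariate_effects = {}` gives a null generator for calibration tests.
- **Participant frailty**: a normal random intercept (SD 0.35) on the
  log-delay scale over and above covariate effects. Real cohorts have
  between-participant delay propensity that covariates do not explain;
  without it the mixed model's random-intercept variance is truly zero
  and every fit is a boundary fit.
- **Routing is covariate-independent** by default (covariates shift
  delays, not transition probabilities); the config accepts alternative
  phase matrices for users who want routing effects.

One root seed drives everything; each participant receives a spawned
substream, so cohorts are bit-reproducible and stable under partial
regeneration.

### What the generator does and does not emulate

It reproduces the phase-asymmetric node mix (community-heavy demand,
clinical-heavy supply), skewed delays, the naive minority, covariate
marginals, and a known covariate → delay effect. It does **not** model
recall bias, date-imputation error, covariate–routing dependence,
covariate correlation structure (covariates are drawn independently), or
calendar effects. Passing tests therefore demonstrate correctness of the
*computations* and recoverability of effects under the assumed data
model — not that any particular real-world cohort satisfies those
assumptions.

## Test problem sizes

Property suites use many small seeded cohorts (1,000 cohorts of 10
participants for conservation; 30 cohorts of 30 for flow balance), null
calibrations use 500–1,000 replicates, and parameter-recovery suites use
100 cohorts of 150 participants — sizes chosen to make Monte-Carlo bands
tight enough to be meaningful while the full suite stays comfortably
runnable on a laptop core.

## Known limitations

- The demand/supply transition switches at antipsychotic prescription; a
  clinician who recognises psychosis but defers prescribing is
  misclassified as demand-side, an acknowledged limit of the proxy event.
- η² from H is a biased-upward effect-size estimate in very small groups.
- The mixed model assumes a common covariate slope across node types;
  flooring and the log1p transform attenuate recovered slopes for
  near-zero community delays (recovered β is typically 60–80% of the
  injected value, sign-consistent).
- Wald inference for fixed effects; no small-sample df correction.
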