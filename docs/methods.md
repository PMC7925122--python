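# Methods

This note documents the models, generative assumptions, numerical choices
and known limitations of the `selfblind` package. It states nothing that
the test suite or `scripts/acceptance.py` does not itself compute.

## 1. The randomization design

A trial is described by `TrialDesign`: a 4-week dose period, capsules on
Mon/Tue/Thu/Fri (none midweek Wednesday or on weekends), two microdose
capsules per microdose week, and a kit of eight weekly envelopes (four
microdose, four placebo). Each envelope carries a 6-digit numeric code,
collision-checked within the kit; the experimenter-only `CodeBook` maps
codes to week types, and nothing in any participant-facing serialization
distinguishes envelope types (a property the tests verify by relabeling).

The constrained draw selects four envelopes such that only three weekly
compositions are possible — 0, 2 or 4 microdose weeks, defining the PL,
HH and MD groups — each with probability ⅓. Internally the group label is
sampled first and a uniformly random arrangement of envelopes consistent
with it second; this realizes the stated marginal distribution with the
least mechanism. Unselected envelopes are retained as `discarded` so the
end-of-study "open your leftover envelopes" check can be simulated.
Within a microdose envelope the two active capsules are placed uniformly
at random among the four capsule days, so the Thursday (acute-assessment)
capsule is active with probability ½ in a microdose week.

Derived constants: 32 capsules per kit at a 3:1 PL:MD ratio (base rate
p = 0.25); 0/4/8 total microdoses for PL/HH/MD schedules; 16 capsule
events per completed schedule.

## 2. Synthetic cohorts

`GenerativeParams` defaults encode the study conditions the package
targets: 240 starters, completion probability 191/240, follow-up
probability 159/191 (dropout is non-informative Bernoulli thinning by
stage); substances 75% LSD/analogue (13 ± 5.5 µg, truncated at 1 µg),
24% psilocybin mushroom (0.2 ± 0.12 g, truncated at 0.02 g, converted at
46 µg/g), 1% other handled like LSD doses; demographics with age
33.5 ± 9.4 and ~70% male, drawn from simple parametric distributions and
carrying no effect, so covariate screening has a calibrated null.

**Guess behavior.** Each capsule guess is a forced binary choice.
Specificity (correct placebo calls) defaults to 0.82. Sensitivity follows
a logistic psychometric function of LSD-equivalent dose,
`sens(d) = 1/(1+exp(−k(d−d₅₀)))` with k = 0.15 /µg and d₅₀ = 13.7 µg,
calibrated once so that mean sensitivity ≈ 0.45 under the default dose
mixture; a constant or arbitrary monotone override is available.
Participant-level Gaussian jitter (SD 0.15 on sensitivity, 0.10 on
specificity, clipped to [0, 1]) widens the between-participant spread of
accuracy toward realistic values; the clipping shifts means by < 0.002.
Week-level guesses apply the same latent discriminability to the week's
capsule composition: the announce-MD probability is the mean per-capsule
announce probability across the week's four capsules. Under these
defaults the simulated cohort mean break-blind rate is ≈ 0.72 with
sensitivity ≈ 0.43 and specificity ≈ 0.81.

**Outcome model.** Self-report scores are Gaussian:
`value = mean + subject_intercept + β_cond·1[MD capsule/week] +
β_guess·1[MD guess] + residual`, clipped to the registry's scale range
(clipping is on by default; integer rounding is off since analyses run on
scale totals). Accumulative change from baseline is
`γ_time + γ_expect·(# MD guesses) + γ_drug·(# microdoses) + noise`, with
the same change process at week 5 and week 9 (sustained effects).
Default effects place expectancy (β_guess, γ_expect) on self-report
scales, a true drug effect only on acute drug intensity (β_cond = 3.4 VAS
points), and nothing on cognition — so the correct analysis verdict on a
default cohort is "guess, not condition, explains the improvements".
Cognitive tasks add concave per-session learning gains (≈ 0.25–0.52
baseline SD across sessions 1–6) to a subject ability intercept.

What the generator does **not** emulate: item-level questionnaire
structure, informative dropout, within-day pharmacokinetics of the acute
window, floor/ceiling response styles, or any dependence between guesses
and outcomes beyond the planted effects. Passing tests therefore show
that the analysis machinery is calibrated and recovers planted effects
under the assumed Gaussian compound-symmetry world — not that the real
data obey those assumptions.

## 3. Scales and the cognitive composite

The scale registry ships as CSV: 7 acute self-report scales (net-affect
PANAS plus six 0–100 VAS items), 4 post-acute scales, 9 accumulative
scales. RPWB is registered with 42 items scored 0–6, total range 0–252.
PANAS is registered as a single net-affect scale (10 item-pairs, −4..+4)
so the acute battery has one PANAS entry; subscale simulation is out of
scope.

The cognitive performance score (CPS) is the mean of per-task z-scores
over six online tasks. Learning (session-order) effects are removed
first: per task, the per-session mean offset relative to baseline is
estimated from sessions *not* taken under an active microdose, then
subtracted; z-scores are formed against baseline mean/SD. Estimating the
learning curve from microdose-free sessions only keeps any true drug
effect out of the correction with the least structure. Consequences, both
tested: CPS is invariant to adding any per-session constant shared by all
participants, and a participant scoring exactly at the adjusted
expectation of every task gets CPS = 0. Sessions with fewer than 4 of 6
tasks yield a missing composite. A zero baseline SD for any task is an
error, not a silent skip.

## 4. Inference

All three families are linear mixed models with a subject random
intercept, which realizes the equal-correlation (compound-symmetry)
within-subject covariance; fixed-effect inference uses the large-sample
normal approximation (z-based Wald tests and CIs). Covariates are
mean-centered before fitting so intercept combinations are adjusted means
at covariate means.

* **Accumulative**: change from baseline ~ group + time + group×time,
  contrasts = within-group adjusted mean change at each timepoint and
  between-group differences (PL vs HH, PL vs MD) per timepoint; the
  number-of-MD-guesses covariate is available as the expectancy
  adjustment.
* **Acute / post-acute**: score ~ condition (+ guess + guess×condition),
  condition defined by the Thursday capsule (acute) or the week type
  (post-acute). In the guess-augmented model the planned PL-vs-MD
  contrast averages the condition effect with equal weight over the two
  guess strata (LSMEANS-style).
* **Strata**: the 2×2 condition×guess table per scale, with four planned
  comparisons (two at fixed guess, two at fixed condition). Over the 11
  self-report acute + post-acute scales this enumerates 22
  fixed-condition comparisons. Empty strata flag their comparisons
  unavailable; a singular design (e.g. guess ≡ condition) is handled by
  pruning linearly dependent columns, and any comparison touching a
  pruned term is likewise unavailable.

Covariate screening is one-at-a-time: each candidate alone against the
outcome in the family's own model, retained iff two-sided p < 0.05 — the
simplest reading of "adjust for all significant baseline covariates".
Twelve candidates are screened for accumulative models; acute/post-acute
screening drops baseline score and total dose. "Total dose" is defined as
(number of microdoses) × (LSD-equivalent per-capsule dose). Degenerate
candidates that fit the outcome perfectly are retained (their p is taken
as 0). No multiplicity correction is applied across scales, matching the
reporting convention of nominal p-values; reports should say so.

`power_sample_size` uses the two-sample normal approximation
n/group = 2(z₁₋α/₂+z_power)²/d², rounded up per group (d = 0.3 at 90%
power, α = 0.05 → 234/group, 468 total).

Known numerical behavior: at the variance boundary (subject variance → 0)
REML may warn about singular covariance; fixed effects remain valid and,
with balanced within-subject designs, agree with OLS to ≤ 1e-6 (tested).
As guess accuracy approaches 1, condition and guess become collinear and
condition CIs widen — the design's fundamental identifiability limit, not
a software defect.

## 5. Blinding integrity

Per-participant break-blind rate, sensitivity and specificity are
computed at the capsule-day level; week-level guesses are summarized
separately and never pooled with day guesses. Cohort summaries are
unweighted means over participants (so the SD is a between-participant
SD); participants with no MD capsules have undefined sensitivity and are
excluded from the sensitivity mean but counted in the report.

The random-guesser null is probability matching at the kit base rate p:
accuracy p² + (1−p)², sensitivity p, specificity 1−p → (0.625, 0.25,
0.75) at p = 0.25. The identity
`pooled accuracy = p·(exposure-weighted sensitivity) + (1−p)·(weighted
specificity)` holds on any dataset and is tested.

The detection threshold regresses per-participant accuracy on
LSD-equivalent dose (OLS, F-test on the slope) and reports the smallest
dose at which the pointwise lower 95% confidence bound of the fitted mean
exceeds the random baseline, searched over the observed dose range
extended at most 2×; undefined when the slope is non-positive or the
bound never crosses. This operationalizes "guesses significantly better
than random" with the simplest concrete criterion. Two properties follow
and are tested: the estimator carries a positive finite-sample offset of
roughly 1.96·SE/slope (so recovery of a planted crossing needs an
accuracy slope steep enough that this offset is small against the
crossing dose — the recovery test plants specificity 0.70 with a linear
sensitivity slope of 0.05/µg crossing at 12 µg, where recovery within
±20% succeeds in ≈ 9 of 10 replicates at n = 240), and steeper
psychometric slopes yield smaller estimated thresholds on average. Note
that with high specificity (0.82), cohort accuracy exceeds the 0.625
baseline at near-zero dose, so thresholds estimated on default-calibrated
cohorts are small; the threshold is strongly criterion-dependent and
should be reported together with its definition.

## 6. Problem sizes and determinism

Every stochastic operation takes an explicit seed or
`numpy.random.Generator`; nothing reads global random state or the clock,
and `run_all` manifests are checksum-identical across reruns. The test
suite's simulation studies use 200 replicates for type-I calibration
(n = 90 subjects per replicate), 100 replicates for parameter recovery
(n = 191, the completer count) and threshold recovery (n = 240, the
starter count), and 10,000 draws for the group-allocation goodness-of-fit
— sizes chosen so each check's binomial/sampling error is small against
the property it verifies.
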