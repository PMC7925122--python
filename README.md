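# selfblind

Tools for designing, simulating, and analyzing **self-blinded
placebo-controlled microdosing trials** — study designs in which
self-experimenters prepare their own opaque active and placebo capsules,
randomize themselves through a constrained envelope draw, and report
outcomes online while only the experimenter's code book can reveal what
was taken when.

The package is aimed at trial methodologists and researchers studying
placebo/expectancy effects. It answers the question such designs exist
for: *when a microdoser improves, is it the drug or the belief?* To do
that it separates, in both simulation and analysis, two channels per
outcome scale:

* **condition** — the capsule actually taken (placebo `PL` vs microdose
  `MD`), and
* **guess** — the participant's forced binary belief about that capsule.

## What's inside

| module | purpose |
| --- | --- |
| `selfblind.design` | envelope kits (4 MD + 4 PL weekly envelopes, 3:1 PL:MD capsule ratio), the constrained semi-random draw (PL/HH/MD groups, probability ⅓ each), experimenter-only code book |
| `selfblind.cohort` | synthetic cohorts: 240 starters → 191 completers → 159 follow-up, dose-dependent guessing, separable drug/expectancy effects, acute/post-acute/accumulative outcome batteries |
| `selfblind.scales` | outcome-scale registry, mushroom→LSD dose conversion (46 µg/g), cognitive composite with learning-effect removal, change from baseline |
| `selfblind.inference` | mixed models for the three outcome families, planned contrasts, covariate screening, 2×2 condition×guess strata comparisons, Cohen's *d*, power |
| `selfblind.blinding` | break-blind rates, the probability-matching random-guesser null, dose→detection-threshold estimation |
| `selfblind.pipeline` / `selfblind.cli` | reproducible end-to-end runs with CSV/JSON artifacts and checksummed manifests |

## The model

Acute and post-acute scores are modeled as

```
y_ij = μ + b_i + β_cond·1[condition=MD] + β_guess·1[guess=MD] + ε_ij
```

with subject random intercept `b_i` (the random-intercept realization of a
compound-symmetry covariance). Accumulative outcomes use change from
baseline with group, time and group×time fixed effects, and optionally the
participant's number of microdose guesses as a covariate. The 2×2 strata
formed by condition and guess are compared four ways per scale (two at
fixed guess, two at fixed condition), which is what lets a "significant
drug effect" be re-attributed to blind-breaking plus expectancy when that
is what the data support.

Blinding integrity is judged against a probability-matching random
guesser: a participant who knows only the kit's microdose base rate
`p = 1/4` and announces "microdose" with probability `p` achieves accuracy
`p² + (1−p)² = 0.625`, sensitivity 0.25, and specificity 0.75. Observed
per-participant accuracy is regressed on LSD-equivalent dose, and the
detection threshold is the smallest dose at which the fitted line's lower
95% confidence bound clears that baseline.

## Worked example

```python
from selfblind.design import TrialDesign, build_kit, draw_envelopes, \
    capsule_composition, microdose_count
from selfblind.blinding import random_guesser_baseline, summarize_blinding
from selfblind.cohort import GenerativeParams, simulate_cohort
from selfblind.pipeline import acute_table
from selfblind.inference import fit_acute

design = TrialDesign()
kit, book = build_kit(design, seed=1)
n_pl, n_md, p = capsule_composition(kit)          # 24, 8, 0.25
schedule = draw_envelopes(kit, book, design, seed=2)
accuracy, sens, spec = random_guesser_baseline(p)  # 0.625, 0.25, 0.75

cohort = simulate_cohort(GenerativeParams(n_start=240, seed=1))
day = cohort.guesses[cohort.guesses["level"] == "capsule_day"]
summary = summarize_blinding(day)

table = acute_table(cohort, "vas_mood", "acute")
plain = fit_acute(table, "vas_mood")
adjusted = fit_acute(table, "vas_mood", include_guess=True)
```

Printed results:

```
kit: 24 placebo / 8 microdose capsules (base rate 0.25)
drawn group: PL, total microdoses: 0
random guesser: accuracy 0.625, sensitivity 0.25, specificity 0.75
break-blind rate 0.72 ± 0.17 (sensitivity 0.43, specificity 0.81)
mood VAS, PL vs MD:            +2.04 (p=0.0260)
mood VAS, guess-adjusted:      +0.65 (p=0.499)
mood VAS, guess PL vs MD:      +4.56 (p=6.1e-07)
```

Reading: participants guess their capsules well above the 0.625 random
baseline (0.72), driven by good placebo identification. A naive
condition-only model finds a "significant" mood benefit of microdosing
(+2.04 points, p = 0.03) — but this cohort was generated with **zero**
true mood effect. Once guess enters the model the condition contrast
collapses (+0.65, p = 0.50) while the guess contrast is large and highly
significant: the apparent drug effect was expectancy riding on broken
blinds, which is exactly the artifact this design exists to expose.

The same pipeline from the shell:

```bash
selfblind run-all --seed 1 --out runs/demo
selfblind blinding --data runs/demo --out runs/demo/blinding.json
```

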