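import numpy as np
import pandas as pd
import pytest

from selfblind.cohort import GenerativeParams, GuessModel, simulate_cohort
from selfblind.design import TrialDesign, build_kit


@pytest.fixture(scope="session")
def design():
    return TrialDesign()


@pytest.fixture(scope="session")
def kit(design):
    return build_kit(design, seed=123)


@pytest.fixture(scope="session")
def small_cohort():
    """A 60-starter cohort with default (expectancy-dominated) effects."""
    return simulate_cohort(GenerativeParams(n_start=60, seed=42))


@pytest.fixture(scope="session")
def completer_cohort():
    """Completers-only cohort at the published guess operating point."""
    params = GenerativeParams(
        n_start=80,
        p_complete=1.0,
        seed=7,
        guess=GuessModel(
            sens_const=0.45, spec=0.82, subject_sd_sens=0.0, subject_sd_spec=0.0
        ),
    )
    return simulate_cohort(params)


def acute_dataset(
    n_subjects,
    beta_cond=0.0,
    beta_guess=0.0,
    subject_sd=5.0,
    resid_sd=4.0,
    mean=50.0,
    sens=0.45,
    spec=0.82,
    seed=0,
    design=None,
):
    """Acute observation table built from the design's own randomization.

    Thursday conditions come from real constrained envelope draws; guesses
    follow the stated per-capsule operating point.  Used for calibration
    and recovery tests where generating every outcome class would be waste.
    """
    from selfblind import design as dz

    design = design or TrialDesign()
    rng = np.random.default_rng(seed)
    rows = []
    thu = design.capsule_days.index(design.acute_day)
    for i in range(n_subjects):
        kit_i, book = dz.build_kit(design, rng)
        sched = dz.draw_envelopes(kit_i, book, design, rng, participant_id=f"s{i}")
        subj = rng.normal(0, subject_sd)
        for w, env in enumerate(sched.drawn_envelopes, start=1):
            cond = env.capsules[thu]
            p_md = sens if cond == "MD" else 1 - spec
            guess = "MD" if rng.random() < p_md else "PL"
            value = (
                mean
                + subj
                + beta_cond * (cond == "MD")
                + beta_guess * (guess == "MD")
                + rng.normal(0, resid_sd)
            )
            rows.append(
                {
                    "participant_id": f"s{i}",
                    "timepoint": f"week{w}",
                    "value": value,
                    "condition": cond,
                    "guess": guess,
                }
            )
    return pd.DataFrame(rows)


def accumulative_dataset(
    n_subjects,
    gamma_time=0.0,
    gamma_expect=0.0,
    gamma_drug=0.0,
    subject_sd=3.0,
    resid_sd=4.0,
    sens=0.45,
    spec=0.82,
    seed=0,
    design=None,
):
    """Change-from-baseline table (week5/week9) from real group draws."""
    from selfblind import design as dz

    design = design or TrialDesign()
    rng = np.random.default_rng(seed)
    rows = []
    for i in range(n_subjects):
        kit_i, book = dz.build_kit(design, rng)
        sched = dz.draw_envelopes(kit_i, book, design, rng, participant_id=f"s{i}")
        n_md = dz.microdose_count(sched)
        p_md_caps = [
            sens if v == "MD" else 1 - spec for v in sched.per_day_truth.values()
        ]
        n_md_guesses = int(np.sum(rng.random(len(p_md_caps)) < p_md_caps))
        subj = rng.normal(0, subject_sd)
        drift = gamma_time + gamma_expect * n_md_guesses + gamma_drug * n_md
        for tp in ("week5", "week9"):
            rows.append(
                {
                    "participant_id": f"s{i}",
                    "group": sched.group,
                    "timepoint": tp,
                    "change": drift + subj + rng.normal(0, resid_sd),
                    "n_md_guesses": n_md_guesses,
                    "n_microdoses": n_md,
                }
            )
    return pd.DataFrame(rows)
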