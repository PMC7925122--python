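"""Synthetic trial cohorts with separable drug and expectancy effects.

The generator emulates a 10-week self-blinded microdosing protocol: each
participant builds an envelope kit, draws a constrained-random schedule
(PL/HH/MD group with probability 1/3 each), takes capsules on four days per
week for four weeks, records forced binary capsule-day and week-level
guesses, and completes acute (Thursday), post-acute (Sunday) and
accumulative (baseline / week 5 / week 9) outcome batteries.  Dropout
thins the cohort from starters to completers to follow-up.

Two effect channels are planted independently per scale:

* a *true drug* effect (``beta_cond`` / ``gamma_drug``) tied to the capsule
  actually taken, and
* an *expectancy* effect (``beta_guess`` / ``gamma_expect``) tied to the
  participant's belief about the capsule.

With default parameters self-report scales carry expectancy but no drug
effect (drug-intensity being the exception) and cognitive tasks carry
neither, so the downstream analyses should attribute apparent benefits to
guesses rather than to capsule content.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Callable, Mapping

import numpy as np
import pandas as pd

from . import design as dz
from .design import MD, PL, TrialDesign
from .scales import COGNITIVE_TASKS, get_scale, load_registry, mushroom_to_lsd_equiv


class ParamsError(ValueError):
    """Raised for invalid generative parameters."""


@dataclass(frozen=True)
class GuessModel:
    """Per-capsule guess behavior.

    Sensitivity (P(guess MD | truth MD)) follows a logistic psychometric
    function of the LSD-equivalent dose unless overridden by ``sens_const``
    (dose-independent) or ``sens_fn`` (arbitrary monotone callable).
    Specificity (P(guess PL | truth PL)) is dose-independent.  Both get
    participant-level Gaussian jitter, clipped to [0, 1], so that the
    between-participant spread of guess accuracy resembles observed data.

    Defaults: specificity 0.82 and a psychometric midpoint/slope calibrated
    so that mean sensitivity is ≈0.45 under the default dose distribution.
    """

    spec: float = 0.82
    sens_d50: float = 13.7  # µg at which sensitivity = 0.5
    sens_slope: float = 0.15  # logistic slope per µg
    sens_max: float = 1.0
    sens_const: float | None = None
    sens_fn: Callable[[np.ndarray], np.ndarray] | None = None
    subject_sd_sens: float = 0.15
    subject_sd_spec: float = 0.10

    def sensitivity(self, dose) -> np.ndarray:
        dose = np.asarray(dose, dtype=float)
        if np.any(dose < 0):
            raise ParamsError("dose must be non-negative")
        if self.sens_fn is not None:
            return np.clip(np.asarray(self.sens_fn(dose), dtype=float), 0.0, 1.0)
        if self.sens_const is not None:
            return np.full_like(dose, self.sens_const)
        return self.sens_max / (1.0 + np.exp(-self.sens_slope * (dose - self.sens_d50)))


@dataclass(frozen=True)
class ScaleEffects:
    """Generative parameters for one self-report scale (score units)."""

    mean: float
    subject_sd: float
    resid_sd: float
    beta_cond: float = 0.0  # acute/post-acute shift when the capsule/week is MD
    beta_guess: float = 0.0  # acute/post-acute shift when the guess is MD
    gamma_time: float = 0.0  # secular change baseline -> week 5 (and week 9)
    gamma_expect: float = 0.0  # accumulative change per MD guess
    gamma_drug: float = 0.0  # accumulative change per microdose taken


@dataclass(frozen=True)
class TaskEffects:
    """Generative parameters for one cognitive task (raw task units)."""

    mean: float
    subject_sd: float
    resid_sd: float
    learning: tuple[float, ...]  # additive session offsets, session 0 first
    beta_cond: float = 0.0


def default_scale_effects() -> dict[str, ScaleEffects]:
    """Study-condition defaults: expectancy on self-report scales, a true
    drug effect only on acute drug intensity, null cognitive effects, and
    secular improvement on the accumulative well-being scales."""
    return {
        # acute (Thursday) self-report
        "panas": ScaleEffects(14.0, 6.0, 4.0, beta_guess=2.5),
        "vas_intensity": ScaleEffects(8.5, 8.0, 9.0, beta_cond=3.4, beta_guess=12.0),
        "vas_mood": ScaleEffects(60.5, 13.0, 9.0, beta_guess=5.0),
        "vas_energy": ScaleEffects(55.3, 13.0, 9.0, beta_guess=5.3),
        "vas_creativity": ScaleEffects(53.5, 13.0, 9.0, beta_guess=4.7),
        "vas_focus": ScaleEffects(57.3, 13.0, 9.0, beta_guess=1.5),
        "vas_temper": ScaleEffects(36.5, 15.0, 10.0, beta_guess=0.0),
        # post-acute (Sunday) self-report
        "wemwbs": ScaleEffects(50.0, 7.0, 3.0, beta_guess=1.0),
        "qids": ScaleEffects(5.5, 3.0, 1.8, beta_guess=-0.5),
        "stait": ScaleEffects(38.0, 8.0, 3.5, beta_guess=-1.5),
        "scs": ScaleEffects(80.0, 12.0, 4.0, beta_guess=1.5),
        # accumulative (baseline / week 5 / week 9)
        "rpwb": ScaleEffects(
            160.0, 25.0, 7.0, gamma_time=2.0, gamma_expect=0.35
        ),
        "cams": ScaleEffects(30.0, 5.0, 2.0, gamma_time=1.4, gamma_expect=0.10),
        "swl": ScaleEffects(23.0, 5.5, 1.8, gamma_time=0.6, gamma_expect=0.08),
        "gpts": ScaleEffects(45.0, 11.0, 3.0, gamma_time=-3.8, gamma_expect=-0.15),
        "b5_neuroticism": ScaleEffects(28.0, 6.0, 1.6, gamma_time=-1.0),
        "b5_extraversion": ScaleEffects(31.0, 6.0, 1.5),
        "b5_openness": ScaleEffects(38.0, 5.0, 1.5, gamma_time=0.6),
        "b5_agreeableness": ScaleEffects(36.0, 5.0, 1.4),
        "b5_conscientiousness": ScaleEffects(34.0, 6.0, 1.5),
    }


def default_task_effects() -> dict[str, TaskEffects]:
    # learning offsets: concave gains over the seven sessions
    def learn(sd):
        return tuple(sd * g for g in (0.0, 0.25, 0.35, 0.42, 0.47, 0.50, 0.52))

    specs = {
        "spatial_span": (6.5, 1.2),
        "paired_associates": (5.5, 1.5),
        "rotations": (80.0, 25.0),
        "odd_one_out": (14.0, 3.0),
        "spatial_planning": (35.0, 8.0),
        "feature_match": (110.0, 25.0),
    }
    return {
        t: TaskEffects(mean=m, subject_sd=0.6 * s, resid_sd=0.7 * s, learning=learn(s))
        for t, (m, s) in specs.items()
    }


@dataclass(frozen=True)
class GenerativeParams:
    """Full description of one synthetic study.

    Cohort-level defaults mirror the published study: 240 starters with
    191/240 completing and 159/191 returning for follow-up; 75% LSD or LSD
    analogue users at 13 ± 5.5 µg, 24% mushroom users at 0.2 ± 0.12 g
    (converted at 46 µg/g), 1% other substances treated like LSD doses.
    """

    n_start: int = 240
    p_complete: float = 191 / 240
    p_followup: float = 159 / 191
    substance_mix: Mapping[str, float] = field(
        default_factory=lambda: {"lsd": 0.75, "mushroom": 0.24, "other": 0.01}
    )
    lsd_dose_mean: float = 13.0
    lsd_dose_sd: float = 5.5
    mushroom_mass_mean: float = 0.2
    mushroom_mass_sd: float = 0.12
    guess: GuessModel = field(default_factory=GuessModel)
    scale_effects: Mapping[str, ScaleEffects] = field(
        default_factory=default_scale_effects
    )
    task_effects: Mapping[str, TaskEffects] = field(default_factory=default_task_effects)
    clip_scores: bool = True
    seed: int = 0

    def validate(self) -> None:
        if self.n_start < 1:
            raise ParamsError("n_start must be positive")
        for p in (self.p_complete, self.p_followup):
            if not 0.0 <= p <= 1.0:
                raise ParamsError("dropout probabilities must be in [0, 1]")
        if not np.isclose(sum(self.substance_mix.values()), 1.0):
            raise ParamsError("substance_mix must sum to 1")
        for sid, eff in self.scale_effects.items():
            if eff.subject_sd < 0 or eff.resid_sd < 0:
                raise ParamsError(f"{sid}: SDs must be non-negative")

    def null_effects(self) -> "GenerativeParams":
        """Copy with every planted effect set to zero (type-I calibration)."""
        zeroed = {
            sid: replace(
                eff, beta_cond=0.0, beta_guess=0.0, gamma_time=0.0,
                gamma_expect=0.0, gamma_drug=0.0,
            )
            for sid, eff in self.scale_effects.items()
        }
        tasks = {t: replace(e, beta_cond=0.0) for t, e in self.task_effects.items()}
        return replace(self, scale_effects=zeroed, task_effects=tasks)


@dataclass
class Cohort:
    """Bundle of long-format tables produced by :func:`simulate_cohort`."""

    participants: pd.DataFrame
    schedules: pd.DataFrame
    guesses: pd.DataFrame
    scores: pd.DataFrame
    params: GenerativeParams
    design: TrialDesign

    def task_scores(self) -> pd.DataFrame:
        """Cognitive task rows in the shape :func:`selfblind.scales.compute_cps` expects."""
        t = self.scores[self.scores["outcome_class"] == "cognitive_task"].copy()
        t = t.rename(columns={"scale_id": "task"})
        return t[["participant_id", "session", "task", "value", "condition"]]

    def to_csv(self, outdir) -> dict[str, str]:
        from pathlib import Path

        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        paths = {}
        for name in ("participants", "schedules", "guesses", "scores"):
            path = outdir / f"{name}.csv"
            getattr(self, name).to_csv(path, index=False)
            paths[name] = str(path)
        return paths


# ---------------------------------------------------------------------------
# elementary generators (single-observation forms used by tests and docs)


def simulate_guess(truth: str, dose: float, params: GenerativeParams, seed) -> str:
    """One forced binary capsule guess given the capsule truth and dose."""
    rng = dz._as_rng(seed)
    if truth == MD:
        p_md = float(params.guess.sensitivity(dose))
    else:
        p_md = 1.0 - params.guess.spec
    return MD if rng.random() < p_md else PL


def simulate_acute_score(
    scale_id: str,
    condition: str,
    guess: str,
    params: GenerativeParams,
    seed,
    subject_intercept: float = 0.0,
) -> float:
    """One acute/post-acute observation: mean + intercept + effects + noise."""
    eff = params.scale_effects.get(scale_id)
    if eff is None:
        raise KeyError(f"scale {scale_id!r} has no generative parameters")
    rng = dz._as_rng(seed)
    value = (
        eff.mean
        + subject_intercept
        + eff.beta_cond * (condition == MD)
        + eff.beta_guess * (guess == MD)
        + rng.normal(0.0, eff.resid_sd)
    )
    return float(value)


def simulate_accumulative_change(
    scale_id: str,
    n_md_guesses: int,
    n_microdoses: int,
    params: GenerativeParams,
    seed,
) -> float:
    """Change from baseline for one participant and accumulative scale."""
    eff = params.scale_effects.get(scale_id)
    if eff is None:
        raise KeyError(f"scale {scale_id!r} has no generative parameters")
    if n_md_guesses is None:
        raise ValueError("guess records are required for accumulative change")
    rng = dz._as_rng(seed)
    return float(
        eff.gamma_time
        + eff.gamma_expect * n_md_guesses
        + eff.gamma_drug * n_microdoses
        + rng.normal(0.0, eff.resid_sd)
    )


# ---------------------------------------------------------------------------
# full cohort


def _draw_doses(params: GenerativeParams, rng, n: int):
    subs = list(params.substance_mix)
    probs = np.array([params.substance_mix[s] for s in subs])
    substance = np.array(subs)[rng.choice(len(subs), size=n, p=probs)]
    reported = np.where(
        substance == "mushroom",
        np.clip(
            rng.normal(params.mushroom_mass_mean, params.mushroom_mass_sd, n), 0.02, None
        ),
        np.clip(rng.normal(params.lsd_dose_mean, params.lsd_dose_sd, n), 1.0, None),
    )
    lsd_equiv = np.where(
        substance == "mushroom", mushroom_to_lsd_equiv(reported), reported
    )
    return substance, reported, lsd_equiv


def _covariates(rng, n: int) -> pd.DataFrame:
    """Demographic covariates (age 33.5 ± 9.4, ~70% male); no planted effect."""
    return pd.DataFrame(
        {
            "age": np.round(np.clip(rng.normal(33.5, 9.4, n), 18, None), 1),
            "sex": (rng.random(n) < 0.70).astype(int),  # 1 = male
            "education": np.round(np.clip(rng.normal(16, 3, n), 8, 24)),
            "suggestibility": np.round(np.clip(rng.normal(50, 10, n), 0, 100), 1),
            "expectation": np.round(np.clip(rng.normal(70, 15, n), 0, 100), 1),
            "n_past_diagnoses": rng.poisson(0.5, n),
            "n_current_medications": rng.poisson(0.15, n),
            "lifetime_macrodoses": np.round(rng.exponential(15, n)),
            "months_microdosing": np.round(rng.exponential(6, n)),
        }
    )


def simulate_cohort(
    params: GenerativeParams, design: TrialDesign | None = None
) -> Cohort:
    """Generate a complete synthetic trial dataset.

    All randomness derives from ``params.seed``.  Starters contribute
    baseline records; completers additionally contribute the full dose
    period (schedules, guesses, acute/post-acute scores, week-5
    accumulative scores); follow-up returners contribute week-9 records.
    """
    params.validate()
    design = design or TrialDesign()
    design.validate()
    rng = np.random.default_rng(params.seed)
    registry = load_registry()
    n = params.n_start
    pid = np.array([f"p{i:04d}" for i in range(n)])

    substance, reported, lsd_equiv = _draw_doses(params, rng, n)
    cov = _covariates(rng, n)

    completed = rng.random(n) < params.p_complete
    followup = completed & (rng.random(n) < params.p_followup)
    stage = np.where(followup, "follow_up", np.where(completed, "completed", "started"))

    # ---- randomization: one kit + one constrained draw per participant
    schedules = []
    groups = np.empty(n, dtype=object)
    n_md = np.zeros(n, dtype=int)
    sched_objs = []
    for i in range(n):
        kit, book = dz.build_kit(design, rng)
        sched = dz.draw_envelopes(kit, book, design, rng, participant_id=pid[i])
        sched_objs.append(sched)
        groups[i] = sched.group
        n_md[i] = dz.microdose_count(sched)
        frame = dz.schedule_frame(sched, design)
        frame["envelope_code"] = np.repeat(
            [e.code for e in sched.drawn_envelopes], design.capsules_per_week
        )
        schedules.append(frame)
    schedules = pd.concat(schedules, ignore_index=True)

    # ---- per-participant guess operating points
    gm = params.guess
    sens_i = np.clip(
        gm.sensitivity(lsd_equiv) + rng.normal(0, gm.subject_sd_sens, n), 0, 1
    )
    spec_i = np.clip(gm.spec + rng.normal(0, gm.subject_sd_spec, n), 0, 1)

    # ---- capsule-day and week-level guesses (completers only)
    guess_rows = []
    n_md_guess = np.full(n, np.nan)
    acute_cond = {}
    acute_guess = {}
    week_cond = {}
    week_guess = {}
    for i in range(n):
        if not completed[i]:
            continue
        sched = sched_objs[i]
        md_guessed = 0
        wk_cond = []
        wk_guess = []
        ac_cond = []
        ac_guess = []
        for w in range(1, design.n_dose_weeks + 1):
            p_announce = []
            for d in design.capsule_days:
                truth = sched.per_day_truth[(w, d)]
                p_md = sens_i[i] if truth == MD else 1.0 - spec_i[i]
                p_announce.append(p_md)
                g = MD if rng.random() < p_md else PL
                md_guessed += g == MD
                guess_rows.append(
                    {
                        "participant_id": pid[i],
                        "level": "capsule_day",
                        "week": w,
                        "day": d,
                        "truth": truth,
                        "guess": g,
                    }
                )
                if d == design.acute_day:
                    ac_cond.append(truth)
                    ac_guess.append(g)
            # week-level guess: latent discriminability applied to the
            # week's capsule composition
            wt = sched.drawn_envelopes[w - 1].week_type
            gw = MD if rng.random() < float(np.mean(p_announce)) else PL
            guess_rows.append(
                {
                    "participant_id": pid[i],
                    "level": "week",
                    "week": w,
                    "day": "",
                    "truth": wt,
                    "guess": gw,
                }
            )
            wk_cond.append(wt)
            wk_guess.append(gw)
        n_md_guess[i] = md_guessed
        acute_cond[i], acute_guess[i] = ac_cond, ac_guess
        week_cond[i], week_guess[i] = wk_cond, wk_guess
    guesses = pd.DataFrame(
        guess_rows,
        columns=["participant_id", "level", "week", "day", "truth", "guess"],
    )

    participants = pd.DataFrame(
        {
            "participant_id": pid,
            "group": groups,
            "substance": substance,
            "reported_dose": np.round(reported, 3),
            "dose": np.round(lsd_equiv, 2),  # LSD-equivalent µg
            "n_microdoses": n_md,
            "total_dose": np.round(n_md * lsd_equiv, 2),
            "n_md_guesses": n_md_guess,
            "stage": stage,
        }
    ).join(cov)

    # ---- scores
    score_rows: list[pd.DataFrame] = []
    comp_idx = np.flatnonzero(completed)
    fup_idx = np.flatnonzero(followup)
    weeks = np.arange(1, design.n_dose_weeks + 1)

    def clip(values, sid):
        if not params.clip_scores:
            return values
        desc = get_scale(sid, registry)
        return np.clip(values, desc.n_items * desc.item_min, desc.n_items * desc.item_max)

    def long(sid, oclass, ids, timepoints, values, cond=None, gss=None, session=None):
        frame = pd.DataFrame(
            {
                "participant_id": ids,
                "scale_id": sid,
                "outcome_class": oclass,
                "timepoint": timepoints,
                "session": session if session is not None else np.nan,
                "value": values,
                "condition": cond if cond is not None else "",
                "guess": gss if gss is not None else "",
            }
        )
        score_rows.append(frame)

    for oclass, cond_map, guess_map in (
        ("acute", acute_cond, acute_guess),
        ("post_acute", week_cond, week_guess),
    ):
        sids = registry.loc[registry["outcome_class"] == oclass, "scale_id"]
        for sid in sids:
            eff = params.scale_effects[sid]
            subj = rng.normal(0, eff.subject_sd, n)
            for i in comp_idx:
                conds = np.array(cond_map[i])
                gs = np.array(guess_map[i])
                vals = (
                    eff.mean
                    + subj[i]
                    + eff.beta_cond * (conds == MD)
                    + eff.beta_guess * (gs == MD)
                    + rng.normal(0, eff.resid_sd, len(weeks))
                )
                long(
                    sid,
                    oclass,
                    np.repeat(pid[i], len(weeks)),
                    [f"week{w}" for w in weeks],
                    clip(vals, sid),
                    conds,
                    gs,
                )

    for sid in registry.loc[registry["outcome_class"] == "accumulative", "scale_id"]:
        eff = params.scale_effects[sid]
        subj = rng.normal(0, eff.subject_sd, n)
        base = eff.mean + subj + rng.normal(0, eff.resid_sd, n)
        long(sid, "accumulative", pid, "baseline", clip(base, sid))
        drift = eff.gamma_expect * np.nan_to_num(n_md_guess) + eff.gamma_drug * n_md
        wk5 = base + eff.gamma_time + drift + rng.normal(0, eff.resid_sd, n)
        long(sid, "accumulative", pid[comp_idx], "week5", clip(wk5[comp_idx], sid))
        wk9 = base + eff.gamma_time + drift + rng.normal(0, eff.resid_sd, n)
        long(sid, "accumulative", pid[fup_idx], "week9", clip(wk9[fup_idx], sid))

    # ---- cognition: sessions 0 (baseline), 1-4 (acute Thursdays), 5, 6
    session_tp = {0: "baseline", 5: "week5", 6: "week9"}
    for task, te in params.task_effects.items():
        subj = rng.normal(0, te.subject_sd, n)

        def task_rows(sess, idx, conds):
            vals = (
                te.mean
                + subj[idx]
                + te.learning[sess]
                + te.beta_cond * (np.asarray(conds) == MD)
                + rng.normal(0, te.resid_sd, len(idx))
            )
            tp = session_tp.get(sess, f"week{sess}")
            long(
                task,
                "cognitive_task",
                pid[idx],
                tp,
                vals,
                cond=conds,
                session=sess,
            )

        task_rows(0, np.arange(n), np.repeat("baseline", n))
        for w in weeks:
            conds = [acute_cond[i][w - 1] for i in comp_idx]
            task_rows(int(w), comp_idx, conds)
        task_rows(5, comp_idx, np.repeat(PL, len(comp_idx)))
        task_rows(6, fup_idx, np.repeat(PL, len(fup_idx)))

    scores = pd.concat(score_rows, ignore_index=True)
    return Cohort(
        participants=participants,
        schedules=schedules,
        guesses=guesses,
        scores=scores,
        params=params,
        design=design,
    )
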