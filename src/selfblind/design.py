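"""Envelope-based self-blinding randomization.

A self-experimenter prepares opaque capsules (active microdoses and empty
placebos), packs them into weekly envelopes together with an opaque numeric
code, and then draws envelopes through a constrained semi-random process.
The draw admits only three weekly compositions of the four-week dose period
— all placebo (PL), half-half (HH), or all microdose (MD) — each with equal
probability.  The code book that maps the numeric codes back to week types
is held by the experimenter only, so the participant remains blind while
the analyst can later recover which capsule was taken when.

All stochastic operations take an explicit integer seed or a
``numpy.random.Generator``; there is no hidden global state.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

PL = "PL"
MD = "MD"
HH = "HH"

#: canonical group labels in ascending order of microdose exposure
GROUPS = (PL, HH, MD)


class DesignError(ValueError):
    """Raised when a trial design or envelope kit violates its invariants."""


def _as_rng(seed) -> np.random.Generator:
    if isinstance(seed, np.random.Generator):
        return seed
    return np.random.default_rng(seed)


@dataclass(frozen=True)
class TrialDesign:
    """Combinatorial description of the dose period.

    Defaults encode the published protocol: a 4-week dose period with
    capsules on Monday, Tuesday, Thursday and Friday (none on Wednesday or
    the weekend), two microdoses per microdose week, four envelopes of each
    type, and groups PL/HH/MD holding 0/2/4 microdose weeks with equal
    probability.  Acute assessments fall on the Thursday capsule day;
    post-acute assessments on the capsule-free Sunday.
    """

    n_dose_weeks: int = 4
    capsule_days: tuple[str, ...] = ("Mon", "Tue", "Thu", "Fri")
    md_per_md_week: int = 2
    n_envelopes_per_type: int = 4
    group_combos: Mapping[str, int] = field(
        default_factory=lambda: {PL: 0, HH: 2, MD: 4}
    )
    group_probs: Mapping[str, float] = field(
        default_factory=lambda: {PL: 1 / 3, HH: 1 / 3, MD: 1 / 3}
    )
    acute_day: str = "Thu"
    postacute_day: str = "Sun"

    def validate(self) -> None:
        if self.md_per_md_week > len(self.capsule_days):
            raise DesignError("md_per_md_week exceeds the number of capsule days")
        if self.md_per_md_week < 0 or self.n_dose_weeks < 1:
            raise DesignError("counts must be non-negative and weeks >= 1")
        if self.acute_day not in self.capsule_days:
            raise DesignError("acute_day must be a capsule day")
        if self.postacute_day in self.capsule_days:
            raise DesignError("postacute_day must be capsule-free")
        if set(self.group_combos) != set(self.group_probs):
            raise DesignError("group_combos and group_probs must share labels")
        if not np.isclose(sum(self.group_probs.values()), 1.0):
            raise DesignError("group probabilities must sum to 1")
        for g, k in self.group_combos.items():
            if k > self.n_dose_weeks or k > self.n_envelopes_per_type:
                raise DesignError(
                    f"group {g!r} needs {k} MD weeks but the design cannot supply them"
                )

    @property
    def capsules_per_week(self) -> int:
        return len(self.capsule_days)


@dataclass(frozen=True)
class Envelope:
    """One week's worth of capsules plus an opaque code.

    ``capsules`` is ordered to match ``TrialDesign.capsule_days``.  The
    ``week_type`` field exists for kit construction and experimenter-side
    bookkeeping; participant-facing serializations expose only the code.
    """

    envelope_id: str
    week_type: str
    capsules: tuple[str, ...]
    code: str


@dataclass(frozen=True)
class CodeBook:
    """Experimenter-only mapping from envelope code to week type."""

    codes: Mapping[str, str]

    def decode(self, token: str) -> str:
        try:
            return self.codes[token]
        except KeyError:
            raise KeyError(f"code {token!r} was not issued by this kit") from None


@dataclass(frozen=True)
class DoseSchedule:
    """A participant's drawn dose period.

    ``per_day_truth`` maps (week index, capsule day) to the capsule type
    actually taken.  Unselected envelopes are retained (``discarded``) so
    the end-of-study "open the leftover envelopes" check can be simulated.
    """

    participant_id: str
    group: str
    drawn_envelopes: tuple[Envelope, ...]
    discarded_envelopes: tuple[Envelope, ...]
    per_day_truth: Mapping[tuple[int, str], str]


def build_kit(design: TrialDesign, seed) -> tuple[list[Envelope], CodeBook]:
    """Prepare the envelope kit: half MD, half PL envelopes with unique codes.

    Within each MD envelope the ``md_per_md_week`` microdose capsules are
    placed uniformly at random among the capsule days, so the acute-day
    capsule is a microdose with probability md_per_md_week/len(capsule_days)
    in an MD week.
    """
    design.validate()
    rng = _as_rng(seed)
    n_total = 2 * design.n_envelopes_per_type
    code_ints = rng.choice(10**6, size=n_total, replace=False)
    codes = [f"{c:06d}" for c in code_ints]
    envelopes: list[Envelope] = []
    for i in range(n_total):
        week_type = MD if i < design.n_envelopes_per_type else PL
        capsules = [PL] * design.capsules_per_week
        if week_type == MD:
            pos = rng.choice(
                design.capsules_per_week, size=design.md_per_md_week, replace=False
            )
            for p in pos:
                capsules[p] = MD
        envelopes.append(
            Envelope(
                envelope_id=f"env{i:02d}",
                week_type=week_type,
                capsules=tuple(capsules),
                code=codes[i],
            )
        )
    rng.shuffle(envelopes)
    book = CodeBook(codes={e.code: e.week_type for e in envelopes})
    return envelopes, book


def decode(codebook: CodeBook, token: str) -> str:
    """Look up an envelope code; raises ``KeyError`` for unknown tokens."""
    return codebook.decode(token)


def draw_envelopes(
    envelopes: Sequence[Envelope],
    codebook: CodeBook,
    design: TrialDesign,
    seed,
    participant_id: str = "p0",
) -> DoseSchedule:
    """Constrained semi-random draw of one dose period.

    The group label is sampled with ``design.group_probs``; the drawn
    envelopes are then a uniformly random arrangement consistent with that
    group's number of microdose weeks.  Only the admissible weekly
    compositions (0/2/4 MD weeks under defaults) can result.
    """
    design.validate()
    if len(envelopes) != 2 * design.n_envelopes_per_type:
        raise DesignError(
            f"kit has {len(envelopes)} envelopes, expected "
            f"{2 * design.n_envelopes_per_type}"
        )
    for e in envelopes:
        if e.code not in codebook.codes:
            raise DesignError(f"envelope code {e.code} missing from the code book")
    rng = _as_rng(seed)
    labels = list(design.group_probs)
    probs = np.array([design.group_probs[g] for g in labels])
    group = labels[rng.choice(len(labels), p=probs)]
    n_md_weeks = design.group_combos[group]

    md_pool = [e for e in envelopes if e.week_type == MD]
    pl_pool = [e for e in envelopes if e.week_type == PL]
    chosen = [md_pool[i] for i in rng.permutation(len(md_pool))[:n_md_weeks]]
    chosen += [
        pl_pool[i]
        for i in rng.permutation(len(pl_pool))[: design.n_dose_weeks - n_md_weeks]
    ]
    order = rng.permutation(len(chosen))
    drawn = tuple(chosen[i] for i in order)
    drawn_codes = {e.code for e in drawn}
    discarded = tuple(e for e in envelopes if e.code not in drawn_codes)

    truth = {
        (w + 1, day): env.capsules[j]
        for w, env in enumerate(drawn)
        for j, day in enumerate(design.capsule_days)
    }
    return DoseSchedule(
        participant_id=participant_id,
        group=group,
        drawn_envelopes=drawn,
        discarded_envelopes=discarded,
        per_day_truth=truth,
    )


def microdose_count(schedule: DoseSchedule) -> int:
    """Total number of microdose capsules in the drawn schedule (0/4/8 default)."""
    return sum(1 for v in schedule.per_day_truth.values() if v == MD)


def capsule_composition(envelopes: Sequence[Envelope]) -> tuple[int, int, float]:
    """Counts of PL and MD capsules and the MD base rate over a set of envelopes."""
    if not envelopes:
        raise DesignError("cannot summarize an empty envelope list")
    n_md = sum(c == MD for e in envelopes for c in e.capsules)
    n_pl = sum(c == PL for e in envelopes for c in e.capsules)
    return n_pl, n_md, n_md / (n_pl + n_md)


# ---------------------------------------------------------------------------
# serialization


def participant_view(schedule: DoseSchedule, design: TrialDesign) -> pd.DataFrame:
    """Participant-facing schedule: week slot, day, and code only.

    Deliberately omits week/capsule types — this frame must be invariant
    under permuting week types for the same draw structure.
    """
    rows = [
        {"week": w + 1, "day": day, "code": env.code}
        for w, env in enumerate(schedule.drawn_envelopes)
        for day in design.capsule_days
    ]
    return pd.DataFrame(rows)


def experimenter_view(
    schedule: DoseSchedule, codebook: CodeBook, design: TrialDesign
) -> pd.DataFrame:
    """Decoded schedule: adds week type and per-day capsule type."""
    frame = participant_view(schedule, design)
    frame["week_type"] = [codebook.decode(c) for c in frame["code"]]
    frame["capsule_type"] = [
        schedule.per_day_truth[(w, d)] for w, d in zip(frame["week"], frame["day"])
    ]
    return frame


def schedule_frame(schedule: DoseSchedule, design: TrialDesign) -> pd.DataFrame:
    """Long-format truth table used by the simulator and analysis stages."""
    rows = [
        {
            "participant_id": schedule.participant_id,
            "week": w,
            "day": d,
            "capsule": schedule.per_day_truth[(w, d)],
            "week_type": schedule.drawn_envelopes[w - 1].week_type,
        }
        for (w, d) in sorted(
            schedule.per_day_truth, key=lambda k: (k[0], design.capsule_days.index(k[1]))
        )
    ]
    return pd.DataFrame(rows)
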