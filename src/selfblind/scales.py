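"""Outcome-scale registry, dose conversion, cognitive composite, and deltas.

The registry ships as a CSV (``data/scales.csv``) with one row per
self-report scale: item count, per-item score range, direction, and the
outcome class it belongs to (acute, post-acute, or accumulative).  Users
may load their own registry with the same columns.

The cognitive composite (CPS) averages per-task z-scores across six online
cognitive tasks after removing session-order (learning) effects.
"""

from __future__ import annotations

from dataclasses import dataclass
from importlib import resources

import numpy as np
import pandas as pd

#: µg LSD considered equivalent to 1 g of dried psilocybin mushroom
LSD_UG_PER_G_MUSHROOM = 46.0

#: the six online cognitive tasks combined into the composite
COGNITIVE_TASKS = (
    "spatial_span",
    "paired_associates",
    "rotations",
    "odd_one_out",
    "spatial_planning",
    "feature_match",
)

#: minimum number of available task z-scores for a defined composite
MIN_TASKS_FOR_CPS = 4


@dataclass(frozen=True)
class ScaleDescriptor:
    scale_id: str
    name: str
    n_items: int
    item_min: float
    item_max: float
    direction: str
    outcome_class: str

    def __post_init__(self):
        if self.item_min >= self.item_max:
            raise ValueError(f"{self.scale_id}: item_min must be < item_max")


_REGISTRY_CACHE: pd.DataFrame | None = None


def load_registry(path=None) -> pd.DataFrame:
    """Load the scale registry (the packaged default, or a user CSV)."""
    global _REGISTRY_CACHE
    if path is not None:
        return pd.read_csv(path)
    if _REGISTRY_CACHE is None:
        with resources.files("selfblind.data").joinpath("scales.csv").open() as fh:
            _REGISTRY_CACHE = pd.read_csv(fh)
    return _REGISTRY_CACHE.copy()


def get_scale(scale_id: str, registry: pd.DataFrame | None = None) -> ScaleDescriptor:
    reg = load_registry() if registry is None else registry
    rows = reg[reg["scale_id"] == scale_id]
    if rows.empty:
        raise KeyError(f"scale {scale_id!r} is not registered")
    return ScaleDescriptor(**rows.iloc[0].to_dict())


def scales_in_class(outcome_class: str, registry: pd.DataFrame | None = None) -> list[str]:
    reg = load_registry() if registry is None else registry
    return reg.loc[reg["outcome_class"] == outcome_class, "scale_id"].tolist()


def scale_range(scale: ScaleDescriptor) -> tuple[float, float]:
    """Total-score range implied by item count and per-item extremes."""
    return scale.n_items * scale.item_min, scale.n_items * scale.item_max


def mushroom_to_lsd_equiv(mass_g: float) -> float:
    """Convert dried psilocybin mushroom mass (g) to µg LSD-equivalent.

    Linear rule: 0.1 g dried mushroom ≈ 4.6 µg LSD.
    """
    mass = np.asarray(mass_g, dtype=float)
    if np.any(mass < 0):
        raise ValueError("mushroom mass must be non-negative")
    out = mass * LSD_UG_PER_G_MUSHROOM
    return float(out) if np.isscalar(mass_g) else out


def lsd_equivalent(substance: str, reported_dose: float) -> float:
    """LSD-equivalent µg for a reported dose in the substance's native units."""
    if substance == "mushroom":
        return mushroom_to_lsd_equiv(reported_dose)
    if reported_dose < 0:
        raise ValueError("dose must be non-negative")
    return float(reported_dose)


# ---------------------------------------------------------------------------
# cognitive composite


def learning_effects(task_scores: pd.DataFrame) -> pd.DataFrame:
    """Per-task, per-session mean offsets relative to baseline.

    Estimated from sessions not performed under an active microdose
    (``condition != 'MD'``), so the learning curve is uncontaminated by any
    true drug effect.  Returns columns (task, session, offset); the
    baseline session's offset is 0 by construction.
    """
    clean = task_scores[task_scores["condition"] != "MD"]
    base = clean[clean["session"] == 0].groupby("task")["value"].mean()
    eff = (
        clean.groupby(["task", "session"])["value"].mean().rename("mean").reset_index()
    )
    eff["offset"] = eff["mean"] - eff["task"].map(base)
    return eff[["task", "session", "offset"]]


def compute_cps(
    task_scores: pd.DataFrame,
    reference: pd.DataFrame | None = None,
) -> pd.DataFrame:
    """Cognitive performance score per (participant, session).

    ``task_scores`` is long format with columns participant_id, session,
    task, value, condition (condition is 'MD' when the session happened
    under an active microdose, anything else otherwise; baseline is
    session 0).  ``reference`` optionally supplies per-task baseline
    statistics (columns task, mean, sd); by default they are computed from
    the session-0 rows.

    Per task, z = (raw − (baseline mean + session offset)) / baseline SD,
    where the session offset is the learning effect estimated from
    microdose-free sessions.  The composite is the mean of available task
    z-scores; sessions with fewer than ``MIN_TASKS_FOR_CPS`` tasks get NaN.
    """
    if task_scores.empty:
        raise ValueError("no task scores supplied")
    if reference is None:
        base = task_scores[task_scores["session"] == 0]
        reference = (
            base.groupby("task")["value"].agg(["mean", "std"]).reset_index()
        ).rename(columns={"std": "sd"})
    if (reference["sd"] <= 0).any() or reference["sd"].isna().any():
        bad = reference.loc[
            (reference["sd"] <= 0) | reference["sd"].isna(), "task"
        ].tolist()
        raise ValueError(f"zero or undefined baseline SD for tasks {bad}")

    eff = learning_effects(task_scores)
    df = task_scores.merge(eff, on=["task", "session"], how="left")
    df["offset"] = df["offset"].fillna(0.0)
    df = df.merge(reference, on="task", how="left")
    df["z"] = (df["value"] - (df["mean"] + df["offset"])) / df["sd"]

    out = (
        df.groupby(["participant_id", "session"])["z"]
        .agg(cps="mean", n_tasks="count")
        .reset_index()
    )
    out.loc[out["n_tasks"] < MIN_TASKS_FOR_CPS, "cps"] = np.nan
    return out


def change_from_baseline(
    scores: pd.DataFrame,
    scale_id: str,
    timepoint: str,
    baseline: str = "baseline",
) -> tuple[pd.DataFrame, list]:
    """Per-participant change ``value(timepoint) − value(baseline)``.

    Participants lacking either record are excluded, not raised; the second
    return value lists their ids so the exclusion is auditable.
    """
    sub = scores[scores["scale_id"] == scale_id]
    b = sub[sub["timepoint"] == baseline].set_index("participant_id")["value"]
    t = sub[sub["timepoint"] == timepoint].set_index("participant_id")["value"]
    common = b.index.intersection(t.index)
    excluded = sorted(set(b.index).symmetric_difference(t.index))
    delta = (t.loc[common] - b.loc[common]).rename("change").reset_index()
    delta["timepoint"] = timepoint
    return delta, excluded
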