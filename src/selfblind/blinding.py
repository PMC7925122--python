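"""Blinding-integrity statistics.

Break-blind rate is the per-participant proportion of correct forced
binary capsule guesses.  Its natural null is the *probability-matching
random guesser*: a participant who knows only the PL:MD capsule ratio of
the prepared kit (3:1 under defaults) and announces "microdose" with
probability equal to that base rate.  Observed rates are compared against
this baseline, and a psychometric detection threshold is estimated as the
smallest dose at which the fitted dose–accuracy relationship exceeds the
baseline by a pointwise confidence criterion.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
import statsmodels.api as sm

from .design import MD, PL


@dataclass(frozen=True)
class BlindingSummary:
    """Per-participant break-blind rates and their cohort summary."""

    per_participant: pd.DataFrame
    mean_rate: float
    sd_rate: float
    mean_sensitivity: float
    sd_sensitivity: float
    mean_specificity: float
    sd_specificity: float
    n_participants: int
    n_without_md_capsules: int
    n_without_pl_capsules: int


@dataclass(frozen=True)
class DoseDetectionFit:
    """Linear dose→accuracy regression and the implied detection threshold."""

    slope: float
    intercept: float
    f_stat: float
    df_num: int
    df_den: int
    p_value: float
    baseline_accuracy: float
    threshold: float | None
    n: int


def summarize_blinding(guesses: pd.DataFrame) -> BlindingSummary:
    """Summarize capsule-day guesses.

    ``guesses`` needs columns participant_id, truth, guess (capsule-day
    level records only; week-level records must be filtered out first).
    Sensitivity is undefined for participants with no MD capsules (the PL
    group) — they are excluded from the sensitivity mean but counted.
    """
    if guesses.empty:
        raise ValueError("no guess records supplied")
    if "level" in guesses.columns:
        levels = set(guesses["level"])
        if levels - {"capsule_day"}:
            raise ValueError(
                "summarize_blinding expects capsule-day records only; "
                f"found levels {sorted(levels)}"
            )

    def per_participant(g):
        correct = (g["truth"] == g["guess"]).mean()
        md = g[g["truth"] == MD]
        pl = g[g["truth"] == PL]
        return pd.Series(
            {
                "rate": correct,
                "sensitivity": (md["guess"] == MD).mean() if len(md) else np.nan,
                "specificity": (pl["guess"] == PL).mean() if len(pl) else np.nan,
                "n_capsules": len(g),
                "n_md": len(md),
            }
        )

    per = (
        guesses.groupby("participant_id")
        .apply(per_participant, include_groups=False)
        .reset_index()
    )
    return BlindingSummary(
        per_participant=per,
        mean_rate=float(per["rate"].mean()),
        sd_rate=float(per["rate"].std()),
        mean_sensitivity=float(per["sensitivity"].mean()),
        sd_sensitivity=float(per["sensitivity"].std()),
        mean_specificity=float(per["specificity"].mean()),
        sd_specificity=float(per["specificity"].std()),
        n_participants=len(per),
        n_without_md_capsules=int(per["sensitivity"].isna().sum()),
        n_without_pl_capsules=int(per["specificity"].isna().sum()),
    )


def random_guesser_baseline(md_base_rate: float) -> tuple[float, float, float]:
    """Accuracy, sensitivity, and specificity of a probability-matching guesser.

    A guesser who announces MD with probability p = ``md_base_rate`` has
    accuracy p² + (1−p)², sensitivity p and specificity 1−p.  At the
    default kit base rate p = 0.25 this gives (0.625, 0.25, 0.75).
    Sensitivity is undefined (NaN) at p = 0 and specificity at p = 1.
    """
    p = float(md_base_rate)
    if not 0.0 <= p <= 1.0:
        raise ValueError("base rate must be in [0, 1]")
    accuracy = p**2 + (1 - p) ** 2
    sensitivity = p if p > 0 else np.nan
    specificity = 1 - p if p < 1 else np.nan
    return accuracy, sensitivity, specificity


def dose_guess_fit(
    rates,
    doses,
    baseline_accuracy: float = 0.625,
    alpha: float = 0.05,
    max_extrapolation: float = 2.0,
) -> DoseDetectionFit:
    """Regress per-participant break-blind rate on LSD-equivalent dose.

    The detection threshold is the smallest dose at which the pointwise
    lower (1−alpha) confidence bound of the fitted mean accuracy exceeds
    the random-guesser baseline, searched over the observed dose range
    extended by ``max_extrapolation``×; None when the slope is not
    positive or the bound never crosses the baseline.
    """
    rates = np.asarray(rates, dtype=float)
    doses = np.asarray(doses, dtype=float)
    mask = ~(np.isnan(rates) | np.isnan(doses))
    rates, doses = rates[mask], doses[mask]
    if len(np.unique(doses)) < 3:
        raise ValueError("need at least three participants with distinct doses")
    exog = sm.add_constant(doses)
    fit = sm.OLS(rates, exog).fit()
    slope = float(fit.params[1])
    intercept = float(fit.params[0])

    threshold = None
    if slope > 0:
        grid = np.linspace(0.0, max_extrapolation * doses.max(), 2001)
        pred = fit.get_prediction(sm.add_constant(grid))
        lower = pred.conf_int(alpha=alpha)[:, 0]
        above = lower > baseline_accuracy
        if above.any():
            threshold = float(grid[np.argmax(above)])
    return DoseDetectionFit(
        slope=slope,
        intercept=intercept,
        f_stat=float(fit.fvalue),
        df_num=int(fit.df_model),
        df_den=int(fit.df_resid),
        p_value=float(fit.f_pvalue),
        baseline_accuracy=baseline_accuracy,
        threshold=threshold,
        n=len(rates),
    )
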