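"""Model fitting and planned contrasts for the three outcome families.

Three families are supported:

* ``accumulative``: repeated-measures model on change from baseline with
  group, time, and group×time fixed effects and a subject random
  intercept.  The random intercept realizes the equal-correlation
  (compound-symmetry) within-subject covariance the family assumes.
* ``acute`` and ``post_acute``: mixed linear models of score on condition
  (the capsule/week actually taken) with a subject random intercept; a
  guess-augmented variant adds guess and guess×condition terms.

Planned contrasts are computed as linear combinations of the fixed
effects.  Covariates are mean-centered before fitting so that intercept
combinations are adjusted means at covariate means; inference on the
fixed effects uses the large-sample normal approximation.

Also here: one-at-a-time covariate screening, the 2×2 condition×guess
strata comparison table, Cohen's d, and the normal-approximation sample
size for a two-group comparison.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats
import statsmodels.api as sm

from .design import GROUPS, MD, PL

#: candidate baseline covariates screened for the accumulative models
ACCUMULATIVE_COVARIATE_CANDIDATES = (
    "age",
    "sex",
    "education",
    "baseline_score",
    "dose",
    "total_dose",
    "suggestibility",
    "expectation",
    "n_past_diagnoses",
    "n_current_medications",
    "lifetime_macrodoses",
    "months_microdosing",
)

#: acute/post-acute screening excludes baseline score and total dose
ACUTE_COVARIATE_CANDIDATES = tuple(
    c
    for c in ACCUMULATIVE_COVARIATE_CANDIDATES
    if c not in ("baseline_score", "total_dose")
)

#: the four planned condition/guess strata comparisons
STRATA_COMPARISONS = (
    ("PL/PL vs MD/PL", "fixed_guess"),
    ("PL/MD vs MD/MD", "fixed_guess"),
    ("PL/PL vs PL/MD", "fixed_condition"),
    ("MD/PL vs MD/MD", "fixed_condition"),
)


class InsufficientDataError(ValueError):
    """Raised when a model's replication preconditions are not met."""


@dataclass
class ModelResult:
    """Fixed effects, variance components, and planned contrasts of one fit."""

    family: str
    scale_id: str
    params: pd.Series
    conf_int: pd.DataFrame
    pvalues: pd.Series
    contrasts: pd.DataFrame
    n_used: int
    n_subjects: int
    subject_var: float
    resid_var: float
    converged: bool
    covariates: tuple[str, ...] = ()


def _contrast(result, names: list[str], combo: dict[str, float], label: str) -> dict:
    """Evaluate L·β with its normal-approximation CI and p-value."""
    L = np.zeros((1, len(names)))
    for k, v in combo.items():
        L[0, names.index(k)] = v
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", RuntimeWarning)
        tt = result.t_test(L)
    lo, hi = np.asarray(tt.conf_int()).ravel()
    return {
        "label": label,
        "estimate": float(np.ravel(tt.effect)[0]),
        "se": float(np.ravel(tt.sd)[0]),
        "ci_low": float(lo),
        "ci_high": float(hi),
        "p": float(np.ravel(tt.pvalue)[0]),
    }


def _center(data: pd.DataFrame, covariates) -> pd.DataFrame:
    data = data.copy()
    for c in covariates:
        if c not in data.columns:
            raise KeyError(f"covariate column {c!r} missing")
        data[c] = data[c] - data[c].mean()
    return data


def _fit_mixed(endog, exog, groups):
    model = sm.MixedLM(endog, exog, groups=groups)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        result = model.fit(reml=True)
    return result


def fit_acute(
    data: pd.DataFrame,
    scale_id: str = "",
    include_guess: bool = False,
    covariates=(),
    family: str = "acute",
) -> ModelResult:
    """Mixed model of score on condition with a subject random intercept.

    ``data`` needs columns participant_id, value, condition, and (when
    ``include_guess``) guess.  The planned PL-vs-MD contrast in the
    guess-augmented model is the condition effect averaged with equal
    weight over the two guess strata (LSMEANS-style).
    """
    data = data.dropna(subset=["value"])
    conditions = set(data["condition"])
    if conditions <= {PL} or conditions <= {MD}:
        raise InsufficientDataError(
            "condition contrast undefined: all observations share one condition"
        )
    data = _center(data, covariates)
    exog = pd.DataFrame(index=data.index)
    exog["Intercept"] = 1.0
    exog["cond"] = (data["condition"] == MD).astype(float)
    if include_guess:
        exog["gss"] = (data["guess"] == MD).astype(float)
        exog["cxg"] = exog["cond"] * exog["gss"]
    for c in covariates:
        exog[c] = data[c].astype(float)
    result = _fit_mixed(data["value"].to_numpy(), exog, data["participant_id"])
    names = list(exog.columns)

    rows = []
    if include_guess:
        rows.append(
            _contrast(result, names, {"cond": 1.0, "cxg": 0.5}, "PL vs MD (guess-adjusted)")
        )
        rows.append(_contrast(result, names, {"gss": 1.0, "cxg": 0.5}, "guess PL vs MD"))
    else:
        rows.append(_contrast(result, names, {"cond": 1.0}, "PL vs MD"))
    contrasts = pd.DataFrame(rows)

    return ModelResult(
        family=family,
        scale_id=scale_id,
        params=result.fe_params,
        conf_int=result.conf_int().iloc[: len(names)],
        pvalues=result.pvalues.iloc[: len(names)],
        contrasts=contrasts,
        n_used=len(data),
        n_subjects=data["participant_id"].nunique(),
        subject_var=float(result.cov_re.iloc[0, 0]),
        resid_var=float(result.scale),
        converged=bool(result.converged),
        covariates=tuple(covariates),
    )


def fit_postacute(data, scale_id="", include_guess=False, covariates=()):
    """Post-acute family: same structure as the acute model, week-level condition."""
    return fit_acute(
        data, scale_id, include_guess=include_guess, covariates=covariates,
        family="post_acute",
    )


def fit_accumulative(
    data: pd.DataFrame,
    scale_id: str = "",
    covariates=(),
    include_md_guess: bool = False,
) -> ModelResult:
    """Repeated-measures model of change from baseline.

    ``data`` needs columns participant_id, group, timepoint (post-baseline
    levels, e.g. week5/week9), change, plus any covariate columns.  Fixed
    effects are group, time and group×time; subjects enter as a random
    intercept (equal-correlation structure).  ``include_md_guess`` adds the
    participant's number of microdose guesses as a covariate.

    Planned contrasts: within-group adjusted mean change at each timepoint,
    and between-group differences (PL vs HH, PL vs MD) at each timepoint.
    """
    data = data.dropna(subset=["change"])
    groups_present = [g for g in GROUPS if g in set(data["group"])]
    if len(groups_present) < 2:
        raise InsufficientDataError("need at least two groups")
    times = sorted(set(data["timepoint"]))
    counts = data.groupby("group")["participant_id"].nunique()
    if (counts < 2).any():
        raise InsufficientDataError("need at least two subjects per group")
    covariates = tuple(covariates) + (("n_md_guesses",) if include_md_guess else ())
    data = _center(data, covariates)

    exog = pd.DataFrame(index=data.index)
    exog["Intercept"] = 1.0
    ref_time = times[0]
    for g in groups_present[1:]:
        exog[f"g_{g}"] = (data["group"] == g).astype(float)
    for t in times[1:]:
        exog[f"t_{t}"] = (data["timepoint"] == t).astype(float)
        for g in groups_present[1:]:
            exog[f"g_{g}:t_{t}"] = exog[f"g_{g}"] * exog[f"t_{t}"]
    for c in covariates:
        exog[c] = data[c].astype(float)
    result = _fit_mixed(data["change"].to_numpy(), exog, data["participant_id"])
    names = list(exog.columns)

    def mean_combo(g, t):
        combo = {"Intercept": 1.0}
        if g != groups_present[0]:
            combo[f"g_{g}"] = 1.0
        if t != ref_time:
            combo[f"t_{t}"] = 1.0
            if g != groups_present[0]:
                combo[f"g_{g}:t_{t}"] = 1.0
        return combo

    rows = []
    for t in times:
        for g in groups_present:
            rows.append(
                _contrast(result, names, mean_combo(g, t), f"{g} change at {t}")
            )
    ref_g = groups_present[0]
    for t in times:
        for g in groups_present[1:]:
            a, b = mean_combo(ref_g, t), mean_combo(g, t)
            combo = {k: b.get(k, 0.0) - a.get(k, 0.0) for k in set(a) | set(b)}
            combo = {k: v for k, v in combo.items() if v != 0.0}
            rows.append(
                _contrast(result, names, combo, f"{ref_g} vs {g} at {t}")
            )
    contrasts = pd.DataFrame(rows)

    return ModelResult(
        family="accumulative",
        scale_id=scale_id,
        params=result.fe_params,
        conf_int=result.conf_int().iloc[: len(names)],
        pvalues=result.pvalues.iloc[: len(names)],
        contrasts=contrasts,
        n_used=len(data),
        n_subjects=data["participant_id"].nunique(),
        subject_var=float(result.cov_re.iloc[0, 0]),
        resid_var=float(result.scale),
        converged=bool(result.converged),
        covariates=covariates,
    )


def screen_covariates(
    data: pd.DataFrame,
    outcome: str,
    candidates,
    groups: str | None = "participant_id",
    alpha: float = 0.05,
) -> list[str]:
    """One-at-a-time covariate screening.

    Each candidate is tested alone against the outcome (a mixed model with
    subject random intercept when ``groups`` is given, OLS otherwise) and
    retained iff its two-sided p-value is below ``alpha``.  Deterministic
    given the data.
    """
    retained = []
    for c in candidates:
        if c not in data.columns:
            raise KeyError(f"candidate column {c!r} missing from data")
        sub = data.dropna(subset=[outcome, c])
        exog = pd.DataFrame(
            {"Intercept": 1.0, c: sub[c].astype(float)}, index=sub.index
        )
        y = sub[outcome].to_numpy(dtype=float)
        if groups is not None and sub[groups].nunique() < len(sub):
            result = _fit_mixed(y, exog, sub[groups])
            p = float(result.pvalues[c])
        else:
            p = float(sm.OLS(y, exog).fit().pvalues[c])
        if not np.isfinite(p):
            # degenerate fits (e.g. a candidate that predicts the outcome
            # perfectly) leave the mixed model without a defined p-value;
            # fall back to the OLS fit and call a perfect fit significant
            ols = sm.OLS(y, exog).fit()
            p = float(ols.pvalues[c])
            if not np.isfinite(p):
                p = 0.0 if ols.ssr <= 1e-12 * max(ols.centered_tss, 1.0) else 1.0
        if p < alpha:
            retained.append(c)
    return retained


def strata_analysis(
    data_by_scale: dict[str, pd.DataFrame],
    covariates=(),
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """2×2 condition×guess strata means and the four planned comparisons.

    ``data_by_scale`` maps scale_id to an acute/post-acute observation
    table (columns participant_id, value, condition, guess).  Per scale the
    guess-augmented mixed model supplies adjusted means for the four
    condition/guess strata and the four planned comparisons: two varying
    condition at fixed guess and two varying guess at fixed condition.
    Empty strata flag their comparisons as unavailable rather than raising.
    """
    mean_rows, comp_rows = [], []
    for sid, data in data_by_scale.items():
        data = data.dropna(subset=["value"])
        occupancy = (
            data.groupby(
                [(data["condition"] == MD), (data["guess"] == MD)]
            )["value"].size()
        )
        occ = {
            (c, g): occupancy.get((c, g), 0) / len(data) for c in (False, True)
            for g in (False, True)
        }
        fit = _refit_for_strata(data, covariates)
        names = list(fit.fe_params.index)

        def stratum_combo(c, g):
            combo = {"Intercept": 1.0}
            if c:
                combo["cond"] = 1.0
            if g:
                combo["gss"] = 1.0
            if c and g:
                combo["cxg"] = 1.0
            return combo

        est = {}
        for c in (False, True):
            for g in (False, True):
                combo = stratum_combo(c, g)
                if occ[(c, g)] == 0 or not set(combo) <= set(names):
                    est[(c, g)] = np.nan
                else:
                    est[(c, g)] = sum(v * fit.fe_params[k] for k, v in combo.items())
        for (c, g), e in est.items():
            mean_rows.append(
                {
                    "scale_id": sid,
                    "condition": MD if c else PL,
                    "guess": MD if g else PL,
                    "adjusted_mean": e,
                    "occupancy": occ[(c, g)],
                }
            )

        comp_defs = {
            "PL/PL vs MD/PL": ((False, False), (True, False), "fixed_guess"),
            "PL/MD vs MD/MD": ((False, True), (True, True), "fixed_guess"),
            "PL/PL vs PL/MD": ((False, False), (False, True), "fixed_condition"),
            "MD/PL vs MD/MD": ((True, False), (True, True), "fixed_condition"),
        }
        for label, (s0, s1, kind) in comp_defs.items():
            keys_needed = set(stratum_combo(*s0)) | set(stratum_combo(*s1))
            if occ[s0] == 0 or occ[s1] == 0 or not keys_needed <= set(names):
                comp_rows.append(
                    {
                        "scale_id": sid,
                        "label": label,
                        "comparison_type": kind,
                        "available": False,
                        "estimate": np.nan,
                        "ci_low": np.nan,
                        "ci_high": np.nan,
                        "p": np.nan,
                    }
                )
                continue
            a, b = stratum_combo(*s0), stratum_combo(*s1)
            combo = {k: b.get(k, 0.0) - a.get(k, 0.0) for k in set(a) | set(b)}
            combo = {k: v for k, v in combo.items() if v != 0.0}
            row = _contrast(fit, names, combo, label)
            comp_rows.append(
                {
                    "scale_id": sid,
                    "label": label,
                    "comparison_type": kind,
                    "available": True,
                    "estimate": row["estimate"],
                    "ci_low": row["ci_low"],
                    "ci_high": row["ci_high"],
                    "p": row["p"],
                }
            )
    means = pd.DataFrame(mean_rows)
    comparisons = pd.DataFrame(comp_rows)
    return means, comparisons


def _prune_collinear(exog: pd.DataFrame) -> pd.DataFrame:
    """Drop columns that are linear combinations of earlier ones (empty
    strata make the full condition×guess design singular)."""
    arr = exog.to_numpy(dtype=float)
    keep: list[int] = []
    rank = 0
    for j in range(arr.shape[1]):
        cand_rank = np.linalg.matrix_rank(arr[:, keep + [j]])
        if cand_rank > rank:
            keep.append(j)
            rank = cand_rank
    return exog.iloc[:, keep]


def _refit_for_strata(data, covariates):
    data = _center(data, covariates)
    exog = pd.DataFrame(index=data.index)
    exog["Intercept"] = 1.0
    exog["cond"] = (data["condition"] == MD).astype(float)
    exog["gss"] = (data["guess"] == MD).astype(float)
    exog["cxg"] = exog["cond"] * exog["gss"]
    for c in covariates:
        exog[c] = data[c].astype(float)
    exog = _prune_collinear(exog)
    return _fit_mixed(data["value"].to_numpy(), exog, data["participant_id"])


def cohen_d(x, y) -> float:
    """Standardized mean difference (mean(y) − mean(x)) / pooled SD."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if len(x) < 2 or len(y) < 2:
        raise ValueError("both samples need at least two observations")
    nx, ny = len(x), len(y)
    pooled = np.sqrt(
        ((nx - 1) * np.var(x, ddof=1) + (ny - 1) * np.var(y, ddof=1)) / (nx + ny - 2)
    )
    if pooled == 0:
        raise ValueError("zero pooled standard deviation")
    return float((y.mean() - x.mean()) / pooled)


def power_sample_size(
    delta: float, sd: float, power: float = 0.90, alpha: float = 0.05
) -> int:
    """Total N (both equal groups) to detect ``delta`` with a two-sample test.

    Normal-approximation formula n/group = 2 (z_{1−α/2} + z_{power})² (sd/δ)²,
    rounded up per group.
    """
    if delta == 0:
        raise ValueError("delta must be non-zero")
    if sd <= 0:
        raise ValueError("sd must be positive")
    d = abs(delta) / sd
    z = stats.norm.ppf(1 - alpha / 2) + stats.norm.ppf(power)
    n_per_group = int(np.ceil(2 * z**2 / d**2))
    return 2 * n_per_group
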