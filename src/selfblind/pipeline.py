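"""End-to-end orchestration: design → simulate → score → analyze → blinding.

Stages exchange long-format CSV tables keyed by participant_id and emit
JSON reports, so every intermediate is diffable and language-neutral.
``run_all`` executes the whole chain deterministically from a single
config and writes a manifest of SHA-256 checksums; re-running the same
config reproduces identical checksums.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .blinding import dose_guess_fit, random_guesser_baseline, summarize_blinding
from .cohort import Cohort, GenerativeParams, simulate_cohort
from .design import TrialDesign, build_kit, capsule_composition
from .inference import (
    ACCUMULATIVE_COVARIATE_CANDIDATES,
    ACUTE_COVARIATE_CANDIDATES,
    InsufficientDataError,
    fit_accumulative,
    fit_acute,
    screen_covariates,
    strata_analysis,
)
from .scales import change_from_baseline, compute_cps, scales_in_class

log = logging.getLogger("selfblind")

#: participant columns usable as covariates without further derivation
_PARTICIPANT_COVARIATES = (
    "age",
    "sex",
    "education",
    "dose",
    "total_dose",
    "suggestibility",
    "expectation",
    "n_past_diagnoses",
    "n_current_medications",
    "lifetime_macrodoses",
    "months_microdosing",
    "n_md_guesses",
)


@dataclass
class RunConfig:
    """One reproducible run: generative settings plus analysis options."""

    seed: int = 0
    n_start: int = 240
    families: tuple[str, ...] = ("accumulative", "acute", "post_acute")
    with_guess: bool = True
    screen: bool = False
    design_overrides: dict = field(default_factory=dict)
    param_overrides: dict = field(default_factory=dict)

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        raw = yaml.safe_load(Path(path).read_text()) or {}
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(raw) - known
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        if "families" in raw:
            raw["families"] = tuple(raw["families"])
        return cls(**raw)

    def to_yaml(self, path) -> None:
        data = dataclasses.asdict(self)
        data["families"] = list(data["families"])
        Path(path).write_text(yaml.safe_dump(data, sort_keys=True))

    def trial_design(self) -> TrialDesign:
        overrides = dict(self.design_overrides)
        for key in ("capsule_days",):
            if key in overrides:
                overrides[key] = tuple(overrides[key])
        return TrialDesign(**overrides)

    def generative_params(self) -> GenerativeParams:
        return GenerativeParams(
            n_start=self.n_start, seed=self.seed, **self.param_overrides
        )


@dataclass(frozen=True)
class RunManifest:
    config_hash: str
    checksums: dict
    version: str

    def to_json(self, path) -> None:
        Path(path).write_text(
            json.dumps(dataclasses.asdict(self), indent=2, sort_keys=True)
        )


# ---------------------------------------------------------------------------
# analysis-ready tables


def acute_table(cohort: Cohort, scale_id: str, outcome_class: str) -> pd.DataFrame:
    """Observation table for the acute/post-acute model of one scale."""
    if scale_id == "cps":
        return _cps_acute_table(cohort)
    sub = cohort.scores[
        (cohort.scores["scale_id"] == scale_id)
        & (cohort.scores["outcome_class"] == outcome_class)
    ]
    cols = ["participant_id", "timepoint", "value", "condition", "guess"]
    return sub[cols].merge(
        cohort.participants[["participant_id", *_PARTICIPANT_COVARIATES]],
        on="participant_id",
    )


def _cps_acute_table(cohort: Cohort) -> pd.DataFrame:
    cps = compute_cps(cohort.task_scores())
    cps = cps[(cps["session"] >= 1) & (cps["session"] <= 4)].copy()
    cps["week"] = cps["session"].astype(int)
    day_guess = cohort.guesses[
        (cohort.guesses["level"] == "capsule_day")
        & (cohort.guesses["day"] == cohort.design.acute_day)
    ][["participant_id", "week", "truth", "guess"]]
    out = cps.merge(day_guess, on=["participant_id", "week"], how="inner")
    out = out.rename(columns={"cps": "value", "truth": "condition"})
    out["timepoint"] = "week" + out["week"].astype(str)
    return out[["participant_id", "timepoint", "value", "condition", "guess"]].merge(
        cohort.participants[["participant_id", *_PARTICIPANT_COVARIATES]],
        on="participant_id",
    )


def accumulative_table(
    cohort: Cohort, scale_id: str, timepoints=("week5", "week9")
) -> pd.DataFrame:
    """Change-from-baseline table for the repeated-measures model."""
    if scale_id == "cps":
        cps = compute_cps(cohort.task_scores())
        scores = cps.rename(columns={"cps": "value"}).dropna(subset=["value"])
        scores["scale_id"] = "cps"
        scores["timepoint"] = scores["session"].map(
            {0: "baseline", 5: "week5", 6: "week9"}
        )
        scores = scores.dropna(subset=["timepoint"])
    else:
        scores = cohort.scores[cohort.scores["scale_id"] == scale_id]
    parts = []
    baseline = scores[scores["timepoint"] == "baseline"].set_index("participant_id")[
        "value"
    ]
    for tp in timepoints:
        delta, _ = change_from_baseline(scores, scale_id, tp)
        parts.append(delta)
    out = pd.concat(parts, ignore_index=True)
    out = out.merge(
        cohort.participants[
            ["participant_id", "group", *_PARTICIPANT_COVARIATES]
        ],
        on="participant_id",
    )
    out["baseline_score"] = out["participant_id"].map(baseline)
    return out


# ---------------------------------------------------------------------------
# stage runners


def analyze_cohort(cohort: Cohort, config: RunConfig) -> dict:
    """Fit every requested family on every registered scale; return a report."""
    report: dict = {"version": __version__, "families": {}}
    if "accumulative" in config.families:
        fam: dict = {}
        for sid in scales_in_class("accumulative") + ["cps"]:
            table = accumulative_table(cohort, sid)
            retained: list[str] = []
            if config.screen:
                retained = screen_covariates(
                    table.dropna(subset=["change"]),
                    "change",
                    [c for c in ACCUMULATIVE_COVARIATE_CANDIDATES if c != "n_md_guesses"],
                )
            try:
                res = fit_accumulative(
                    table, sid, covariates=retained,
                    include_md_guess=config.with_guess,
                )
            except InsufficientDataError as err:
                fam[sid] = {"error": str(err)}
                continue
            fam[sid] = _result_dict(res, retained)
        report["families"]["accumulative"] = fam
        log.info("accumulative: %d scales analyzed", len(fam))

    strata_inputs: dict[str, pd.DataFrame] = {}
    for family, oclass in (("acute", "acute"), ("post_acute", "post_acute")):
        if family not in config.families:
            continue
        fam = {}
        sids = scales_in_class(oclass) + (["cps"] if oclass == "acute" else [])
        for sid in sids:
            table = acute_table(cohort, sid, oclass)
            retained = []
            if config.screen:
                retained = screen_covariates(
                    table.dropna(subset=["value"]), "value",
                    ACUTE_COVARIATE_CANDIDATES,
                )
            try:
                plain = fit_acute(table, sid, covariates=retained, family=family)
                entry = {"no_guess": _result_dict(plain, retained)}
                if config.with_guess:
                    adj = fit_acute(
                        table, sid, include_guess=True, covariates=retained,
                        family=family,
                    )
                    entry["with_guess"] = _result_dict(adj, retained)
                    strata_inputs[sid] = table
            except InsufficientDataError as err:
                entry = {"error": str(err)}
            fam[sid] = entry
        report["families"][family] = fam
        log.info("%s: %d scales analyzed", family, len(fam))

    if config.with_guess and strata_inputs:
        means, comparisons = strata_analysis(strata_inputs)
        report["strata"] = {
            "means": means.to_dict(orient="records"),
            "comparisons": comparisons.to_dict(orient="records"),
        }
    return report


def _result_dict(res, retained) -> dict:
    return {
        "n_used": res.n_used,
        "n_subjects": res.n_subjects,
        "converged": res.converged,
        "subject_var": res.subject_var,
        "resid_var": res.resid_var,
        "retained_covariates": list(retained),
        "contrasts": res.contrasts.to_dict(orient="records"),
    }


def blinding_report(cohort: Cohort) -> dict:
    """Cohort blinding summary, random-guesser null, and dose-detection fit."""
    day = cohort.guesses[cohort.guesses["level"] == "capsule_day"]
    summary = summarize_blinding(day)
    kit, _ = build_kit(cohort.design, 0)
    _, _, base_rate = capsule_composition(kit)
    accuracy, sensitivity, specificity = random_guesser_baseline(base_rate)
    merged = summary.per_participant.merge(
        cohort.participants[["participant_id", "dose"]], on="participant_id"
    )
    fit = dose_guess_fit(
        merged["rate"], merged["dose"], baseline_accuracy=accuracy
    )
    return {
        "cohort": {
            "mean_rate": summary.mean_rate,
            "sd_rate": summary.sd_rate,
            "mean_sensitivity": summary.mean_sensitivity,
            "sd_sensitivity": summary.sd_sensitivity,
            "mean_specificity": summary.mean_specificity,
            "sd_specificity": summary.sd_specificity,
            "n_participants": summary.n_participants,
            "n_without_md_capsules": summary.n_without_md_capsules,
        },
        "random_guesser": {
            "md_base_rate": base_rate,
            "accuracy": accuracy,
            "sensitivity": sensitivity,
            "specificity": specificity,
        },
        "dose_fit": {
            "slope": fit.slope,
            "intercept": fit.intercept,
            "f_stat": fit.f_stat,
            "df": [fit.df_num, fit.df_den],
            "p_value": fit.p_value,
            "detection_threshold_ug": fit.threshold,
            "n": fit.n,
        },
    }


def _sha256(path: Path) -> str:
    return hashlib.sha256(path.read_bytes()).hexdigest()


def run_all(config: RunConfig, outdir) -> RunManifest:
    """Execute simulate → analyze → blinding and write all artifacts."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    design = config.trial_design()
    params = config.generative_params()
    log.info("simulating cohort: n_start=%d seed=%d", params.n_start, params.seed)
    cohort = simulate_cohort(params, design)
    paths = cohort.to_csv(outdir)
    log.info(
        "tables written: %s",
        {k: len(getattr(cohort, k)) for k in ("participants", "guesses", "scores")},
    )

    report = analyze_cohort(cohort, config)
    report_path = outdir / "report.json"
    report_path.write_text(json.dumps(report, indent=2, default=_json_default))
    paths["report"] = str(report_path)

    blind = blinding_report(cohort)
    blind_path = outdir / "blinding.json"
    blind_path.write_text(json.dumps(blind, indent=2, default=_json_default))
    paths["blinding"] = str(blind_path)

    config_path = outdir / "config.yaml"
    config.to_yaml(config_path)
    paths["config"] = str(config_path)

    config_hash = hashlib.sha256(config_path.read_bytes()).hexdigest()
    checksums = {name: _sha256(Path(p)) for name, p in paths.items()}
    manifest = RunManifest(
        config_hash=config_hash, checksums=checksums, version=__version__
    )
    manifest.to_json(outdir / "manifest.json")
    return manifest


def _json_default(obj):
    if isinstance(obj, (np.integer,)):
        return int(obj)
    if isinstance(obj, (np.floating,)):
        return float(obj)
    if isinstance(obj, np.ndarray):
        return obj.tolist()
    raise TypeError(f"not JSON serializable: {type(obj)}")
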