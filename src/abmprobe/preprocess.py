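"""Trial-level cleaning, participant exclusion, and the attentional bias index.

Cleaning applies three staged discard rules to each measurement assessment:

1. error trials (incorrect responses) are dropped;
2. trials with RT < 200 ms or > 2000 ms are dropped (strict inequalities);
3. per trial type (congruent / incongruent) separately, trials whose RT
   lies more than 2 sample standard deviations from that type's mean —
   both computed over the survivors of stages 1-2 — are dropped in a
   single pass (no re-iteration).

A participant is flagged for exclusion when more than 20% (strictly) of
the input trials of either type, in either the pre- or post-training
measurement, were discarded.

The bias index is

    bias = mean(RT | incongruent) - mean(RT | congruent)

over retained trials: positive values mean faster responses to probes
replacing threat faces (vigilance toward threat).  Filler (neutral-neutral)
trials have no congruency and never enter trimming or the bias index.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .schedule import CONGRUENT, INCONGRUENT, FILLER

TRIAL_TYPES = (CONGRUENT, INCONGRUENT)


@dataclass
class TypeTally:
    """Per-trial-type audit of the staged discard rules."""

    input: int = 0
    discarded_error: int = 0
    discarded_bounds: int = 0
    discarded_sd: int = 0
    retained: int = 0

    @property
    def discard_fraction(self) -> float:
        if self.input == 0:
            return 0.0
        return (self.input - self.retained) / self.input


@dataclass
class CleaningReport:
    """Audit of one assessment's cleaning: tallies per trial type + warnings."""

    tallies: dict = field(default_factory=dict)  # trial type -> TypeTally
    warnings: list = field(default_factory=list)

    def tally(self, trial_type: str) -> TypeTally:
        return self.tallies.setdefault(trial_type, TypeTally())


@dataclass(frozen=True)
class BiasIndex:
    """Bias statistic (ms) with the retained trial counts behind it."""

    value: float
    n_congruent: int
    n_incongruent: int


def filter_trials(
    assessment: pd.DataFrame,
    rt_min: float = 200.0,
    rt_max: float = 2000.0,
    sd_k: float = 2.0,
) -> tuple[pd.DataFrame, CleaningReport]:
    """Apply the three staged discard rules to one assessment.

    ``assessment`` needs columns ``congruency``, ``correct``, ``rt_ms``;
    filler rows are ignored (dropped from the output, not tallied).
    Returns the retained trials and a :class:`CleaningReport` whose
    per-type tallies always sum to the input count.  A trial type with
    fewer than 2 survivors at stage 3 skips the SD trim with a warning
    (its SD is undefined).
    """
    if len(assessment) == 0:
        raise ValueError("empty assessment")
    df = assessment[assessment["congruency"].isin(TRIAL_TYPES)]
    report = CleaningReport()
    kept = []
    for trial_type in TRIAL_TYPES:
        sub = df[df["congruency"] == trial_type]
        tally = report.tally(trial_type)
        tally.input = len(sub)
        ok = sub[sub["correct"].astype(bool)]
        tally.discarded_error = len(sub) - len(ok)
        in_bounds = ok[(ok["rt_ms"] >= rt_min) & (ok["rt_ms"] <= rt_max)]
        tally.discarded_bounds = len(ok) - len(in_bounds)
        if len(in_bounds) >= 2:
            mean = in_bounds["rt_ms"].mean()
            sd = in_bounds["rt_ms"].std(ddof=1)
            surv = in_bounds[(in_bounds["rt_ms"] - mean).abs() <= sd_k * sd]
            tally.discarded_sd = len(in_bounds) - len(surv)
        else:
            surv = in_bounds
            report.warnings.append(
                f"{trial_type}: fewer than 2 in-bounds correct trials; SD trim skipped"
            )
        tally.retained = len(surv)
        kept.append(surv)
    retained = pd.concat(kept).sort_index() if kept else df.iloc[0:0]
    return retained, report


def exclusion_flag(
    pre_report: CleaningReport,
    post_report: CleaningReport,
    threshold: float = 0.20,
) -> tuple[bool, list[str]]:
    """Flag a participant whose discard fraction strictly exceeds
    ``threshold`` for any trial type in either measurement assessment.

    Returns (flag, offending "assessment/type" cells); a fraction exactly
    at the threshold does not trigger exclusion.
    """
    reasons = []
    for label, report in (("pre", pre_report), ("post", post_report)):
        for trial_type in TRIAL_TYPES:
            if report.tally(trial_type).discard_fraction > threshold:
                reasons.append(f"{label}/{trial_type}")
    return bool(reasons), reasons


def bias_index(retained: pd.DataFrame) -> BiasIndex:
    """Mean incongruent RT minus mean congruent RT over retained trials."""
    con = retained.loc[retained["congruency"] == CONGRUENT, "rt_ms"]
    inc = retained.loc[retained["congruency"] == INCONGRUENT, "rt_ms"]
    if len(con) == 0 or len(inc) == 0:
        raise ValueError(
            f"bias index undefined: {len(con)} congruent, {len(inc)} incongruent retained trials"
        )
    return BiasIndex(float(inc.mean() - con.mean()), len(con), len(inc))


def participant_bias_table(
    trials: pd.DataFrame,
    rt_min: float = 200.0,
    rt_max: float = 2000.0,
    sd_k: float = 2.0,
    exclude_threshold: float = 0.20,
    phases: tuple[str, str] = ("pre", "post"),
) -> pd.DataFrame:
    """Clean every participant's measurement phases and tabulate bias indices.

    Input is the long trial table (``participant_id``, ``phase``, trial
    attributes, ``correct``, ``rt_ms``); training phases are ignored.
    Output has one row per participant x phase with columns ``bias_ms``,
    ``n_con``, ``n_inc``, the participant-level ``excluded`` flag and its
    ``reasons`` (comma-joined), plus the group label when present.
    """
    rows = []
    for pid, sub in trials[trials["phase"].isin(phases)].groupby("participant_id", sort=True):
        reports = {}
        cleaned = {}
        for phase in phases:
            assessment = sub[sub["phase"] == phase]
            if len(assessment) == 0:
                continue
            cleaned[phase], reports[phase] = filter_trials(assessment, rt_min, rt_max, sd_k)
        if set(phases) <= set(reports):
            excluded, reasons = exclusion_flag(
                reports[phases[0]], reports[phases[1]], exclude_threshold
            )
        else:
            excluded, reasons = True, ["missing assessment"]
        group = sub["group"].iloc[0] if "group" in sub.columns else None
        for phase, retained in cleaned.items():
            bi = bias_index(retained)
            rows.append(
                {
                    "participant_id": pid,
                    "group": group,
                    "phase": phase,
                    "bias_ms": bi.value,
                    "n_con": bi.n_congruent,
                    "n_inc": bi.n_incongruent,
                    "excluded": excluded,
                    "reasons": ",".join(reasons),
                }
            )
    out = pd.DataFrame(rows)
    if "group" in out.columns and out["group"].isna().all():
        out = out.drop(columns=["group"])
    return out


def cleaned_measurement_rts(
    trials: pd.DataFrame,
    phase: str = "pre",
    rt_min: float = 200.0,
    rt_max: float = 2000.0,
    sd_k: float = 2.0,
    exclude_threshold: float = 0.20,
) -> dict[str, tuple[np.ndarray, np.ndarray]]:
    """Cleaned per-participant RT arrays for one measurement phase.

    Returns {participant_id: (congruent RTs, incongruent RTs)} for
    non-excluded participants — the input the split-half reliability
    estimator consumes.
    """
    out = {}
    table = participant_bias_table(trials, rt_min, rt_max, sd_k, exclude_threshold)
    excluded = set(table.loc[table["excluded"], "participant_id"])
    for pid, sub in trials[trials["phase"] == phase].groupby("participant_id", sort=True):
        if pid in excluded:
            continue
        retained, _ = filter_trials(sub, rt_min, rt_max, sd_k)
        con = retained.loc[retained["congruency"] == CONGRUENT, "rt_ms"].to_numpy()
        inc = retained.loc[retained["congruency"] == INCONGRUENT, "rt_ms"].to_numpy()
        out[pid] = (con, inc)
    return out
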