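"""Jacobson-Truax reliable change and clinically significant change.

From a baseline sample's mean, SD, and a reliability estimate:

* SE_M  = SD * sqrt(1 - reliability)        (standard error of measurement)
* S_diff = sqrt(2 * SE_M^2)                 (SE of a difference score)
* reliable change: |followup - baseline| >= 1.96 * S_diff (inclusive)
* criterion-A cutoff (when the instrument's lower scores are healthier):
  baseline mean - 1.96 * baseline SD, reported both raw and rounded to the
  instrument's integer scale (the rounded value is used for classification
  by default).

Five mutually exclusive categories per follow-up:

* ``recovered``              — reliable improvement and score past the cutoff
* ``non-reliably recovered`` — past the cutoff without reliable change
* ``improved``               — reliable improvement, not past the cutoff
* ``deteriorated``           — reliable change in the harmful direction
* ``unchanged``              — otherwise

For the bias index only the reliable-change half applies (no meaningful
clinical cutoff exists for a ms difference score); :func:`rci_classify`
covers that case.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import pandas as pd

CATEGORIES = (
    "recovered",
    "non-reliably recovered",
    "improved",
    "unchanged",
    "deteriorated",
)

Z_95 = 1.96  # two-sided 95% normal quantile used throughout


@dataclass(frozen=True)
class JTParams:
    """Psychometric constants for reliable/clinically-significant change."""

    baseline_mean: float
    baseline_sd: float
    reliability: float
    se_m: float
    s_diff: float
    rc_threshold: float  # 1.96 * s_diff
    cutoff: float | None = None  # criterion A, raw
    cutoff_rounded: int | None = None  # integer-scale cutoff used by default
    lower_is_better: bool = True


@dataclass(frozen=True)
class JTClassification:
    participant_id: str
    timepoint: int
    change: float  # followup - baseline
    category: str


def jt_params(
    baseline_scores,
    reliability: float,
    with_cutoff: bool = False,
    lower_is_better: bool = True,
) -> JTParams:
    """Compute SE_M, S_diff, the reliable-change threshold, and optionally
    the criterion-A cutoff from baseline scores.

    ``reliability`` may be negative (as split-half bias reliabilities can
    be) but must be < 1.  The cutoff is only defined for instruments where
    lower scores are healthier; it is reported raw and rounded to the
    integer scale.
    """
    scores = np.asarray(baseline_scores, dtype=float)
    if len(scores) < 2:
        raise ValueError("need >= 2 baseline scores")
    if reliability >= 1:
        raise ValueError("reliability must be < 1 for a non-degenerate SE_M")
    mean = float(scores.mean())
    sd = float(scores.std(ddof=1))
    return jt_params_from_moments(mean, sd, reliability, with_cutoff, lower_is_better)


def jt_params_from_moments(
    baseline_mean: float,
    baseline_sd: float,
    reliability: float,
    with_cutoff: bool = False,
    lower_is_better: bool = True,
) -> JTParams:
    """As :func:`jt_params`, from a published mean/SD instead of raw scores."""
    if reliability >= 1:
        raise ValueError("reliability must be < 1 for a non-degenerate SE_M")
    if baseline_sd <= 0:
        raise ValueError("degenerate baseline SD")
    se_m = baseline_sd * math.sqrt(1.0 - reliability)
    s_diff = math.sqrt(2.0 * se_m**2)
    cutoff = cutoff_rounded = None
    if with_cutoff:
        if not lower_is_better:
            raise NotImplementedError("criterion-A cutoff implemented for lower-is-better scales")
        cutoff = baseline_mean - Z_95 * baseline_sd
        cutoff_rounded = int(round(cutoff))
    return JTParams(
        baseline_mean=baseline_mean,
        baseline_sd=baseline_sd,
        reliability=reliability,
        se_m=se_m,
        s_diff=s_diff,
        rc_threshold=Z_95 * s_diff,
        cutoff=cutoff,
        cutoff_rounded=cutoff_rounded,
        lower_is_better=lower_is_better,
    )


def rci_classify(change: float, rc_threshold: float, lower_is_better: bool = True) -> str:
    """Reliable-change-only classification: improved / unchanged / deteriorated.

    A change of exactly the threshold counts as reliable ("at least"
    semantics); with ``lower_is_better`` a negative change is improvement.
    """
    if not lower_is_better:
        change = -change
    if change <= -rc_threshold:
        return "improved"
    if change >= rc_threshold:
        return "deteriorated"
    return "unchanged"


def jt_classify(
    baseline: float,
    followup: float,
    params: JTParams,
    participant_id: str = "",
    timepoint: int = 0,
    use_rounded_cutoff: bool = True,
) -> JTClassification:
    """Full five-category Jacobson-Truax classification of one follow-up.

    Requires ``params`` with a criterion-A cutoff.  Crossing the cutoff is
    strict ("lower than"); reliable change is threshold-inclusive.
    """
    if params.cutoff is None:
        raise ValueError("params lack a criterion-A cutoff")
    cutoff = params.cutoff_rounded if use_rounded_cutoff else params.cutoff
    change = followup - baseline
    rc = rci_classify(change, params.rc_threshold, params.lower_is_better)
    below = followup < cutoff if params.lower_is_better else followup > cutoff
    if rc == "improved" and below:
        category = "recovered"
    elif rc != "deteriorated" and below:
        category = "non-reliably recovered"
    elif rc == "improved":
        category = "improved"
    elif rc == "deteriorated":
        category = "deteriorated"
    else:
        category = "unchanged"
    return JTClassification(participant_id, timepoint, float(change), category)


def classify_cohort(
    scores: pd.DataFrame,
    params: JTParams,
    timepoints=(1, 2, 3),
    baseline_timepoint: int = 0,
    use_rounded_cutoff: bool = True,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Classify every participant at every available follow-up against baseline.

    ``scores`` is a long table with ``participant_id``, ``timepoint``,
    ``total`` (and optionally ``group``).  Missing follow-ups yield no row.
    Returns (classification table, category counts per timepoint [x group]).
    """
    rows = []
    groups = {}
    if "group" in scores.columns:
        groups = scores.drop_duplicates("participant_id").set_index("participant_id")["group"]
    wide = scores.pivot_table(index="participant_id", columns="timepoint", values="total")
    if baseline_timepoint not in wide.columns:
        raise ValueError("no baseline scores present")
    for pid, row in wide.iterrows():
        baseline = row.get(baseline_timepoint)
        if pd.isna(baseline):
            raise ValueError(f"participant {pid} lacks a baseline score")
        for t in timepoints:
            followup = row.get(t)
            if followup is None or pd.isna(followup):
                continue
            cls = jt_classify(baseline, followup, params, pid, t, use_rounded_cutoff)
            rec = {
                "participant_id": pid,
                "timepoint": t,
                "change": cls.change,
                "category": cls.category,
            }
            if len(groups):
                rec["group"] = groups.get(pid)
            rows.append(rec)
    table = pd.DataFrame(rows)
    by = ["timepoint", "group"] if "group" in table.columns else ["timepoint"]
    counts = (
        table.groupby(by + ["category"]).size().rename("n").reset_index()
        if len(table)
        else pd.DataFrame(columns=by + ["category", "n"])
    )
    return table, counts
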