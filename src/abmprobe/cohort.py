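"""Synthetic study cohort with known ground truth.

Emulates a four-arm single-session attentional-bias-modification trial:
100 participants block-randomized (blocks of 4, 8, or 12) to
{2D, 3D} x {mock, active} training, each completing a 100-trial
pre-measurement, two 190-trial training blocks, a 100-trial
post-measurement, and the LSAS-SR at four timepoints (baseline, post,
1-week, 3-months) with missing-completely-at-random dropout at the
follow-ups.

Reaction times follow an ex-Gaussian model — the convolution of a normal
component N(mu, sigma) with an exponential tail of mean tau, the standard
generative account of RT distributions.  A participant's true attentional
bias ``bias_delta`` shifts the normal component by +delta/2 on incongruent
and -delta/2 on congruent trials, so the expected incongruent-minus-
congruent difference equals delta.  Contaminant processes exercise every
downstream cleaning rule: anticipatory fast guesses (uniform 50-200 ms),
attentional lapses (uniform 2000-4000 ms), and response errors.

LSAS-SR totals follow the linear trajectory a random-intercept/random-slope
longitudinal model assumes: intercept + slope*t + residual, clipped to the
0-144 scale, with 48 item scores (24 items rated for fear and avoidance,
each 0-3) that sum exactly to the total.

All randomness derives from one seed via ``numpy.random.SeedSequence``
spawning, so a cohort is byte-reproducible.
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict, replace

import numpy as np
import pandas as pd

from .schedule import (
    CONGRUENT,
    INCONGRUENT,
    FILLER,
    LETTERS,
    SessionSchedule,
    TrialSpec,
    generate_measurement_schedule,
    generate_training_schedule,
)

GROUPS = ("2D-mock", "2D-active", "3D-mock", "3D-active")

TRIAL_COLUMNS = [
    "participant_id",
    "group",
    "phase",
    "trial_index",
    "pair_type",
    "threat_position",
    "probe_position",
    "probe_letter",
    "congruency",
    "block",
    "response_letter",
    "correct",
    "rt_ms",
]


@dataclass(frozen=True)
class ParticipantParams:
    """Ground-truth generative parameters for one synthetic participant."""

    id: str
    group: str
    rt_mu: float  # normal component mean, ms
    rt_sigma: float  # normal component SD, ms
    rt_tau: float  # exponential tail mean, ms
    bias_delta: float  # true incongruent-minus-congruent effect, ms
    error_rate: float
    fast_guess_rate: float
    lapse_rate: float
    lsas_intercept: float  # points at baseline
    lsas_slope: float  # points per assessment step
    dropout_1wk: bool = False
    dropout_3mo: bool = False


@dataclass(frozen=True)
class TrialResult:
    """Observed response to one trial."""

    trial: TrialSpec
    response_letter: str
    correct: bool
    rt_ms: float


@dataclass
class CohortConfig:
    """Population-level generative settings (defaults emulate the study design)."""

    n_participants: int = 100
    block_sizes: tuple[int, ...] = (12, 12, 12, 12, 12, 12, 12, 8, 8)
    # ex-Gaussian RT population distribution (between-participant)
    rt_mu_mean: float = 450.0
    rt_mu_sd: float = 50.0
    rt_sigma_mean: float = 50.0
    rt_sigma_sd: float = 10.0
    rt_tau_mean: float = 100.0
    rt_tau_sd: float = 30.0
    # true bias effect, ms (study found none at baseline: mean 0)
    bias_delta_mean: float = 0.0
    bias_delta_sd: float = 10.0
    # contaminant rates
    error_rate_mean: float = 0.03
    error_rate_sd: float = 0.02
    fast_guess_rate_mean: float = 0.01
    fast_guess_rate_sd: float = 0.01
    lapse_rate_mean: float = 0.01
    lapse_rate_sd: float = 0.01
    # LSAS-SR trajectory
    lsas_intercept_mean: float = 69.7
    lsas_intercept_sd: float = 19.3
    lsas_slope_mean: float = -5.9
    lsas_slope_sd: float = 4.0
    lsas_residual_sd: float = 7.0
    lsas_item_count: int = 48  # 24 items x (fear, avoidance), each 0-3
    # MCAR dropout probabilities at the two follow-ups
    dropout_1wk: float = 0.06
    dropout_3mo: float = 0.11
    # task structure
    n_measurement_trials: int = 100
    training_blocks: int = 2
    trials_per_block: int = 190
    filler_rate: float = 0.20
    include_training: bool = True
    # post-training reduction of bias_delta in active groups (0 = no effect,
    # as observed in the study)
    training_effect_ms: float = 0.0
    # emulate the recording fault that dropped the first pre-measurement
    # trial of the first participant in each group
    first_trial_loss: bool = False
    seed: int = 0


@dataclass
class CohortData:
    """Simulated dataset bundle: trials, questionnaires, and ground truth."""

    trials: pd.DataFrame
    questionnaires: pd.DataFrame
    ground_truth: pd.DataFrame
    config: CohortConfig


def allocate_groups(n: int, block_sizes: list[int], seed=None) -> list[str]:
    """Blocked randomization of ``n`` slots to the four groups.

    Each block (size 4, 8, or 12 — any multiple of 4) contains the four
    group labels in exactly equal numbers, in seeded random order; blocks
    must partition ``n``.
    """
    if sum(block_sizes) != n:
        raise ValueError(f"block sizes sum to {sum(block_sizes)}, expected {n}")
    rng = np.random.default_rng(seed)
    out: list[str] = []
    for size in block_sizes:
        if size % 4:
            raise ValueError(f"block size {size} is not divisible by 4 groups")
        block = list(GROUPS) * (size // 4)
        rng.shuffle(block)
        out += block
    return out


def draw_participant_params(
    pid: str, group: str, config: CohortConfig, rng: np.random.Generator
) -> ParticipantParams:
    """Draw one participant's generative parameters from the population config."""

    def clip_rate(x):
        return float(np.clip(x, 0.0, 0.95))

    return ParticipantParams(
        id=pid,
        group=group,
        rt_mu=float(max(rng.normal(config.rt_mu_mean, config.rt_mu_sd), 250.0)),
        rt_sigma=float(max(rng.normal(config.rt_sigma_mean, config.rt_sigma_sd), 5.0)),
        rt_tau=float(max(rng.normal(config.rt_tau_mean, config.rt_tau_sd), 10.0)),
        bias_delta=float(rng.normal(config.bias_delta_mean, config.bias_delta_sd)),
        error_rate=clip_rate(rng.normal(config.error_rate_mean, config.error_rate_sd)),
        fast_guess_rate=clip_rate(
            rng.normal(config.fast_guess_rate_mean, config.fast_guess_rate_sd)
        ),
        lapse_rate=clip_rate(rng.normal(config.lapse_rate_mean, config.lapse_rate_sd)),
        lsas_intercept=float(rng.normal(config.lsas_intercept_mean, config.lsas_intercept_sd)),
        lsas_slope=float(rng.normal(config.lsas_slope_mean, config.lsas_slope_sd)),
        dropout_1wk=bool(rng.random() < config.dropout_1wk),
        dropout_3mo=bool(rng.random() < config.dropout_3mo),
    )


def _congruency_sign(congruency: np.ndarray) -> np.ndarray:
    c = np.zeros(len(congruency))
    c[congruency == INCONGRUENT] = 1.0
    c[congruency == CONGRUENT] = -1.0
    return c


def simulate_responses(
    schedule_frame: pd.DataFrame,
    params: ParticipantParams,
    rng: np.random.Generator,
    bias_delta: float | None = None,
) -> pd.DataFrame:
    """Vectorized response simulation for every trial in a schedule frame.

    RT ~ exGaussian(mu + c*delta/2, sigma, tau) with c = +1 incongruent,
    -1 congruent, 0 filler; fast guesses replace the RT with U(50, 200) and
    lapses with U(2000, 4000); responses are incorrect with probability
    ``error_rate`` (the response letter then being the wrong one).
    """
    n = len(schedule_frame)
    delta = params.bias_delta if bias_delta is None else bias_delta
    c = _congruency_sign(schedule_frame["congruency"].to_numpy())
    rt = rng.normal(params.rt_mu + c * delta / 2.0, params.rt_sigma, size=n)
    rt += rng.exponential(params.rt_tau, size=n)
    u = rng.random(n)
    fast = u < params.fast_guess_rate
    lapse = (u >= params.fast_guess_rate) & (u < params.fast_guess_rate + params.lapse_rate)
    rt[fast] = rng.uniform(50.0, 200.0, size=int(fast.sum()))
    rt[lapse] = rng.uniform(2000.0, 4000.0, size=int(lapse.sum()))
    rt = np.maximum(rt, 1.0)  # RTs are strictly positive
    correct = rng.random(n) >= params.error_rate
    probe = schedule_frame["probe_letter"].to_numpy()
    wrong = np.where(probe == LETTERS[0], LETTERS[1], LETTERS[0])
    out = schedule_frame.copy()
    out["response_letter"] = np.where(correct, probe, wrong)
    out["correct"] = correct
    out["rt_ms"] = np.round(rt, 1)
    return out


def simulate_response(
    trial: TrialSpec, params: ParticipantParams, rng: np.random.Generator
) -> TrialResult:
    """Simulate the response to a single trial (scalar wrapper)."""
    frame = pd.DataFrame([asdict(trial)])
    row = simulate_responses(frame, params, rng).iloc[0]
    return TrialResult(
        trial=trial,
        response_letter=row["response_letter"],
        correct=bool(row["correct"]),
        rt_ms=float(row["rt_ms"]),
    )


def simulate_lsas(
    params: ParticipantParams,
    config: CohortConfig,
    rng: np.random.Generator,
    timepoints=(0, 1, 2, 3),
) -> pd.DataFrame:
    """Simulate LSAS-SR records at the requested timepoints.

    Totals follow clip(intercept + slope*t + N(0, residual_sd), 0, 144),
    rounded to the integer scale.  Item scores (each 0-3) are drawn
    uniformly over all bounded compositions summing to the total, via
    multivariate hypergeometric sampling, so items always sum to the total
    exactly.  Dropout flags remove the 1-week (t=2) and/or 3-months (t=3)
    records.
    """
    k = config.lsas_item_count
    rows = []
    for t in timepoints:
        if (t == 2 and params.dropout_1wk) or (t == 3 and params.dropout_3mo):
            continue
        total = params.lsas_intercept + params.lsas_slope * t
        total += rng.normal(0.0, config.lsas_residual_sd) if config.lsas_residual_sd else 0.0
        total = int(round(float(np.clip(total, 0, 3 * k))))
        items = rng.multivariate_hypergeometric([3] * k, total)
        row = {
            "participant_id": params.id,
            "instrument": "LSAS-SR",
            "timepoint": t,
            "total": total,
        }
        row.update({f"item_{i + 1}": int(x) for i, x in enumerate(items)})
        rows.append(row)
    return pd.DataFrame(rows)


def _schedule_frame(schedule: SessionSchedule, phase_of_block=None) -> pd.DataFrame:
    df = schedule.to_frame()
    if phase_of_block is not None:
        df["phase"] = df["block"].map(phase_of_block)
    return df


def simulate_cohort(config: CohortConfig) -> CohortData:
    """Simulate a complete study dataset.

    Per participant: a pre measurement, training per group variant (active
    groups get the contingency schedule, mock groups a measurement-like
    one), a post measurement, and four LSAS-SR timepoints.  The ground-truth
    parameter table is retained for recovery tests.
    """
    ss = np.random.SeedSequence(config.seed)
    alloc_ss, *child_ss = ss.spawn(config.n_participants + 1)
    groups = allocate_groups(
        config.n_participants, list(config.block_sizes), np.random.default_rng(alloc_ss)
    )

    trial_frames = []
    quest_frames = []
    truth_rows = []
    first_seen: set[str] = set()
    for i, (group, child) in enumerate(zip(groups, child_ss)):
        pid = f"P{i + 1:03d}"
        rng = np.random.default_rng(child)
        params = draw_participant_params(pid, group, config, rng)
        truth_rows.append(asdict(params))

        stimuli = "3D" if group.startswith("3D") else "2D"
        active = group.endswith("active")
        seed_pre, seed_train, seed_post = rng.integers(0, 2**31 - 1, size=3)

        pre = _schedule_frame(
            generate_measurement_schedule(config.n_measurement_trials, config.filler_rate, int(seed_pre))
        )
        pre["phase"] = "pre"
        if config.first_trial_loss and group not in first_seen:
            pre = pre.iloc[1:].reset_index(drop=True)
            first_seen.add(group)
        frames = [simulate_responses(pre, params, rng)]

        if config.include_training:
            train = generate_training_schedule(
                config.training_blocks,
                config.trials_per_block,
                active=active,
                stimuli_mode=stimuli,
                filler_rate=config.filler_rate,
                seed=int(seed_train),
            )
            tdf = _schedule_frame(train, phase_of_block=lambda b: f"training{b}")
            frames.append(simulate_responses(tdf, params, rng))

        post = _schedule_frame(
            generate_measurement_schedule(config.n_measurement_trials, config.filler_rate, int(seed_post))
        )
        post["phase"] = "post"
        post_delta = params.bias_delta
        if active:
            post_delta -= config.training_effect_ms
        frames.append(simulate_responses(post, params, rng, bias_delta=post_delta))

        pdf = pd.concat(frames, ignore_index=True)
        pdf.insert(0, "participant_id", pid)
        pdf.insert(1, "group", group)
        trial_frames.append(pdf[TRIAL_COLUMNS])

        quest_frames.append(simulate_lsas(params, config, rng))

    trials = pd.concat(trial_frames, ignore_index=True)
    questionnaires = pd.concat(quest_frames, ignore_index=True)
    ground_truth = pd.DataFrame(truth_rows)
    return CohortData(trials, questionnaires, ground_truth, config)


def export_cohort(data: CohortData, out_dir) -> dict[str, str]:
    """Write the cohort bundle as delimited text tables; returns the paths."""
    from pathlib import Path

    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    paths = {
        "trials": str(out / "trials.csv"),
        "questionnaires": str(out / "questionnaires.csv"),
        "ground_truth": str(out / "ground_truth.csv"),
    }
    data.trials.to_csv(paths["trials"], index=False)
    data.questionnaires.to_csv(paths["questionnaires"], index=False)
    data.ground_truth.to_csv(paths["ground_truth"], index=False)
    return paths
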