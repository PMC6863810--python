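"""Dot-probe trial schedules: generation, validation, and text export.

A dot-probe trial shows a vertically arranged face pair (one threatening,
one neutral — or two neutral faces on *filler* trials), then a probe letter
('E' or 'F') at the location of one face.  Trials where the probe replaces
the threat face are *congruent*; where it replaces the neutral face,
*incongruent*; neutral-neutral fillers have no congruency and conceal the
training contingency.

Three task variants share this trial structure:

* ``measurement`` — probe equally often at the threat and neutral location.
* ``active`` — training contingency: the probe always replaces the neutral
  face (every threat-neutral trial is incongruent).
* ``mock`` — a training session that is structurally identical to
  measurement (no contingency).

Generators counterbalance exactly (not merely in expectation) within each
block and then shuffle trial order with a seeded RNG, so the multiset of
trial attribute combinations is seed-independent.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, asdict

import numpy as np
import pandas as pd

PAIR_THREAT_NEUTRAL = "threat-neutral"
PAIR_NEUTRAL_NEUTRAL = "neutral-neutral"
CONGRUENT = "congruent"
INCONGRUENT = "incongruent"
FILLER = "filler"
POSITIONS = ("top", "bottom")
LETTERS = ("E", "F")

SCHEDULE_COLUMNS = [
    "trial_index",
    "pair_type",
    "threat_position",
    "probe_position",
    "probe_letter",
    "congruency",
    "block",
]


class BalanceError(ValueError):
    """Requested trial counts cannot satisfy an exact counterbalance constraint."""


@dataclass(frozen=True)
class TrialSpec:
    """Design attributes of a single dot-probe trial.

    ``threat_position`` is ``"none"`` exactly when the trial is a
    neutral-neutral filler; for threat-neutral pairs, congruency is defined
    by whether the probe position matches the threat position.
    """

    trial_index: int
    pair_type: str
    threat_position: str
    probe_position: str
    probe_letter: str
    congruency: str
    block: int = 1
    fixation_ms: int = 500
    faces_ms: int = 500
    iti_ms: int = 500


@dataclass
class SessionSchedule:
    """An ordered list of trials plus block structure for one task session."""

    variant: str  # measurement | active | mock
    stimuli_mode: str  # 2D | 3D
    trials: list[TrialSpec] = field(default_factory=list)
    blocks: list[tuple[int, int]] = field(default_factory=list)  # 1-based inclusive ranges

    def __len__(self) -> int:
        return len(self.trials)

    def to_frame(self) -> pd.DataFrame:
        rows = [asdict(t) for t in self.trials]
        return pd.DataFrame(rows)[SCHEDULE_COLUMNS]


@dataclass(frozen=True)
class Violation:
    """One failed counterbalance/contingency check (data, not an exception)."""

    constraint: str
    observed: float
    expected: float
    detail: str = ""


def _filler_count(n_trials: int, filler_rate: float) -> int:
    raw = n_trials * filler_rate
    n_filler = round(raw)
    if abs(raw - n_filler) > 1e-9:
        raise BalanceError(
            f"filler count {n_trials} x {filler_rate} = {raw} is not an integer"
        )
    return n_filler


def _block_cells(
    n_trials: int, filler_rate: float, active: bool
) -> tuple[int, list[tuple[str, str, str]]]:
    """Return (n_filler, scored cells) for one block, each cell
    (congruency, threat_position, probe_position)."""
    n_filler = _filler_count(n_trials, filler_rate)
    n_scored = n_trials - n_filler
    cells: list[tuple[str, str, str]] = []
    if active:
        if n_scored % 2:
            raise BalanceError(
                f"{n_scored} scored active trials cannot balance threat position "
                "top/bottom (need a count divisible by 2)"
            )
        for threat in POSITIONS:
            probe = "bottom" if threat == "top" else "top"  # probe at neutral face
            cells += [(INCONGRUENT, threat, probe)] * (n_scored // 2)
    else:
        if n_scored % 4:
            raise BalanceError(
                f"{n_scored} scored trials cannot fill the 2 congruency x 2 "
                "threat-position design (need a count divisible by 4)"
            )
        per_cell = n_scored // 4
        for congruency in (CONGRUENT, INCONGRUENT):
            for threat in POSITIONS:
                if congruency == CONGRUENT:
                    probe = threat
                else:
                    probe = "bottom" if threat == "top" else "top"
                cells += [(congruency, threat, probe)] * per_cell
    return n_filler, cells


def _balanced_tokens(n: int, tokens: tuple[str, str], rng: np.random.Generator) -> list[str]:
    """n tokens split as evenly as possible (odd n: the extra token is random)."""
    half = n // 2
    out = [tokens[0]] * half + [tokens[1]] * half
    if n % 2:
        out.append(tokens[int(rng.integers(2))])
    rng.shuffle(out)
    return out


def _generate_block(
    n_trials: int,
    filler_rate: float,
    active: bool,
    rng: np.random.Generator,
    block: int,
    start_index: int,
) -> list[TrialSpec]:
    n_filler, cells = _block_cells(n_trials, filler_rate, active)
    records: list[tuple[str, str, str, str]] = [
        (PAIR_THREAT_NEUTRAL,) + cell[1:] + (cell[0],) for cell in cells
    ]
    filler_probes = _balanced_tokens(n_filler, POSITIONS, rng)
    records += [(PAIR_NEUTRAL_NEUTRAL, "none", p, FILLER) for p in filler_probes]
    letters = _balanced_tokens(n_trials, LETTERS, rng)

    order = rng.permutation(len(records))
    trials = []
    for i, j in enumerate(order):
        pair, threat, probe, congruency = records[j]
        trials.append(
            TrialSpec(
                trial_index=start_index + i,
                pair_type=pair,
                threat_position=threat,
                probe_position=probe,
                probe_letter=letters[i],
                congruency=congruency,
                block=block,
            )
        )
    return trials


def generate_measurement_schedule(
    n_trials: int = 100,
    filler_rate: float = 0.20,
    seed: int | None = None,
    stimuli_mode: str = "2D",
) -> SessionSchedule:
    """Generate a single-block bias-measurement schedule.

    The default 100 trials with 20% neutral-neutral fillers gives 20 filler
    + 40 congruent + 40 incongruent trials; scored trials balance the
    2 congruency x 2 threat-position design exactly and probe letters E/F
    are balanced across all trials.

    Raises :class:`BalanceError` when ``n_trials`` and ``filler_rate``
    cannot satisfy the exact design.
    """
    rng = np.random.default_rng(seed)
    trials = _generate_block(n_trials, filler_rate, active=False, rng=rng, block=1, start_index=1)
    return SessionSchedule("measurement", stimuli_mode, trials, [(1, n_trials)])


def generate_training_schedule(
    n_blocks: int = 2,
    trials_per_block: int = 190,
    active: bool = True,
    stimuli_mode: str = "2D",
    filler_rate: float = 0.20,
    seed: int | None = None,
) -> SessionSchedule:
    """Generate a training schedule of ``n_blocks`` blocks.

    ``active=True`` applies the training contingency: the probe always
    replaces the neutral face, so every threat-neutral trial is
    incongruent.  ``active=False`` (mock) reproduces the measurement
    structure per block.  Counterbalancing is exact within each block.
    """
    rng = np.random.default_rng(seed)
    trials: list[TrialSpec] = []
    blocks: list[tuple[int, int]] = []
    for b in range(1, n_blocks + 1):
        start = len(trials) + 1
        trials += _generate_block(
            trials_per_block, filler_rate, active=active, rng=rng, block=b, start_index=start
        )
        blocks.append((start, len(trials)))
    variant = "active" if active else "mock"
    return SessionSchedule(variant, stimuli_mode, trials, blocks)


def _check_balance(
    violations: list[Violation], constraint: str, a: int, b: int, exact: bool, detail: str
) -> None:
    tol = 0 if exact else 1
    if abs(a - b) > tol:
        violations.append(Violation(constraint, a, b, detail))


def validate_schedule(schedule: SessionSchedule) -> list[Violation]:
    """Check every counterbalance/contingency constraint for the declared variant.

    Returns an empty list iff the schedule is valid; each violation names
    the constraint with observed vs expected counts.  Odd counts are allowed
    an off-by-one imbalance for probe letters and filler probe sides.
    """
    v: list[Violation] = []
    df = schedule.to_frame()

    # per-trial structural invariants
    filler_mask = df["congruency"] == FILLER
    bad = df[filler_mask != (df["pair_type"] == PAIR_NEUTRAL_NEUTRAL)]
    for idx in bad["trial_index"]:
        v.append(Violation("filler_pair_type", idx, idx, "congruency/pair_type mismatch"))
    bad = df[filler_mask != (df["threat_position"] == "none")]
    for idx in bad["trial_index"]:
        v.append(Violation("filler_threat_position", idx, idx, "threat_position/congruency mismatch"))
    tn = df[~filler_mask]
    miscoded = tn[(tn["probe_position"] == tn["threat_position"]) != (tn["congruency"] == CONGRUENT)]
    for idx in miscoded["trial_index"]:
        v.append(Violation("congruency_coding", idx, idx, "probe/threat position vs congruency"))

    n_con = int((df["congruency"] == CONGRUENT).sum())
    n_inc = int((df["congruency"] == INCONGRUENT).sum())
    if schedule.variant == "active":
        if n_con:
            v.append(Violation("contingency", n_con, 0, "active training must have no congruent trials"))
    else:
        _check_balance(v, "congruency balance", n_con, n_inc, exact=True,
                       detail="congruent vs incongruent counts")

    letters = df["probe_letter"].value_counts()
    _check_balance(v, "probe_letter balance", int(letters.get("E", 0)), int(letters.get("F", 0)),
                   exact=len(df) % 2 == 0, detail="letters E vs F across all trials")

    fill = df[filler_mask]
    _check_balance(v, "filler probe balance",
                   int((fill["probe_position"] == "top").sum()),
                   int((fill["probe_position"] == "bottom").sum()),
                   exact=len(fill) % 2 == 0, detail="filler probe top vs bottom")

    for start, end in (schedule.blocks or [(1, len(df))]):
        blk = df[(df["trial_index"] >= start) & (df["trial_index"] <= end) & ~filler_mask]
        top = int((blk["threat_position"] == "top").sum())
        bot = int((blk["threat_position"] == "bottom").sum())
        _check_balance(v, "threat_position balance", top, bot,
                       exact=len(blk) % 2 == 0, detail=f"block {start}-{end}")
    return v


def write_schedule(schedule: SessionSchedule, path) -> None:
    """Write a schedule as a comma-delimited table (lowercase tokens, header row)."""
    schedule.to_frame().to_csv(path, index=False)


def read_schedule(path, variant: str = "measurement", stimuli_mode: str = "2D") -> SessionSchedule:
    """Read a schedule table written by :func:`write_schedule`."""
    df = pd.read_csv(path)
    missing = set(SCHEDULE_COLUMNS) - set(df.columns)
    if missing:
        raise ValueError(f"schedule file missing columns: {sorted(missing)}")
    trials = [
        TrialSpec(
            trial_index=int(r.trial_index),
            pair_type=r.pair_type,
            threat_position=r.threat_position,
            probe_position=r.probe_position,
            probe_letter=r.probe_letter,
            congruency=r.congruency,
            block=int(r.block),
        )
        for r in df.itertuples()
    ]
    blocks = []
    for b, sub in df.groupby("block"):
        blocks.append((int(sub["trial_index"].min()), int(sub["trial_index"].max())))
    return SessionSchedule(variant, stimuli_mode, trials, sorted(blocks))
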