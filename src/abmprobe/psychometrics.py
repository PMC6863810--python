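"""Internal reliability: permutation split-half of the bias index and
Cronbach's alpha.

The bias index is a difference of two trial-mean RTs, so its reliability
is estimated by repeatedly splitting each participant's retained trials in
half (stratified by congruency, so both halves contain both trial types),
computing a bias index per half, correlating the two halves across
participants, and applying the Spearman-Brown prophecy 2r/(1+r).  The
final estimate averages over many random splits (default 5000).  Bias
indices from dot-probe data are notoriously unreliable; negative split-half
estimates are a real possibility and are corrected as-is, without
truncation at zero.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np


@dataclass
class ReliabilityEstimate:
    method: str  # "splithalf-SB" | "cronbach-alpha"
    value: float
    n_participants: int
    n_splits: int | None = None
    seed: int | None = None
    per_split: np.ndarray | None = None
    dropped: list = field(default_factory=list)


def spearman_brown(r_half: float) -> float:
    """Project a half-test correlation to full-test reliability: 2r/(1+r).

    Defined on (-1, 1]; strictly increasing; fixed points at 0 and 1.
    """
    if r_half <= -1.0:
        raise ValueError("Spearman-Brown correction undefined at r = -1")
    return 2.0 * r_half / (1.0 + r_half)


def _half_means(values: np.ndarray, rng: np.random.Generator, n_splits: int):
    """For each of n_splits random partitions of `values` into two
    near-equal halves, return (mean of half 1, mean of half 2) arrays.

    Odd counts assign the extra element to a random half per split.
    """
    n = len(values)
    perms = np.argsort(rng.random((n_splits, n)), axis=1)
    shuffled = values[perms]
    csum = np.cumsum(shuffled, axis=1)
    m = np.full(n_splits, n // 2)
    if n % 2:
        m = m + rng.integers(0, 2, size=n_splits)
    total = csum[:, -1]
    s1 = csum[np.arange(n_splits), m - 1]
    return s1 / m, (total - s1) / (n - m)


def splithalf_bias_reliability(
    participant_rts: dict,
    n_splits: int = 5000,
    seed: int | None = None,
    correct_each_split: bool = True,
) -> ReliabilityEstimate:
    """Spearman-Brown corrected average split-half reliability of the bias index.

    ``participant_rts`` maps participant id -> (congruent RT array,
    incongruent RT array) of cleaned trials (see
    :func:`abmprobe.preprocess.cleaned_measurement_rts`).  Per split, each
    participant's congruent and incongruent trials are independently
    partitioned into two near-equal halves; each half yields a bias index;
    the Pearson correlation of half-1 vs half-2 indices across participants
    is Spearman-Brown corrected and the corrected values are averaged
    (``correct_each_split=False`` instead averages the raw correlations and
    corrects the mean).

    Participants with fewer than 2 trials of either type cannot be split
    and are dropped with a warning record; fewer than 3 contributing
    participants is an error.
    """
    rng = np.random.default_rng(seed)
    dropped = [
        pid for pid, (con, inc) in participant_rts.items() if len(con) < 2 or len(inc) < 2
    ]
    ids = [pid for pid in participant_rts if pid not in set(dropped)]
    if len(ids) < 3:
        raise ValueError(f"need >= 3 participants with splittable trials, have {len(ids)}")

    h1 = np.empty((len(ids), n_splits))
    h2 = np.empty((len(ids), n_splits))
    for i, pid in enumerate(ids):
        con, inc = participant_rts[pid]
        c1, c2 = _half_means(np.asarray(con, dtype=float), rng, n_splits)
        i1, i2 = _half_means(np.asarray(inc, dtype=float), rng, n_splits)
        h1[i] = i1 - c1
        h2[i] = i2 - c2

    # per-split Pearson correlation across participants, vectorized
    a = h1 - h1.mean(axis=0)
    b = h2 - h2.mean(axis=0)
    denom = np.sqrt((a**2).sum(axis=0) * (b**2).sum(axis=0))
    with np.errstate(invalid="ignore", divide="ignore"):
        r = (a * b).sum(axis=0) / denom
    r = np.clip(r, -0.999999, 1.0)  # guard degenerate splits

    if correct_each_split:
        per_split = 2.0 * r / (1.0 + r)
        value = float(np.nanmean(per_split))
    else:
        per_split = r
        value = spearman_brown(float(np.nanmean(r)))
    return ReliabilityEstimate(
        method="splithalf-SB",
        value=value,
        n_participants=len(ids),
        n_splits=n_splits,
        seed=seed,
        per_split=per_split,
        dropped=dropped,
    )


def cronbach_alpha(item_matrix) -> ReliabilityEstimate:
    """Cronbach's alpha of a participants x items score matrix.

    alpha = k/(k-1) * (1 - sum of item variances / variance of totals),
    with sample (n-1) variances.  Rows containing missing items are
    dropped and recorded.  Requires >= 2 items, >= 3 complete rows, and
    non-zero total variance.
    """
    x = np.asarray(item_matrix, dtype=float)
    if x.ndim != 2 or x.shape[1] < 2:
        raise ValueError("item matrix must be 2-D with at least 2 items")
    complete = ~np.isnan(x).any(axis=1)
    dropped = list(np.where(~complete)[0])
    x = x[complete]
    if x.shape[0] < 3:
        raise ValueError(f"need >= 3 complete rows, have {x.shape[0]}")
    k = x.shape[1]
    item_var = x.var(axis=0, ddof=1).sum()
    total_var = x.sum(axis=1).var(ddof=1)
    if total_var == 0:
        raise ValueError("zero variance of totals; alpha undefined")
    value = (k / (k - 1)) * (1.0 - item_var / total_var)
    return ReliabilityEstimate(
        method="cronbach-alpha", value=float(value), n_participants=x.shape[0], dropped=dropped
    )
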