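"""Baseline summary statistics of the trial cohort the synthetic generator emulates.

The study enrolled 100 adults with elevated social anxiety and randomized
them to four single-session training groups (mock vs. active contingency,
crossed with 2D vs. 3D stimuli).  Five participants were later excluded for
excess discarded trials, leaving the published per-group baseline summaries
below (N, mean, SD) for the LSAS-SR total (0-144) and the dot-probe bias
index (ms).  These summaries are inputs to the Jacobson-Truax constants:
pooling them with the combined-groups variance formula reproduces the
reliable-change and clinical-cutoff parameters without participant-level
data.
"""

from __future__ import annotations

import math

GROUPS = ("2D-mock", "2D-active", "3D-mock", "3D-active")

#: per-group baseline sample sizes after exclusions
BASELINE_N = {"2D-mock": 23, "2D-active": 25, "3D-mock": 23, "3D-active": 24}

#: LSAS-SR total at baseline, per group: (mean, sd)
BASELINE_LSAS = {
    "2D-mock": (71.00, 20.02),
    "2D-active": (68.68, 18.24),
    "3D-mock": (70.35, 18.02),
    "3D-active": (69.00, 21.86),
}

#: dot-probe bias index (ms) at baseline, per group: (mean, sd)
BASELINE_BIAS = {
    "2D-mock": (-6.07, 32.94),
    "2D-active": (3.13, 29.72),
    "3D-mock": (14.52, 43.22),
    "3D-active": (-4.45, 39.17),
}

#: Cronbach's alpha of the baseline LSAS-SR in this cohort
LSAS_ALPHA = 0.92

#: Spearman-Brown corrected permutation split-half reliability of the
#: baseline bias index (5000 random splits) in this cohort
BIAS_SPLITHALF_RELIABILITY = -0.04


def pool_group_summaries(
    ns: list[int], means: list[float], sds: list[float]
) -> tuple[float, float, int]:
    """Recombine group (n, mean, sd) summaries into the combined-sample
    mean and SD.

    Uses the exact combined-groups variance identity

        s^2 = [sum (n_i - 1) s_i^2 + sum n_i (m_i - m)^2] / (N - 1)

    so the result equals the sample SD of the concatenated raw data.
    Returns (pooled mean, pooled sd, total n).
    """
    if len(ns) != len(means) or len(ns) != len(sds):
        raise ValueError("ns, means, sds must have equal length")
    n_total = sum(ns)
    if n_total < 2:
        raise ValueError("need at least 2 observations to pool")
    grand = sum(n * m for n, m in zip(ns, means)) / n_total
    ss = sum((n - 1) * s**2 for n, s in zip(ns, sds))
    ss += sum(n * (m - grand) ** 2 for n, m in zip(ns, means))
    return grand, math.sqrt(ss / (n_total - 1)), n_total


def pooled_baseline(table: dict[str, tuple[float, float]]) -> tuple[float, float, int]:
    """Pool one of the per-group baseline tables over all four groups."""
    ns = [BASELINE_N[g] for g in GROUPS]
    means = [table[g][0] for g in GROUPS]
    sds = [table[g][1] for g in GROUPS]
    return pool_group_summaries(ns, means, sds)
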