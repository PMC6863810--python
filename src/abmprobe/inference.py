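"""Inferential layer: bias-anxiety correlations, the 2 x 4 mixed-design
ANOVA on bias, and the dummy-coded linear mixed-effects model ladder.

The longitudinal anxiety analysis fits a set of nested linear mixed-effects
models to LSAS-SR totals over timepoints coded 0 (baseline), 1 (post),
2 (1-week), 3 (3-months), with two dummy variables replacing the group
factor: ``condition`` (0 mock, 1 active) and ``stimuli`` (0 2D, 1 3D).
Every model carries a random intercept and a random time slope per
participant and is fitted by maximum likelihood (not REML), so AIC and
likelihood-ratio comparisons across fixed-effect structures are valid.
Models are ranked by AIC = 2k - 2 logLik, where k counts fixed effects,
random-effect (co)variances, and the residual variance.

Participants with missing follow-ups contribute their available rows — no
imputation.  t-test degrees of freedom follow a containment heuristic
(within-participant terms: nobs - nsubj - #within terms; between terms:
nsubj - 1 - #between terms), configurable via ``df_method``.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

DEFAULT_LADDER = [
    ("null", "1"),
    ("time", "time"),
    ("time+condition", "time + condition"),
    ("time*condition", "time * condition"),
    ("time+stimuli", "time + stimuli"),
    ("time*stimuli", "time * stimuli"),
    ("two-way", "time * condition + time * stimuli + condition * stimuli"),
    ("full", "time * condition * stimuli"),
]

GROUP_DUMMIES = {
    "2D-mock": (0, 0),
    "2D-active": (1, 0),
    "3D-mock": (0, 1),
    "3D-active": (1, 1),
}


@dataclass
class ModelFit:
    """One fitted candidate model: estimates, logLik, and AIC."""

    model_id: str
    formula: str
    fixed_effects: pd.DataFrame  # term, estimate, se, df, t, p
    log_likelihood: float
    n_params: int  # fixed + RE covariances + residual
    aic: float
    n_obs: int
    n_participants: int
    random_structure: str = "random intercept + time slope per participant"
    converged: bool = True
    message: str = ""


def correlate(x, y) -> tuple[float, float]:
    """Pearson correlation with two-sided p; pairwise deletion of missing."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    ok = ~(np.isnan(x) | np.isnan(y))
    x, y = x[ok], y[ok]
    if len(x) < 3:
        raise ValueError(f"need >= 3 complete pairs, have {len(x)}")
    if x.std() == 0 or y.std() == 0:
        raise ValueError("zero variance; correlation undefined")
    r, p = stats.pearsonr(x, y)
    return float(r), float(p)


def make_long_scores(questionnaires: pd.DataFrame, groups: pd.Series) -> pd.DataFrame:
    """Build the dummy-coded long score table from a questionnaire table.

    ``groups`` maps participant_id -> group label.  Output columns:
    participant_id, time, condition, stimuli, score.
    """
    df = questionnaires[["participant_id", "timepoint", "total"]].copy()
    df = df.rename(columns={"timepoint": "time", "total": "score"})
    glab = df["participant_id"].map(groups)
    if glab.isna().any():
        missing = df.loc[glab.isna(), "participant_id"].unique()
        raise ValueError(f"no group label for participants: {list(missing)[:5]}")
    dummies = glab.map(GROUP_DUMMIES)
    df["condition"] = [d[0] for d in dummies]
    df["stimuli"] = [d[1] for d in dummies]
    return df.dropna(subset=["score"]).reset_index(drop=True)


def rm_anova_bias(bias_table: pd.DataFrame) -> pd.DataFrame:
    """2 (time: pre/post, within) x 4 (group, between) mixed-design ANOVA.

    ``bias_table`` is the preprocessed bias table (participant_id, group,
    phase, bias_ms, excluded).  Excluded participants and incomplete
    pre/post pairs are removed; the numeric decomposition delegates to
    ``pingouin.mixed_anova``.  Returns a tidy frame with F, df, and p for
    the group, time, and interaction effects.
    """
    import pingouin as pg

    df = bias_table[~bias_table["excluded"].astype(bool)].copy()
    counts = df.groupby("participant_id")["phase"].nunique()
    complete = counts[counts == 2].index
    df = df[df["participant_id"].isin(complete)]
    per_group = df.drop_duplicates("participant_id").groupby("group").size()
    if (per_group < 2).any() or len(per_group) < 2:
        raise ValueError(f"each group needs >= 2 complete participants: {per_group.to_dict()}")
    if df["bias_ms"].std() == 0:
        raise ValueError("degenerate input: all bias values identical")
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        aov = pg.mixed_anova(
            data=df, dv="bias_ms", within="phase", between="group", subject="participant_id"
        )
    out = aov.rename(
        columns={"Source": "effect", "DF1": "df1", "DF2": "df2", "p_unc": "p", "p-unc": "p"}
    )
    out["effect"] = out["effect"].replace({"phase": "time", "Interaction": "time x group"})
    return out[["effect", "df1", "df2", "F", "p"]]


def _containment_df(terms: list[str], n_obs: int, n_subj: int) -> dict[str, float]:
    within = [t for t in terms if "time" in t.lower() and t != "Intercept"]
    between = [t for t in terms if t not in within and t != "Intercept"]
    df_within = max(n_obs - n_subj - len(within), 1)
    df_between = max(n_subj - 1 - len(between), 1)
    out = {}
    for t in terms:
        out[t] = df_within if (t in within or t == "Intercept") else df_between
    return out


def fit_lmm(
    long: pd.DataFrame,
    formula_rhs: str,
    model_id: str | None = None,
    df_method: str = "containment",
) -> ModelFit:
    """Fit one candidate model by ML with random intercept + time slope.

    ``long`` needs columns participant_id, time, condition, stimuli, score.
    """
    import statsmodels.formula.api as smf

    formula = f"score ~ {formula_rhs}"
    n_subj = long["participant_id"].nunique()
    model = smf.mixedlm(formula, long, groups=long["participant_id"], re_formula="~time")
    converged, message = True, ""
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        try:
            res = model.fit(reml=False, method="lbfgs", maxiter=400)
            if not res.converged:
                res = model.fit(reml=False, method="powell", maxiter=800)
            converged = bool(res.converged)
        except Exception as exc:  # pragma: no cover - rare numerical failure
            return ModelFit(
                model_id or formula_rhs,
                formula,
                pd.DataFrame(),
                float("nan"),
                0,
                float("inf"),
                len(long),
                n_subj,
                converged=False,
                message=str(exc),
            )

    fe = res.fe_params
    k = len(fe) + model.k_re2 + 1  # fixed + RE covariances + residual variance
    llf = float(res.llf)
    terms = list(fe.index)
    se = res.bse_fe
    tvals = fe / se
    if df_method == "containment":
        dfs = _containment_df(terms, len(long), n_subj)
        pvals = {t: 2 * stats.t.sf(abs(tvals[t]), dfs[t]) for t in terms}
    else:  # normal approximation
        dfs = {t: np.inf for t in terms}
        pvals = {t: 2 * stats.norm.sf(abs(tvals[t])) for t in terms}
    fixed = pd.DataFrame(
        {
            "term": terms,
            "estimate": [float(fe[t]) for t in terms],
            "se": [float(se[t]) for t in terms],
            "df": [dfs[t] for t in terms],
            "t": [float(tvals[t]) for t in terms],
            "p": [float(pvals[t]) for t in terms],
        }
    )
    return ModelFit(
        model_id or formula_rhs,
        formula,
        fixed,
        llf,
        k,
        2 * k - 2 * llf,
        len(long),
        n_subj,
        converged=converged,
        message=message,
    )


def fit_lmm_set(
    long: pd.DataFrame,
    ladder=None,
    df_method: str = "containment",
) -> list[ModelFit]:
    """Fit the candidate ladder and return the fits sorted by AIC.

    The default ladder runs from the intercept-only model through additive
    and interactive time/condition/stimuli structures up to the full
    three-way model; convergence failures are reported per model without
    aborting the set.
    """
    ladder = DEFAULT_LADDER if ladder is None else ladder
    fits = [fit_lmm(long, rhs, model_id, df_method) for model_id, rhs in ladder]
    return sorted(fits, key=lambda f: f.aic)


def likelihood_ratio(nested: ModelFit, full: ModelFit) -> tuple[float, int, float]:
    """Likelihood-ratio test of a nested model against a fuller one.

    statistic = 2 (logLik_full - logLik_nested), df = parameter-count
    difference, chi-square p.  Requires ML fits with the nested model's
    fixed-effect terms a subset of the full model's.
    """
    nested_terms = set(nested.fixed_effects["term"])
    full_terms = set(full.fixed_effects["term"])
    if not nested_terms <= full_terms:
        raise ValueError(
            f"models are not nested: {sorted(nested_terms - full_terms)} not in the full model"
        )
    df = full.n_params - nested.n_params
    stat = max(2.0 * (full.log_likelihood - nested.log_likelihood), 0.0)
    p = float(stats.chi2.sf(stat, df)) if df > 0 else 1.0
    if df == 0:
        stat = 0.0
    return float(stat), int(df), p


def model_comparison_table(fits: list[ModelFit]) -> pd.DataFrame:
    """Tidy AIC ranking of a fitted model set."""
    rows = [
        {
            "model_id": f.model_id,
            "k": f.n_params,
            "logLik": f.log_likelihood,
            "AIC": f.aic,
            "converged": f.converged,
        }
        for f in fits
    ]
    out = pd.DataFrame(rows).sort_values("AIC").reset_index(drop=True)
    out["dAIC"] = out["AIC"] - out["AIC"].min()
    return out
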