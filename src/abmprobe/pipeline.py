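"""End-to-end pipeline orchestration and the run manifest.

``run_pipeline`` chains the analysis stages on a trial table and a
questionnaire table (simulated or real exports with the same schema):

1. preprocess — staged cleaning, exclusions, bias table;
2. psychometrics — split-half bias reliability, Cronbach's alpha;
3. clinical change — reliable change for bias, full Jacobson-Truax for
   the questionnaire totals;
4. inference — bias/anxiety correlations, 2 x 4 mixed ANOVA, the LMM
   ladder with AIC ranking and the nested-vs-full likelihood-ratio test.

All outputs are comma-delimited text plus a JSON manifest (config echo,
seed, version, per-stage counts) sufficient for exact re-execution.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .preprocess import participant_bias_table, cleaned_measurement_rts
from .psychometrics import splithalf_bias_reliability, cronbach_alpha
from .clinical_change import jt_params, classify_cohort, rci_classify
from .inference import (
    correlate,
    rm_anova_bias,
    make_long_scores,
    fit_lmm_set,
    likelihood_ratio,
    model_comparison_table,
)

TRIAL_SCHEMA = [
    "participant_id",
    "phase",
    "congruency",
    "correct",
    "rt_ms",
]
SCORE_SCHEMA = ["participant_id", "instrument", "timepoint", "total"]


@dataclass
class RunConfig:
    """All pipeline parameters; defaults are the study's stated values."""

    seed: int = 0
    rt_min: float = 200.0
    rt_max: float = 2000.0
    sd_k: float = 2.0
    exclude_threshold: float = 0.20
    n_splits: int = 5000
    correct_each_split: bool = True
    jt_reliability: float | None = None  # None -> use Cronbach's alpha from items
    use_rounded_cutoff: bool = True
    out_dir: str = "abmprobe_out"

    def to_yaml(self, path) -> None:
        Path(path).write_text(yaml.safe_dump(asdict(self), sort_keys=False))

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        return cls(**yaml.safe_load(Path(path).read_text()))


class SchemaError(ValueError):
    """Input table does not match the expected schema."""


def check_schema(df: pd.DataFrame, required: list[str], name: str) -> None:
    missing = [c for c in required if c not in df.columns]
    if missing:
        raise SchemaError(f"{name} table is missing columns: {missing}")


@dataclass
class PipelineResult:
    bias_table: pd.DataFrame
    bias_reliability: object
    alpha: object
    bias_jt: pd.DataFrame
    jt_classifications: pd.DataFrame
    jt_counts: pd.DataFrame
    correlations: pd.DataFrame
    anova: pd.DataFrame | None
    model_fits: list
    model_comparison: pd.DataFrame
    lrt: tuple | None
    manifest: dict = field(default_factory=dict)


def run_pipeline(
    config: RunConfig,
    trials: pd.DataFrame,
    scores: pd.DataFrame,
    out_dir: str | Path | None = None,
) -> PipelineResult:
    """Execute every analysis stage; optionally write the report bundle."""
    check_schema(trials, TRIAL_SCHEMA, "trials")
    check_schema(scores, SCORE_SCHEMA, "scores")
    manifest: dict = {
        "version": __version__,
        "config": asdict(config),
        "stages": {},
    }

    # --- preprocess ------------------------------------------------------
    bias_table = participant_bias_table(
        trials, config.rt_min, config.rt_max, config.sd_k, config.exclude_threshold
    )
    n_excluded = int(bias_table.drop_duplicates("participant_id")["excluded"].sum())
    manifest["stages"]["preprocess"] = {
        "participants": int(bias_table["participant_id"].nunique()),
        "excluded": n_excluded,
    }

    # --- psychometrics ---------------------------------------------------
    pre_rts = cleaned_measurement_rts(
        trials, "pre", config.rt_min, config.rt_max, config.sd_k, config.exclude_threshold
    )
    bias_rel = splithalf_bias_reliability(
        pre_rts, config.n_splits, config.seed, config.correct_each_split
    )
    lsas = scores[scores["instrument"] == "LSAS-SR"]
    item_cols = [c for c in lsas.columns if c.startswith("item_")]
    alpha = None
    if item_cols:
        baseline_items = lsas[lsas["timepoint"] == 0][item_cols]
        alpha = cronbach_alpha(baseline_items.to_numpy())
    manifest["stages"]["psychometrics"] = {
        "splithalf": bias_rel.value,
        "n_splits": config.n_splits,
        "alpha": alpha.value if alpha else None,
    }

    # --- clinical change -------------------------------------------------
    included = bias_table[~bias_table["excluded"]]
    wide_bias = included.pivot(index="participant_id", columns="phase", values="bias_ms")
    wide_bias = wide_bias.dropna(subset=["pre", "post"])
    bias_params = jt_params(wide_bias["pre"], bias_rel.value, with_cutoff=False)
    bias_jt = pd.DataFrame(
        {
            "participant_id": wide_bias.index,
            "change": (wide_bias["post"] - wide_bias["pre"]).to_numpy(),
        }
    )
    bias_jt["category"] = [
        rci_classify(c, bias_params.rc_threshold) for c in bias_jt["change"]
    ]

    jt_reliability = (
        config.jt_reliability
        if config.jt_reliability is not None
        else (alpha.value if alpha else None)
    )
    if jt_reliability is None:
        raise ValueError("no reliability available for the questionnaire JT analysis")
    baseline_scores = lsas[lsas["timepoint"] == 0]["total"]
    lsas_params = jt_params(baseline_scores, jt_reliability, with_cutoff=True)
    score_cols = ["participant_id", "timepoint", "total"] + (
        ["group"] if "group" in lsas.columns else []
    )
    jt_table, jt_counts = classify_cohort(
        lsas[score_cols], lsas_params, use_rounded_cutoff=config.use_rounded_cutoff
    )
    manifest["stages"]["clinical_change"] = {
        "bias_s_diff_ms": bias_params.s_diff,
        "lsas_s_diff": lsas_params.s_diff,
        "lsas_cutoff": lsas_params.cutoff_rounded,
        "bias_categories": bias_jt["category"].value_counts().to_dict(),
    }

    # --- inference -------------------------------------------------------
    lsas_wide = lsas.pivot_table(index="participant_id", columns="timepoint", values="total")
    corr_rows = []
    for label, phase, t in (("pre", "pre", 0), ("post", "post", 1)):
        merged = wide_bias[phase].to_frame("bias").join(lsas_wide[t].rename("score"), how="inner")
        r, p = correlate(merged["bias"], merged["score"])
        corr_rows.append({"pair": f"bias_{label} vs LSAS_{label}", "r": r, "p": p, "n": len(merged)})
    chg = (wide_bias["post"] - wide_bias["pre"]).to_frame("bias_change").join(
        (lsas_wide[1] - lsas_wide[0]).rename("score_change"), how="inner"
    ).dropna()
    r, p = correlate(chg["bias_change"], chg["score_change"])
    corr_rows.append({"pair": "bias change vs LSAS change", "r": r, "p": p, "n": len(chg)})
    correlations = pd.DataFrame(corr_rows)

    anova = rm_anova_bias(bias_table) if "group" in bias_table.columns else None

    model_fits, comparison, lrt = [], pd.DataFrame(), None
    if "group" in scores.columns or "group" in bias_table.columns:
        groups = (
            scores.drop_duplicates("participant_id").set_index("participant_id")["group"]
            if "group" in scores.columns
            else bias_table.drop_duplicates("participant_id").set_index("participant_id")["group"]
        )
        long = make_long_scores(lsas, groups)
        model_fits = fit_lmm_set(long)
        comparison = model_comparison_table(model_fits)
        by_id = {f.model_id: f for f in model_fits}
        if "time*condition" in by_id and "full" in by_id:
            lrt = likelihood_ratio(by_id["time*condition"], by_id["full"])
    manifest["stages"]["inference"] = {
        "models_fit": len(model_fits),
        "best_model": comparison.iloc[0]["model_id"] if len(comparison) else None,
    }

    result = PipelineResult(
        bias_table=bias_table,
        bias_reliability=bias_rel,
        alpha=alpha,
        bias_jt=bias_jt,
        jt_classifications=jt_table,
        jt_counts=jt_counts,
        correlations=correlations,
        anova=anova,
        model_fits=model_fits,
        model_comparison=comparison,
        lrt=lrt,
        manifest=manifest,
    )
    if out_dir is not None:
        write_bundle(result, out_dir)
    return result


def write_bundle(result: PipelineResult, out_dir) -> None:
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    result.bias_table.to_csv(out / "bias_table.csv", index=False)
    result.bias_jt.to_csv(out / "bias_reliable_change.csv", index=False)
    result.jt_classifications.to_csv(out / "jt_classifications.csv", index=False)
    result.jt_counts.to_csv(out / "jt_counts.csv", index=False)
    result.correlations.to_csv(out / "correlations.csv", index=False)
    if result.anova is not None:
        result.anova.to_csv(out / "anova.csv", index=False)
    if len(result.model_comparison):
        result.model_comparison.to_csv(out / "model_comparison.csv", index=False)
    for fit in result.model_fits:
        if fit.model_id == "full" and len(fit.fixed_effects):
            fit.fixed_effects.to_csv(out / "full_model_fixed_effects.csv", index=False)
    (out / "manifest.json").write_text(json.dumps(result.manifest, indent=2, default=str))
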