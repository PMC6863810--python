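# abmprobe

A tested, reusable implementation of the quantitative pipeline behind a
dot-probe **attentional bias modification (ABM)** trial, for researchers who
run or re-analyze cognitive-bias-modification experiments.

The dot-probe task shows a threat/neutral face pair, then a probe letter at
one face's location; attentional bias is the RT advantage for probes
replacing threat faces,

```
bias = mean(RT | incongruent) − mean(RT | congruent)
```

where *congruent* trials put the probe at the threat face. ABM training adds
a contingency — the probe always replaces the neutral face — concealed by 20%
neutral–neutral filler trials. The package covers every quantitative stage of
such a trial:

- **`schedule`** — exactly counterbalanced trial schedules for the
  measurement, active-training, and mock-training task variants, with a
  validator and CSV import/export.
- **`cohort`** — a synthetic four-arm cohort (blocked randomization in blocks
  of 4/8/12; ex-Gaussian RTs with contaminants; LSAS-SR trajectories with
  item-level scores and MCAR dropout) with a retained ground-truth table, so
  every downstream stage is testable without participant data.
- **`preprocess`** — the three staged trial-discard rules (errors; RT outside
  200–2000 ms; beyond 2 SD of the per-person per-type mean), the >20%
  discard exclusion flag, and the bias index.
- **`psychometrics`** — permutation split-half reliability of the bias index
  with Spearman–Brown correction (default 5000 random splits), and
  Cronbach's α.
- **`clinical_change`** — Jacobson–Truax machinery: SE_M = SD·√(1−r),
  S_diff = √(2·SE_M²), the 1.96·S_diff reliable-change threshold, the
  criterion-A cutoff (baseline mean − 1.96·SD), and the five-category
  classification (recovered / non-reliably recovered / improved / unchanged /
  deteriorated).
- **`inference`** — Pearson bias–anxiety correlations, the 2×4 mixed-design
  ANOVA on bias (pre/post × group), and a ladder of linear mixed-effects
  models (random intercept + time slope per participant, ML fits) compared by
  AIC and likelihood-ratio test.
- **`pipeline` / `cli`** — end-to-end orchestration with a JSON run manifest,
  and an `abmprobe` command with verbs `schedule`, `simulate`, `preprocess`,
  `reliability`, `alpha`, `jt`, `analyze`, `run`.

## Worked example

```python
from abmprobe import CohortConfig, simulate_cohort, RunConfig, run_pipeline
from abmprobe.clinical_change import jt_params_from_moments
from abmprobe.reference import BASELINE_LSAS, LSAS_ALPHA, pooled_baseline

# Jacobson-Truax constants from the published per-group baseline summaries
mean, sd, n = pooled_baseline(BASELINE_LSAS)
params = jt_params_from_moments(mean, sd, reliability=LSAS_ALPHA, with_cutoff=True)
print(f"pooled baseline: mean={mean:.1f}, sd={sd:.1f} (n={n})")
print(f"SE_M={params.se_m:.2f}  S_diff={params.s_diff:.2f}  "
      f"cutoff={params.cutoff:.1f} -> {params.cutoff_rounded}")

# full pipeline on a synthetic cohort
data = simulate_cohort(CohortConfig(seed=1))
scores = data.questionnaires.merge(
    data.ground_truth[["id", "group"]].rename(columns={"id": "participant_id"}),
    on="participant_id")
res = run_pipeline(RunConfig(seed=1, n_splits=5000), data.trials, scores)
print(f"split-half bias reliability: {res.bias_reliability.value:.3f}")
print(f"Cronbach's alpha (baseline items): {res.alpha.value:.3f}")
print("LRT nested vs full: stat=%.2f df=%d p=%.3f" % res.lrt)
```

prints

```
pooled baseline: mean=69.7, sd=19.3 (n=95)
SE_M=5.46  S_diff=7.72  cutoff=31.9 -> 32
split-half bias reliability: 0.489
Cronbach's alpha (baseline items): 0.914
LRT nested vs full: stat=7.75 df=4 p=0.101
```

The first block reproduces the reliable-change constants for the LSAS-SR
(social-anxiety total, 0–144): a change of at least 1.96 × 7.72 ≈ 15.1 points
is reliable, and a follow-up score below 32 crosses the clinical cutoff. The
second block simulates 100 participants (pre-measurement, two 190-trial
training blocks, post-measurement, four questionnaire timepoints), cleans the
RTs, and runs the psychometric and longitudinal analyses; the split-half
value reflects the generator's between-person bias variance, and the
likelihood-ratio test compares the time×condition model against the full
three-way model.

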