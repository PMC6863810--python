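# Methods

## The task and the bias index

A dot-probe trial presents a fixation cross (500 ms), a vertical pair of
faces (500 ms) — one disgusted/threatening and one neutral, or two neutral
faces on filler trials — then a probe letter ('E' or 'F') at the location of
one face, followed by a 500 ms inter-trial interval. Trials where the probe
replaces the threat face are congruent; the neutral face, incongruent. The
attentional bias index is the mean incongruent RT minus the mean congruent
RT over retained trials: positive values indicate vigilance toward threat.

Three schedule variants share this structure. The measurement task places
the probe at either face with equal frequency; active training always places
it at the neutral face (every threat-neutral trial incongruent); mock
training is structurally identical to measurement. All variants carry a
configurable neutral-neutral filler proportion (default 20%), which conceals
the training contingency. The default measurement block is 100 trials (20
filler + 40 congruent + 40 incongruent); training is 2 blocks × 190 trials
(38 filler + 152 scored per block). We read the filler proportion as
applying to all task variants, including measurement, and expose
`filler_rate` so the alternative (training-only filler) is a parameter
choice, not a code change.

Counterbalancing is enforced exactly within each block — equal congruent and
incongruent counts, threat position balanced top/bottom, probe letters E/F
balanced across trials, filler probe sides balanced — and the trial order is
then shuffled with a seeded generator. Exact (rather than stochastic)
balance was an open design choice; it makes the validator's assertions
integer-exact and is the stricter reading of "counterbalanced". Counts that
cannot satisfy the design (scored trials not divisible by 4, or by 2 for
active blocks; fractional filler counts) raise a `BalanceError` naming the
violated constraint. Odd totals allow an off-by-one imbalance in the binary
balances, assigned at random.

## Synthetic cohort

The generator emulates the study design: 100 participants allocated by
blocked randomization (blocks of 12,12,12,12,12,12,12,8,8; each block
containing the four groups in equal number), a 100-trial pre-measurement,
two 190-trial training blocks per group variant, a 100-trial
post-measurement, and LSAS-SR assessments at timepoints 0–3 with
missing-completely-at-random dropout at the follow-ups (rates 0.06 and
0.11, matching the observed 6 and 11 missing follow-ups out of 100).

Reaction times are ex-Gaussian — N(mu, sigma) plus an exponential tail of
mean tau — the standard generative model for RT data; no RT distribution
was reported for the original sample, so the population defaults
(mu 450 ± 50, sigma 50 ± 10, tau 100 ± 30 ms between participants) were
chosen once to give realistic dot-probe RT means around 550 ms and are
exposed in `CohortConfig`. A participant's true bias delta shifts the
normal component by ±delta/2 by congruency, so the expected
incongruent-minus-congruent difference equals delta; the population default
is delta ~ N(0, 10) ms, reflecting the absence of a detectable baseline
bias in this population. Contaminants exercise every cleaning rule:
fast guesses U(50, 200) ms, lapses U(2000, 4000) ms, and response errors
(default rates 1%, 1%, 3%). A `training_effect_ms` knob can impose a true
pre-to-post bias reduction in the active groups for power simulations; its
default is 0, matching the null result the pipeline is built to detect or
reject.

LSAS-SR totals follow the trajectory the longitudinal model assumes:
intercept + slope·t + residual, clipped to 0–144 and rounded to the integer
scale, with population defaults intercept ~ N(69.7, 19.3) (the pooled
published baseline), slope ~ N(−5.9, 4.0) points per assessment, residual
SD 7. The 48 item scores (24 items × fear/avoidance, each 0–3) are drawn by
multivariate hypergeometric sampling — the uniform distribution over
bounded item compositions summing to the total — so items always sum to the
total exactly while varying realistically across items.

What the generator does **not** emulate: practice/fatigue trends within a
session, sequential trial dependencies, item-level factor structure of the
questionnaire, informative dropout, and any cognitive-process account of
attention. Passing tests therefore certify the pipeline's arithmetic and
statistical calibration on data satisfying the model assumptions, not the
psychometric behavior of real dot-probe data.

All randomness descends from one seed through `numpy.random.SeedSequence`
spawning (one child stream per participant), so cohorts and the full
pipeline are byte-reproducible.

## Cleaning and the exclusion rule

Trials are discarded in three fixed stages: (1) error trials; (2) RT
< 200 ms or > 2000 ms (strict inequalities; boundary values are kept);
(3) per trial type, RTs more than 2 sample SDs (n−1 denominator) from that
type's mean, where mean and SD are computed over the survivors of stages
1–2, in a single pass without re-iteration. The stage order and the
single-pass trim were open choices: the per-person mean and SD are only
meaningful on in-bounds correct trials, and no iteration was described. A
type with fewer than two stage-3 candidates skips the trim with a warning
(its SD is undefined). Cleaning reports are conservation-checked: per type,
input = errors + out-of-bounds + trimmed + retained.

A participant is excluded when any of the four assessment × trial-type
discard fractions strictly exceeds 20% ("more than" is read as strict);
the denominator is the input trial count of that type. Filler trials never
enter trimming statistics or the bias index. Training-phase trials are
never cleaned or analyzed for bias.

## Reliability

Split-half reliability of the bias index: per random split, each
participant's retained congruent and incongruent trials are independently
partitioned into two near-equal halves (stratification is required so both
halves yield a bias index; odd counts send the extra trial to a random
half), a bias index is computed per half, the half-1 vs half-2 Pearson
correlation across participants is Spearman–Brown corrected (2r/(1+r)),
and the corrected values are averaged over 5000 splits. Correct-then-
average is the default order, matching common permutation split-half
practice; average-then-correct is available via a flag. Negative split
correlations are corrected as-is without truncation — difference-score
reliabilities can legitimately be negative. Participants with fewer than
two trials of a type are dropped from splits with a record; fewer than
three contributors is an error. The estimate is computed on the
pre-training assessment by default, since it feeds the baseline S_diff.

Cronbach's alpha uses the standard item-variance formula with sample
variances; rows with missing items are dropped and reported.

## Reliable and clinically significant change

From a baseline mean, SD, and reliability r: SE_M = SD·√(1−r),
S_diff = √(2·SE_M²), reliable-change threshold 1.96·S_diff. Change is
followup − baseline; improvement is negative for both the LSAS-SR and the
bias index. "At least 1.96 × S_diff" makes the reliable-change boundary
inclusive; the criterion-A cutoff (baseline mean − 1.96·SD, for
lower-is-better instruments) is a strict "lower than" comparison.
Classification uses the integer-rounded cutoff by default — the continuous
value (≈31.9 for the published baseline, reported as 32) is retained and
selectable — because questionnaire totals live on an integer scale. For
the bias index only the reliable-change half of the machinery applies;
there is no meaningful clinical cutoff for a millisecond difference score.

The published per-group baseline summaries (N, mean, SD) are recombined
with the exact combined-groups variance identity; this reproduces the
LSAS-SR S_diff (7.72 ≈ 7.7 points) and cutoff (31.9 → 32) to rounding, and
the bias-index S_diff to within ~2% (53.1 vs 54.3 ms) — the residual gap
is attributable to the rounding of the published group SDs, and exact
reproduction would require the participant-level data.

## Inference

Bias–anxiety associations are plain Pearson correlations with pairwise
deletion. The bias change analysis is a 2 (time: pre/post, within) × 4
(group, between) mixed-design ANOVA on complete, non-excluded pairs; the
numeric decomposition delegates to `pingouin.mixed_anova`, with the module
owning data shaping and degenerate-input checks.

The longitudinal anxiety analysis fits a ladder of linear mixed-effects
models (statsmodels `MixedLM`) to the long score table with time coded
0,1,2,3 (equal steps per assessment — calendar spacing deliberately not
used) and two dummies: condition (0 mock, 1 active) and stimuli (0 2D,
1 3D). The default ladder runs: intercept-only; time; time+condition;
time×condition; time+stimuli; time×stimuli; all two-way interactions; full
three-way. The exact intermediate rungs were not fully specified and the
ladder is a configurable argument. Every model carries a random intercept
and random time slope per participant and is fitted by maximum likelihood
(not REML), so AIC = 2k − 2·logLik (k = fixed effects + random-effect
covariances + residual variance) and likelihood-ratio tests are comparable
across fixed-effect structures. Participants with missing follow-ups
contribute their available rows; no imputation. Convergence failures are
reported per model without aborting the set.

t-test degrees of freedom default to a containment heuristic: terms
involving time (and the intercept) use nobs − nsubj − (number of within
terms); purely between-participant terms use nsubj − 1 − (number of
between terms). A normal-approximation alternative is selectable. The
heuristic reproduces the qualitative within/between df split of nested
longitudinal designs, not any particular software's exact denominator-df
algorithm.

## Numerical choices and degenerate inputs

- Sample (n−1) variances throughout.
- Split correlations are clipped to ≥ −0.999999 before the Spearman–Brown
  map to guard division blow-ups on degenerate splits.
- Bias index requires ≥ 1 retained trial of each type; zero-variance
  correlation and alpha inputs raise rather than returning NaN.
- Noiseless model-fit inputs (zero residual variance) are estimated to
  optimizer precision (~1e-3), since the likelihood is singular there.
- RTs are floored at 1 ms; questionnaire totals clipped to 0–144.

## Simulation sizes in the test suite

Calibration tests use reduced designs chosen for statistical power per
unit compute, with pre-registered tolerance bands: type-I error of the
mixed ANOVA uses 200 replicate null cohorts of 32 participants with
24-trial measurement phases (3σ binomial band around 0.05); the 4-df
likelihood-ratio test uses 200 replicates of 48 participants; parameter
recovery (bias delta ∈ {0, 30} ms; LSAS slope −5.9) uses single cohorts of
100 participants with 3·SE tolerances. The acceptance script runs the full
default cohort (100 participants, 580 trials each, 5000 reliability
splits) end to end.

## Known limitations

- The containment df heuristic approximates, but does not replicate,
  nlme-style denominator df on unbalanced data.
- The mock-training variant is generated as measurement-structured blocks;
  stimulus identity (which face pair appears) is out of scope throughout.
- Split-half reliability is estimated on the pre-training assessment only;
  pooled pre+post estimation would need a deliberate choice about phase
  effects and is not implemented.
- The criterion-A cutoff is implemented for lower-is-better instruments
  only; normative-population cutoffs (criteria B/C) are out of scope.
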