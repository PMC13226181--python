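# Methods

## The measurement problem

Metacognition is usually measured by comparing confidence reports against the
objective accuracy of a first-order ("type-1") judgment. For emotional
experience there is no objective accuracy: if a participant rates the
pleasantness (valence) of a picture 72/100, nothing in the world makes that
rating right or wrong. `emometa` implements a measurement scheme that makes
continuous emotion ratings scoreable and then applies the standard type-2
(confidence-based) ROC machinery.

## Participant-based accuracy for continuous ratings

For every trial the rating V (or arousal A) on the 0–100 scale is compared to
a normative standard V_n for that stimulus. Four standards are supported:

| condition | V_n |
|---|---|
| `diff`  | the participant's own report of what most people would feel |
| `diff2` | the affective-database norm for the picture (9-point scale, rescaled) |
| `avg`   | the sample mean of all participants' own ratings of the picture |
| `oavg`  | the sample mean of all participants' others-estimates for the picture |

Per participant (and session) the differences d_i = V_i − V_n,i are collected
over all trials; the trial is scored **correct** iff

    mean(d) − 0.675·SD(d)  ≤  d_i  ≤  mean(d) + 0.675·SD(d).

0.675 is the 75th percentile of the standard normal, so under Gaussian
differences the band captures ≈50% of trials: the correct/incorrect split is
balanced by construction, decoupling the type-1 "hit rate" from bias and
scale use. The multiplier `k` is a parameter (default 0.675) so simulations
can tune the split. SD uses the sample (n−1) denominator — the participant's
trial set is a sample of their response distribution — with `ddof` exposed.
Band boundaries are inclusive; a zero-SD series yields a zero-width band in
which only differences exactly equal to the mean count as correct. These two
conventions only matter on measure-zero/integer-tie cases.

The 9-point database norms are mapped onto the collection scale linearly with
endpoints pinned (1→0, 9→100) — the only affine choice preserving order and
the midpoint. Class labels for databases that provide only ratings use the
rule: above 5 → high, below 5 → low, exactly 5 → metadata error.

For forced-choice (2AFC) data accuracy is categorical: 'pleasant' is correct
exactly for high-valence stimuli, 'high' for high-arousal stimuli.

## Type-2 ROC and AUROC2

Given per-trial (correct, confidence) pairs with confidence on 1–100, a
criterion X is swept over the fixed grid {5, 10, …, 100}; at each X,
confidence ≥ X counts as a high-confidence report and the type-2 confusion is

    TP = correct & conf ≥ X      FN = correct & conf < X
    FP = incorrect & conf ≥ X    TN = incorrect & conf < X

with TPR = TP/(TP+FN) and FPR = FP/(FP+TN). The (FPR, TPR) points are
augmented with the (0,0) and (1,1) anchors, de-duplicated, sorted, and
integrated with the trapezoidal rule. This non-parametric area equals the
probability that a randomly drawn correct trial carries higher (grid-binned)
confidence than a randomly drawn incorrect one, ties counting ½ — the
property the test suite verifies by exhaustive pairwise enumeration.
Confidences below the first criterion (1–4) are simply below every grid
criterion; no special handling.

A curve needs both classes; participants with fewer than `min_class`
(default 5) correct or incorrect trials get NaN with an explicit warning
rather than a silently degenerate area.

## Type-1 d′ and meta-d′

2AFC d′ uses the equal-variance Gaussian model: d′ = z(HR) − z(FAR),
c = −½(z(HR)+z(FAR)), with hit/false-alarm rates of 0 or 1 pulled in by the
1/(2N) rule before the z-transform. For continuous ratings (where the task
defines no binary accuracy) a double median split is provided as an explicit,
flag-level convention: stimulus class by the median normative value, response
by the participant's median rating.

meta-d′ is fitted by maximum likelihood on stimulus × response × confidence
counts. Confidence is first discretized to K = 4 levels at fixed edges
25/50/75 (a value equal to an edge maps up); fixed edges keep the levels
comparable across participants, at the cost of some participants
concentrating mass in few levels. The model holds the type-1 response totals
fixed, scales the meta-level type-1 criterion as c′ = c·(meta-d′/d′), and
fits meta-d′ together with K−1 type-2 criteria per response side
(parameterized as positive gaps stacked outward from c′) by maximizing the
multinomial likelihood of the response-conditional confidence counts. Every
cell is padded by 1/(2K) before evaluation (exposed as a parameter).
Optimization is L-BFGS-B, meta-d′ bounded to [0, 5d′+1], with deterministic
multi-starts at {0.5, 1, 1.5}·d′; the result carries the final negative
log-likelihood and a convergence flag that is never silently dropped.
Degenerate inputs (a response with zero trials, non-positive d′) raise.
M-ratio = meta-d′/d′.

## Reliability statistics

- **ICC(3,1)** — two-way mixed effects, consistency, single measure
  (McGraw–Wong C,1): ICC = (MS_R − MS_E)/(MS_R + (k−1)MS_E) from the subject ×
  session ANOVA, 95% CI from F-distribution bounds on MS_R/MS_E. Implemented
  directly from the mean squares so the CI is exactly the F-bound form; the
  tests cross-check it against an independent ANOVA oracle and against
  `pingouin.intraclass_corr`. Zero between-subject variance yields a
  non-positive ICC reported as computed, not clipped.
- **Bland–Altman** — bias = mean of paired differences, limits of agreement
  bias ± 1.96·SD (sample SD).
- **Correlations** — Pearson or Spearman; `method='auto'` runs Shapiro–Wilk
  at α = 0.05 on each margin and falls back to Spearman if either fails.
  (Which normality test drives the choice is a convention of this package.)
- **Paired comparisons** — paired t with Cohen's d = t/√n, the paired-design
  convention consistent with published (t, df, d) triples for this design.
- **Power utility** — smallest n for detecting a population correlation ρ at
  a target power, under the *exact* sampling distribution of the sample
  correlation of a bivariate normal (hypergeometric-series density integrated
  by quadrature over the t-based rejection region), not the Fisher-z
  approximation. For ρ = 0.35, one-tailed α = 0.05, power 0.8 the exact answer
  is 49 while Fisher-z gives 50; the approximation is kept as a cross-check.

## The synthetic-experiment generator

The simulator produces trial tables with exactly the structure the analysis
assumes, so the whole pipeline is testable without collected data.

Rating design: each stimulus has a latent normative mean μ_s per dimension
(uniform on [10, 90] unless supplied). A trial's internal evidence is
e = μ_s + b_p + ε with participant bias b_p ~ N(0, σ_b) and first-order noise
ε ~ N(0, σ_1); the rating is e clipped to [0, 100] and rounded (clipping
counts are recorded in the truth record). The others-estimate is μ_s
corrupted by N(0, σ_o). Confidence deliberately targets the quantity the
accuracy rule scores: the trial's rating-norm difference is read through
metacognitive noise N(0, σ_m), compared against the participant's running
mean difference, and −|deviation| is mapped affinely into 1–100 per
participant-session. σ_m = 0 therefore gives near-perfect second-order access
(AUROC2 → high) and large σ_m decouples confidence from accuracy
(AUROC2 → 0.5).

2AFC design: standard equal-variance SDT with class means ±d_true/2, response
by sign, stimulus classes balanced over the four valence × arousal quadrants;
confidence is |decision variable| + N(0, σ_m) mapped into 1–100.

Defaults are one session of 60 stimuli and 55 participants — the scale of a
single-lab affective-picture study after exclusions. The noise defaults
σ_b = 10, σ_1 = 12, σ_o = 10, σ_m = 10 rating points were chosen once as
realistic slider-report variability (first-order report SD around one eighth
of the scale, metacognitive noise of the same order); d_true = 1.5 is a
typical mid-range sensitivity. `sigma_m_spread` (default 0) draws a stable
per-participant metacognitive noise level σ_m,p ~ N(σ_m, spread), truncated
at 0, once per participant and shared across sessions — this is what creates
true between-participant differences and hence positive test–retest ICC in
two-session simulations. Where a noise grid in "units" of second-order noise
is needed (e.g. the degradation checks), the grid {0, 0.5, 1, 2} is
interpreted as multiples of σ_1 for the rating design, matching the 2AFC case
where the evidence SD is 1.

All randomness flows from one integer seed through
`numpy.random.SeedSequence.spawn`, one child stream per participant:
identical configs give byte-identical tables and participant blocks are
independent of generation order.

What the simulator does **not** emulate: heaping/anchor effects on sliders,
category-structured stimulus means for the rating task, familiarity-dependent
responding, session-order or memory effects, and any real covariance between
valence and arousal. Passing tests therefore show the estimators recover the
generative model's structure, not that any particular empirical dataset will
behave this way.

## Exclusions and other data-handling rules

A participant-session is excluded when any single rated parameter (each
rating, each confidence, the others-estimates, familiarity, or a 2AFC
response) is constant over all its trials — flat responding on one channel
already invalidates the trial set for these analyses. The rule is applied per
session by default (least destructive reading), with a flag for
whole-participant exclusion. Group means for the `avg`/`oavg` standards are
computed after exclusion, within session, and include the target participant
(a leave-one-out flag exists but is off by default: with typical sample sizes
the self-contribution is below the rating resolution). Familiarity splits at
≥50 = high.

## Problem sizes used in the checked examples

The test suite runs the Gaussian half-split at 10⁵ differences, the
AUROC2-oracle equivalence on 1,000 random instances of ≤20 trials, meta-d′
recovery at 10⁴ trials per class, and the pipeline degradation curve at 200
simulated participants × 60 trials per noise level — sizes at which the
stochastic assertions have comfortable margins while the full suite stays
fast.

## Known limitations

- meta-d′ assumes the equal-variance type-1 model and a single meta-d′ for
  both response sides; no hierarchical/Bayesian variant.
- AUROC2 remains weakly dependent on the type-1 split when accuracy is
  defined categorically (2AFC); the interval rule avoids this by forcing a
  ~50% split.
- The `auto` correlation mode's Shapiro–Wilk gate is a convention; small
  samples have little power to detect non-normality.
- The fixed confidence-bin edges for meta-d′ can leave sparse cells for
  participants with narrow confidence use; cell padding keeps the fit defined
  but shrinks extreme participants toward the middle.
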