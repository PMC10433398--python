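# Methods

## Task environment

The engine implements the two-stage Markov task with the design constants
of the magic-carpet variant: two first-stage options mapping to opposite
preferred second-stage states with `p_common = 0.70`; four second-stage
reward probabilities bounded in `[0.25, 0.75]`; 250 trials per session in
5 contiguous blocks. The drift mechanism for the reward probabilities is
not fully determined by the task description ("slowly drifting"), so the
package adopts the convention of the task lineage: four **independent
Gaussian random walks** with per-trial step SD `drift_sd = 0.025`,
**reflected** at both bounds. Reflection preserves the bounds exactly and
leaves the walk symmetric about the interval midpoint (0.50), which the
test suite verifies against a folded free-walk oracle at 10^6 steps.
Walks are initialized uniform on the interval and stepped once per trial,
including the first; block rests have no effect on walk dynamics. Whether
the four walks should instead be anti-correlated is unknowable from the
task description; independence is the simplest choice and is exposed only
through `drift_sd` and the bounds, all configurable.

The action→state mapping is fixed (action *a* prefers state *a*) and
counterbalance-free: choices are tracked by option identity, and screen
side is presentation detail outside the generative model.

## Hybrid agents

No update equations are printed in the study this task design comes from
(it deliberately analyzed behavior by regression rather than
computational-model fitting), so the generator uses the canonical hybrid
agent of the two-step literature, which is exactly the generator of the
two prototypical stay patterns the analysis targets:

- **Model-free**: SARSA(λ) with a shared learning rate α; the first-stage
  value of the chosen option is updated toward the *pre-update*
  second-stage value plus a λ-weighted reward prediction error.
- **Model-based**: a planner that combines the **true** transition
  probabilities with the current second-stage values,
  `Q_MB(a) = 0.7·max Q2(pref(a), ·) + 0.3·max Q2(other, ·)`. Giving agents
  the true transition model matches the task's instruction design, which
  was built to ensure subjects understand the transition structure.
- **Choice rule**: softmax with inverse temperature β1 over
  `w·Q_MB + (1−w)·Q_MF + persev·repeat`, and β2 over `Q2(state2, ·)` at
  the second stage. `w ∈ [0, 1]` is the model-based weight.

Defaults: `α = 0.4, λ = 0.6, β1 = β2 = 5, persev = 0.1`, all overridable
and drawn truncated-normal per subject-session in cohort simulation. With
λ < 1 a pure model-free agent (w = 0) shows a small apparent
reward × transition interaction (a known property of TD(λ) in this task);
at the defaults it stays within sampling noise of zero at 30 subjects ×
250 trials, which the acceptance suite checks.

## Cohort generator

`CohortSpec` mirrors the study design: group and delay are
between-subject (n_per_cell subjects per group × delay cell, default 15,
close to the study's ~15 per cell), condition and visit within-subject
with condition order counterbalanced inside each cell; site is crossed
with the counterbalancing inside each cell so the two are never
confounded. Ages are truncated-normal per group (control ≈ N(29.6, 8.1),
PTSD ≈ N(37.1, 9.2), bounds [21, 50]) so the PTSD group is older on
average — the imbalance the age-matching procedure exists for; IQ ~
N(114, 12). The per-cell means of `w` default to a pattern reproducing
the study's qualitative effect ordering (PTSD more model-based after
moderate than light exercise, most at long delay; controls high except
moderate/long); a `visit_w_increment` (default 0.05) emulates the
practice-related rise in model-based control from visit 1 to 2. The
generator emulates stationary per-session control weights; it does not
model within-session drift of strategy, reaction times, or payout
framing, so passing tests speak to the analysis machinery, not to those
aspects of real data.

## Stay/switch frame and descriptives

Lagged features are defined for trials ≥ 2 within a session (249 rows per
250-trial session); lags cross block boundaries but never sessions (a
flag drops block-opening trials instead). Previous reward and previous
transition are effect-coded ±0.5, which makes the logistic interaction
coefficient equal to the log-odds crossover contrast and leaves main
effects interpretable at the factor midpoint. QC excludes a subject
entirely if any of their sessions has an invariant first-stage choice
sequence — the "same response throughout the task" rule mapped to
first-stage choices, the stage the analysis concerns. Cohen's d is
computed between groups of per-subject bin stay-probabilities with the
pooled-SD formula (n−1 weights); no Hedges correction.

## Inference engine

The reference analysis for this task is a by-subject random-effects
logistic model. Estimating a full GLMM is out of proportion for this
package; the default engine is **pooled maximum-likelihood logistic
regression (IRLS)** with **cluster-robust (CR0) sandwich standard errors
clustered by subject**, which targets the same population-level fixed
effects. The omnibus specification is the full factorial over
(prev_reward, prev_transition, condition, delay, group, visit), a site
main effect, mean-centered age crossed with the full
reward × transition × condition × delay × group family ("fully
interactive" age), and additive mean-centered IQ — 98 columns. Wald
tests use the normal reference (with ~30,000 observations z and t are
indistinguishable).

Numerical choices: IRLS from a zero start, convergence when the largest
coefficient change is < 1e−8 (max 100 iterations, flagged if not
converged); rank checked by pivoted QR with the offending columns named;
perfect separation raised either when coefficients diverge (>1e4) or when
every observation is fitted to within 1e−6. The CR0 sandwich applies no
small-sample scaling, so it reduces exactly to the HC0 estimator under
singleton clusters and is invariant to duplicating clusters.

**Limitation — few-cluster inference.** CR0 standard errors require more
clusters than model columns; with the 98-column omnibus and fewer than
~100 subjects the five-way interaction's z-statistic is over-dispersed
(measured null SD ≈ 1.25 at 60 subjects, ≈ 1.08 at 120). The calibration
checks in the acceptance suite therefore run at 120 subjects; omnibus
fits on smaller cohorts remain unbiased in their estimates but their
p-values should be read cautiously. A mixed-model backend can be plugged
in by fitting any engine to the design matrix `build_design` produces.

Simple effects refit the full factorial over the contrast variables on
the filtered subset (e.g. reward × transition × condition within
PTSD/long-delay), cluster-robust by subject. The significance gate
returns coefficients with p < α (default .001) ordered by |z|. The age
trim removes one subject per group per step — youngest from the
younger-mean group, oldest from the older — until a Welch t-test gives
p ≥ .05, with age ties broken by subject id.

## Problem sizes in the test suite

The acceptance tests run at the sizes a desk machine handles in minutes:
100,000 transition draws and 10,000-step walks for the design constants;
30-subject single-session cohorts for prototype signatures and the
monotonicity sweep (w ∈ {0, .25, .5, .75, 1}); 100 seeds of direct
logistic simulation (30 subjects × 249 trials) for coefficient recovery;
160-subject cohorts for five-way detection; and 200 seeds of 120-subject
null cohorts for the type-I calibration of the .001 gate. The detection
scenario elevates `w` delay-asymmetrically in the PTSD × moderate cells
(strongest at long delay), since a delay-symmetric elevation moves the
four-way term but leaves the five-way interaction at zero by symmetry;
its magnitudes were set by power analysis so a true effect is detected
with high probability at that cohort size.

## Known limitations

- No GLMM random effects (see above); between-subject heterogeneity
  enters only through the sandwich covariance.
- The generator's agents know the true transition matrix; misbelief about
  transitions (a real driver of apparent model-free behavior) is not
  modeled.
- Reward-walk independence across the four arms is an assumption, not a
  measured property of the original implementation.
- Coefficient magnitudes depend on the ±0.5 effect coding; comparisons
  with analyses using other codings require rescaling.
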