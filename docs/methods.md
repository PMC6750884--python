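# Methods

This note documents the models, the estimation machinery, the synthetic-data
generator and the numerical choices behind `twostage`, in the spirit of the
methods documentation of statsmodels or msprime: what is computed, under what
assumptions, and what the tests do and do not establish.

## Task model

The environment is a two-stage discrimination with reversals. A trial is a
stage-1 lever press `a1 ∈ {L, R}` from S0, a transition to a stage-2 state
`s2 ∈ {S1, S2}`, a stage-2 press `a2`, and a binary outcome. The components
are:

* **Transition**: `a1` reaches its *common* state (`contingency[a1]`,
  default L→S2, R→S1, reversible for reversed-contingency sessions) with
  probability `p_common` — 1.0 in training, 0.8 (or 0.5) in probe sessions —
  and the other state otherwise; each trial carries a common/rare label.
* **Reward**: 1 iff `s2` equals the current rewarding state *and* `a2` is
  that state's discriminative action (R in S2, L in S1).
* **Reversal**: evaluated exactly once, immediately after an earned outcome,
  flipping the rewarding state with probability `p_reversal` (default 0.14);
  never on unrewarded trials, never spontaneously.
* **Session control**: a session ends after `max_outcomes` pellets (default
  60) or `max_trials` (safety cap, default 2000). The initial rewarding
  state of each session is drawn uniformly and recorded. Aborted trials
  (strict-sequence magazine entries) are representable — `a2` empty,
  outcome 0 — and can be generated with a configurable per-trial abort
  probability, but are off by default. Inter-trial time is not modelled;
  an optional constant `rt` is carried for interface compatibility.

## Agent families

Eight families formalise hypotheses about the state-space and the action
repertoire. All values live in [0, 1] when rewards are binary, learning
rates are in [0, 1] and values initialise at `q0` (default 0.5, the midpoint
of the reward range — a symmetric start).

Stage-1 option values:

* single action `a` (all families except pure H, FLAT):
  `V(a) = w·V_MB(a) + (1−w)·Q1mf(a)` with
  `V_MB(a) = Σ_s T[a,s]·max_a' Q2[s,a']` (exact ties in the max average,
  so planning is deterministic); `w = 1` for pure MB families, `w = 0` for
  pure MF, free in hybrids;
* sequence `L→R` or `R→L` (hierarchical families): the cached value
  `Qseq`, treated as a single response unit;
* FLAT: a single merged state with per-press values `Qflat`.

The sequence set is exactly {L→R, R→L}: homogeneous sequences (L→L, R→R)
are never reinforced because reward requires alternation, and are excluded.

Policies are softmax with inverse temperatures `beta1` (stage 1) and `beta2`
(stage 2), optionally mixed with a uniform lapse `eps ∈ [0, 0.5)`. The
stage-2 utility adds a discrimination-tendency bias `b_disc` to the state's
discriminative action, independent of learned values, letting agents express
"one action in each stage-2 state is never rewarded" without value learning.

**Sequence execution and interruption.** A sequence selected at stage 1
executes its first press; with probability `p_int` execution is interrupted
and the stage-2 policy (the same policy used after single actions) chooses
`a2`; otherwise the second element is emitted regardless of `s2`. Because
the selected option is latent given observed `(a1, s2, a2)`, the trial
likelihood marginalises over the modes consistent with `a1`:

    P(a1, a2) = P1(a1)·P2(a2|s2)
              + P1(seq(a1)) · [ (1−p_int)·1[a2 = second] + p_int·P2(a2|s2) ]

with the first term absent for pure H and the second for non-hierarchical
families. Observations with probability zero (pure H, `p_int = eps = 0`,
incomplete sequence) raise an explicit impossible-observation error rather
than returning −inf.

Learning, per completed trial with reward `r`:

* `Q2[s2,a2] += alpha2·(r − Q2)`;
* MF stage-1 cache (SARSA with eligibility `lam`, default 1):
  `Q1mf[a1] += alpha1·(Q2_before − Q1mf) + alpha1·lam·(r − Q2_before)`;
* transition estimates (when enabled): `T[a1,s2] += alpha_T·(1 − T)` with
  the complementary entry renormalised; by default `T` stays at its
  initialisation — the trained contingency smoothed by pseudo-count weight
  `kappa` (default 0.2, giving 0.92/0.08 rows), reflecting that fits target
  probe sessions reached after extensive deterministic training;
* sequence values: `Qseq += resp·alpha_seq·(r − Qseq)`, weighted by the
  posterior responsibility that a sequence was selected. A spec switch
  (`resp_weighted_seq=False`) selects full, unweighted updates for
  sensitivity analyses;
* FLAT treats each press as a choice from one merged state with immediate
  feedback: `Qflat[a1] += alpha1·(0 − Qflat[a1])`,
  `Qflat[a2] += alpha1·(r − Qflat[a2])` — the mechanism that makes a flat
  learner repeat the press most proximal to reward and hence *switch* at
  stage 1 after rewards.

**The generative agent realises the fitted model exactly.** Simulated agents
also update sequence values with marginal responsibilities computed from the
observed trial, not with their private latent mode. This choice makes
simulation and likelihood two views of the same stochastic process, which is
the premise of model- and parameter-recovery studies; with private-mode
(0/1) updates instead, the pure-sequence family — which has no latent-mode
ambiguity — acquires a small systematic evidence advantage on data from the
hybrid sequence families.

Learned values reset at each session boundary (sessions are modelled as
independent learning episodes from `q0` and the smoothed contingency), both
in simulation and in fitting, and "previous trial" relations never cross
session boundaries.

Base models per family, used throughout the recovery studies: a shared
learning rate, `beta1`, `beta2`, `b_disc` for every state-aware family,
plus `p_int` for sequence families and `w` for hybrids (FLAT: `alpha1`,
`beta1`), giving 2–6 free parameters. Toggles (separate learning rates,
free eligibility, lapse, learnable transitions, dropping the bias or the
interruption parameter) span a configurable model grid per family via
`enumerate_models`; pinning parameters with `fixed` removes them from the
free set.

## Estimation and model comparison

Fitting is per subject, by MAP on an unconstrained scale: logit for rates,
probabilities and weights (`eps` via a logit scaled to [0, 0.5)), log for
inverse temperatures, identity for `b_disc`. Default priors are standard
normal on the transformed scale (Normal(0, 2) for `b_disc`) — proper, hence
a proper marginal likelihood, but weakly informative; all are overridable
through `PriorSpec`. Optimisation uses L-BFGS-B from `n_restarts` starts
drawn from the prior (default 10; the first start is the prior mode), with
the seed recorded in the results for exact reproducibility. Degenerate
inputs: a zero-trial subject returns the prior mode with nll = 0 and log
evidence 0; an objective that is non-finite at every start raises an
explicit fit failure.

The per-subject log model-evidence is the Laplace approximation at the MAP
(see README for the formula), with the Hessian computed by central finite
differences (step 1e-4 on the transformed scale, configurable). A
non-positive-definite Hessian triggers a flagged per-subject BIC fallback.
Laplace error decays like 1/n: against adaptive quadrature on a 2-parameter
model it is ≈0.14 nats at 20 trials, ≈0.04 at 80 and ≈0.01 at 320, which is
why the quadrature validation uses an 80-trial session and the unit tests
additionally assert the decay itself. Group evidence is the sum over
subjects (fixed-effects aggregation, one group number per model);
hierarchical empirical-Bayes group priors are out of scope. Pseudo-r² is
`1 − nll/(n·ln 2)` with two modelled binary decisions per non-aborted trial,
averaged over subjects for group tables.

## Behavioural analyses

`annotate` derives lag fields (previous reward, stage-1/stage-2 stay,
previous transition, same stage-2 state, previous correct discrimination,
and — when the simulator's latent `rewarding` column is present — whether
the previous stage-1 action led commonly to the rewarding state). Aborted
trials are dropped *before* lagging, so the previous trial is the last
non-aborted one; the first usable trial per session has no lags.

Standard filters: stage-1 analyses keep trials with a usable predecessor
and (by default) a *correct discrimination* on the previous trial; stage-2
analyses additionally require the stage-2 state to differ from the previous
trial. The correct-discrimination filter is disabled for the control
analysis that instead adds the `correct` predictor (previous stage-1 action
was currently the best one), which absorbs the local response bias that can
masquerade as a reward × transition interaction: with rewards deterministic
within a reversal, conditioning on correct discriminations would make that
predictor collinear with reward × transition, so the control analysis keeps
all trials.

Predictors are coded ±0.5 (centered), so main effects are averages over the
levels of the other factors and the intercept is the overall stay tendency;
the reward × transition interaction is coding-invariant.

The regression engine is a two-stage summary-statistics analysis: a
logistic GLM per subject (per session within subject when sessions are
pooled, combined inverse-variance within subject — the nested structure),
then DerSimonian–Laird random-effects aggregation across subjects, treating
every fixed effect as varying across subjects. Wald intervals are
estimate ± 1.96·SE. Quasi-separated groups are ridge-stabilised and
flagged; inestimable groups (degenerate outcome, constant predictor) are
dropped with a flag, and fewer than two estimable subjects marks the whole
table non-converged. A variational mixed-effects logistic engine
(statsmodels `BinomialBayesMixedGLM`, subject random intercepts) is
available as `engine="vb"`. Calibration on synthetic logistic data
(n = 5000, 8 subjects, 100 replicates) puts the 95% Wald coverage of every
term between 0.94 and 0.99.

`session_stay_profile` runs the {intercept, reward} stage-1 regression per
session — the developmental profile whose reward coefficient flips sign
when control shifts from flat to state-aware — flagging sessions with too
few usable trials or a constant reward predictor (e.g. sessions without
rewards) rather than guessing.

## Synthetic cohorts

`generate_cohort` simulates the study design: default 8 subjects, 40
training sessions (deterministic transitions, 60-outcome cap, 2000-trial
guard) with one probe inserted mid-training and two at the end (80/20
transitions), under a developmental regime that switches the acting
controller from FLAT to H-MB at session 10 (a per-session mixture-weight
schedule is available for gradual shifts; with a mixture, both controllers
learn from every trial and the actor is drawn per trial). Per-subject
parameters are drawn once per subject: learning rates Beta(3, 3), inverse
temperatures log-normal(median 3, σ = 0.4), `p_int` Beta(2, 8), `b_disc`
Normal(1, 0.5), hybrid weight Beta(3, 3) — chosen to give discriminating,
non-degenerate behaviour; all overridable. All randomness derives from the
master seed through spawned generators, and the ground-truth sidecar
(families, drawn parameters, seed) regenerates a cohort bit-exactly.
`probe_cohort` produces the recovery-style design: one long probe session
per subject with the outcome cap lifted.

What the generator does *not* emulate: pre-training phases, reaction-time
dynamics, magazine entries and satiety/motivation drift, within-session
non-stationarity of real animals, and any carry-over of learned values
across sessions. Passing tests therefore establish that the pipeline is
internally consistent — that it recovers what the model family generates —
not that real rats obey these equations.

## Test and validation design (problem sizes)

* Simulator fidelity: 10⁵ trials per statistic.
* Likelihood: 1000 random parameter/state draws against brute-force
  enumeration over latent modes at 1e-10; the compiled session kernel is
  pinned to the step-by-step reference at 1e-10 by a property test.
* Evidence: conjugate-Gaussian closed form at 1e-8 (with a coarser Hessian
  step, exact for quadratics); 2-parameter quadrature at 0.1 nats on an
  80-trial session; invariance under linear reparameterisation at 1e-6.
* Model recovery: 10 replicate cohorts (8 subjects × 300 probe trials) per
  generating family, 7 candidate families, 3 optimizer restarts per fit;
  the generating family must win ≥8/10. Observed: 10/10 for all seven.
* Parameter recovery: pure-H cohort, 20 subjects × 500 trials, priors
  matched to the generating population (the standard recovery design);
  Spearman ≥ 0.7 for the shared learning rate, `beta1`, `beta2`, `p_int`.
  The pure-sequence family is used because it expresses interruption on
  every trial; in hybrid cohorts `p_int` is weakly identified at this scale
  (it trades off against `beta2`/`b_disc` on interrupted trials).
* Fingerprints: FLAT training cohort (negative reward effect); single
  probe cohorts for H (control analysis: positive reward, interaction CI
  covering 0) and MB (positive interaction); three pooled replicate cohorts
  for H-MB (positive reward sign and interaction under the control
  analysis; positive stage-2 reward × stay), pooled because the centered
  H-MB reward effect is small (≈ +0.17) relative to between-subject spread.
* Calibration: 100 replicates, n = 5000, 8 subjects, coverage in
  [0.90, 0.99].

All test seeds are fixed constants; recovery and fingerprint seeds are
spawned from small bases chosen before the final evaluation.

## Known limitations

* Evidence magnitudes depend on the (unknown, configurable) priors; only
  differences (log Bayes factors) between models fitted under the same
  priors are meaningful, and absolute values are not comparable to other
  implementations with other priors or group-level machinery.
* The Laplace approximation is unreliable below ~50 trials per subject.
* The summary-statistics regression engine estimates population effects
  well for ≥ ~6 subjects; with very few subjects its DL heterogeneity
  estimate is noisy and intervals can be conservative.
* The per-session value reset is a modelling convenience: for datasets
  where learning demonstrably carries across sessions, a burn-in by
  simulation would be the alternative (not enabled by default).
* The exact degrees of freedom of the best-fitting published variants of
  these families cannot be reproduced without their full model
  specifications; the base models here have 4–6 free parameters per family
  and the enumeration grid is configurable rather than fixed at any
  particular historical model count.
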