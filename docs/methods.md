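# Methods

## The task

The environment is a two-stage Markov decision task. On each trial a
binary first-stage choice leads to one of two second-stage states; each
first-stage action has a fixed "common" destination reached with
probability 0.7 (the other state is reached 30% of the time). The
second-stage state presents its own binary choice, rewarded 0/1 according
to one of four payoff probabilities. To keep subjects learning, the four
payoff probabilities follow independent Gaussian random walks (SD 0.025
per trial) with *reflecting* boundaries at 0.25 and 0.75: a proposal that
overshoots a boundary is folded back (q' = 2·hi − q, applied iteratively;
a bounded iteration count guards against pathological step sizes).
Sessions are 201 trials in three 67-trial blocks.

Choices the task does not constrain and the source material does not pin
down are fixed here as package conventions:

- Walk initial values are drawn uniformly in [0.25, 0.75] unless
  configured explicitly.
- The action→state association is fixed per session and recorded in the
  config (counterbalancing of stimuli is presentation-level and out of
  scope).
- The simulator generates only completed trials by default; a
  `completion_prob < 1` option emulates response timeouts, and the
  session reader accepts real logs with incomplete trials, which are
  flagged rather than dropped.

## The hybrid agent

Two valuation systems share one table of second-stage action values
`Q2[s, a]`, updated from outcomes with learning rate α₂:

- **Model-free (SARSA(λ)).** Stage-1 values `Q_MF[a]` are updated twice
  within each trial: toward the visited second-stage action's value with
  rate α₁ (prediction error δ₁ = Q2[s₂, a₂] − Q_MF[a₁]), and again by
  the outcome prediction error δ₂ = r − Q2[s₂, a₂] scaled by α₁·λ. λ=1
  is pure direct reinforcement (only the final reward matters); λ=0 is
  pure value chaining through the second stage. Eligibility applies only
  within the trial; traces do not persist across trials.
- **Model-based.** Stage-1 values are computed fresh each trial by
  one-step Bellman evaluation over the known transition probabilities:
  `Q_MB[a] = 0.7·max_a' Q2[s_common(a), a'] + 0.3·max_a' Q2[s_other, a']`.
  The agent is given the true transition structure (subjects were
  instructed about it); estimating the mapping from experienced counts is
  not attempted.

Net stage-1 values are the mixture `Q_net = w·Q_MB + (1 − w)·Q_MF`.
Stage-1 choice probabilities are a softmax with inverse temperature β₁
plus a perseveration bonus `p` (in logit units, added to the previous
trial's choice — additive rather than scaled by β₁, which keeps the
Normal(0, 1) prior on `p` scale-sensible). Stage-2 choices are a plain
softmax with β₂. All values initialize at zero; rewards are 0/1.

The second-stage-onset prediction error is measured against the stage-1
value of the chosen action under the respective system (model-free or
model-based); the outcome prediction error is shared because `Q2` is
shared. These are the only two within-trial timepoints used, which
avoids ambiguity about the baseline for a first-stage prediction error.

The exact within-trial update order (second-stage error before the
outcome error; `Q2` updated between them) is a reconstruction anchored to
the main-text description of the algorithm; supplementary-level equation
detail was not available, and the construction here is the standard one
in which the systems differ only in stage-1 evaluation.

## Fitting

Per-subject maximum likelihood sums the log-probabilities of both
observed choices over completed trials (incomplete trials contribute
nothing and trigger no learning or perseveration carryover). Bounds:
α₁, α₂ ∈ [0, 1]; β₁, β₂ ∈ [0, 30]; p ∈ [−10, 10]; λ and w are allowed to
float beyond the unit interval in a [−2, 3] box so that tests of whether
estimates differ from the nominal boundaries are meaningful — out-of-range
values enter the linear combinations as-is, with no clipping. Optimization
is L-BFGS-B with numeric gradients from (default) 10 jittered restarts;
the likelihood is smooth but can be multimodal in (λ, w). The Hessian at
the optimum is by central finite differences with relative step 1e-4.
`pseudo_r2 = 1 − (−LL)/(N·2·log 2)` measures fit against the
uniform-choice baseline over the two binary choices per trial.

MAP fitting adds the priors Beta(1.1, 1.1) on α₁, α₂, λ, w (which
restricts λ, w to their support), Normal(0, 1) on p, Gamma(1.2, 5) on
β₁, β₂. The Gamma is parameterized shape/scale by default (mode 1, mean
6 — diffuse over the temperature range typically estimated on this task;
a shape/rate reading would concentrate the prior an order of magnitude
below those values), with a `gamma_parameterization="rate"` switch.

The mixed-effects style refit for regressor generation
(`fit_shared_w`) maximizes the summed likelihood over all subjects
jointly, with the six non-w parameters shared and one w per subject;
this puts prediction-error regressors on a common scale across subjects.

## Model comparison

Nested restrictions (TD-only w=0, model-based-only w=1, λ=0, λ=1) are
tested classically by likelihood-ratio tests; per-subject df = the number
of restricted parameters, aggregate df = subjects × restricted
parameters. The Laplace approximation to the log evidence is
`log lik + log prior + (d/2)·log 2π − ½·log det H` at the MAP point, with
H the penalized-objective Hessian (an error is raised if H is not
positive definite). Random-effects model selection treats model identity
as a random effect: a variational loop alternates posterior model
assignments with Dirichlet counts (uniform Dirichlet(1) prior,
convergence tolerance 1e-6), and exceedance probabilities come from 10⁶
Monte-Carlo draws of the posterior Dirichlet.

## Behavioral signatures

The factorial stay analysis codes consecutive completed-trial pairs:
`stay` = the first-stage choice repeats; predictors are the earlier
trial's reward and transition type, effect-coded ±½ so the intercept is
the grand stay tendency. Pairs spanning block breaks are retained by
default (configurable). Stay tables average per-subject cell means,
unweighted, across subjects.

The stay/switch regression fits each subject by penalized logistic ML
(ridge 1e-4 to guard against separation) and draws group inference from
one-sample location tests across subjects — a summary-statistics
approximation to a full hierarchical fit. The primary p-value is the
Wilcoxon signed-rank test: subjects with a sparse factorial cell produce
quasi-separated coefficients whose magnitude is essentially arbitrary,
and a rank test keeps its nominal level where a mean-based t-test does
not; t statistics are reported alongside. Per-subject 95% interval flags
(estimate minus 1.96 SE above zero) mirror per-individual effect counts.

## Regressors

Event tables carry, per completed trial, the model-free RPE and the
difference regressor (model-based minus model-free; the sign is recorded
in the output, and analyses interpret only whether it loads) at the
second-stage onset and outcome, the difference orthogonalized against the
model-free series over all included events, and the trial-start
anticipatory value of the chosen first-stage action labeled by the
previous trial's reward × transition cell (switches, and the first trial,
form a fifth category). Two identities hold by construction and are
enforced in tests: the difference is exactly zero at outcomes, and the
orthogonalized difference has zero inner product with the model-free
series. No HRF convolution or volume timing is applied — imaging-level
design matrices are out of scope; the tables are event-level.

## Synthetic cohorts

Cohorts default to 17 subjects × 201 trials. Parameters are drawn per
subject around the mixed-effects point estimates (β₁ 4.23, β₂ 2.95,
α₁ 0.70, α₂ 0.40, λ 0.63, p 0.17): Gamma laws for temperatures, mean/SD
matched Beta laws for unit-interval parameters, Normal for perseveration,
each at a 25% coefficient of variation — a convention, since
between-subject spreads for these parameters are not published — and w
from a Beta law with mean 0.51 and SD 0.31, the one empirically anchored
spread. Zero-spread (degenerate) laws are supported for homogeneous
cohorts.

What the generator emulates: the task's generative process and a
population of hybrid learners with realistic parameter heterogeneity.
What it does not: response-time structure, within-session drift of w or
other parameters, lapses/attention failures, and any correlation between
parameters across subjects. Passing recovery tests therefore show the
estimation machinery is correct and well-calibrated under the model's own
assumptions, not that real choice data satisfy those assumptions.

## Problem sizes and numerical choices

Validation experiments use the study-scale defaults: signature cohorts of
20 agents × 201 trials; recovery over 10 replicate cohorts of 17 subjects
× 201 trials with 4 optimizer restarts per fit (restarts beyond this do
not change the recovered optima at these data sizes; the library default
for one-off fits remains 10). BMS cross-checks use 2–4 × 10⁵ Dirichlet
draws, enough to resolve exceedance probabilities to ~0.002. Likelihood
ties and zero-probability guards: softmax uses max-subtraction; the
orthogonalizer passes the target through (with a warning) when the
reference is identically zero.

## Known limitations

- The summary-statistics group regression is an approximation to the
  joint hierarchical fit; with few, short sessions its group means can be
  noisy even though the rank-based tests stay calibrated.
- Laplace evidence assumes a locally Gaussian posterior; for subjects
  whose MAP estimate sits near a prior boundary the approximation
  degrades (the positive-definiteness check catches the worst cases).
- The shared-w refit optimizes a 6 + n_subjects dimensional surface
  jointly; for large cohorts alternating schemes would scale better.
- w and λ trade off against the temperatures in short sessions; recovery
  of their absolute values at 201 trials is noisy (rank order is
  preserved much more reliably), which is why group-level summaries are
  reported alongside per-subject estimates.
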