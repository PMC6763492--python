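# Methods

This note records how the simulator is put together: the generative models,
the variational scheme, the precision mechanism, the choices made where the
design was genuinely open, and what the synthetic tasks do and do not
capture.

## Generative models and processes

Each task pairs a *generative model* (the agent's beliefs) with a
*generative process* (the world). Both share factor and modality spaces; the
process always carries the raw, unmodulated likelihoods and the true hidden
levels, while the model's likelihood is passed through the precision matrix.
This separation is what lets the colour/shape task express "the agent
believes the shape mapping is uninformative although in the world it is
deterministic", and is the entire mechanistic content of the TD/ASD and
safe/threat manipulations: the world never changes, only the model-side ζ.

All transition matrices are identities except the controllable *Where*
factor, for which action *a* moves fixation to location *a* from anywhere,
deterministically. Policies are single saccades (depth 1), one per location,
re-evaluated at every timestep; the planning horizon is therefore one step,
which is sufficient for every phenomenon simulated here and keeps policy
evaluation linear in the number of locations.

## State estimation

The trial-long posterior is factorised across hidden-state factors
(mean-field) but kept exact along time within each factor: one sweep
recomputes, for each factor in turn, the per-timestep log-evidence implied
by the observations and the other factors' current beliefs, runs exact
forward–backward smoothing along that factor's chain, and moves the
log-beliefs `v = ln s` a fractional `step_size` toward the result (a damped
gradient descent on the state prediction errors `ε = ln s* − v`), applying a
softmax after every update. Iteration stops when `max|ε| ≤ tol` or after
`n_iterations` sweeps.

Consequences worth knowing:

- With a single hidden factor the scheme is exact Bayes (the target does not
  depend on the factor's own beliefs), which the tests exploit by comparing
  converged posteriors against brute-force enumeration (KL < 1e-6 over 100
  random models).
- With several factors it is a structured mean-field approximation. Its
  accuracy degrades with likelihood coupling between latent factors; in the
  weak-coupling regime the tasks occupy (given the observed fixation
  location, each informative modality depends on one latent factor) the
  error stays below KL ≈ 1e-3, which is what the two-factor property test
  asserts at 5% cross-coupling. Strongly coupled random tables can make
  mean-field miss by orders more; no claim is made there.
- `step_size = 1` makes the sweep plain block coordinate ascent, which
  converges in a handful of sweeps on these models; the engine default is a
  conservative 0.25 with 16 sweeps. The bundled experiments use
  `step_size = 1, n_iterations = 16, tol = 1e-8` so that trials run fast
  and posteriors are converged to well below every decision margin.
- Timestep convention: the initial central fixation is t = 0; the first
  post-fixation saccade lands at t = 1. Future timesteps receive only
  neighbouring-timestep messages (pure prediction under the policy).

Unobserved-future prediction, free energy (complexity − accuracy over the
observed window) and the Bayesian model average follow the standard discrete
active-inference formulation. For a static single-factor model the free
energy at the exact posterior equals −ln(evidence), which is tested; for
chains with stochastic transitions the time-factorised complexity term makes
F an upper bound only.

## Expected free energy

For each policy, predictive state beliefs are propagated one step through B
and scored per modality:

- risk `o·(ln o − ln σ(C))` and ambiguity `H·s` (H the per-column outcome
  entropy);
- extrinsic value `o·ln σ(C)` and epistemic value, computed independently as
  the mutual information `Σ_s q(s) KL(A(·|s) ‖ o)`, so that the identity
  `risk + ambiguity = −(extrinsic + epistemic)` is a genuine numerical check
  (asserted to 1e-8) rather than a tautology;
- novelty `o·W·s` with `W = ½(1/a − 1/Σa)` from Dirichlet counts, active
  only while likelihoods are being learned.

Preferences are stored as unnormalised log-utilities (the colour/shape task
enters +2/−4 nats on right/wrong verbatim) and log-softmaxed inside the
risk/extrinsic computation.

## Precision modulation and floors

A modulated column is `softmax(ζ · ln max(p, ε))`. Two floors with different
jobs:

- **Modulation floor** `ε = exp(−8)`. This sets the assumed dynamic range
  (8 nats) of a log-likelihood mapping and thereby what fractional
  precisions mean: a one-hot column under precision ζ acquires
  off-probability `∝ exp(−8ζ)`. The value matters only where ζ is strictly
  between 0 and ∞ — the face task. With a much smaller floor (say 1e-16),
  ζ = 0.1 already yields a near-deterministic mapping, every face cell is
  identified in one fixation, and the safe/threat decision-time contrast
  collapses; 8 nats keeps the printed ζ values (0.1 / 0.25 / 0.9) on a
  graded scale. ζ = ∞ is a sentinel that copies the raw column bit-exactly,
  and ζ = 0 yields an exactly uniform column.
- **Log-safety floor** 1e-16, used when taking logs of probabilities during
  inference and free-energy evaluation, so that deterministic mappings
  provide ±37-nat evidence and resolved states have vanishing residual
  epistemic value (re-fixating a seen informative location is worth < 1e-6
  nats).

## Policy precision and action selection

- γ (policy precision) defaults to 1 in `EngineConfig`; the bundled
  experiments use γ = 4. The choice is analytic, not fitted: at the initial
  colour/shape fixation the G-gap between the informative and uninformative
  quadrants is exactly the category information ln 3, so the policy-odds
  ratio is `3^γ`; γ = 4 gives the near-deterministic, rule-respecting
  exploration described for these tasks (ratio 81) while any γ below ~2.1
  would leave the agent wandering. The β → γ update dynamics are not
  modelled; γ is a fixed scalar.
- Actions are sampled from the sharpened marginal `u^α` over next-step
  actions (α = 512 by default): effectively "take the most likely action,
  break exact ties at random". This reproduces both the deterministic
  scanpaths (colour-first trials always categorise at t = 2, shape-first at
  t = 3) and the genuinely random 50/50 choice at the salience tie.

## Tasks

**Colour/shape.** Eight locations: centre (1), four quadrants (2–5), three
choice locations (6–8). Only location 4 is informative about colour and
location 3 about shape; all other non-choice locations emit null in both
What modalities. Choice locations emit right/wrong feedback in the
rule-relevant modality (and null in the other), mapping choice location
6 + k to category k. The rule is cued unambiguously at every fixation; the
rule-indexed ζ matrix carries ∞ for Rule/Where and for the task-relevant
What modality, and the manipulated z for the task-irrelevant one.

**Yarbus.** Thirteen locations; furniture/clothing at {2,4,6,9,10,11},
faces at {3,5,7,8,12,13}. A scene is (wealth, age, scene-type): the
majority feature at each location class matches the category, and the scene
type selects a fixed exception table (0–2 of 6 locations deviate by a fixed
category offset), so the scene type is identifiable by looking and majority
vote always recovers the category. Three scene types per category by
default. There are no choice locations; trials run a fixed saccade budget
(12 for the instruction experiments) and the reported statistic is the
fixation proportion on objects vs faces vs centre, excluding the initial
central fixation. TD sets the task-irrelevant z to 0, ASD to ∞ — nothing
else differs between the groups, and the instruction give-the-ages stands
in for the empirical how-long-away instruction, both being face-directed.

**Face identification.** Context × Face type × Where (5 facial areas); a
10-outcome expressions modality (5 fearful-typical, 5 happy-typical
attributes, disjoint). The process maps (face type, area) to its typical
attribute deterministically; the trial starts fixating the forehead and
ends when the face-type posterior crosses the decision threshold, the
decision time being the number of areas fixated. The expressions ζ is
indexed by Context × Face type: fearful (0.1 safe, 0.9 threat), happy
(0.25, 0.25).

The **anxiety experiment threshold is 0.80** rather than the engine's 0.95
default, and this is a substantive choice: with disjoint attribute sets the
evidence for a happy face also depends on how sharp the *fearful* column is
(the likelihood ratio has the other hypothesis in its denominator), so
happy identification would inherit a context effect at high thresholds. At
the 8-nat floor, the single-observation likelihood ratios order as
fearful-safe (3.25) < happy-safe (5.07) < fearful-threat (16.3), and any
threshold with posterior odds in (3.25, 5.07] — e.g. 0.80 — yields exactly
the target pattern: fearful in 1 fixation under threat vs 2 under safe,
happy in 1 fixation in both contexts, with wide margins. Decision times are
deterministic per cell (the process is noiseless), so the bootstrap
intervals are degenerate; they are reported anyway for uniformity.

## Likelihood learning

Learnable modalities (Yarbus object/face) carry Dirichlet counts with prior
floor `a0 = 1e-3`; the model uses the normalised counts as its likelihood,
and counts update by `a += η · (outcome indicator ⊗ joint state beliefs)`.
During free exploration the flat likelihood provides no evidence about the
category/scene states, so increments are smeared uniformly over the 54
hidden category combinations; the prior mass per column must therefore be
small against the per-visit increment (1/54 of mass lands in each column),
which is why `a0` is 1e-3 and not the conventional 1. The learning metric
is correspondingly the location → feature conditional (counts marginalised
over all non-Where state axes) against the true mapping; it falls below
L1 = 0.1 at a location after about two visits, and the novelty term's
strict monotonicity in counts makes exploration near round-robin, so a
64-saccade budget gives every feature location 4–5 visits.

## What the synthetic scenes do and do not emulate

The generators reproduce the *structure* of the original stimuli — which
locations carry which information under which context — not their
appearance: there is no pixel rendering, no foveal/peripheral resolution
gradient, no saccade dynamics or latencies, and decision "times" are
fixation counts, not milliseconds. Scene statistics are idealised (uniform
category draws; deterministic feature placement given category and scene
type; noiseless outcomes). Passing tests therefore demonstrate that the
precision mechanism produces the qualitative attention patterns under these
idealised conditions; they say nothing about fits to human eye-tracking
data, and the simulated fixation proportions are expected to differ
quantitatively from empirical ones (a handful of discrete locations versus
continuous scanpaths).

## Problem sizes and reproducibility

The bundled statistics use 100 trials per colour/shape condition, 100
trials per Yarbus group × instruction cell (12 saccades each), 200 trials
per face cell, a 64-saccade learning run, and 1000 bootstrap resamples for
all intervals. One RNG per trial (seed = base seed + trial index, recorded
in the trial record); identical seeds and configs give bit-identical
records, summaries and output hashes.

## Known limitations

- Mean-field across factors: posteriors (and hence G) are approximate when
  latent factors are strongly coupled through a modality.
- Depth-1 policies cannot express multi-saccade plans; nothing here needs
  them, but tasks with delayed information structure would.
- γ/β dynamics, habit learning (E updates), transition learning and
  hierarchical models are out of scope.
- The face task's disjoint-attribute design makes identification speed
  threshold-sensitive (see above); an overlapping-attribute design would
  trade this for extra free parameters.
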