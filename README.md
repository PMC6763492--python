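# attnmdp

Active-inference simulations of **selective visual attention**: discrete-state
(POMDP) agents whose likelihood precision is modulated by their beliefs about
context, so that expected information gain — and hence saccadic sampling — is
directed only at task-relevant stimuli.

The package is aimed at computational cognitive scientists who want a small,
fully inspectable testbed for context-dependent epistemic foraging: it bundles
three classic visual-search settings (rule-based colour/shape categorisation,
instruction-dependent exploration of a painting, and happy/fearful face
identification under safe/threat contexts) together with the "pathology"
parameterisations in which attenuation of task-irrelevant precision fails
(an autism-like agent) or threat sharpens anxiogenic mappings (anxiety).

## The model

An agent holds a factorised generative model of a trial: hidden-state factors
`s^1..s^F` (rule/instruction/context, fixation location, scene categories)
generate categorical outcomes `o^m` in several modalities through likelihood
tensors **A**, evolve under transition matrices **B** (action-dependent for
the controllable *Where* factor), start from priors **D**, and are valued via
log-preferences **C**. Perception minimises variational free energy

    F = D_KL[Q(s) || P(s)] − E_Q[ln P(o | s)]          (complexity − accuracy)

and policies π (single saccades, re-planned at every step) are scored by the
expected free energy of their outcomes,

    G(π) = risk + ambiguity − novelty
         = −extrinsic value − epistemic value − novelty,

with `π = softmax(ln E − F − γ G)`. Epistemic value is the expected Bayesian
surprise (mutual information between hidden states and predicted outcomes);
novelty is the expected information gain about Dirichlet-parameterised
likelihoods and drives exploration while the scene layout is being learned.

Selective attention enters through a context-indexed precision matrix ζ: each
likelihood column is re-weighted as `softmax(ζ · ln A)`, with `ζ = ∞` leaving
the mapping untouched and `ζ = 0` flattening it. An imprecise mapping offers
no expected information gain, so the agent simply stops looking at stimuli
that are irrelevant under the inferred context — attention as part of
planning, not a filter applied after sampling.

## Worked example

```bash
$ attnmdp demo --seed 1
z=inf: loc1 -> loc3 -> loc4 -> loc6 (feedback at t=3)
z=0: loc1 -> loc4 -> loc8 (feedback at t=2)
```

Both trials categorise a scene by its colour (the rule is cued at the central
fixation, location 1; the colour object sits in the top-right quadrant,
location 4; the shape object, irrelevant under this rule, in the bottom-left
quadrant, location 3; locations 6–8 report a category and return feedback).
With full task-irrelevant precision (`z=inf`) the shape quadrant is exactly
as salient as the colour quadrant, the tie is broken at random — here toward
location 3 — and correct feedback arrives at timestep 3. With the
task-irrelevant precision attenuated (`z=0`) the agent ignores the shape
quadrant, saccades straight to the colour object and categorises one step
earlier, at timestep 2.

The same library functions drive the other experiments:

```python
from attnmdp.experiments import anxiety_experiment
res = anxiety_experiment(n_trials=50, seed=0)
{k: v["mean"] for k, v in res.summary.items()}
# {'happy/safe': 1.0, 'fearful/safe': 2.0, 'happy/threat': 1.0, 'fearful/threat': 1.0}
```

i.e. fearful faces are identified after fewer fixated facial areas in the
threat context than in the safe context, while happy-face identification is
unchanged — the anxiety pattern, produced purely by raising the
fearful-expression precision from 0.1 to 0.9 under threat.

CLI subcommands `contextual`, `yarbus-learn`, `yarbus-groups`, `anxiety`,
`validate-config` and `demo` write scanpath CSVs, summary JSON, config
snapshots and a hash manifest under `--out`.

## Layout

- `attnmdp.core` — model containers (factors, modalities, A/B/C/D tables),
  precision specs and the likelihood-modulation operations.
- `attnmdp.engine` — variational state estimation, free energy, expected
  free energy with the risk/ambiguity and value decompositions, policy and
  action selection, Dirichlet count updates, trial loop.
- `attnmdp.tasks` — builders for the three tasks and their scene samplers.
- `attnmdp.experiments` — experiment runners and statistics.
- `attnmdp.config` / `attnmdp.cli` — config validation, outputs, CLI.

See `docs/methods.md` for the modelling choices, numerical conventions and
known limitations.
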