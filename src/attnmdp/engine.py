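"""Belief updating, policy evaluation and action selection.

Perception is structured variational inference: the trial-long posterior is
factorised across hidden-state factors (a mean-field approximation), but kept
exact along time within each factor, so a single-factor model recovers exact
Bayesian smoothing.  Each sweep recomputes, for one factor, the per-timestep
log-evidence implied by the observations and the other factors' current
beliefs, runs forward-backward along the chain, and moves the log-beliefs a
fractional step toward the result (a damped gradient descent on the state
prediction errors).

Policies are scored by the path integral of expected free energy

    G = risk + ambiguity - novelty
      = -(extrinsic value) - (epistemic value) - novelty,

and the policy posterior is ``softmax(ln E - F - gamma * G)``.  An action is
then drawn from a sharpened marginal over next actions (near-argmax with
random tie-breaking), matching sampling "from the most likely policy".
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
from scipy.special import log_softmax, softmax, xlogy

from .core import (
    PROB_FLOOR,
    GenerativeModel,
    GenerativeProcess,
    PolicySet,
    entropy_vector,
    normalize_columns,
)

__all__ = [
    "EngineConfig",
    "BeliefArray",
    "EFEBreakdown",
    "DirichletCounts",
    "TrialRecord",
    "TrialTermination",
    "infer_states",
    "free_energy",
    "expected_outcomes",
    "expected_free_energy",
    "novelty_term",
    "policy_posterior",
    "select_action",
    "bayesian_model_average",
    "update_counts",
    "run_trial",
]


@dataclass(frozen=True)
class EngineConfig:
    """Numerical and behavioural knobs of the inference scheme.

    gamma : policy precision (inverse temperature of the policy softmax)
    n_iterations : maximum variational sweeps per perception step
    step_size : damping of the log-belief update toward the sweep target
    tol : convergence tolerance on the max absolute prediction error (nats)
    eta : learning rate for Dirichlet count updates
    decision_threshold : posterior mass that counts as an identification
    action_precision : sharpening (alpha) of the action marginal before
        sampling; large values approximate "take the most likely action,
        break exact ties at random"
    """

    gamma: float = 1.0
    n_iterations: int = 16
    step_size: float = 0.25
    tol: float = 1e-4
    eta: float = 1.0
    decision_threshold: float = 0.95
    action_precision: float = 512.0
    rng_seed: int = 0

    def __post_init__(self) -> None:
        if self.gamma < 0:
            raise ValueError("gamma must be >= 0")
        if not (0 < self.step_size <= 1):
            raise ValueError("step_size must lie in (0, 1]")
        if self.n_iterations < 1:
            raise ValueError("n_iterations must be >= 1")

    @property
    def beta(self) -> float:
        """Temperature of policy selection (1/gamma)."""
        return float("inf") if self.gamma == 0 else 1.0 / self.gamma


@dataclass
class BeliefArray:
    """Posterior marginals per factor and timestep, with log form and the
    last sweep's prediction errors."""

    s: dict[str, np.ndarray]        # factor -> (T, n_levels)
    v: dict[str, np.ndarray]        # log-beliefs (log-softmax normalised)
    eps: dict[str, np.ndarray]      # last prediction errors, same shape
    n_sweeps: int = 0
    converged: bool = False

    @property
    def horizon(self) -> int:
        return next(iter(self.s.values())).shape[0]

    def marginals_at(self, t: int) -> dict[str, np.ndarray]:
        return {f: self.s[f][t] for f in self.s}

    def max_error(self) -> float:
        return max(float(np.abs(e).max()) for e in self.eps.values())


@dataclass
class EFEBreakdown:
    """Per-policy decomposition of expected free energy (natural units)."""

    risk: np.ndarray
    ambiguity: np.ndarray
    extrinsic: np.ndarray
    epistemic: np.ndarray
    novelty: np.ndarray
    F: np.ndarray

    @property
    def G(self) -> np.ndarray:
        return self.risk + self.ambiguity - self.novelty

    def as_dict(self) -> dict[str, list[float]]:
        return {
            k: np.asarray(getattr(self, k)).tolist()
            for k in ("risk", "ambiguity", "extrinsic", "epistemic", "novelty", "F")
        } | {"G": self.G.tolist()}


@dataclass
class DirichletCounts:
    """Concentration counts over state-outcome pairs for learnable
    modalities; the novelty term and likelihood learning both read these."""

    a: dict[str, np.ndarray]
    a0: float = 1e-3

    def __post_init__(self) -> None:
        if self.a0 <= 0:
            raise ValueError("prior floor a0 must be positive")
        self.a = {m: np.asarray(t, dtype=float).copy() for m, t in self.a.items()}
        for m, t in self.a.items():
            if np.any(t < self.a0 - 1e-12):
                raise ValueError(f"counts for {m!r} fall below the prior floor")

    @classmethod
    def flat(cls, model: GenerativeModel, a0: float = 1e-3) -> "DirichletCounts":
        return cls(
            a={m: np.full_like(np.asarray(model.A[m]), a0) for m in model.learnable},
            a0=a0,
        )

    def expected_likelihood(self) -> dict[str, np.ndarray]:
        return {m: normalize_columns(t) for m, t in self.a.items()}


@dataclass
class TrialRecord:
    """Everything one simulated trial produced."""

    locations: list[int]                       # fixated location index per t
    observations: list[dict[str, int]]         # outcome index per modality
    actions: list[int]                         # chosen location per saccade
    policy_posteriors: list[np.ndarray]
    marginals: list[dict[str, np.ndarray]]     # BMA beliefs at each t
    efe: list[EFEBreakdown]
    decision_timestep: int | None
    seed: int

    @property
    def n_steps(self) -> int:
        return len(self.locations)


@dataclass(frozen=True)
class TrialTermination:
    """How a trial ends.

    kind 'feedback': ends when the fixated location (of ``where_factor``)
    enters ``locations``; decision_timestep is that t (initial fixation is
    t = 0, the first saccade lands at t = 1).
    kind 'threshold': ends when the posterior over ``factor`` exceeds the
    decision threshold; decision_timestep is the number of observations made.
    kind 'budget': runs the full saccade budget.
    """

    kind: str = "budget"
    locations: frozenset[int] = frozenset()
    factor: str | None = None

    def __post_init__(self) -> None:
        if self.kind not in ("feedback", "threshold", "budget"):
            raise ValueError(f"unknown termination kind {self.kind!r}")
        object.__setattr__(self, "locations", frozenset(self.locations))


# ---------------------------------------------------------------------------
# tensor contraction helpers
_LETTERS = "abcdefgh"


def _contract_all(tensor: np.ndarray, marginals: Sequence[np.ndarray]) -> np.ndarray:
    """Contract every state axis (axes 1..) with the factor marginals."""
    res = tensor
    for b in marginals:
        res = np.tensordot(res, b, axes=(1, 0))
    return res


def _contract_state(tensor: np.ndarray, marginals: Sequence[np.ndarray]) -> float:
    """Contract a state-shaped tensor (no outcome axis) to a scalar."""
    res = tensor
    for b in marginals:
        res = np.tensordot(res, b, axes=(0, 0))
    return float(res)


def _contract_except(
    tensor: np.ndarray, marginals: Sequence[np.ndarray], keep: int
) -> np.ndarray:
    """Contract all state axes except ``keep``; returns (n_outcomes, d_keep)."""
    k = len(marginals)
    subs_m = [_LETTERS[i] for i in range(k) if i != keep]
    ops = [tensor] + [marginals[i] for i in range(k) if i != keep]
    if not subs_m:
        return tensor
    ein = "z" + _LETTERS[:k] + "," + ",".join(subs_m) + "->z" + _LETTERS[keep]
    return np.einsum(ein, *ops)


def _safe_log(p: np.ndarray) -> np.ndarray:
    return np.log(np.maximum(p, PROB_FLOOR))


def _forward_backward(
    log_phi: np.ndarray,
    D: np.ndarray,
    B_seq: Sequence[np.ndarray],
) -> np.ndarray:
    """Exact smoothing for one factor's chain given local log-evidence.

    log_phi: (T, n) per-timestep log-evidence (zeros for unobserved steps);
    B_seq: T-1 transition matrices (next given previous).  Returns the
    (T, n) posterior marginals.
    """
    T, n = log_phi.shape
    phi = np.exp(log_phi - log_phi.max(axis=1, keepdims=True))
    alpha = np.empty((T, n))
    a = D * phi[0]
    alpha[0] = a / a.sum()
    for t in range(1, T):
        a = phi[t] * (B_seq[t - 1] @ alpha[t - 1])
        alpha[t] = a / a.sum()
    post = np.empty((T, n))
    post[T - 1] = alpha[T - 1]
    beta = np.ones(n)
    for t in range(T - 2, -1, -1):
        beta = B_seq[t].T @ (phi[t + 1] * beta)
        beta = beta / beta.sum()
        p = alpha[t] * beta
        post[t] = p / p.sum()
    return post


def _action_matrices(
    model: GenerativeModel, actions: Sequence[Mapping[str, int]], fname: str
) -> list[np.ndarray]:
    B = model.B[fname]
    return [B[:, :, int(a.get(fname, 0))] for a in actions]


def infer_states(
    model: GenerativeModel,
    observations: Sequence[Mapping[str, int]],
    actions: Sequence[Mapping[str, int]],
    config: EngineConfig,
    *,
    A: Mapping[str, np.ndarray] | None = None,
    horizon: int | None = None,
    warm_start: BeliefArray | None = None,
) -> BeliefArray:
    """Infer posteriors over every factor for timesteps 0..horizon-1.

    ``observations`` covers timesteps 0..t; ``actions`` is the action taken
    (or planned, for a policy) before each subsequent timestep, as
    factor-name -> action-index mappings.  Timesteps beyond the observed
    window receive only the neighbouring-timestep messages, i.e. they are
    pure predictions under the action sequence.
    """
    n_obs = len(observations)
    T = horizon if horizon is not None else max(n_obs, len(actions) + 1)
    if T < n_obs or len(actions) < T - 1:
        raise ValueError("horizon shorter than observations/actions")
    A = dict(A) if A is not None else model.modulated_A()
    for m in model.modalities:
        for o in (obs[m.name] for obs in observations):
            if not 0 <= int(o) < m.n:
                raise ValueError(
                    f"observation {o} outside outcomes of modality {m.name!r}"
                )
    logA = {m: _safe_log(np.asarray(A[m])) for m in A}
    names = model.factor_names

    # initial log-beliefs: warm start where available, flat elsewhere
    v: dict[str, np.ndarray] = {}
    for f in model.factors:
        vf = np.zeros((T, f.n))
        if warm_start is not None and f.name in warm_start.v:
            prev = warm_start.v[f.name]
            k = min(T, prev.shape[0])
            vf[:k] = prev[:k]
        v[f.name] = log_softmax(vf, axis=1)
    s = {f: softmax(v[f], axis=1) for f in v}
    eps = {f.name: np.zeros((T, f.n)) for f in model.factors}

    converged = False
    sweep = 0
    for sweep in range(1, config.n_iterations + 1):
        max_err = 0.0
        for k, f in enumerate(model.factors):
            log_phi = np.zeros((T, f.n))
            for tau in range(n_obs):
                marg = [s[n_][tau] for n_ in names]
                for m in model.modalities:
                    lik = _contract_except(logA[m.name], marg, k)
                    log_phi[tau] += lik[int(observations[tau][m.name])]
            B_seq = _action_matrices(model, actions[: T - 1], f.name)
            target = _forward_backward(log_phi, model.D[f.name], B_seq)
            log_target = _safe_log(target)
            log_target -= log_target.max(axis=1, keepdims=True)
            log_target = log_softmax(log_target, axis=1)
            e = log_target - v[f.name]
            eps[f.name] = e
            max_err = max(max_err, float(np.abs(e).max()))
            v[f.name] = log_softmax(v[f.name] + config.step_size * e, axis=1)
            s[f.name] = softmax(v[f.name], axis=1)
        if max_err <= config.tol:
            converged = True
            break
    return BeliefArray(s=s, v=v, eps=eps, n_sweeps=sweep, converged=converged)


def free_energy(
    beliefs: BeliefArray,
    observations: Sequence[Mapping[str, int]],
    actions: Sequence[Mapping[str, int]],
    model: GenerativeModel,
    *,
    A: Mapping[str, np.ndarray] | None = None,
) -> float:
    """Variational free energy of the observed window: complexity - accuracy.

    Complexity is the KL of each factor's marginal from its one-step
    prediction (the prior D at t = 0); accuracy is the expected
    log-likelihood of each observation under the posterior.  At the exact
    posterior of a single-factor model this equals -ln(evidence).
    """
    A = dict(A) if A is not None else model.modulated_A()
    logA = {m: _safe_log(np.asarray(A[m])) for m in A}
    names = model.factor_names
    F = 0.0
    for fname in names:
        S = beliefs.s[fname]
        B_seq = _action_matrices(model, actions, fname)
        for tau in range(len(observations)):
            prior = model.D[fname] if tau == 0 else B_seq[tau - 1] @ S[tau - 1]
            q = S[tau]
            F += float(np.sum(xlogy(q, q)) - q @ _safe_log(prior))
    for tau, obs in enumerate(observations):
        marg = [beliefs.s[n_][tau] for n_ in names]
        for m in model.modalities:
            lik = logA[m.name][int(obs[m.name])]
            res = lik
            for b in marg:
                res = np.tensordot(res, b, axes=(0, 0))
            F -= float(res)
    return F


def expected_outcomes(
    A: Mapping[str, np.ndarray], state_beliefs: Mapping[str, np.ndarray],
    factor_order: Sequence[str],
) -> dict[str, np.ndarray]:
    """Predictive outcome distribution per modality: o = A . (x) s_f."""
    marg = [np.asarray(state_beliefs[f]) for f in factor_order]
    return {m: _contract_all(np.asarray(A[m]), marg) for m in A}


def novelty_term(
    counts: DirichletCounts,
    predictive_outcomes: Mapping[str, np.ndarray],
    predictive_states: Mapping[str, np.ndarray],
    factor_order: Sequence[str],
) -> float:
    """Expected information gain about the likelihood parameters.

    Uses the count-based approximation W = (1/a - 1/sum(a))/2 contracted
    with predicted outcomes and states; non-negative, and shrinking as
    counts accumulate.
    """
    marg = [np.asarray(predictive_states[f]) for f in factor_order]
    total = 0.0
    for m, a in counts.a.items():
        W = 0.5 * (1.0 / a - 1.0 / a.sum(axis=0, keepdims=True))
        total += float(
            _contract_all(W, marg) @ np.asarray(predictive_outcomes[m])
        )
    return total


def expected_free_energy(
    model: GenerativeModel,
    state_beliefs: Mapping[str, np.ndarray],
    *,
    A: Mapping[str, np.ndarray] | None = None,
    counts: DirichletCounts | None = None,
) -> dict[str, float]:
    """One-step-ahead expected free energy terms for given predictive
    state beliefs (one policy, one future timestep).

    risk = o . (ln o - ln softmax(C));  ambiguity = H . s;
    extrinsic = o . ln softmax(C);  epistemic = I(s; o) under the
    predictive joint;  novelty from Dirichlet counts when learning.
    """
    A = dict(A) if A is not None else model.modulated_A()
    names = model.factor_names
    marg = [np.asarray(state_beliefs[f]) for f in names]
    H = entropy_vector(A)
    risk = ambiguity = extrinsic = epistemic = 0.0
    o_pred: dict[str, np.ndarray] = {}
    for m in model.modalities:
        Am = np.asarray(A[m.name])
        o = _contract_all(Am, marg)
        o_pred[m.name] = o
        lnC = log_softmax(model.C[m.name])
        risk += float(np.sum(xlogy(o, o)) - o @ lnC)
        extrinsic += float(o @ lnC)
        ambiguity += _contract_state(H[m.name], marg)
        # mutual information: sum_s q(s) KL(A(.|s) || o_pred)
        kl_s = xlogy(Am, Am).sum(axis=0) - np.tensordot(
            Am, _safe_log(o), axes=(0, 0)
        )
        epistemic += _contract_state(kl_s, marg)
    novelty = 0.0
    if counts is not None:
        novelty = novelty_term(counts, o_pred, state_beliefs, names)
    return {
        "risk": risk,
        "ambiguity": ambiguity,
        "extrinsic": extrinsic,
        "epistemic": epistemic,
        "novelty": novelty,
    }


def policy_posterior(
    F: np.ndarray, G: np.ndarray, config: EngineConfig, E: np.ndarray | None = None
) -> np.ndarray:
    """pi = softmax(ln E - F - gamma * G)."""
    G = np.asarray(G, dtype=float)
    F = np.broadcast_to(np.asarray(F, dtype=float), G.shape)
    if not (np.all(np.isfinite(F)) and np.all(np.isfinite(G))):
        raise ValueError("F and G must be finite")
    lnE = 0.0 if E is None else _safe_log(np.asarray(E, dtype=float))
    return softmax(lnE - F - config.gamma * G)


def select_action(
    posterior: np.ndarray,
    policies: PolicySet,
    rng: np.random.Generator,
    action_precision: float = 512.0,
) -> np.ndarray:
    """Sample the next action (one entry per factor) from the sharpened
    marginal over the policies' first-step actions."""
    first = policies.actions[:, 0, :]
    uniq, inverse = np.unique(first, axis=0, return_inverse=True)
    u = np.zeros(len(uniq))
    np.add.at(u, inverse, np.asarray(posterior, dtype=float))
    logu = np.where(u > 0, np.log(np.maximum(u, PROB_FLOOR)), -np.inf)
    p = softmax(action_precision * logu) if np.isfinite(action_precision) else None
    if p is None:  # pure argmax with random tie-break
        best = logu == logu.max()
        p = best / best.sum()
    idx = int(np.searchsorted(np.cumsum(p), rng.random(), side="right"))
    return uniq[min(idx, len(uniq) - 1)]


def bayesian_model_average(
    posterior: np.ndarray, per_policy: Sequence[Mapping[str, np.ndarray]]
) -> dict[str, np.ndarray]:
    """Policy-averaged state beliefs: s = sum_pi pi(pi) s^pi."""
    posterior = np.asarray(posterior, dtype=float)
    out: dict[str, np.ndarray] = {}
    for f in per_policy[0]:
        acc = sum(
            w * np.asarray(b[f]) for w, b in zip(posterior, per_policy)
        )
        out[f] = acc / acc.sum()
    return out


def update_counts(
    counts: DirichletCounts,
    observation: Mapping[str, int],
    marginals: Mapping[str, np.ndarray],
    eta: float,
    factor_order: Sequence[str],
) -> DirichletCounts:
    """a <- a + eta * (outcome indicator x joint state beliefs), in place,
    for the learnable modalities only."""
    joint = None
    for f in factor_order:
        b = np.asarray(marginals[f])
        joint = b if joint is None else np.multiply.outer(joint, b)
    for m, a in counts.a.items():
        a[int(observation[m])] += eta * joint
    return counts


def run_trial(
    model: GenerativeModel,
    process: GenerativeProcess,
    config: EngineConfig,
    T_max: int,
    *,
    termination: TrialTermination = TrialTermination(),
    where_factor: str = "where",
    counts: DirichletCounts | None = None,
    learn: bool = False,
) -> TrialRecord:
    """Run one perception-planning-action trial.

    ``T_max`` is the saccade budget (number of actions); the initial
    fixation is timestep 0.  Policies are one-step saccades re-evaluated at
    every timestep.  When ``learn`` is set, Dirichlet counts are updated
    after every observation and the learnable likelihoods are refreshed.
    """
    if T_max < 1:
        raise ValueError("T_max must be >= 1")
    rng = np.random.default_rng(config.rng_seed)
    names = model.factor_names
    ctrl_axis = names.index(where_factor)

    def current_A() -> dict[str, np.ndarray]:
        base = {m: np.asarray(model.A[m]) for m in model.A}
        if counts is not None:
            base.update(counts.expected_likelihood())
        if model.precision is not None:
            from .core import modulated_likelihood

            return modulated_likelihood(base, model.precision, model.factors)
        return base

    A_mod = current_A()
    obs_hist: list[dict[str, int]] = []
    act_hist: list[dict[str, int]] = []
    beliefs: BeliefArray | None = None

    locations: list[int] = []
    actions: list[int] = []
    posts: list[np.ndarray] = []
    margs: list[dict[str, np.ndarray]] = []
    efes: list[EFEBreakdown] = []
    decision: int | None = None

    for t in range(T_max + 1):
        locations.append(process.true_levels[where_factor])
        obs_hist.append(process.sample_outcomes(rng))
        beliefs = infer_states(
            model, obs_hist, act_hist, config, A=A_mod, warm_start=beliefs
        )
        marg_t = beliefs.marginals_at(t)
        margs.append({f: m.copy() for f, m in marg_t.items()})
        if learn and counts is not None:
            update_counts(counts, obs_hist[-1], marg_t, config.eta, names)
            A_mod = current_A()

        if termination.kind == "feedback" and locations[-1] in termination.locations:
            decision = t
            break
        if termination.kind == "threshold":
            if float(marg_t[termination.factor].max()) >= config.decision_threshold:
                decision = t + 1  # number of observations made
                break
        if t == T_max:
            break

        # policy evaluation: one-step lookahead per policy
        F = free_energy(beliefs, obs_hist, act_hist, model, A=A_mod)
        n_pol = model.policies.n
        terms = {k: np.zeros(n_pol) for k in
                 ("risk", "ambiguity", "extrinsic", "epistemic", "novelty")}
        for p in range(n_pol):
            avec = model.policies.actions[p, 0]
            pred = {
                f.name: model.B[f.name][:, :, int(avec[k_])] @ marg_t[f.name]
                for k_, f in enumerate(model.factors)
            }
            efe = expected_free_energy(
                model, pred, A=A_mod, counts=counts if learn else None
            )
            for k_ in terms:
                terms[k_][p] = efe[k_]
        breakdown = EFEBreakdown(F=np.full(n_pol, F), **terms)
        efes.append(breakdown)
        post = policy_posterior(
            breakdown.F, breakdown.G, config, model.policies.prior
        )
        posts.append(post)
        avec = select_action(post, model.policies, rng, config.action_precision)
        actions.append(int(avec[ctrl_axis]))
        act_map = {
            f.name: int(avec[k_]) for k_, f in enumerate(model.factors)
        }
        act_hist.append(act_map)
        process.step(act_map, rng)

    return TrialRecord(
        locations=locations,
        observations=obs_hist,
        actions=actions,
        policy_posteriors=posts,
        marginals=margs,
        efe=efes,
        decision_timestep=decision,
        seed=config.rng_seed,
    )
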