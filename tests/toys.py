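"""Small random generative models and brute-force oracles used by the tests.

The oracles enumerate joint state trajectories directly, independently of
the message-passing implementation they are checked against.
"""

from __future__ import annotations

from itertools import product

import numpy as np

from attnmdp.core import FactorSpec, GenerativeModel, ModalitySpec, PolicySet


def _random_columns(rng, n_out: int, dims: tuple[int, ...]) -> np.ndarray:
    t = np.moveaxis(rng.dirichlet(np.ones(n_out), size=dims), -1, 0)
    t = np.maximum(t, 0.02)
    return t / t.sum(axis=0)


def random_single_factor_model(
    rng: np.random.Generator, *, stochastic_B: bool = True
) -> GenerativeModel:
    """1 factor (2-4 levels), 1-2 modalities, optional random 2-action B."""
    n = int(rng.integers(2, 5))
    factor = FactorSpec("state", tuple(f"l{i}" for i in range(n)), stochastic_B)
    mods, A = [], {}
    for m in range(int(rng.integers(1, 3))):
        no = int(rng.integers(2, 5))
        mods.append(ModalitySpec(f"m{m}", tuple(f"o{i}" for i in range(no))))
        A[f"m{m}"] = _random_columns(rng, no, (n,))
    if stochastic_B:
        B = np.stack(
            [
                np.stack([rng.dirichlet(np.ones(n)) for _ in range(n)], axis=1)
                for _ in range(2)
            ],
            axis=2,
        )
    else:
        B = np.eye(n)[:, :, None]
    return GenerativeModel(
        factors=(factor,),
        modalities=tuple(mods),
        A=A,
        B={"state": B},
        C={m.name: np.zeros(m.n) for m in mods},
        D={"state": rng.dirichlet(np.ones(n))},
        policies=PolicySet(np.zeros((1, 1, 1), dtype=int)),
    )


def random_two_factor_model(
    rng: np.random.Generator, coupling: float = 0.05
) -> GenerativeModel:
    """Two static factors with weakly coupled likelihoods: each modality is
    driven by one factor, mixed with a ``coupling`` fraction of a random
    joint table (the regime the tasks occupy, where outcomes depend on one
    latent factor given the fixated location)."""
    d1, d2 = int(rng.integers(2, 4)), int(rng.integers(2, 4))
    factors = (
        FactorSpec("f0", tuple(f"a{i}" for i in range(d1))),
        FactorSpec("f1", tuple(f"b{i}" for i in range(d2))),
    )
    mods, A = [], {}
    for m, (drive, other) in enumerate(((0, d2), (1, d1))):
        no = int(rng.integers(2, 5))
        mods.append(ModalitySpec(f"m{m}", tuple(f"o{i}" for i in range(no))))
        own = _random_columns(rng, no, (d1 if drive == 0 else d2,))
        joint = _random_columns(rng, no, (d1, d2))
        base = own[:, :, None] * np.ones((1, 1, d2)) if drive == 0 else (
            own[:, None, :] * np.ones((1, d1, 1))
        )
        A[f"m{m}"] = (1 - coupling) * base + coupling * joint
    return GenerativeModel(
        factors=factors,
        modalities=tuple(mods),
        A=A,
        B={"f0": np.eye(d1)[:, :, None], "f1": np.eye(d2)[:, :, None]},
        C={m.name: np.zeros(m.n) for m in mods},
        D={"f0": rng.dirichlet(np.ones(d1)), "f1": rng.dirichlet(np.ones(d2))},
        policies=PolicySet(np.zeros((1, 1, 2), dtype=int)),
    )


def random_observations(rng, model, T: int):
    obs = [
        {m.name: int(rng.integers(m.n)) for m in model.modalities}
        for _ in range(T)
    ]
    n_act = max(model.B[f.name].shape[2] for f in model.factors)
    acts = [
        {
            f.name: int(rng.integers(model.B[f.name].shape[2]))
            for f in model.factors
        }
        for _ in range(T - 1)
    ]
    return obs, acts


def exact_marginals(model, obs_seq, act_seq):
    """Posterior marginals by exhaustive enumeration of joint trajectories."""
    dims = model.state_dims
    T = len(obs_seq)
    joint_states = list(product(*[range(d) for d in dims]))
    post = {f.name: np.zeros((T, f.n)) for f in model.factors}
    total = 0.0
    for traj in product(joint_states, repeat=T):
        p = 1.0
        for k, f in enumerate(model.factors):
            p *= model.D[f.name][traj[0][k]]
        for t in range(1, T):
            for k, f in enumerate(model.factors):
                a = act_seq[t - 1].get(f.name, 0)
                p *= model.B[f.name][traj[t][k], traj[t - 1][k], a]
        for t in range(T):
            for m in model.modalities:
                p *= model.A[m.name][(obs_seq[t][m.name],) + traj[t]]
        if p == 0:
            continue
        total += p
        for t in range(T):
            for k, f in enumerate(model.factors):
                post[f.name][t, traj[t][k]] += p
    for f in post:
        post[f] /= total
    return post, total


def max_kl(p_marginals, q_beliefs) -> float:
    """Largest KL(p || q) over factors and timesteps."""
    worst = 0.0
    for f, P in p_marginals.items():
        Q = q_beliefs.s[f]
        for t in range(P.shape[0]):
            p, q = P[t], np.maximum(Q[t], 1e-300)
            worst = max(worst, float(np.sum(np.where(p > 0, p * np.log(p / q), 0))))
    return worst


def efe_enumeration_oracle(model, state_beliefs):
    """Term-by-term expected free energy by direct summation over the joint
    state and outcome spaces (no shared code with the engine)."""
    names = [f.name for f in model.factors]
    dims = model.state_dims
    out = {"risk": 0.0, "ambiguity": 0.0, "extrinsic": 0.0, "epistemic": 0.0}
    states = list(product(*[range(d) for d in dims]))
    qs = {
        s: float(np.prod([state_beliefs[names[k]][s[k]] for k in range(len(s))]))
        for s in states
    }
    for m in model.modalities:
        A = model.A[m.name]
        lnC = np.asarray(model.C[m.name], dtype=float)
        lnC = lnC - np.log(np.exp(lnC).sum())
        o_pred = np.zeros(m.n)
        for s in states:
            for o in range(m.n):
                o_pred[o] += qs[s] * A[(o,) + s]
        for o in range(m.n):
            if o_pred[o] > 0:
                out["risk"] += o_pred[o] * (np.log(o_pred[o]) - lnC[o])
            out["extrinsic"] += o_pred[o] * lnC[o]
        for s in states:
            for o in range(m.n):
                a = A[(o,) + s]
                if a > 0:
                    out["ambiguity"] += -qs[s] * a * np.log(a)
                    if o_pred[o] > 0:
                        out["epistemic"] += qs[s] * a * np.log(a / o_pred[o])
    return out
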