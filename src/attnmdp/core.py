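"""Discrete generative models with context-dependent likelihood precision.

The agent's world model is a factorised partially observed Markov decision
process: hidden state *factors* (e.g. Rule, Where, Category) jointly cause
categorical *outcomes* in several modalities through a likelihood tensor
``A``, evolve under per-factor transition matrices ``B`` (action-dependent
for controllable factors), start from priors ``D``, and are valued through
log-preferences ``C``.

Selective attention enters through a :class:`PrecisionSpec`: for each
modality, a precision ``zeta`` indexed by the joint level of one or more
*context* factors is applied to the log-likelihood column and renormalised,

    P(o | s) = softmax(zeta * ln A_raw(o | s)).

``zeta = inf`` is a sentinel meaning the raw column is used unchanged
(a deterministic mapping stays deterministic); ``zeta = 0`` yields a uniform
column, so the outcome carries no information about the state.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
from scipy.special import softmax, xlogy

__all__ = [
    "LOG_FLOOR",
    "MOD_FLOOR",
    "PROB_FLOOR",
    "FactorSpec",
    "ModalitySpec",
    "PrecisionSpec",
    "PolicySet",
    "GenerativeModel",
    "GenerativeProcess",
    "normalize_columns",
    "apply_precision",
    "modulated_likelihood",
    "entropy_vector",
]

#: Log-space floor (nats) assumed for zero entries when a finite precision is
#: applied to a likelihood column.  Defines the dynamic range of the mapping:
#: a one-hot column under precision zeta has off-probability ~ exp(zeta*LOG_FLOOR),
#: so fractional precisions in (0, 1) produce graded ambiguity.
LOG_FLOOR = -8.0
MOD_FLOOR = float(np.exp(LOG_FLOOR))

#: Much smaller floor used purely for numerical safety when taking logs of
#: probabilities during inference and free-energy evaluation.
PROB_FLOOR = 1e-16

COL_TOL = 1e-10


def _check_unique(labels: Sequence[str], what: str) -> None:
    if len(set(labels)) != len(labels):
        raise ValueError(f"duplicate {what} labels: {labels!r}")


@dataclass(frozen=True)
class FactorSpec:
    """A hidden-state dimension: named, discrete, optionally controllable."""

    name: str
    levels: tuple[str, ...]
    controllable: bool = False

    def __post_init__(self) -> None:
        object.__setattr__(self, "levels", tuple(self.levels))
        if len(self.levels) < 2:
            raise ValueError(f"factor {self.name!r} needs >= 2 levels")
        _check_unique(self.levels, f"level ({self.name})")

    @property
    def n(self) -> int:
        return len(self.levels)


@dataclass(frozen=True)
class ModalitySpec:
    """An outcome modality: a named set of mutually exclusive outcomes."""

    name: str
    outcomes: tuple[str, ...]

    def __post_init__(self) -> None:
        object.__setattr__(self, "outcomes", tuple(self.outcomes))
        if len(self.outcomes) < 1:
            raise ValueError(f"modality {self.name!r} needs outcomes")
        _check_unique(self.outcomes, f"outcome ({self.name})")

    @property
    def n(self) -> int:
        return len(self.outcomes)


@dataclass(frozen=True)
class PrecisionSpec:
    """Per-modality likelihood precisions indexed by joint context level.

    ``zeta[m]`` is an array whose shape matches the level counts of
    ``context_factors`` (one axis per context factor).  ``np.inf`` entries are
    the pass-through sentinel; finite entries rescale the log-likelihood.
    ``z`` records the manipulated scalar that was written into the matrix
    (for reporting only).
    """

    context_factors: tuple[str, ...]
    zeta: Mapping[str, np.ndarray]
    z: float | None = None

    def __post_init__(self) -> None:
        object.__setattr__(self, "context_factors", tuple(self.context_factors))
        zeta = {m: np.asarray(t, dtype=float) for m, t in self.zeta.items()}
        for m, table in zeta.items():
            if np.any(table < 0) or np.any(np.isnan(table)):
                raise ValueError(f"negative or NaN precision for modality {m!r}")
        object.__setattr__(self, "zeta", zeta)

    def table_for(self, modality: str) -> np.ndarray:
        try:
            return self.zeta[modality]
        except KeyError:
            raise KeyError(f"no precision entries for modality {modality!r}") from None


@dataclass(frozen=True)
class PolicySet:
    """Candidate action sequences.

    ``actions`` has shape ``(n_policies, depth, n_factors)``; uncontrollable
    factors carry the null action 0 at every step.  ``prior`` is the habit
    vector E (flat by default).
    """

    actions: np.ndarray
    prior: np.ndarray | None = None

    def __post_init__(self) -> None:
        actions = np.asarray(self.actions, dtype=int)
        if actions.ndim != 3 or actions.shape[0] < 1:
            raise ValueError("policies must be a non-empty (n, depth, n_factors) array")
        object.__setattr__(self, "actions", actions)
        prior = self.prior
        if prior is None:
            prior = np.full(actions.shape[0], 1.0 / actions.shape[0])
        prior = np.asarray(prior, dtype=float)
        if prior.shape != (actions.shape[0],) or abs(prior.sum() - 1.0) > COL_TOL:
            raise ValueError("policy prior E must be a distribution over policies")
        object.__setattr__(self, "prior", prior)

    @property
    def n(self) -> int:
        return int(self.actions.shape[0])

    @property
    def depth(self) -> int:
        return int(self.actions.shape[1])


def normalize_columns(table: np.ndarray) -> np.ndarray:
    """Normalise a non-negative table so each column (axis 0) sums to one.

    A column is everything obtained by fixing all trailing indices.  Zero-sum
    columns are construction errors and raise, naming the offending column.
    """
    table = np.asarray(table, dtype=float)
    if np.any(table < 0):
        raise ValueError("table has negative entries")
    sums = table.sum(axis=0)
    bad = np.asarray(sums <= 0.0)
    if bad.any():
        idx = np.argwhere(bad)[0]
        raise ValueError(f"zero-sum column at index {tuple(int(i) for i in idx)}")
    return table / sums


def apply_precision(
    raw_column: np.ndarray, zeta: float, floor: float = MOD_FLOOR
) -> np.ndarray:
    """Re-weight one likelihood column by a precision ``zeta``.

    Returns ``softmax(zeta * ln max(p, floor))``; equivalently
    ``p^zeta / sum(p^zeta)`` for floored entries.  ``zeta = inf`` returns the
    raw column unchanged; ``zeta = 0`` returns the uniform distribution.
    """
    p = np.asarray(raw_column, dtype=float)
    if zeta < 0 or np.isnan(zeta):
        raise ValueError(f"precision must be >= 0, got {zeta}")
    if np.isinf(zeta):
        return p.copy()
    return softmax(zeta * np.log(np.maximum(p, floor)))


def modulated_likelihood(
    raw: Mapping[str, np.ndarray],
    spec: PrecisionSpec,
    factors: Sequence[FactorSpec],
    floor: float = MOD_FLOOR,
) -> dict[str, np.ndarray]:
    """Apply a :class:`PrecisionSpec` to every column of every modality.

    Each modality's tensor has shape ``(n_outcomes, *factor_levels)``; the
    precision used for a column is the ``zeta`` entry at that column's joint
    context level.  Columns with the ``inf`` sentinel are copied bit-exactly.
    """
    names = [f.name for f in factors]
    ctx_axes = []
    for cname in spec.context_factors:
        if cname not in names:
            raise KeyError(f"context factor {cname!r} not in model factors {names}")
        ctx_axes.append(names.index(cname))

    out: dict[str, np.ndarray] = {}
    for m, A in raw.items():
        A = np.asarray(A, dtype=float)
        table = spec.table_for(m)
        expected = tuple(factors[ax].n for ax in ctx_axes)
        if table.shape != expected:
            raise ValueError(
                f"precision table for {m!r} has shape {table.shape}, "
                f"expected {expected} (context levels)"
            )
        # broadcast zeta over the state shape, zeta axes aligned to context
        # factor positions; axis 0 of A is outcomes
        order = np.argsort(ctx_axes)
        z_sorted = np.transpose(table, axes=order) if table.ndim > 1 else table
        tgt_shape = [1] * (A.ndim - 1)
        for ax, nlev in zip(sorted(ctx_axes), z_sorted.shape):
            tgt_shape[ax] = nlev
        zb = z_sorted.reshape(tgt_shape)
        zb = np.broadcast_to(zb, A.shape[1:])[None, ...]  # (1, *state_dims)

        logp = np.log(np.maximum(A, floor))
        finite = np.isfinite(zb)
        scaled = np.where(finite, zb, 0.0) * logp
        mod = softmax(scaled, axis=0)
        out[m] = np.where(np.broadcast_to(finite, A.shape), mod, A)
    return out


def entropy_vector(A: Mapping[str, np.ndarray]) -> dict[str, np.ndarray]:
    """Outcome entropy of every likelihood column, per modality (nats)."""
    return {
        m: -xlogy(np.asarray(t), np.asarray(t)).sum(axis=0) for m, t in A.items()
    }


@dataclass
class GenerativeModel:
    """The agent's beliefs: factors, modalities and the A/B/C/D tables."""

    factors: tuple[FactorSpec, ...]
    modalities: tuple[ModalitySpec, ...]
    A: dict[str, np.ndarray]
    B: dict[str, np.ndarray]
    C: dict[str, np.ndarray]
    D: dict[str, np.ndarray]
    policies: PolicySet
    precision: PrecisionSpec | None = None
    learnable: frozenset[str] = field(default_factory=frozenset)

    def __post_init__(self) -> None:
        self.factors = tuple(self.factors)
        self.modalities = tuple(self.modalities)
        self.learnable = frozenset(self.learnable)
        self.validate()

    # -- indexing helpers -------------------------------------------------
    @property
    def factor_names(self) -> list[str]:
        return [f.name for f in self.factors]

    @property
    def modality_names(self) -> list[str]:
        return [m.name for m in self.modalities]

    @property
    def state_dims(self) -> tuple[int, ...]:
        return tuple(f.n for f in self.factors)

    def factor(self, name: str) -> FactorSpec:
        for f in self.factors:
            if f.name == name:
                return f
        raise KeyError(name)

    def factor_axis(self, name: str) -> int:
        return self.factor_names.index(name)

    def modality(self, name: str) -> ModalitySpec:
        for m in self.modalities:
            if m.name == name:
                return m
        raise KeyError(name)

    # -- validation -------------------------------------------------------
    def validate(self) -> None:
        dims = self.state_dims
        _check_unique(self.factor_names, "factor")
        _check_unique(self.modality_names, "modality")
        for m in self.modalities:
            A = np.asarray(self.A[m.name], dtype=float)
            if A.shape != (m.n, *dims):
                raise ValueError(
                    f"A[{m.name!r}] shape {A.shape} != {(m.n, *dims)}"
                )
            if np.any(A < 0):
                raise ValueError(f"A[{m.name!r}] has negative entries")
            if not np.allclose(A.sum(axis=0), 1.0, atol=COL_TOL):
                raise ValueError(f"A[{m.name!r}] columns do not sum to 1")
            self.A[m.name] = A
        for f in self.factors:
            B = np.asarray(self.B[f.name], dtype=float)
            if B.ndim != 3 or B.shape[0] != f.n or B.shape[1] != f.n:
                raise ValueError(f"B[{f.name!r}] must be (n, n, n_actions)")
            if not np.allclose(B.sum(axis=0), 1.0, atol=COL_TOL):
                raise ValueError(f"B[{f.name!r}] columns do not sum to 1")
            if not f.controllable:
                if B.shape[2] != 1 or not np.array_equal(B[:, :, 0], np.eye(f.n)):
                    raise ValueError(
                        f"uncontrollable factor {f.name!r} must carry exactly "
                        "the identity transition"
                    )
            self.B[f.name] = B
            D = np.asarray(self.D[f.name], dtype=float)
            if D.shape != (f.n,) or abs(D.sum() - 1.0) > COL_TOL or np.any(D < 0):
                raise ValueError(f"D[{f.name!r}] must be a distribution")
            self.D[f.name] = D
        for m in self.modalities:
            C = np.asarray(self.C.get(m.name, np.zeros(m.n)), dtype=float)
            if C.shape != (m.n,) or not np.all(np.isfinite(C)):
                raise ValueError(f"C[{m.name!r}] must be finite with shape ({m.n},)")
            self.C[m.name] = C
        n_fac = len(self.factors)
        if self.policies.actions.shape[2] != n_fac:
            raise ValueError("policy action array does not match factor count")
        for k, f in enumerate(self.factors):
            if np.any(self.policies.actions[:, :, k] >= self.B[f.name].shape[2]):
                raise ValueError(f"policy action out of range for factor {f.name!r}")
        if self.precision is not None:
            for m in self.modalities:
                self.precision.table_for(m.name)

    # -- derived quantities ----------------------------------------------
    def modulated_A(self) -> dict[str, np.ndarray]:
        """The attention-weighted likelihood the agent actually uses."""
        if self.precision is None:
            return {m: a.copy() for m, a in self.A.items()}
        return modulated_likelihood(self.A, self.precision, self.factors)


@dataclass
class GenerativeProcess:
    """The real world: true states and the unmodulated outcome sampler."""

    factors: tuple[FactorSpec, ...]
    modalities: tuple[ModalitySpec, ...]
    A: dict[str, np.ndarray]
    B: dict[str, np.ndarray]
    true_levels: dict[str, int]

    def __post_init__(self) -> None:
        self.factors = tuple(self.factors)
        self.modalities = tuple(self.modalities)
        for f in self.factors:
            lev = self.true_levels[f.name]
            if not 0 <= lev < f.n:
                raise ValueError(f"true level {lev} out of range for {f.name!r}")

    @property
    def state_index(self) -> tuple[int, ...]:
        return tuple(self.true_levels[f.name] for f in self.factors)

    def outcome_distribution(self, modality: str) -> np.ndarray:
        idx = (slice(None),) + self.state_index
        return np.asarray(self.A[modality])[idx]

    def sample_outcomes(self, rng: np.random.Generator) -> dict[str, int]:
        """Draw one outcome per modality (fixed modality order, one uniform
        draw each, via inverse CDF) at the current true state."""
        obs: dict[str, int] = {}
        for m in self.modalities:
            col = self.outcome_distribution(m.name)
            u = rng.random()
            obs[m.name] = int(np.searchsorted(np.cumsum(col), u, side="right"))
        return obs

    def step(self, actions: Mapping[str, int], rng: np.random.Generator) -> None:
        """Advance every factor one step under the given per-factor actions."""
        for f in self.factors:
            a = int(actions.get(f.name, 0))
            col = np.asarray(self.B[f.name])[:, self.true_levels[f.name], a]
            u = rng.random()
            self.true_levels[f.name] = int(
                np.searchsorted(np.cumsum(col), u, side="right")
            )
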