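"""Experiment runners: contextual exploration, Yarbus learning and
instruction effects (TD/ASD), and anxiety-modulated face identification.

Each runner assembles a task, simulates seeded trials (one RNG per trial,
seed = base seed + trial index), and reduces the records to the summary
statistics the corresponding figures report: scanpath heat values,
learning curves, fixation proportions by location class, and decision
times with bootstrap confidence intervals.
"""

from __future__ import annotations

from dataclasses import dataclass, replace
from typing import Iterable, Mapping, Sequence

import numpy as np

from .core import GenerativeProcess
from .engine import (
    DirichletCounts,
    EngineConfig,
    TrialRecord,
    TrialTermination,
    run_trial,
)
from . import tasks
from .tasks import (
    CONTEXTS,
    FACE_LOCATIONS,
    FACE_TYPES,
    INSTRUCTIONS,
    OBJECT_LOCATIONS,
    build_colour_shape,
    build_face,
    build_yarbus,
    colour_shape_termination,
    face_termination,
    sample_colour_shape_scene,
    sample_yarbus_scene,
)

__all__ = [
    "DEFAULT_ENGINE",
    "ExperimentResult",
    "bootstrap_ci",
    "fixation_proportions",
    "decision_time",
    "contextual_exploration",
    "free_exploration_learning",
    "yarbus_instruction_experiment",
    "anxiety_experiment",
    "YARBUS_LOCATION_CLASSES",
]

#: Engine settings used by the bundled experiments: a policy precision high
#: enough that exploration is near-deterministic except at exact salience
#: ties (gamma = 4), and undamped coordinate sweeps, which converge in a few
#: iterations on these models.
DEFAULT_ENGINE = EngineConfig(gamma=4.0, n_iterations=16, step_size=1.0, tol=1e-8)

#: Partition of the 13 Yarbus locations used for fixation proportions.
YARBUS_LOCATION_CLASSES: dict[str, frozenset[int]] = {
    "objects": frozenset(OBJECT_LOCATIONS),
    "faces": frozenset(FACE_LOCATIONS),
    "centre": frozenset({1}),
}

N_BOOTSTRAP = 1000


@dataclass
class ExperimentResult:
    """Per-condition trial records plus the statistics derived from them."""

    conditions: dict[str, list[TrialRecord]]
    summary: dict[str, dict]
    config: dict
    seeds: dict[str, list[int]]

    def records(self, condition: str) -> list[TrialRecord]:
        return self.conditions[condition]


def bootstrap_ci(
    values: Sequence[float],
    rng: np.random.Generator,
    n_boot: int = N_BOOTSTRAP,
    level: float = 0.95,
) -> tuple[float, float]:
    """Percentile bootstrap interval for the mean."""
    values = np.asarray(values, dtype=float)
    if values.size == 0:
        raise ValueError("cannot bootstrap an empty sample")
    idx = rng.integers(0, values.size, size=(n_boot, values.size))
    means = values[idx].mean(axis=1)
    lo, hi = np.quantile(means, [(1 - level) / 2, 1 - (1 - level) / 2])
    return float(lo), float(hi)


def _summarize(values: Sequence[float], rng: np.random.Generator) -> dict:
    lo, hi = bootstrap_ci(values, rng)
    return {
        "mean": float(np.mean(values)),
        "ci95": [lo, hi],
        "n": int(len(values)),
        "values": [float(v) for v in values],
    }


def fixation_proportions(
    records: Sequence[TrialRecord],
    location_classes: Mapping[str, Iterable[int]],
) -> dict[str, float]:
    """Fraction of fixations per location class, pooled over records.

    ``location_classes`` maps class name -> 1-based locations and must
    partition the task's location set.  The initial (t = 0) fixation of
    each record is excluded.
    """
    classes = {k: frozenset(v) for k, v in location_classes.items()}
    all_locs = [loc for s in classes.values() for loc in s]
    if len(all_locs) != len(set(all_locs)):
        raise ValueError("location classes overlap")
    universe = set(all_locs)
    counts = {k: 0 for k in classes}
    total = 0
    for rec in records:
        for loc0 in rec.locations[1:]:
            loc = loc0 + 1
            if loc not in universe:
                raise ValueError(f"location {loc} not covered by the classes")
            for k, s in classes.items():
                if loc in s:
                    counts[k] += 1
            total += 1
    if total == 0:
        raise ValueError("no post-initial fixations in the records")
    return {k: counts[k] / total for k in classes}


def decision_time(
    record: TrialRecord, threshold: float, factor: str = "face_type"
) -> int | None:
    """Number of fixations before the posterior over ``factor`` crosses
    ``threshold`` (1 = decided on the first observation); None if the
    budget ran out first."""
    for t, marg in enumerate(record.marginals):
        if float(np.asarray(marg[factor]).max()) >= threshold:
            return t + 1
    return None


# ---------------------------------------------------------------------------
# colour/shape: contextual exploration (two task-irrelevant precision levels)
def contextual_exploration(
    z_irrelevant: Sequence[float] = (np.inf, 0.0),
    n_trials: int = 100,
    seed: int = 0,
    engine: EngineConfig | None = None,
) -> ExperimentResult:
    """Explore colour scenes under the rule categorise-colour for each
    task-irrelevant (shape) precision level.

    Summaries per condition: categorisation accuracy, mean feedback
    timestep, the fraction of trials that fixated the shape quadrant before
    categorising, and the mean policy posterior over the 8 locations at the
    initial fixation (the salience heat map).
    """
    engine = engine or DEFAULT_ENGINE
    conditions: dict[str, list[TrialRecord]] = {}
    summary: dict[str, dict] = {}
    seeds: dict[str, list[int]] = {}
    for ci, z in enumerate(z_irrelevant):
        label = f"z={z:g}"
        model, make_process = build_colour_shape(z_shape=float(z))
        scene_rng = np.random.default_rng(seed + 7919 * (ci + 1))
        recs: list[TrialRecord] = []
        used: list[int] = []
        for i in range(n_trials):
            s = sample_colour_shape_scene(scene_rng)
            scene = replace(s, rule="categorise-colour")
            trial_seed = seed + i
            rec = run_trial(
                model,
                make_process(scene),
                replace(engine, rng_seed=trial_seed),
                T_max=10,
                termination=colour_shape_termination(),
            )
            recs.append(rec)
            used.append(trial_seed)
        conditions[label] = recs
        seeds[label] = used
        right_idx = len(tasks.COLOURS) + 1  # outcomes: r,g,b,null,right,wrong
        acc = [
            float(r.observations[r.decision_timestep]["colours"] == right_idx)
            for r in recs
        ]
        visited_shape = [
            float(
                (tasks.SHAPE_QUADRANT - 1) in r.locations[1 : r.decision_timestep]
            )
            for r in recs
        ]
        stat_rng = np.random.default_rng(seed + 104729)
        summary[label] = {
            "accuracy": float(np.mean(acc)),
            "decision_timestep": _summarize(
                [float(r.decision_timestep) for r in recs], stat_rng
            ),
            "shape_quadrant_before_decision": float(np.mean(visited_shape)),
            "initial_policy_heat": np.mean(
                [r.policy_posteriors[0] for r in recs], axis=0
            ).tolist(),
        }
    return ExperimentResult(
        conditions=conditions,
        summary=summary,
        config={
            "experiment": "contextual_exploration",
            "z_irrelevant": [float(z) for z in z_irrelevant],
            "n_trials": n_trials,
            "seed": seed,
            "engine": engine.__dict__ | {},
        },
        seeds=seeds,
    )


# ---------------------------------------------------------------------------
# Yarbus: likelihood learning during free exploration
def _counts_location_mapping(a: np.ndarray) -> np.ndarray:
    """Normalized location -> feature conditional implied by counts:
    marginalise the concentration counts over every non-Where state axis."""
    marg = a.sum(axis=tuple(ax for ax in range(1, a.ndim) if ax != 2))
    return marg / marg.sum(axis=0, keepdims=True)


def _true_location_mapping(process: GenerativeProcess, modality: str) -> np.ndarray:
    A = np.asarray(process.A[modality])
    idx = process.state_index
    n_loc = A.shape[2]
    cols = np.stack(
        [A[(slice(None), idx[0], j, *idx[2:])] for j in range(n_loc)], axis=1
    )
    return cols


def free_exploration_learning(
    n_saccades: int = 64,
    seed: int = 0,
    engine: EngineConfig | None = None,
) -> dict:
    """Free exploration of one Yarbus scene with Dirichlet likelihood
    learning (context-naive: both precision columns at infinity).

    Returns the learning curve — after each observation, the mean L1
    distance between the counts-implied location->feature mapping and the
    true one, averaged over the 12 feature locations and both modalities —
    plus the final per-location distances and visit record.
    """
    engine = engine or DEFAULT_ENGINE
    model, make_process = build_yarbus(z=np.inf, learnable=True)
    scene_rng = np.random.default_rng(seed + 3571)
    scene = sample_yarbus_scene(scene_rng)
    process = make_process(scene)
    counts = DirichletCounts.flat(model)
    rec = run_trial(
        model,
        process,
        replace(engine, rng_seed=seed),
        T_max=n_saccades,
        termination=TrialTermination(kind="budget"),
        counts=counts,
        learn=True,
    )
    # reconstruct the counts trajectory from the stored record
    feature_locs = {
        "object": [loc - 1 for loc in OBJECT_LOCATIONS],
        "face": [loc - 1 for loc in FACE_LOCATIONS],
    }
    true_maps = {m: _true_location_mapping(process, m) for m in feature_locs}
    a_run = {m: np.full_like(np.asarray(model.A[m]), counts.a0) for m in feature_locs}
    names = model.factor_names

    def distances() -> dict[str, np.ndarray]:
        out = {}
        for m, locs in feature_locs.items():
            est = _counts_location_mapping(a_run[m])
            out[m] = np.abs(est - true_maps[m]).sum(axis=0)[locs]
        return out

    curve = [float(np.mean(np.concatenate(list(distances().values()))))]
    for obs, marg in zip(rec.observations, rec.marginals):
        joint = None
        for f in names:
            b = np.asarray(marg[f])
            joint = b if joint is None else np.multiply.outer(joint, b)
        for m in feature_locs:
            a_run[m][int(obs[m])] += engine.eta * joint
        curve.append(float(np.mean(np.concatenate(list(distances().values())))))
    per_loc = distances()
    visited = sorted({loc + 1 for loc in rec.locations})
    return {
        "curve": np.asarray(curve),
        "final_l1": {m: per_loc[m].tolist() for m in per_loc},
        "visited": visited,
        "scene": {
            "wealth": scene.wealth,
            "age": scene.age,
            "scene_type": scene.scene_type,
        },
        "record": rec,
        "counts": counts,
        "baseline": float(curve[0]),
    }


# ---------------------------------------------------------------------------
# Yarbus: instruction x group (TD vs ASD) fixation proportions
def yarbus_instruction_experiment(
    group: str,
    instruction: str,
    n_trials: int = 100,
    seed: int = 0,
    engine: EngineConfig | None = None,
    n_saccades: int = 12,
) -> ExperimentResult:
    """Fixation proportions on objects vs faces under one instruction.

    TD agents attenuate task-irrelevant precision (z = 0); the ASD
    parameterisation cannot (z = inf).  The model otherwise uses the true
    scene likelihoods (layout knowledge acquired beforehand).
    """
    if group not in ("TD", "ASD"):
        raise ValueError(f"unknown group {group!r} (expected 'TD' or 'ASD')")
    if instruction not in INSTRUCTIONS:
        raise ValueError(f"unknown instruction {instruction!r}")
    engine = engine or DEFAULT_ENGINE
    z = 0.0 if group == "TD" else np.inf
    model, make_process = build_yarbus(z=z)
    scene_rng = np.random.default_rng(seed + 6397)
    recs: list[TrialRecord] = []
    used: list[int] = []
    for i in range(n_trials):
        scene = sample_yarbus_scene(scene_rng)
        process = make_process(scene)
        process.true_levels["instruction"] = INSTRUCTIONS.index(instruction)
        trial_seed = seed + i
        rec = run_trial(
            model,
            process,
            replace(engine, rng_seed=trial_seed),
            T_max=n_saccades,
            termination=TrialTermination(kind="budget"),
        )
        recs.append(rec)
        used.append(trial_seed)
    per_trial = {
        k: [fixation_proportions([r], YARBUS_LOCATION_CLASSES)[k] for r in recs]
        for k in YARBUS_LOCATION_CLASSES
    }
    stat_rng = np.random.default_rng(seed + 104729)
    label = f"{group}/{instruction}"
    summary = {
        label: {
            cls: _summarize(vals, stat_rng) for cls, vals in per_trial.items()
        }
    }
    return ExperimentResult(
        conditions={label: recs},
        summary=summary,
        config={
            "experiment": "yarbus_instruction",
            "group": group,
            "instruction": instruction,
            "z": float(z),
            "n_trials": n_trials,
            "n_saccades": n_saccades,
            "seed": seed,
            "engine": engine.__dict__ | {},
        },
        seeds={label: used},
    )


# ---------------------------------------------------------------------------
# face identification under safe/threat contexts
ANXIETY_THRESHOLD = 0.80


def anxiety_experiment(
    n_trials: int = 200,
    seed: int = 0,
    engine: EngineConfig | None = None,
    zeta_fearful: tuple[float, float] = (0.1, 0.9),
    zeta_happy: tuple[float, float] = (0.25, 0.25),
    threshold: float = ANXIETY_THRESHOLD,
) -> ExperimentResult:
    """Decision times (number of facial areas fixated before identification)
    per context x face-type cell, with bootstrap intervals.

    The threat context sharpens only the fearful-expression mapping
    (zeta 0.1 -> 0.9); happy expressions keep zeta 0.25 in both contexts.
    """
    engine = engine or DEFAULT_ENGINE
    engine = replace(engine, decision_threshold=threshold)
    model, make_process = build_face(zeta_fearful, zeta_happy)
    conditions: dict[str, list[TrialRecord]] = {}
    summary: dict[str, dict] = {}
    seeds: dict[str, list[int]] = {}
    stat_rng = np.random.default_rng(seed + 104729)
    for ci, ctx in enumerate(CONTEXTS):
        for fi, ft in enumerate(FACE_TYPES):
            label = f"{ft}/{ctx}"
            recs, used, times = [], [], []
            for i in range(n_trials):
                trial_seed = seed + i + 10000 * (2 * ci + fi)
                rec = run_trial(
                    model,
                    make_process(tasks.FaceScene(ctx, ft)),
                    replace(engine, rng_seed=trial_seed),
                    T_max=8,
                    termination=face_termination(),
                )
                recs.append(rec)
                used.append(trial_seed)
                times.append(float(rec.decision_timestep))
            conditions[label] = recs
            seeds[label] = used
            summary[label] = _summarize(times, stat_rng)
    return ExperimentResult(
        conditions=conditions,
        summary=summary,
        config={
            "experiment": "anxiety",
            "n_trials": n_trials,
            "seed": seed,
            "zeta_fearful": list(zeta_fearful),
            "zeta_happy": list(zeta_happy),
            "threshold": threshold,
            "engine": engine.__dict__ | {},
        },
        seeds=seeds,
    )
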