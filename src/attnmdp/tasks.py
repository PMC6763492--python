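"""Builders for the three visual-attention tasks.

Each builder returns the agent's :class:`~attnmdp.core.GenerativeModel`
(with its context-dependent precision matrix) and a *process template*: a
callable that instantiates the :class:`~attnmdp.core.GenerativeProcess` (the
real world, with unmodulated likelihoods) for a given scene.

Location conventions are 1-based in labels and reports (location 1 is the
central fixation) and 0-based in all array indexing.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Callable

import numpy as np

from .core import (
    FactorSpec,
    GenerativeModel,
    GenerativeProcess,
    ModalitySpec,
    PolicySet,
    PrecisionSpec,
)
from .engine import TrialTermination

__all__ = [
    "ColourShapeScene",
    "YarbusScene",
    "FaceScene",
    "build_colour_shape",
    "sample_colour_shape_scene",
    "build_yarbus",
    "sample_yarbus_scene",
    "yarbus_exceptions",
    "build_face",
    "COLOURS",
    "SHAPES",
    "CHOICE_LOCATIONS",
    "SHAPE_QUADRANT",
    "COLOUR_QUADRANT",
    "OBJECT_LOCATIONS",
    "FACE_LOCATIONS",
    "WEALTH_LEVELS",
    "AGE_LEVELS",
    "OBJECT_FEATURES",
    "FACE_FEATURES",
    "FACE_AREAS",
    "FEARFUL_ATTRS",
    "HAPPY_ATTRS",
]

INF = np.inf

# ---------------------------------------------------------------------------
# colour/shape task
COLOURS = ("red", "green", "blue")
SHAPES = ("square", "circle", "triangle")
RULES = ("categorise-colour", "categorise-shape")
#: 1-based location labels: 1 centre, 2-5 quadrants, 6-8 choice locations.
SHAPE_QUADRANT = 3      # bottom-left quadrant: determines the shape category
COLOUR_QUADRANT = 4     # top-right quadrant: determines the colour category
CHOICE_LOCATIONS = (6, 7, 8)
_N_CS_LOC = 8


@dataclass(frozen=True)
class ColourShapeScene:
    rule: str
    colour_category: str
    shape_category: str

    def __post_init__(self) -> None:
        if self.rule not in RULES:
            raise ValueError(f"unknown rule {self.rule!r}")
        if self.colour_category not in COLOURS:
            raise ValueError(f"unknown colour {self.colour_category!r}")
        if self.shape_category not in SHAPES:
            raise ValueError(f"unknown shape {self.shape_category!r}")


def sample_colour_shape_scene(rng: np.random.Generator) -> ColourShapeScene:
    """Uniform draw over the 2 x 3 x 3 rule/colour/shape combinations."""
    return ColourShapeScene(
        rule=RULES[rng.integers(2)],
        colour_category=COLOURS[rng.integers(3)],
        shape_category=SHAPES[rng.integers(3)],
    )


def _saccade_B(n_loc: int) -> np.ndarray:
    """Action a moves to location a from anywhere, deterministically."""
    B = np.zeros((n_loc, n_loc, n_loc))
    for a in range(n_loc):
        B[a, :, a] = 1.0
    return B


def _identity_B(n: int) -> np.ndarray:
    return np.eye(n)[:, :, None]


def _one_hot(i: int, n: int) -> np.ndarray:
    v = np.zeros(n)
    v[i] = 1.0
    return v


def _single_saccade_policies(n_loc: int, n_factors: int, where_axis: int) -> PolicySet:
    acts = np.zeros((n_loc, 1, n_factors), dtype=int)
    acts[:, 0, where_axis] = np.arange(n_loc)
    return PolicySet(actions=acts)


def _colour_shape_A() -> dict[str, np.ndarray]:
    """Raw (unmodulated) likelihood tables shared by model and process."""
    dims = (2, _N_CS_LOC, 3, 3)  # rule, where, colour, shape
    A: dict[str, np.ndarray] = {
        "rule": np.zeros((2, *dims)),
        "where": np.zeros((_N_CS_LOC, *dims)),
        "colours": np.zeros((6, *dims)),
        "shapes": np.zeros((6, *dims)),
    }
    NULL, RIGHT, WRONG = 3, 4, 5
    for i in range(2):
        A["rule"][i, i] = 1.0
    for j in range(_N_CS_LOC):
        A["where"][j, :, j] = 1.0
    for i in range(2):
        for j in range(_N_CS_LOC):
            for k in range(3):
                for l in range(3):
                    loc = j + 1
                    # colours modality
                    if loc == COLOUR_QUADRANT:
                        oc = k
                    elif loc in CHOICE_LOCATIONS and i == 0:
                        oc = RIGHT if (loc - CHOICE_LOCATIONS[0]) == k else WRONG
                    else:
                        oc = NULL
                    A["colours"][oc, i, j, k, l] = 1.0
                    # shapes modality
                    if loc == SHAPE_QUADRANT:
                        os_ = l
                    elif loc in CHOICE_LOCATIONS and i == 1:
                        os_ = RIGHT if (loc - CHOICE_LOCATIONS[0]) == l else WRONG
                    else:
                        os_ = NULL
                    A["shapes"][os_, i, j, k, l] = 1.0
    return A


def build_colour_shape(
    z_colour: float = INF,
    z_shape: float = INF,
    utilities: tuple[float, float] = (2.0, -4.0),
) -> tuple[GenerativeModel, Callable[[ColourShapeScene], GenerativeProcess]]:
    """Colour/shape categorisation: 4 factors, 4 modalities, 8 locations.

    ``z_colour`` modulates the colour mapping when the rule is
    categorise-shape (task-irrelevant there), and ``z_shape`` the shape
    mapping when the rule is categorise-colour, per the rule-indexed
    precision matrix; the task-relevant mapping is always at full precision.
    """
    if not all(np.isfinite(u) for u in utilities):
        raise ValueError("utilities must be finite")
    factors = (
        FactorSpec("rule", RULES),
        FactorSpec("where", tuple(f"loc{j + 1}" for j in range(_N_CS_LOC)), True),
        FactorSpec("colour", COLOURS),
        FactorSpec("shape", SHAPES),
    )
    modalities = (
        ModalitySpec("rule", RULES),
        ModalitySpec("where", tuple(f"loc{j + 1}" for j in range(_N_CS_LOC))),
        ModalitySpec("colours", COLOURS + ("null", "right", "wrong")),
        ModalitySpec("shapes", SHAPES + ("null", "right", "wrong")),
    )
    A = _colour_shape_A()
    B = {
        "rule": _identity_B(2),
        "where": _saccade_B(_N_CS_LOC),
        "colour": _identity_B(3),
        "shape": _identity_B(3),
    }
    right, wrong = utilities
    feedback_C = np.array([0.0, 0.0, 0.0, 0.0, right, wrong])
    C = {
        "rule": np.zeros(2),
        "where": np.zeros(_N_CS_LOC),
        "colours": feedback_C.copy(),
        "shapes": feedback_C.copy(),
    }
    D = {
        "rule": np.full(2, 0.5),
        "where": _one_hot(0, _N_CS_LOC),
        "colour": np.full(3, 1 / 3),
        "shape": np.full(3, 1 / 3),
    }
    precision = PrecisionSpec(
        context_factors=("rule",),
        zeta={
            "rule": np.array([INF, INF]),
            "where": np.array([INF, INF]),
            "colours": np.array([INF, z_colour]),
            "shapes": np.array([z_shape, INF]),
        },
    )
    model = GenerativeModel(
        factors=factors,
        modalities=modalities,
        A=A,
        B={k: v.copy() for k, v in B.items()},
        C=C,
        D=D,
        policies=_single_saccade_policies(_N_CS_LOC, 4, 1),
        precision=precision,
    )

    def make_process(scene: ColourShapeScene) -> GenerativeProcess:
        return GenerativeProcess(
            factors=factors,
            modalities=modalities,
            A={k: v.copy() for k, v in A.items()},
            B={k: v.copy() for k, v in B.items()},
            true_levels={
                "rule": RULES.index(scene.rule),
                "where": 0,
                "colour": COLOURS.index(scene.colour_category),
                "shape": SHAPES.index(scene.shape_category),
            },
        )

    return model, make_process


def colour_shape_termination() -> TrialTermination:
    return TrialTermination(
        kind="feedback", locations=frozenset(j - 1 for j in CHOICE_LOCATIONS)
    )


# ---------------------------------------------------------------------------
# Yarbus task
WEALTH_LEVELS = ("wealthy", "middle-class", "poor")
AGE_LEVELS = ("young", "middle-aged", "old")
INSTRUCTIONS = ("estimate-wealth", "estimate-age")
OBJECT_FEATURES = ("antique", "modest", "common")
FACE_FEATURES = ("young", "middle-aged", "old")
#: 1-based painting locations; location 1 is the centre of the scene.
OBJECT_LOCATIONS = (2, 4, 6, 9, 10, 11)
FACE_LOCATIONS = (3, 5, 7, 8, 12, 13)
_N_Y_LOC = 13


def yarbus_exceptions(scene_type: int) -> tuple[tuple[int, int], ...]:
    """Fixed minority-feature table: slots (into the sorted location list)
    and category offsets that deviate from the majority feature.

    At most two of six locations deviate, so the majority always recovers
    the generating category, and distinct scene types place their
    exceptions differently, so the scene type is identifiable by looking.
    """
    n = scene_type % 3
    return tuple(((scene_type + 2 * j) % 6, 1 + (j % 2)) for j in range(n))


def _slot_feature(category: int, scene_type: int, slot: int) -> int:
    for s, off in yarbus_exceptions(scene_type):
        if s == slot:
            return (category + off) % 3
    return category


@dataclass(frozen=True)
class YarbusScene:
    wealth: str
    age: str
    scene_type: int
    layout: dict[int, str]  # 1-based location -> feature label

    def __post_init__(self) -> None:
        if self.wealth not in WEALTH_LEVELS or self.age not in AGE_LEVELS:
            raise ValueError("invalid wealth/age category")
        for loc, feat in self.layout.items():
            if loc in OBJECT_LOCATIONS and feat not in OBJECT_FEATURES:
                raise ValueError(f"object location {loc} holds {feat!r}")
            if loc in FACE_LOCATIONS and feat not in FACE_FEATURES:
                raise ValueError(f"face location {loc} holds {feat!r}")


def sample_yarbus_scene(
    rng: np.random.Generator,
    wealth: str | None = None,
    age: str | None = None,
    scene_type: int | None = None,
    n_scene_types: int = 3,
) -> YarbusScene:
    """Construct a scene: majority features match the categories, with the
    scene type's fixed exception pattern applied to both location classes."""
    if wealth is None:
        wealth = WEALTH_LEVELS[rng.integers(3)]
    if age is None:
        age = AGE_LEVELS[rng.integers(3)]
    if scene_type is None:
        scene_type = int(rng.integers(n_scene_types))
    w, a = WEALTH_LEVELS.index(wealth), AGE_LEVELS.index(age)
    layout: dict[int, str] = {}
    for slot, loc in enumerate(OBJECT_LOCATIONS):
        layout[loc] = OBJECT_FEATURES[_slot_feature(w, scene_type, slot)]
    for slot, loc in enumerate(FACE_LOCATIONS):
        layout[loc] = FACE_FEATURES[_slot_feature(a, scene_type, slot)]
    return YarbusScene(wealth=wealth, age=age, scene_type=scene_type, layout=layout)


def _yarbus_A(n_scene_types: int) -> dict[str, np.ndarray]:
    dims = (2, _N_Y_LOC, 3, 3, n_scene_types)
    A: dict[str, np.ndarray] = {
        "instruction": np.zeros((2, *dims)),
        "where": np.zeros((_N_Y_LOC, *dims)),
        "object": np.zeros((4, *dims)),
        "face": np.zeros((4, *dims)),
    }
    NULL = 3
    for i in range(2):
        A["instruction"][i, i] = 1.0
    for j in range(_N_Y_LOC):
        A["where"][j, :, j] = 1.0
    obj_slot = {loc - 1: s for s, loc in enumerate(OBJECT_LOCATIONS)}
    face_slot = {loc - 1: s for s, loc in enumerate(FACE_LOCATIONS)}
    for j in range(_N_Y_LOC):
        for w in range(3):
            for a in range(3):
                for sc in range(n_scene_types):
                    if j in obj_slot:
                        o = _slot_feature(w, sc, obj_slot[j])
                    else:
                        o = NULL
                    A["object"][o, :, j, w, a, sc] = 1.0
                    if j in face_slot:
                        o = _slot_feature(a, sc, face_slot[j])
                    else:
                        o = NULL
                    A["face"][o, :, j, w, a, sc] = 1.0
    return A


def build_yarbus(
    z: float = INF,
    n_scene_types: int = 3,
    learnable: bool = False,
) -> tuple[GenerativeModel, Callable[[YarbusScene], GenerativeProcess]]:
    """Yarbus' picture-viewing paradigm: 13 locations, two instructions.

    ``z`` fills the task-irrelevant cells of the instruction-indexed
    precision matrix (faces under estimate-wealth, objects under
    estimate-age); ``z = 0`` models attenuation of irrelevant mappings
    (typically developing), ``z = inf`` its failure (the autism
    parameterisation).  When ``learnable``, the object/face likelihoods are
    flagged for Dirichlet learning (the agent starts ignorant of the layout).
    """
    if n_scene_types < 2:
        raise ValueError("n_scene_types must be >= 2")
    loc_labels = tuple(f"loc{j + 1}" for j in range(_N_Y_LOC))
    factors = (
        FactorSpec("instruction", INSTRUCTIONS),
        FactorSpec("where", loc_labels, True),
        FactorSpec("wealth", WEALTH_LEVELS),
        FactorSpec("age", AGE_LEVELS),
        FactorSpec("scene", tuple(f"scene-{k + 1}" for k in range(n_scene_types))),
    )
    A = _yarbus_A(n_scene_types)
    modalities = (
        ModalitySpec("instruction", INSTRUCTIONS),
        ModalitySpec("where", loc_labels),
        ModalitySpec("object", OBJECT_FEATURES + ("null",)),
        ModalitySpec("face", FACE_FEATURES + ("null",)),
    )
    B = {
        "instruction": _identity_B(2),
        "where": _saccade_B(_N_Y_LOC),
        "wealth": _identity_B(3),
        "age": _identity_B(3),
        "scene": _identity_B(n_scene_types),
    }
    C = {m.name: np.zeros(m.n) for m in modalities}
    D = {
        "instruction": np.full(2, 0.5),
        "where": _one_hot(0, _N_Y_LOC),
        "wealth": np.full(3, 1 / 3),
        "age": np.full(3, 1 / 3),
        "scene": np.full(n_scene_types, 1 / n_scene_types),
    }
    precision = PrecisionSpec(
        context_factors=("instruction",),
        zeta={
            "instruction": np.array([INF, INF]),
            "where": np.array([INF, INF]),
            "object": np.array([INF, z]),
            "face": np.array([z, INF]),
        },
    )
    model = GenerativeModel(
        factors=factors,
        modalities=modalities,
        A=A,
        B={k: v.copy() for k, v in B.items()},
        C=C,
        D=D,
        policies=_single_saccade_policies(_N_Y_LOC, 5, 1),
        precision=precision,
        learnable=frozenset({"object", "face"}) if learnable else frozenset(),
    )

    def make_process(scene: YarbusScene) -> GenerativeProcess:
        return GenerativeProcess(
            factors=factors,
            modalities=modalities,
            A={k: v.copy() for k, v in A.items()},
            B={k: v.copy() for k, v in B.items()},
            true_levels={
                "instruction": 0,
                "where": 0,
                "wealth": WEALTH_LEVELS.index(scene.wealth),
                "age": AGE_LEVELS.index(scene.age),
                "scene": scene.scene_type,
            },
        )

    return model, make_process


# ---------------------------------------------------------------------------
# face identification task
FACE_AREAS = ("forehead", "eyebrows", "eyelids", "cheeks", "teeth")
CONTEXTS = ("safe", "threat")
FACE_TYPES = ("happy", "fearful")
FEARFUL_ATTRS = (
    "wrinkled-forehead",
    "raised-eyebrows",
    "wide-eyelids",
    "tense-cheeks",
    "gritted-teeth",
)
HAPPY_ATTRS = (
    "smooth-forehead",
    "relaxed-eyebrows",
    "narrow-eyelids",
    "raised-cheeks",
    "exposed-teeth",
)


@dataclass(frozen=True)
class FaceScene:
    context: str
    face_type: str

    def __post_init__(self) -> None:
        if self.context not in CONTEXTS or self.face_type not in FACE_TYPES:
            raise ValueError("invalid context/face type")

    @property
    def attributes(self) -> dict[str, str]:
        attrs = HAPPY_ATTRS if self.face_type == "happy" else FEARFUL_ATTRS
        return dict(zip(FACE_AREAS, attrs))


def build_face(
    zeta_fearful: tuple[float, float] = (0.1, 0.9),
    zeta_happy: tuple[float, float] = (0.25, 0.25),
) -> tuple[GenerativeModel, Callable[[FaceScene], GenerativeProcess]]:
    """Happy/fearful face identification over 5 facial areas.

    The expressions precision is indexed by Context x Face type:
    ``zeta_fearful = (safe, threat)`` and ``zeta_happy = (safe, threat)``.
    The true mapping from (face type, area) to its typical attribute is
    deterministic; only the agent's expected fidelity varies with context.
    """
    factors = (
        FactorSpec("context", CONTEXTS),
        FactorSpec("face_type", FACE_TYPES),
        FactorSpec("where", FACE_AREAS, True),
    )
    outcomes = FEARFUL_ATTRS + HAPPY_ATTRS
    modalities = (
        ModalitySpec("context", CONTEXTS),
        ModalitySpec("expressions", outcomes),
        ModalitySpec("where", FACE_AREAS),
    )
    A = {
        "context": np.zeros((2, 2, 2, 5)),
        "expressions": np.zeros((10, 2, 2, 5)),
        "where": np.zeros((5, 2, 2, 5)),
    }
    for c in range(2):
        A["context"][c, c] = 1.0
    for w in range(5):
        A["where"][w, :, :, w] = 1.0
        A["expressions"][w, :, FACE_TYPES.index("fearful"), w] = 1.0
        A["expressions"][5 + w, :, FACE_TYPES.index("happy"), w] = 1.0
    B = {
        "context": _identity_B(2),
        "face_type": _identity_B(2),
        "where": _saccade_B(5),
    }
    C = {m.name: np.zeros(m.n) for m in modalities}
    D = {
        "context": np.full(2, 0.5),
        "face_type": np.full(2, 0.5),
        "where": _one_hot(0, 5),
    }
    zeta_expr = np.zeros((2, 2))  # (context, face_type)
    for c in range(2):
        zeta_expr[c, FACE_TYPES.index("fearful")] = zeta_fearful[c]
        zeta_expr[c, FACE_TYPES.index("happy")] = zeta_happy[c]
    precision = PrecisionSpec(
        context_factors=("context", "face_type"),
        zeta={
            "context": np.full((2, 2), INF),
            "expressions": zeta_expr,
            "where": np.full((2, 2), INF),
        },
    )
    model = GenerativeModel(
        factors=factors,
        modalities=modalities,
        A=A,
        B={k: v.copy() for k, v in B.items()},
        C=C,
        D=D,
        policies=_single_saccade_policies(5, 3, 2),
        precision=precision,
    )

    def make_process(scene: FaceScene) -> GenerativeProcess:
        return GenerativeProcess(
            factors=factors,
            modalities=modalities,
            A={k: v.copy() for k, v in A.items()},
            B={k: v.copy() for k, v in B.items()},
            true_levels={
                "context": CONTEXTS.index(scene.context),
                "face_type": FACE_TYPES.index(scene.face_type),
                "where": 0,
            },
        )

    return model, make_process


def face_termination() -> TrialTermination:
    return TrialTermination(kind="threshold", factor="face_type")
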