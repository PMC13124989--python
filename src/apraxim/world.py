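"""The visuomotor world: action repertoire and the three-level model.

The agent's repertoire distinguishes *movement segments* (primitive,
context-free kinematic elements such as grasp, lift, strike) from
*sequences of segments* (ordered combinations realizing an action, such as
hammering = grasp -> lift -> strike) and *concepts* (the semantic label of
a meaningful sequence; meaningless sequences map to NONE).

`build_world` instantiates the hierarchical generative model:

- action observation level: segments, observed through a noisy kinematic
  likelihood ``A_kin = (1 - eps) I + eps * uniform-off-diagonal``;
- action understanding level: sequences, linked to segments by one
  structural likelihood per within-sequence position (the action input
  system), and to concepts by the functional/semantic likelihood
  ``A_functional``; verbal labels reach concepts through the phonological
  input lexicon ``A_phon``; multisensory tool-use consequences (tactile,
  auditory, visual) act as affordance evidence on the sequence factor;
- action execution level: motor primitives with deterministic transitions,
  a policy per candidate segment sequence, and action precision ``alpha``.

Route arbitration: the lexical route (posterior-informed policy prior E)
and the direct route (observation-informed preferences C) are mixed by a
gate weight ``w = route_gate(sequence posterior)`` that grows with the
posterior mass on meaningful sequences — familiar gestures are
automatically captured by the lexical route, meaningless ones fall through
to the direct route.
"""

from __future__ import annotations

import copy
import itertools
from dataclasses import dataclass, field, asdict

import numpy as np

from apraxim.core import Categorical, assert_column_stochastic
from apraxim.hierarchy import GenerativeLevel

__all__ = [
    "NONE_CONCEPT",
    "TOOL_MODALITIES",
    "Repertoire",
    "WorldConfig",
    "VisuomotorModel",
    "default_repertoire",
    "build_world",
    "route_gate",
]

NONE_CONCEPT = "none"

#: Multisensory consequences available when a real tool is in the hand.
TOOL_MODALITIES = ("tactile", "auditory", "visual_consequence")

ACTION_OBSERVATION = "action_observation"
ACTION_UNDERSTANDING = "action_understanding"
ACTION_EXECUTION = "action_execution"


class ConfigurationError(ValueError):
    """Inconsistent world, task or lesion configuration."""


@dataclass(frozen=True)
class Repertoire:
    """Segments, sequences and concepts known to the agent.

    ``sequences`` maps a sequence label to its ordered segment tuple;
    ``concept_of`` maps every sequence label to a concept (meaningless
    sequences map to :data:`NONE_CONCEPT`).
    """

    segments: tuple[str, ...]
    sequences: dict[str, tuple[str, ...]]
    concept_of: dict[str, str]
    concepts: tuple[str, ...]

    def __post_init__(self) -> None:
        if NONE_CONCEPT not in self.concepts:
            raise ConfigurationError("concept set must include NONE")
        seg_set = set(self.segments)
        seen: set[tuple[str, ...]] = set()
        for label, segs in self.sequences.items():
            if not set(segs) <= seg_set:
                raise ConfigurationError(f"sequence {label} uses unknown segments")
            if tuple(segs) in seen:
                raise ConfigurationError(f"duplicate segment order for {label}")
            seen.add(tuple(segs))
            if label not in self.concept_of:
                raise ConfigurationError(f"sequence {label} has no concept mapping")
            if self.concept_of[label] not in self.concepts:
                raise ConfigurationError(f"unknown concept for sequence {label}")
        if not self.meaningless_sequences:
            raise ConfigurationError("repertoire needs at least one meaningless sequence")

    # -- label orderings (index spaces are fixed by these tuples) --------
    @property
    def sequence_labels(self) -> tuple[str, ...]:
        return tuple(self.sequences)

    @property
    def meaningful_sequences(self) -> tuple[str, ...]:
        return tuple(s for s in self.sequences if self.concept_of[s] != NONE_CONCEPT)

    @property
    def meaningless_sequences(self) -> tuple[str, ...]:
        return tuple(s for s in self.sequences if self.concept_of[s] == NONE_CONCEPT)

    @property
    def meaningful_mask(self) -> np.ndarray:
        return np.array([self.concept_of[s] != NONE_CONCEPT for s in self.sequences])

    @property
    def sequence_length(self) -> int:
        (length,) = {len(s) for s in self.sequences.values()}
        return length

    def segment_index(self, segment: str) -> int:
        return self.segments.index(segment)

    def sequence_index(self, label: str) -> int:
        return self.sequence_labels.index(label)

    def concept_index(self, concept: str) -> int:
        return self.concepts.index(concept)

    def sequence_of_concept(self, concept: str) -> str:
        for label in self.meaningful_sequences:
            if self.concept_of[label] == concept:
                return label
        raise KeyError(concept)


def default_repertoire() -> Repertoire:
    """Canonical fixture: three symbolic gestures plus two meaningless ones.

    Hammering is grasp -> lift -> strike; waving a goodbye arc; saluting a
    hand-to-brow gesture.  The meaningless sequences reuse known segments
    in novel orders and map to NONE.
    """
    segments = (
        "grasp", "lift", "strike", "arc_out", "arc_in", "to_brow", "hold", "lower",
    )
    sequences = {
        "hammering": ("grasp", "lift", "strike"),
        "waving": ("arc_out", "arc_in", "arc_out"),
        "saluting": ("to_brow", "hold", "lower"),
        "meaningless_1": ("lift", "arc_in", "grasp"),
        "meaningless_2": ("lower", "strike", "to_brow"),
    }
    concept_of = {
        "hammering": "hammer",
        "waving": "wave",
        "saluting": "salute",
        "meaningless_1": NONE_CONCEPT,
        "meaningless_2": NONE_CONCEPT,
    }
    concepts = ("hammer", "wave", "salute", NONE_CONCEPT)
    return Repertoire(segments, sequences, concept_of, concepts)


@dataclass(frozen=True)
class WorldConfig:
    """Sizes, noise levels and precision of the simulated world.

    epsilon is the kinematic confusion probability (the chance that an
    observed segment is registered as some other segment); epsilon_tool the
    per-modality confusion of tool-use consequences; alpha the action
    precision at the execution level; gate_exponent sharpens the lexical
    route gate.
    """

    n_segments: int = 8
    n_meaningful_sequences: int = 3
    n_meaningless_sequences: int = 2
    n_concepts: int = 3
    sequence_length: int = 3
    epsilon: float = 0.05
    epsilon_tool: float = 0.05
    alpha: float = 16.0
    gate_exponent: float = 4.0
    seed: int = 0

    def __post_init__(self) -> None:
        if min(self.n_segments, self.n_meaningful_sequences, self.n_concepts) < 1:
            raise ConfigurationError("counts must be >= 1")
        if self.n_meaningless_sequences < 1:
            raise ConfigurationError("need at least one meaningless sequence")
        if not 0.0 <= self.epsilon < 0.5:
            raise ConfigurationError("epsilon must lie in [0, 0.5)")
        if not 0.0 <= self.epsilon_tool < 0.5:
            raise ConfigurationError("epsilon_tool must lie in [0, 0.5)")
        if self.alpha < 0:
            raise ConfigurationError("alpha must be nonnegative")
        if self.n_meaningful_sequences < self.n_concepts:
            raise ConfigurationError("each concept needs at least one sequence")


@dataclass
class VisuomotorModel:
    """The three coupled generative levels plus cross-level mappings.

    Cross-level structures (index spaces follow the repertoire orderings):

    - ``A_kin``        (n_seg, n_seg): kinematic features | segment.
    - ``A_structural`` list over positions, each (n_seg, n_seq): segment at
      that position | sequence (the action input system).
    - ``A_functional`` (n_seq, n_concepts): sequence | concept (semantic
      memory, read in both directions).
    - ``A_phon``       (n_meaningful_concepts, n_concepts): verbal label |
      concept (phonological input lexicon).
    - ``A_tool``       per modality (n_concepts, n_seq): multisensory
      consequence cue | sequence (affordance/motor-prior evidence).
    - ``B_segments``   (n_seq, n_seg, n_seg): sequence-conditional segment
      transitions (each sequence's segment order).

    ``procedural_link_damage`` and ``direct_route_damage`` are runtime
    lesion dials in [0, 1]: the first attenuates the information reaching
    the execution-level policy prior E (severing the lexical-to-procedural
    link), the second flattens the preferences C that inform the
    goal-directed controller G (severing the visuomotor conversion link).
    """

    repertoire: Repertoire
    config: WorldConfig
    levels: dict[str, GenerativeLevel]
    A_kin: np.ndarray
    A_structural: list[np.ndarray]
    A_functional: np.ndarray
    A_phon: np.ndarray
    A_tool: dict[str, np.ndarray]
    B_segments: np.ndarray
    policies: np.ndarray
    sequence_policy_rows: np.ndarray = field(default_factory=lambda: np.empty(0, int))
    procedural_link_damage: float = 0.0
    direct_route_damage: float = 0.0

    @property
    def execution(self) -> GenerativeLevel:
        return self.levels[ACTION_EXECUTION]

    @property
    def understanding(self) -> GenerativeLevel:
        return self.levels[ACTION_UNDERSTANDING]

    @property
    def observation_level(self) -> GenerativeLevel:
        return self.levels[ACTION_OBSERVATION]

    def copy(self) -> "VisuomotorModel":
        return copy.deepcopy(self)

    def policy_index(self, segments: tuple[str, ...]) -> int:
        """Row of ``policies`` that produces the given segment order."""
        idx = np.array([self.repertoire.segment_index(s) for s in segments])
        match = np.flatnonzero((self.policies == idx).all(axis=1))
        return int(match[0])

    def fixture_dict(self) -> dict:
        """JSON-serializable dump of the world structures, for inspection."""
        return {
            "config": asdict(self.config),
            "segments": list(self.repertoire.segments),
            "sequences": {k: list(v) for k, v in self.repertoire.sequences.items()},
            "concept_of": dict(self.repertoire.concept_of),
            "concepts": list(self.repertoire.concepts),
            "A_kin": self.A_kin.tolist(),
            "A_structural": [a.tolist() for a in self.A_structural],
            "A_functional": self.A_functional.tolist(),
            "A_phon": self.A_phon.tolist(),
            "A_tool": {k: v.tolist() for k, v in self.A_tool.items()},
        }


def _noisy_identity(n: int, eps: float) -> np.ndarray:
    """(1 - eps) identity with eps spread uniformly off the diagonal."""
    if n == 1:
        return np.ones((1, 1))
    A = np.full((n, n), eps / (n - 1))
    np.fill_diagonal(A, 1.0 - eps)
    return A


def _generated_repertoire(config: WorldConfig, rng: np.random.Generator) -> Repertoire:
    # Synthetic repertoires for non-default sizes; sequences are distinct
    # random segment orders, concepts assigned round-robin.
    segments = tuple(f"seg{i}" for i in range(config.n_segments))
    n_total = config.n_meaningful_sequences + config.n_meaningless_sequences
    orders: list[tuple[str, ...]] = []
    seen: set[tuple[int, ...]] = set()
    while len(orders) < n_total:
        cand = tuple(int(i) for i in rng.integers(0, config.n_segments,
                                                  size=config.sequence_length))
        if cand in seen:
            continue
        seen.add(cand)
        orders.append(tuple(segments[i] for i in cand))
    sequences: dict[str, tuple[str, ...]] = {}
    concept_of: dict[str, str] = {}
    concepts = tuple(f"concept{i}" for i in range(config.n_concepts)) + (NONE_CONCEPT,)
    for i in range(config.n_meaningful_sequences):
        label = f"action{i}"
        sequences[label] = orders[i]
        concept_of[label] = concepts[i % config.n_concepts]
    for i in range(config.n_meaningless_sequences):
        label = f"meaningless_{i + 1}"
        sequences[label] = orders[config.n_meaningful_sequences + i]
        concept_of[label] = NONE_CONCEPT
    return Repertoire(segments, sequences, concept_of, concepts)


def build_world(config: WorldConfig | None = None,
                repertoire: Repertoire | None = None) -> VisuomotorModel:
    """Instantiate the three-level visuomotor model.

    Deterministic given ``config.seed``: the default sizes use the
    canonical repertoire; other sizes generate a synthetic repertoire from
    the seed.
    """
    config = config or WorldConfig()
    rng = np.random.default_rng(config.seed)
    if repertoire is None:
        if (config.n_segments, config.n_meaningful_sequences,
                config.n_meaningless_sequences, config.n_concepts,
                config.sequence_length) == (8, 3, 2, 3, 3):
            repertoire = default_repertoire()
        else:
            repertoire = _generated_repertoire(config, rng)
    rep = repertoire
    n_seg = len(rep.segments)
    seq_labels = rep.sequence_labels
    n_seq = len(seq_labels)
    n_con = len(rep.concepts)
    length = rep.sequence_length

    A_kin = _noisy_identity(n_seg, config.epsilon)

    # Action input system: one structural link per within-sequence position.
    A_structural = []
    for t in range(length):
        link = np.zeros((n_seg, n_seq))
        for j, label in enumerate(seq_labels):
            link[rep.segment_index(rep.sequences[label][t]), j] = 1.0
        A_structural.append(link)

    # Semantic memory: sequence | concept.  Each concept spreads over its
    # sequences; NONE spreads over the meaningless ones.
    A_functional = np.zeros((n_seq, n_con))
    for c, concept in enumerate(rep.concepts):
        members = [j for j, s in enumerate(seq_labels) if rep.concept_of[s] == concept]
        for j in members:
            A_functional[j, c] = 1.0 / len(members)

    # Phonological input lexicon: one verbal label per meaningful concept;
    # NONE has no label of its own (uniform over labels).
    meaningful_concepts = [c for c in rep.concepts if c != NONE_CONCEPT]
    n_phon = len(meaningful_concepts)
    A_phon = np.zeros((n_phon, n_con))
    for c, concept in enumerate(rep.concepts):
        if concept == NONE_CONCEPT:
            A_phon[:, c] = 1.0 / n_phon
        else:
            A_phon[meaningful_concepts.index(concept), c] = 1.0

    # Tool-use consequences: each meaningful sequence produces the cue of
    # its concept; meaningless sequences a neutral cue.  One likelihood per
    # modality (identical structure, independent draws).
    n_cue = n_phon + 1  # one cue per meaningful concept plus neutral
    cue_template = np.zeros((n_cue, n_seq))
    for j, label in enumerate(seq_labels):
        concept = rep.concept_of[label]
        row = n_phon if concept == NONE_CONCEPT else meaningful_concepts.index(concept)
        cue_template[:, j] = config.epsilon_tool / (n_cue - 1)
        cue_template[row, j] = 1.0 - config.epsilon_tool
    A_tool = {m: cue_template.copy() for m in TOOL_MODALITIES}

    # Sequence-conditional segment dynamics (the worked hammering order):
    # within sequence j, segment at position t advances to position t+1
    # with probability 1 - epsilon.
    B_segments = np.full((n_seq, n_seg, n_seg),
                         config.epsilon / (n_seg - 1) if n_seg > 1 else 1.0)
    for j, label in enumerate(seq_labels):
        segs = [rep.segment_index(s) for s in rep.sequences[label]]
        for s in range(n_seg):
            B_segments[j, s, s] = 1.0 - config.epsilon  # default: persist
        for t in range(len(segs) - 1):
            B_segments[j, :, segs[t]] = config.epsilon / (n_seg - 1) if n_seg > 1 else 0.0
            B_segments[j, segs[t + 1], segs[t]] = 1.0 - config.epsilon

    # Execution level: one policy per candidate segment sequence.
    if n_seg ** length > 100_000:
        raise ConfigurationError("policy space too large; reduce segments or length")
    policies = np.array(list(itertools.product(range(n_seg), repeat=length)), dtype=int)
    B_exec = np.zeros((n_seg, n_seg, n_seg))
    for a in range(n_seg):
        B_exec[a, a, :] = 1.0  # producing primitive a lands in segment a

    levels = {
        ACTION_OBSERVATION: GenerativeLevel(
            name=ACTION_OBSERVATION,
            A={"kinematic": A_kin},
            D=Categorical.uniform(n_seg, rep.segments),
            timescale=1,
        ),
        ACTION_UNDERSTANDING: GenerativeLevel(
            name=ACTION_UNDERSTANDING,
            A={f"segment_pos{t}": A_structural[t] for t in range(length)},
            D=Categorical.uniform(n_seq, seq_labels),
            timescale=length,
        ),
        ACTION_EXECUTION: GenerativeLevel(
            name=ACTION_EXECUTION,
            A={"proprioceptive": np.eye(n_seg)},
            B=B_exec,
            D=Categorical.uniform(n_seg, rep.segments),
            E=Categorical.uniform(len(policies)),
            policies=policies,
            alpha=config.alpha,
            timescale=1,
        ),
    }
    for t, link in enumerate(A_structural):
        assert_column_stochastic(link, f"A_structural[{t}]")
    assert_column_stochastic(A_functional, "A_functional")
    assert_column_stochastic(A_phon, "A_phon")
    seq_rows = np.empty(n_seq, dtype=int)
    for j, label in enumerate(seq_labels):
        idx = np.array([rep.segment_index(s) for s in rep.sequences[label]])
        seq_rows[j] = int(np.flatnonzero((policies == idx).all(axis=1))[0])
    return VisuomotorModel(
        repertoire=rep,
        config=config,
        levels=levels,
        A_kin=A_kin,
        A_structural=A_structural,
        A_functional=A_functional,
        A_phon=A_phon,
        A_tool=A_tool,
        B_segments=B_segments,
        policies=policies,
        sequence_policy_rows=seq_rows,
    )


def route_gate(structural_posterior: np.ndarray | Categorical,
               meaningful_mask: np.ndarray,
               exponent: float = 4.0) -> float:
    """Lexical-dominance weight w in [0, 1].

    w is the posterior mass on meaningful sequences, sharpened by the gate
    exponent g: ``w <- w**g / (w**g + (1 - w)**g)``.  Familiar gestures
    (mass near 1) hand control to the lexical route; meaningless ones
    (mass near 0) leave the direct route in charge.  Monotone nondecreasing
    in the meaningful mass for any g > 0.
    """
    probs = structural_posterior.probs if isinstance(structural_posterior, Categorical) \
        else np.asarray(structural_posterior, dtype=float)
    m = float(probs[np.asarray(meaningful_mask, bool)].sum())
    m = min(max(m, 0.0), 1.0)
    num = m ** exponent
    den = num + (1.0 - m) ** exponent
    return float(num / den) if den > 0 else 0.5
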