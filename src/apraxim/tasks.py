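"""Clinical task specifications.

The battery mirrors a bedside apraxia assessment: the clinician shows a
gesture and asks what it means (recognition), names an action and asks for
it (verbal command), demonstrates a familiar or a meaningless gesture and
asks for imitation, or hands over the real tool and asks for its use.
An optional sixth probe asks only whether a gesture is familiar.
"""

from __future__ import annotations

import enum
from dataclasses import dataclass, replace

from apraxim.world import NONE_CONCEPT, Repertoire, TOOL_MODALITIES, ConfigurationError

__all__ = ["TaskKind", "TaskSpec", "battery_tasks", "make_task", "enrich_observations"]


class TaskKind(str, enum.Enum):
    RECOGNIZE_FAMILIAR = "recognize_familiar"
    EXECUTE_VERBAL_COMMAND = "execute_verbal_command"
    IMITATE_FAMILIAR = "imitate_familiar"
    IMITATE_MEANINGLESS = "imitate_meaningless"
    USE_REAL_TOOL = "use_real_tool"
    DISCRIMINATE_FAMILIARITY = "discriminate_familiarity"


#: Task kinds scored on the produced segment sequence.
PRODUCTION_KINDS = frozenset({
    TaskKind.EXECUTE_VERBAL_COMMAND,
    TaskKind.IMITATE_FAMILIAR,
    TaskKind.IMITATE_MEANINGLESS,
    TaskKind.USE_REAL_TOOL,
})

#: Task kinds whose stimulus is an observed gesture.
OBSERVED_GESTURE_KINDS = frozenset({
    TaskKind.RECOGNIZE_FAMILIAR,
    TaskKind.IMITATE_FAMILIAR,
    TaskKind.IMITATE_MEANINGLESS,
    TaskKind.DISCRIMINATE_FAMILIARITY,
})


@dataclass(frozen=True)
class TaskSpec:
    """One trial's task: what is presented and what counts as correct.

    ``stimulus`` is a sequence label (gesture tasks) or a concept label
    (verbal command).  ``response_space`` is the set of candidate
    responses the clinician could have probed; its size fixes the chance
    level used by the profile classifier.  ``correct_response`` is a
    concept label (recognition), a familiarity judgement, or the target
    segment tuple (production tasks, scored by exact ordered match).
    """

    kind: TaskKind
    stimulus: str
    response_space: tuple[str, ...]
    correct_response: str | tuple[str, ...]
    modalities: tuple[str, ...] = ()

    @property
    def chance(self) -> float:
        return 1.0 / len(self.response_space)


def make_task(kind: TaskKind | str, stimulus: str, repertoire: Repertoire) -> TaskSpec:
    """Build a consistent :class:`TaskSpec` for one stimulus."""
    kind = TaskKind(kind)
    rep = repertoire
    if kind is TaskKind.EXECUTE_VERBAL_COMMAND:
        if stimulus not in rep.concepts or stimulus == NONE_CONCEPT:
            raise ConfigurationError(f"verbal command needs a meaningful concept, got {stimulus!r}")
        return TaskSpec(kind, stimulus, rep.meaningful_sequences,
                        rep.sequences[rep.sequence_of_concept(stimulus)])
    if stimulus not in rep.sequences:
        raise ConfigurationError(f"unknown sequence stimulus {stimulus!r}")
    meaningful = rep.concept_of[stimulus] != NONE_CONCEPT
    if kind is TaskKind.RECOGNIZE_FAMILIAR:
        if not meaningful:
            raise ConfigurationError("recognition stimuli must be meaningful gestures")
        return TaskSpec(kind, stimulus, rep.concepts, rep.concept_of[stimulus])
    if kind is TaskKind.IMITATE_FAMILIAR:
        if not meaningful:
            raise ConfigurationError("imitate_familiar stimuli must be meaningful")
        return TaskSpec(kind, stimulus, rep.meaningful_sequences, rep.sequences[stimulus])
    if kind is TaskKind.IMITATE_MEANINGLESS:
        if meaningful:
            raise ConfigurationError("imitate_meaningless stimuli must map to NONE")
        return TaskSpec(kind, stimulus, rep.meaningless_sequences, rep.sequences[stimulus])
    if kind is TaskKind.USE_REAL_TOOL:
        if not meaningful:
            raise ConfigurationError("tool use stimuli must be meaningful gestures")
        return TaskSpec(kind, stimulus, rep.meaningful_sequences, rep.sequences[stimulus])
    if kind is TaskKind.DISCRIMINATE_FAMILIARITY:
        return TaskSpec(kind, stimulus, ("meaningful", "meaningless"),
                        "meaningful" if meaningful else "meaningless")
    raise ConfigurationError(f"unknown task kind {kind!r}")


def enrich_observations(task: TaskSpec,
                        modalities: tuple[str, ...] = TOOL_MODALITIES) -> TaskSpec:
    """Add the intact multisensory tool modalities to a tool-use task.

    Real object manipulation delivers a cascade of tactile, auditory and
    visual-consequence evidence; pantomime delivers none.  Only
    ``use_real_tool`` tasks can be enriched.
    """
    if task.kind is not TaskKind.USE_REAL_TOOL:
        raise ConfigurationError("only tool-use tasks receive multisensory enrichment")
    unknown = set(modalities) - set(TOOL_MODALITIES)
    if unknown:
        raise ConfigurationError(f"unknown tool modalities {sorted(unknown)}")
    return replace(task, modalities=tuple(modalities))


def battery_tasks(repertoire: Repertoire,
                  include_discrimination: bool = False) -> dict[TaskKind, list[TaskSpec]]:
    """The per-kind stimulus lists of the standard five-task battery."""
    rep = repertoire
    battery: dict[TaskKind, list[TaskSpec]] = {
        TaskKind.RECOGNIZE_FAMILIAR: [
            make_task(TaskKind.RECOGNIZE_FAMILIAR, s, rep) for s in rep.meaningful_sequences
        ],
        TaskKind.EXECUTE_VERBAL_COMMAND: [
            make_task(TaskKind.EXECUTE_VERBAL_COMMAND, c, rep)
            for c in rep.concepts if c != NONE_CONCEPT
        ],
        TaskKind.IMITATE_FAMILIAR: [
            make_task(TaskKind.IMITATE_FAMILIAR, s, rep) for s in rep.meaningful_sequences
        ],
        TaskKind.IMITATE_MEANINGLESS: [
            make_task(TaskKind.IMITATE_MEANINGLESS, s, rep) for s in rep.meaningless_sequences
        ],
        TaskKind.USE_REAL_TOOL: [
            enrich_observations(make_task(TaskKind.USE_REAL_TOOL, s, rep))
            for s in rep.meaningful_sequences
        ],
    }
    if include_discrimination:
        battery[TaskKind.DISCRIMINATE_FAMILIARITY] = [
            make_task(TaskKind.DISCRIMINATE_FAMILIARITY, s, rep) for s in rep.sequences
        ]
    return battery
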