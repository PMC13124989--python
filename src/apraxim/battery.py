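"""Battery execution, performance matrices and clinical-profile classification.

The battery runs the five standard tasks (recognition, verbal command,
imitation of familiar and of meaningless gestures, real tool use) for a
fixed number of trials each, with per-trial random streams derived
deterministically from a single seed.  Accuracies are turned into
impaired/spared flags against explicit thresholds (the literature reports
the dissociations only qualitatively, so the thresholds are part of this
package's operational definition) and the flag pattern is matched to one
of the classical limb-apraxia profiles.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from apraxim.agent import TrialTrace, run_trial
from apraxim.lesions import LesionSite, LesionSpec, apply_lesion
from apraxim.tasks import TaskKind, battery_tasks, enrich_observations, make_task
from apraxim.world import ConfigurationError, TOOL_MODALITIES, VisuomotorModel

__all__ = [
    "Thresholds",
    "PerformanceMatrix",
    "ClinicalProfile",
    "EXPECTED_PROFILES",
    "PROFILE_LABELS",
    "TARGETED_TASKS",
    "trial_rng",
    "run_battery",
    "classify_profile",
    "tool_compensation_contrast",
]

#: Battery column order (stable across runs and output files).
BATTERY_ORDER = (
    TaskKind.RECOGNIZE_FAMILIAR,
    TaskKind.EXECUTE_VERBAL_COMMAND,
    TaskKind.IMITATE_FAMILIAR,
    TaskKind.IMITATE_MEANINGLESS,
    TaskKind.USE_REAL_TOOL,
)

#: Expected impaired (I) / spared (S) pattern per severity-1 lesion, in
#: BATTERY_ORDER, together with the classical profile label.
EXPECTED_PROFILES: dict[str, tuple[str, ...]] = {
    "intact": ("S", "S", "S", "S", "S"),
    LesionSite.STRUCTURAL_A.value: ("I", "S", "S", "S", "S"),
    LesionSite.FUNCTIONAL_A.value: ("I", "I", "S", "S", "S"),
    LesionSite.PROCEDURAL_E.value: ("S", "I", "I", "S", "I"),
    LesionSite.DIRECT_C.value: ("S", "S", "S", "I", "S"),
    LesionSite.PRECISION_ALPHA.value: ("S", "I", "I", "I", "I"),
}

PROFILE_LABELS: dict[str, str] = {
    "intact": "intact",
    LesionSite.STRUCTURAL_A.value: "pantomime_agnosia",
    LesionSite.FUNCTIONAL_A.value: "conceptual_apraxia",
    LesionSite.PROCEDURAL_E.value: "procedural_apraxia",
    LesionSite.DIRECT_C.value: "conduction_apraxia",
    LesionSite.PRECISION_ALPHA.value: "action_wm_apraxia",
}

#: The task each lesion primarily targets (used by severity sweeps).
TARGETED_TASKS: dict[str, TaskKind] = {
    LesionSite.STRUCTURAL_A.value: TaskKind.RECOGNIZE_FAMILIAR,
    LesionSite.FUNCTIONAL_A.value: TaskKind.EXECUTE_VERBAL_COMMAND,
    LesionSite.PROCEDURAL_E.value: TaskKind.IMITATE_FAMILIAR,
    LesionSite.DIRECT_C.value: TaskKind.IMITATE_MEANINGLESS,
    LesionSite.PRECISION_ALPHA.value: TaskKind.IMITATE_FAMILIAR,
}


@dataclass(frozen=True)
class Thresholds:
    """Operational impaired/spared cutoffs.

    A task is impaired when accuracy <= chance + ``impaired_margin`` (chance
    being 1 / |response space| for that task) and spared when accuracy >=
    ``spared``.  The two bands must not overlap for any task.
    """

    impaired_margin: float = 0.10
    spared: float = 0.75


@dataclass
class PerformanceMatrix:
    """Task-by-accuracy table for one lesion condition."""

    accuracies: dict[str, float]
    chance: dict[str, float]
    n_trials: int
    seed: int
    lesion: LesionSpec | None = None

    def __post_init__(self) -> None:
        if self.n_trials < 1:
            raise ConfigurationError("n_trials must be >= 1")
        for task, acc in self.accuracies.items():
            if not 0.0 <= acc <= 1.0:
                raise ConfigurationError(f"accuracy for {task} outside [0, 1]")


@dataclass
class ClinicalProfile:
    """Impaired/spared flags per task and the matched clinical label."""

    label: str
    impaired: dict[str, bool]
    spared: dict[str, bool]
    accuracies: dict[str, float]

    def pattern(self) -> tuple[str, ...]:
        """I/S/ambiguous flag per task in battery order."""
        out = []
        for kind in BATTERY_ORDER:
            k = kind.value
            out.append("I" if self.impaired[k] else ("S" if self.spared[k] else "?"))
        return tuple(out)


def trial_rng(seed: int, task_index: int, trial: int) -> np.random.Generator:
    """Deterministic per-trial stream derived from the battery seed."""
    return np.random.default_rng([seed, task_index, trial])


def run_battery(
    model: VisuomotorModel,
    lesion: LesionSpec | None = None,
    n_trials: int = 200,
    seed: int = 0,
    include_discrimination: bool = False,
    collect_traces: bool = False,
) -> PerformanceMatrix | tuple[PerformanceMatrix, dict[str, list[TrialTrace]]]:
    """Apply the lesion (if any) and run every battery task.

    Each trial draws its stimulus uniformly from the task's stimulus list
    and runs on its own derived random stream, so severities sweep over
    *shared* noise realizations when the seed is held fixed.
    """
    if n_trials < 1:
        raise ConfigurationError("n_trials must be >= 1")
    patient = apply_lesion(model, lesion) if lesion is not None else model
    tasks = battery_tasks(model.repertoire, include_discrimination)
    order = list(BATTERY_ORDER) + (
        [TaskKind.DISCRIMINATE_FAMILIARITY] if include_discrimination else [])
    accuracies: dict[str, float] = {}
    chance: dict[str, float] = {}
    traces: dict[str, list[TrialTrace]] = {}
    for task_index, kind in enumerate(order):
        task_list = tasks[kind]
        n_correct = 0
        kind_traces: list[TrialTrace] = []
        for trial in range(n_trials):
            rng = trial_rng(seed, task_index, trial)
            task = task_list[int(rng.integers(len(task_list)))]
            trace = run_trial(patient, task, rng)
            n_correct += trace.correct
            if collect_traces:
                kind_traces.append(trace)
        accuracies[kind.value] = n_correct / n_trials
        chance[kind.value] = task_list[0].chance
        if collect_traces:
            traces[kind.value] = kind_traces
    matrix = PerformanceMatrix(accuracies, chance, n_trials, seed, lesion)
    return (matrix, traces) if collect_traces else matrix


def task_accuracy(
    model: VisuomotorModel,
    kind: TaskKind,
    lesion: LesionSpec | None = None,
    n_trials: int = 200,
    seed: int = 0,
) -> float:
    """Accuracy on a single battery task under an optional lesion.

    Uses the same derived trial streams as :func:`run_battery`, so sweeps
    over lesion severity at a fixed seed share their noise realizations.
    """
    patient = apply_lesion(model, lesion) if lesion is not None else model
    task_list = battery_tasks(model.repertoire)[kind]
    task_index = BATTERY_ORDER.index(kind)
    n_correct = 0
    for trial in range(n_trials):
        rng = trial_rng(seed, task_index, trial)
        task = task_list[int(rng.integers(len(task_list)))]
        n_correct += run_trial(patient, task, rng).correct
    return n_correct / n_trials


def classify_profile(matrix: PerformanceMatrix,
                     thresholds: Thresholds = Thresholds()) -> ClinicalProfile:
    """Match the impaired/spared pattern to a classical apraxia profile.

    Patterns (production = verbal command + both imitations + tool use):

    - all tasks spared -> intact;
    - recognition impaired, production spared -> pantomime agnosia;
    - verbal command impaired, both imitations spared -> conceptual apraxia;
    - imitate-familiar impaired, imitate-meaningless and recognition
      spared -> procedural apraxia;
    - imitate-meaningless impaired, the rest spared -> conduction apraxia;
    - all production impaired -> action working-memory apraxia;
    - anything else -> unclassified.
    """
    impaired: dict[str, bool] = {}
    spared: dict[str, bool] = {}
    for task, acc in matrix.accuracies.items():
        bound = matrix.chance[task] + thresholds.impaired_margin
        if bound >= thresholds.spared:
            raise ConfigurationError(
                f"impaired bound {bound:.2f} overlaps spared bound for {task}")
        impaired[task] = acc <= bound
        spared[task] = acc >= thresholds.spared
    rec = TaskKind.RECOGNIZE_FAMILIAR.value
    verb = TaskKind.EXECUTE_VERBAL_COMMAND.value
    im_f = TaskKind.IMITATE_FAMILIAR.value
    im_m = TaskKind.IMITATE_MEANINGLESS.value
    tool = TaskKind.USE_REAL_TOOL.value

    if all(spared[t] for t in (rec, verb, im_f, im_m, tool)):
        label = "intact"
    elif impaired[rec] and spared[verb] and spared[im_f] and spared[im_m]:
        label = "pantomime_agnosia"
    elif impaired[verb] and spared[im_f] and spared[im_m]:
        label = "conceptual_apraxia"
    elif impaired[im_f] and spared[im_m] and spared[rec]:
        label = "procedural_apraxia"
    elif impaired[im_m] and spared[rec] and spared[verb] and spared[im_f]:
        label = "conduction_apraxia"
    elif impaired[verb] and impaired[im_f] and impaired[im_m]:
        label = "action_wm_apraxia"
    else:
        label = "unclassified"
    return ClinicalProfile(label, impaired, spared, dict(matrix.accuracies))


def tool_compensation_contrast(
    model: VisuomotorModel,
    lesion: LesionSpec,
    n_trials: int = 200,
    seed: int = 0,
    modalities: tuple[str, ...] = TOOL_MODALITIES,
) -> tuple[float, float]:
    """Pantomime-to-command versus real-tool accuracy under semantic damage.

    Returns ``(pantomime_accuracy, real_tool_accuracy)``.  Only meaningful
    for ``functional_A`` lesions: the contrast probes whether the
    multisensory cascade of actual object manipulation compensates for
    damaged semantic access.
    """
    if LesionSite(lesion.site) is not LesionSite.FUNCTIONAL_A:
        raise ConfigurationError("tool compensation contrast requires a functional_A lesion")
    patient = apply_lesion(model, lesion)
    rep = model.repertoire
    verbal_tasks = [make_task(TaskKind.EXECUTE_VERBAL_COMMAND, c, rep)
                    for c in rep.concepts if c != "none"]
    tool_tasks = [enrich_observations(make_task(TaskKind.USE_REAL_TOOL, s, rep), modalities)
                  for s in rep.meaningful_sequences]
    accs = []
    for arm, task_list in enumerate((verbal_tasks, tool_tasks)):
        n_correct = 0
        for trial in range(n_trials):
            rng = np.random.default_rng([seed, 100 + arm, trial])
            task = task_list[int(rng.integers(len(task_list)))]
            n_correct += run_trial(patient, task, rng).correct
        accs.append(n_correct / n_trials)
    return accs[0], accs[1]
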