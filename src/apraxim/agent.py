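"""Trial execution: the full perception-inference-action loop.

A trial has two phases.  During *stimulus presentation* the agent
accumulates evidence: an observed gesture delivers one noisy kinematic
observation per fast step, each of which is turned into a bottom-up
segment posterior and sent upward as a soft observation for the sequence
factor; the sequence posterior updates at the slow-timescale boundary and
is read into a concept posterior through semantic memory.  A verbal
command delivers a phonological observation on the concept factor (plus a
prior shift toward the commanded action); a real tool delivers multisensory
affordance evidence directly on the sequence factor.

During *response production* (the execution level "proceeds at its own
pace" after presentation completes) the two routes are mixed by the gate
weight w:

- lexical route: the sequence-level drive becomes the policy prior E over
  the repertoire's motor programs, attenuated by any procedural-link
  damage, with weight w;
- direct route: smoothed per-position segment beliefs become preferred
  observations C for the goal-directed controller G, with weight 1 - w,
  attenuated by any direct-route damage.

Policies are scored by sigma(ln E - F - G) (no observations arrive while
planning, so F contributes nothing at this level) and read out action by
action through the precision-weighted softmax with the execution alpha.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from apraxim.core import (
    EPS,
    Categorical,
    column_entropies,
    floor_log,
    kl_divergence,
    normalize,
    policy_posterior,
    sample_action,
    softmax,
)
from apraxim.hierarchy import ascend, descend, soft_update
from apraxim.tasks import (
    OBSERVED_GESTURE_KINDS,
    PRODUCTION_KINDS,
    TaskKind,
    TaskSpec,
)
from apraxim.world import ConfigurationError, VisuomotorModel, route_gate

__all__ = ["TrialTrace", "run_trial", "observe_gesture", "efe_table", "plan_response"]


@dataclass
class TrialTrace:
    """Per-trial record of observations, beliefs and behavior."""

    task: TaskSpec
    observations: dict[str, list[int]]
    l1_bottom_up: list[np.ndarray]
    l2_beliefs: list[np.ndarray]
    q_sequence: Categorical
    q_concept: Categorical
    smoothed_segments: list[np.ndarray] = field(default_factory=list)
    gate_w: float | None = None
    policy_post: Categorical | None = None
    actions: list[int] = field(default_factory=list)
    response: str | tuple[str, ...] = ()
    correct: bool = False


@dataclass
class _Perception:
    observations: dict[str, list[int]]
    l1_bottom_up: list[np.ndarray]
    l2_beliefs: list[np.ndarray]
    q_sequence: Categorical
    q_concept: Categorical
    smoothed_segments: list[np.ndarray]


def _concept_posterior(model: VisuomotorModel, q_seq: Categorical,
                       prior: Categorical | None = None) -> Categorical:
    """Concept posterior from the sequence posterior via semantic memory."""
    rep = model.repertoire
    prior = prior or Categorical.uniform(len(rep.concepts), rep.concepts)
    evidence = model.A_functional.T @ q_seq.probs  # expected likelihood per concept
    return soft_update(prior, evidence)


def observe_gesture(model: VisuomotorModel, sequence_label: str,
                    rng: np.random.Generator) -> _Perception:
    """Watch one demonstrated gesture and infer segments, sequence, concept.

    The ascending messages use the bottom-up (likelihood-only) segment
    posteriors, which makes the sequence posterior exact; the descending
    predictions re-enter afterwards as empirical priors for the *smoothed*
    segment beliefs that later feed the direct route.
    """
    rep = model.repertoire
    segs = [rep.segment_index(s) for s in rep.sequences[sequence_label]]
    n_seg = len(rep.segments)
    A_kin = model.A_kin
    D_seq = model.understanding.D

    obs = [int(rng.choice(n_seg, p=A_kin[:, k])) for k in segs]

    bottom_up: list[np.ndarray] = []
    messages: list[np.ndarray] = []
    l2_beliefs: list[np.ndarray] = [D_seq.probs.copy()]
    for t, o in enumerate(obs):
        b = normalize(A_kin[o, :])
        bottom_up.append(b)
        messages.append(ascend(Categorical(b), model.A_structural[t]))
        # slow factor holds its belief until the timescale boundary
        l2_beliefs.append(l2_beliefs[-1])
    q_seq = D_seq
    for m in messages:
        q_seq = soft_update(q_seq, m)
    l2_beliefs[-1] = q_seq.probs.copy()

    q_con = _concept_posterior(model, q_seq)

    # Retrospective smoothing: exact posterior marginal over the segment at
    # each position given the whole stimulus,
    #   p(k_t | o_1..T) = sum_j q(j) link_t[k, j] p(o_t | k) / p(o_t | j).
    # With confident recognition this is descending replay of the
    # recognized sequence; with a flat (lesioned) structural link it falls
    # back to the bottom-up kinematic likelihood.
    smoothed = []
    for t, o in enumerate(obs):
        link = model.A_structural[t]
        lik = A_kin[o, :]
        per_seq_evidence = link.T @ lik  # p(o_t | sequence j)
        weights = q_seq.probs / np.maximum(per_seq_evidence, EPS)
        smoothed.append(normalize((link * lik[:, None]) @ weights))
    return _Perception({"kinematic": obs}, bottom_up, l2_beliefs, q_seq, q_con, smoothed)


def _hear_command(model: VisuomotorModel, concept: str,
                  rng: np.random.Generator) -> _Perception:
    """Verbal command: phonological observation plus a concept prior shift."""
    rep = model.repertoire
    n_con = len(rep.concepts)
    c = rep.concept_index(concept)
    prior = Categorical(normalize(
        0.5 * np.full(n_con, 1.0 / n_con) + 0.5 * np.eye(n_con)[c]), rep.concepts)
    phon_obs = int(rng.choice(model.A_phon.shape[0], p=model.A_phon[:, c]))
    q_con = soft_update(prior, model.A_phon[phon_obs, :])
    drive = descend(q_con, model.A_functional, rep.sequence_labels)
    D = model.understanding.D
    return _Perception({"phonological": [phon_obs]}, [], [D.probs.copy(), drive.probs.copy()],
                       drive, q_con, [])


def _feel_tool(model: VisuomotorModel, task: TaskSpec,
               rng: np.random.Generator) -> _Perception:
    """Real tool in hand: multisensory affordance evidence on sequences."""
    rep = model.repertoire
    j = rep.sequence_index(task.stimulus)
    q_seq = model.understanding.D
    obs: dict[str, list[int]] = {}
    for modality in task.modalities:
        A = model.A_tool[modality]
        o = int(rng.choice(A.shape[0], p=A[:, j]))
        obs[modality] = [o]
        q_seq = soft_update(q_seq, A[o, :])
    q_con = _concept_posterior(model, q_seq)
    D = model.understanding.D
    return _Perception(obs, [], [D.probs.copy(), q_seq.probs.copy()], q_seq, q_con, [])


# ---------------------------------------------------------------------------
# Response production
# ---------------------------------------------------------------------------


def efe_table(policies: np.ndarray, A: np.ndarray, C_rows: np.ndarray) -> np.ndarray:
    """Expected free energy of every policy under deterministic transitions.

    Valid when executing primitive ``a`` lands the state on ``a`` with
    certainty (the execution level's B), so the predicted state at step t
    is a delta on the policy's t-th action.  Per-step costs are then a
    lookup: ``cost[t, a] = KL(A[:, a] || sigma(C_t)) + H(A[:, a])``, and G
    sums the looked-up costs.  Agrees with
    :func:`apraxim.core.expected_free_energy` policy by policy.
    """
    policies = np.asarray(policies, dtype=int)
    horizon = policies.shape[1]
    n_obs, n_states = A.shape
    h_cols = column_entropies(A)
    cost = np.empty((horizon, n_states))
    for t in range(horizon):
        pref = softmax(C_rows[t])
        for a in range(n_states):
            cost[t, a] = kl_divergence(A[:, a], pref) + h_cols[a]
    G = np.zeros(len(policies))
    for t in range(horizon):
        G += cost[t, policies[:, t]]
    return G


def plan_response(model: VisuomotorModel, drive: Categorical,
                  direct_prefs: list[np.ndarray] | None,
                  rng: np.random.Generator) -> tuple[list[int], Categorical, float]:
    """Arbitrate the two routes, score policies, and emit motor primitives.

    ``drive`` is the lexical route's distribution over repertoire
    sequences (from the sequence posterior or from semantic access);
    ``direct_prefs`` are per-position segment beliefs from the observed
    gesture, or None when no gesture was shown.
    """
    rep = model.repertoire
    cfg = model.config
    exec_level = model.execution
    policies = model.policies
    n_pol = len(policies)
    n_seg = len(rep.segments)
    horizon = policies.shape[1]
    uniform_pol = np.full(n_pol, 1.0 / n_pol)
    uniform_seg = np.full(n_seg, 1.0 / n_seg)

    w = route_gate(drive, rep.meaningful_mask, cfg.gate_exponent)

    # Lexical route -> policy prior E (severed by procedural-link damage).
    E_lex = np.zeros(n_pol)
    np.add.at(E_lex, model.sequence_policy_rows, drive.probs)
    pd = model.procedural_link_damage
    E_informed = (1.0 - pd) * E_lex + pd * uniform_pol
    E = w * E_informed + (1.0 - w) * uniform_pol

    # Direct route -> preferred observations C (flattened by direct-route
    # damage); the risk term of G then steers toward the observed segments.
    A_exec = exec_level.A["proprioceptive"]
    cd = model.direct_route_damage
    C_rows = np.empty((horizon, n_seg))
    for t in range(horizon):
        r = direct_prefs[t] if direct_prefs is not None else uniform_seg
        p = (1.0 - w) * r + w * uniform_seg
        p = (1.0 - cd) * p + cd * uniform_seg
        C_rows[t] = floor_log(p)
    G = efe_table(policies, A_exec, C_rows)

    post = policy_posterior(E, 0.0, G)

    actions: list[int] = []
    probs = post.probs.copy()
    for t in range(horizon):
        a = sample_action(Categorical(probs), policies[:, t:], exec_level.alpha,
                          rng, n_actions=n_seg)
        actions.append(a)
        mask = policies[:, t] == a
        conditioned = probs * mask
        total = conditioned.sum()
        probs = conditioned / total if total > EPS else mask / mask.sum()
    return actions, post, w


def _argmax_with_ties(probs: np.ndarray, rng: np.random.Generator) -> int:
    top = np.flatnonzero(probs >= probs.max() - 1e-12)
    return int(top[0]) if top.size == 1 else int(rng.choice(top))


def run_trial(model: VisuomotorModel, task: TaskSpec,
              rng: np.random.Generator) -> TrialTrace:
    """Execute one clinical trial and score it.

    Recognition and familiarity judgements are read from the concept /
    sequence posteriors (belief level); production tasks are scored by
    exact ordered match between the emitted segment sequence and the
    target.
    """
    rep = model.repertoire
    kind = task.kind
    if kind in OBSERVED_GESTURE_KINDS:
        perception = observe_gesture(model, task.stimulus, rng)
        direct_prefs: list[np.ndarray] | None = perception.smoothed_segments
    elif kind is TaskKind.EXECUTE_VERBAL_COMMAND:
        perception = _hear_command(model, task.stimulus, rng)
        direct_prefs = None
    elif kind is TaskKind.USE_REAL_TOOL:
        perception = _feel_tool(model, task, rng)
        direct_prefs = None
    else:  # pragma: no cover - TaskSpec construction already validates
        raise ConfigurationError(f"unsupported task kind {kind!r}")

    trace = TrialTrace(
        task=task,
        observations=perception.observations,
        l1_bottom_up=perception.l1_bottom_up,
        l2_beliefs=perception.l2_beliefs,
        q_sequence=perception.q_sequence,
        q_concept=perception.q_concept,
        smoothed_segments=perception.smoothed_segments,
    )

    if kind is TaskKind.RECOGNIZE_FAMILIAR:
        c = _argmax_with_ties(perception.q_concept.probs, rng)
        trace.response = rep.concepts[c]
    elif kind is TaskKind.DISCRIMINATE_FAMILIARITY:
        meaningful_mass = float(
            perception.q_sequence.probs[rep.meaningful_mask].sum())
        trace.response = "meaningful" if meaningful_mass > 0.5 else "meaningless"
    elif kind in PRODUCTION_KINDS:
        actions, post, w = plan_response(model, perception.q_sequence,
                                         direct_prefs, rng)
        trace.actions = actions
        trace.policy_post = post
        trace.gate_w = w
        trace.response = tuple(rep.segments[a] for a in actions)
    trace.correct = trace.response == task.correct_response
    return trace
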