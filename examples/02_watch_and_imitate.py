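"""One intact trial of gesture observation and imitation.

The agent watches a demonstrated hammering gesture (three noisy kinematic
observations), infers the movement segments, the sequence and its concept,
then reproduces the gesture through the execution level.
"""

import numpy as np

from apraxim import TaskKind, build_world, make_task, run_trial

model = build_world()
task = make_task(TaskKind.IMITATE_FAMILIAR, "hammering", model.repertoire)
trace = run_trial(model, task, np.random.default_rng(0))

rep = model.repertoire
print(f"stimulus gesture : {rep.sequences['hammering']}")
print(f"kinematic obs    : {[rep.segments[o] for o in trace.observations['kinematic']]}")
seq_belief = {k: round(float(v), 3) for k, v in zip(rep.sequence_labels, trace.q_sequence.probs)}
con_belief = {k: round(float(v), 3) for k, v in zip(rep.concepts, trace.q_concept.probs)}
print(f"sequence belief  : {seq_belief}")
print(f"concept belief   : {con_belief}")
print(f"lexical gate w   : {trace.gate_w:.3f}  (near 1: familiar gesture, lexical route)")
print(f"imitated response: {trace.response}  correct={trace.correct}")
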