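"""Core active-inference machinery on a tiny two-state problem.

Builds a 2-state/2-observation agent, performs exact state inference,
evaluates the two decompositions of variational free energy, and scores a
one-step policy by expected free energy (risk + ambiguity).
"""

import numpy as np

from apraxim import Categorical, expected_free_energy, infer_states, variational_free_energy
from apraxim.core import floor_log

prior = Categorical(np.array([0.5, 0.5]), labels=("left", "right"))
A = np.array([[0.9, 0.1],
              [0.1, 0.9]])  # p(observation | state)

post = infer_states(prior, A, obs=0)
print(f"posterior after observing cue 0: {np.round(post.probs, 4)}")
# -> mass moves onto 'left', the state that best predicts the cue

f_div = variational_free_energy(post, prior, A, obs=0, form="divergence")
f_eng = variational_free_energy(post, prior, A, obs=0, form="energy")
print(f"free energy at the posterior: {f_div:.6f} nats "
      f"(energy form {f_eng:.6f}, both equal -ln p(o))")

B = np.stack([np.eye(2)])                     # a single 'stay' action
C = floor_log(np.array([0.8, 0.2]))           # prefer observation 0
G = expected_free_energy(np.array([0]), prior, B, A, C)
print(f"expected free energy of staying: {G:.6f} nats")
print("  = risk (predictions vs preferences) + ambiguity (likelihood entropy);")
print("  lower G marks policies that reach preferred, unambiguous outcomes")
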