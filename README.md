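# apraxim

Virtual-lesion simulation of **limb apraxia** in a hierarchical
active-inference model of the visuomotor system.

Limb apraxia is a disorder of intentional action that fractionates into
strikingly selective profiles: patients who imitate gestures they cannot
recognize (pantomime agnosia), who cannot pantomime to verbal command but
imitate normally (conceptual apraxia), who recognize familiar gestures but
cannot execute them while still imitating meaningless ones (procedural
apraxia), who fail only at imitating novel gestures (conduction apraxia),
or whose every production is imprecise (action working-memory apraxia).
`apraxim` implements a computational account of this spectrum: the
visuomotor system is a three-level discrete active-inference agent —
kinematic analysis → movement segments → action sequences and concepts →
motor execution — and each clinical profile is produced by damaging one
identified component of the generative model.

The agent perceives by minimizing variational free energy
`F = KL[q(s) || p(s|o)] − ln p(o)`, plans by minimizing expected free
energy `G(π) = risk + ambiguity`, selects policies through
`π = σ(ln E − F − G)` and executes them with action precision α.  Five
parameterized lesion operators target, respectively: the structural
likelihood mapping segments to sequences, the semantic likelihood mapping
sequences to concepts, the link informing the policy prior E, the
preferences C informing the goal-directed controller G, and α itself.  A
clinical task battery (recognition, verbal command, imitation of familiar
and meaningless gestures, real tool use) turns each lesioned model into an
impaired/spared profile.  See `docs/methods.md` for the full model
description.

Intended for computational neuropsychologists and active-inference
researchers who want a small, fully seeded, testable sandbox for
lesion-to-behavior reasoning.

## Worked example

```python
from apraxim import LesionSpec, build_world, classify_profile, run_battery

model = build_world()                     # canonical 8-segment world
lesion = LesionSpec("procedural_E", 1.0)  # sever the lexical drive into E
matrix = run_battery(model, lesion, n_trials=200, seed=42)
print(matrix.accuracies)
print(classify_profile(matrix).label)
```

prints

```
{'recognize_familiar': 1.0, 'execute_verbal_command': 0.005,
 'imitate_familiar': 0.0, 'imitate_meaningless': 0.99, 'use_real_tool': 0.005}
procedural_apraxia
```

Recognition is perfect (the perceptual hierarchy is untouched) while
familiar-gesture execution collapses to chance — although the direct
visuomotor route is intact, familiar input captures the lexical route
near winner-take-all, so the intact route cannot compensate.  Meaningless
imitation (0.99) rides that direct route unharmed.  This is the
execution-subtype dissociation of procedural apraxia.

The `examples/` directory walks through each capability: belief updating
and free-energy functionals (`01`), a single observe-and-imitate trial
(`02`), the full lesion-by-task dissociation matrix (`03`), and the
multisensory compensation of semantic damage during real tool use (`04`).
A thin CLI wraps the same machinery:

```bash
apraxim reproduce-paper            # intact + 5 lesions, PASS/FAIL per cell
apraxim run --lesion direct_C --severity 1 --trials 200 --seed 42
apraxim make-fixture --out world.json
```

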