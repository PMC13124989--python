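"""Multisensory compensation of semantic damage during real tool use.

With semantic memory fully flattened (conceptual apraxia), pantomime to
verbal command collapses to chance among the known gestures, but handling
the real tool restores performance: tactile, auditory and visual
consequences act as affordance evidence that re-constrains the motor
program directly.
"""

from apraxim import LesionSpec, build_world, tool_compensation_contrast

model = build_world()
for severity in (0.0, 1.0):
    lesion = LesionSpec("functional_A", severity)
    pantomime, tool = tool_compensation_contrast(model, lesion, n_trials=200, seed=42)
    print(f"severity {severity:.0%}: pantomime-to-command {pantomime:.3f}, "
          f"real tool {tool:.3f}, gap {tool - pantomime:+.3f}")
print("\nat severity 1 the gap is the behavioral signature of temporary")
print("recovery; at severity 0 enrichment is redundant and the gap vanishes.")
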