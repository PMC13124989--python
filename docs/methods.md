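# Methods

## The model

`apraxim` simulates the human visuomotor system as a hierarchical discrete
active-inference agent — a stack of coupled POMDPs whose beliefs are
categorical distributions and whose structures are the standard A/B/C/D/E
arrays of discrete active inference:

- **A (likelihood)** maps hidden states to observations (column-stochastic);
- **B (transition)** maps states across time, one slice per action;
- **C (preferences)** are log-priors over observations that bias
  goal-directed selection through the expected free energy;
- **D** is the initial-state prior; **E** the habitual prior over policies;
- **α (action precision)** controls how faithfully the selected policy is
  translated into executed movements.

Perception minimizes variational free energy

    F(q, o) = KL[q(s) || p(s|o)] − ln p(o)
            = E_q[ln q(s) − ln p(o, s)],

which for a single state factor is attained exactly at the Bayes posterior
(the package computes that posterior in closed form; both decompositions
are implemented and must agree, which the tests check to 1e-8).  Planning
scores each policy π by expected free energy

    G(π) = Σ_t KL[q(o_t|π) || σ(C_t)] + E_{q(s_t|π)}[H[p(o|s)]]

(risk plus ambiguity, additive over the policy's steps), and the policy
posterior is σ(ln E − F − G).  No observations arrive while the execution
level plans, so F contributes nothing there; it is exercised and tested at
the perceptual levels.  Actions are read out one step at a time by
marginalizing the (progressively conditioned) policy posterior onto the
current step's actions m and sampling from σ(α ln m): α = 0 yields uniform
random acts, large α the planned act almost surely.

### The three levels

1. **Action observation** — hidden states are movement segments (grasp,
   lift, strike, …) observed through a noisy kinematic likelihood
   `A_kin = (1 − ε)I + ε·uniform-off-diagonal`.
2. **Action understanding** — hidden states are segment sequences
   (hammering = grasp → lift → strike), linked to segments by one
   structural likelihood per position (the action input system) and to
   concepts by the functional likelihood (semantic memory).  Verbal labels
   reach the concept factor through the phonological lexicon.
3. **Action execution** — motor primitives with deterministic transitions,
   one candidate policy per possible segment triple, precision α.

Levels run at different timescales: the sequence factor integrates one
step per `timescale = 3` kinematic steps.  Ascending messages are **soft
evidence**: the lower level's bottom-up posterior (likelihood times a
uniform prior), pushed through the structural link and multiplied into the
upper prior at the timescale boundary.  Using the bottom-up posterior —
rather than a posterior already shaped by descending predictions — avoids
double-counting evidence and makes the hierarchical update *exact*: it
reproduces brute-force inference on the flattened joint model, which is
how the tests validate it.

Descending influence appears in two places: as empirical priors (semantic
access maps a recognized concept onto its sequence; a verbal command also
shifts the concept-level initial prior), and in the *smoothed* segment
beliefs computed after the stimulus ends,

    p(k_t | o_1..T) ∝ Σ_j q(j) · link_t[k, j] · p(o_t | k) / p(o_t | j),

the exact per-position posterior marginal.  When recognition is confident
this is top-down replay of the recognized sequence (a single misperceived
frame is corrected); when the structural link is flat (lesioned) it falls
back to the raw kinematic likelihood.  Production runs only after the
stimulus completes — tasks are observe-then-respond, with no interleaved
re-observation.

### Route arbitration

Three routes connect vision to movement.  The *lexical* routes drive the
execution-level policy prior E with the sequence-level drive (the sequence
posterior for observed gestures; semantic access for commands and tools).
The *direct* route turns the smoothed segment beliefs into preferred
observations C, steering the goal-directed controller G.  They are mixed
by a gate

    w = m^g / (m^g + (1 − m)^g),   m = posterior mass on meaningful sequences,

with gate exponent g = 4: familiar gestures are captured near
winner-take-all by the lexical route, meaningless ones fall through to the
direct route.  The sharp gate is what resolves the apparent paradox of
procedural apraxia — with the lexical link to E severed, familiar-gesture
imitation fails even though the direct route is intact, because the intact
route is automatically suppressed for recognized-familiar input (w ≈ 1
shuts the direct preferences off); meaningless gestures set w ≈ 0 and are
imitated normally.  The lexical drive covers all repertoire sequences
(including the known-meaningless ones); selectivity of the lexical route
for meaningful material is enforced entirely by the gate.

### Virtual lesions

All lesions are convex mixtures toward the flat structure, parameterized
by a severity in [0, 1] (the clinical descriptions only fix the endpoint;
the graded dial supports monotonicity checks and future phenotyping):

| site              | transformation                                  | profile at severity 1 |
|-------------------|--------------------------------------------------|-----------------------|
| `structural_A`    | flatten segment-given-sequence likelihoods       | pantomime agnosia     |
| `functional_A`    | flatten sequence-given-concept likelihood        | conceptual apraxia    |
| `procedural_E`    | sever the drive into E (uniform regardless of recognition) | procedural apraxia |
| `direct_C`        | flatten the C informing G (ambiguity retained)   | conduction apraxia    |
| `precision_alpha` | α ← α(1 − severity)                              | action working-memory apraxia |

`procedural_E` and `direct_C` are implemented as *severed links* (runtime
attenuation of the information flowing into E and C) rather than static
flattening, so they stay inert at severity 0 bit-for-bit and never touch
stored structures.

## Tasks and scoring

Five tasks, 200 trials each by default, stimuli drawn uniformly per trial:
recognition of familiar gestures (response = modal concept, random
tie-breaking so flat posteriors behave as guesses), execution on verbal
command, imitation of familiar and of meaningless gestures, and real tool
use with three intact multisensory modalities (tactile, auditory, visual
consequence) delivering affordance evidence on the sequence factor.
Production is scored by exact ordered segment match.  An optional sixth
probe (familiarity discrimination, thresholding the meaningful posterior
mass at 0.5) is available but not part of the headline matrix.

Recognition under `precision_alpha` is scored from the concept posterior
(belief level): the motor readout noise applies to gesture production, not
to the verbal report of a recognized concept.

The tool modalities are attached to the *sequence* factor rather than the
concept factor: real object manipulation constrains the space of motor
programs through affordances and motor priors stored in sensorimotor
associations, which is what lets rich multisensory input compensate for a
fully flattened semantic mapping (evidence routed through the flat mapping
itself could never reach action selection).  In this parameterization the
compensation is near-complete rather than partial.

Chance levels are 1/|response space| with the response space defined as
the task's stimulus set (4 concepts for recognition; 3 meaningful gestures
for command, familiar imitation and tool use; 2 meaningless gestures for
meaningless imitation).  A task is *impaired* at accuracy ≤ chance + 0.10
and *spared* at ≥ 0.75; profiles are matched on the resulting flag
pattern (intact, the five apraxias, otherwise unclassified).

## Default parameters

| parameter | default | meaning |
|---|---|---|
| segments / sequences / concepts | 8 / 3+2 / 3+NONE | smallest world exhibiting every dissociation |
| sequence length | 3 | matches the canonical grasp → lift → strike example |
| ε (kinematic confusion) | 0.05 | probability a segment is misregistered |
| ε_tool (per-modality confusion) | 0.05 | one confusion scale for all perceptual channels |
| α (action precision) | 16 | near-faithful motor readout when intact |
| gate exponent g | 4 | near-winner-take-all lexical capture, still continuous |
| probability floor | 1e-16 | all logs floored; keeps flat/delta structures well defined |

All randomness flows from a single seed; per-trial generators are derived
as `default_rng([seed, task_index, trial])`, so severity sweeps at a fixed
seed share their noise realizations and severity-0 lesions replay intact
trials bit-for-bit.

## What the synthetic world does and does not capture

The generator emulates the *computational* structure of gesture
processing: noisy categorical kinematics, compositional sequences, a
semantic layer with verbal access, and multisensory consequences of tool
use.  It does not model continuous kinematics or body-schema geometry,
saccadic information sampling during observation, learning of the
likelihood structures, reaction times, or error taxonomies (spatial vs
content errors).  Meaningless sequences are drawn from the same segment
alphabet and are stored as structural descriptions known to be
meaningless, rather than being truly novel movements.  Passing the battery
therefore shows that the *lesion-to-dissociation logic* is coherent and
reproducible, not that the model fits patient kinematics.

## Numerical choices and degenerate cases

Zero-probability entries are floored at 1e-16 inside every logarithm, so
severity-1 lesions (exact flat or delta structures) never produce
infinities.  An observation with zero likelihood under the entire prior
support raises a degenerate-evidence error instead of silently
renormalizing.  Exactly tied recognition posteriors are resolved by a
uniform draw among the maximizers.  The execution level's expected free
energy is computed by a per-(step, action) cost table — valid because its
transitions are deterministic — and is tested for equality against the
generic per-policy implementation.

## Problem sizes

Default runs use 200 trials per task per condition (binomial SE ≤ 0.035),
512 execution policies (8³ segment triples) and the 5-sequence canonical
repertoire; a full six-condition battery plus severity sweeps completes in
a few seconds on one CPU.
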