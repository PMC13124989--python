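"""The five virtual-lesion operators.

Each lesion is a pure, site-local transformation of a
:class:`~apraxim.world.VisuomotorModel` with a graded severity in [0, 1]
implemented as a convex mixture toward the maximally entropic (flat)
structure; severity 1 reproduces the fully "flat" endpoint and severity 0
is an exact no-op.

Sites and their clinical correspondences:

- ``structural_A``:   flatten the action input system (segment | sequence
  likelihoods) -> pantomime agnosia;
- ``functional_A``:   flatten semantic memory (sequence | concept) ->
  conceptual (semantic ideational) apraxia;
- ``procedural_E``:   sever the link from the understanding level into the
  execution policy prior E -> procedural apraxia;
- ``direct_C``:       sever the visuomotor conversion link so preferences C
  are flat and the goal-directed controller G carries no target ->
  conduction apraxia;
- ``precision_alpha``: scale down the action precision alpha -> action
  working-memory apraxia.
"""

from __future__ import annotations

import enum
from dataclasses import dataclass

import numpy as np

from apraxim.core import Categorical, floor_log, softmax
from apraxim.world import ConfigurationError, VisuomotorModel

__all__ = [
    "LesionSite",
    "LesionSpec",
    "flatten_likelihood",
    "flatten_policy_prior",
    "flatten_preferences",
    "scale_precision",
    "apply_lesion",
]


class LesionSite(str, enum.Enum):
    STRUCTURAL_A = "structural_A"
    FUNCTIONAL_A = "functional_A"
    PROCEDURAL_E = "procedural_E"
    DIRECT_C = "direct_C"
    PRECISION_ALPHA = "precision_alpha"


@dataclass(frozen=True)
class LesionSpec:
    """Site plus severity in the closed unit interval."""

    site: LesionSite
    severity: float

    def __post_init__(self) -> None:
        object.__setattr__(self, "site", LesionSite(self.site))
        if not 0.0 <= self.severity <= 1.0:
            raise ConfigurationError("lesion severity must lie in [0, 1]")


def flatten_likelihood(A: np.ndarray, severity: float) -> np.ndarray:
    """Mix every state column of a likelihood with the uniform distribution.

    Column entropy is nondecreasing in severity; severity 1 renders the
    mapping maximally entropic ("flat").
    """
    A = np.asarray(A, dtype=float)
    n_obs = A.shape[0]
    uniform = np.full_like(A, 1.0 / n_obs)
    return (1.0 - severity) * A + severity * uniform


def flatten_policy_prior(E: Categorical | np.ndarray, severity: float) -> Categorical:
    """Mix a policy prior with the uniform prior over policies."""
    probs = E.probs if isinstance(E, Categorical) else np.asarray(E, dtype=float)
    labels = E.labels if isinstance(E, Categorical) else None
    uniform = np.full_like(probs, 1.0 / probs.size)
    return Categorical((1.0 - severity) * probs + severity * uniform, labels)


def flatten_preferences(C: np.ndarray, severity: float) -> np.ndarray:
    """Flatten log-preferences: mix sigma(C) with uniform, back to log space."""
    C = np.asarray(C, dtype=float)
    p = softmax(C)
    uniform = np.full_like(p, 1.0 / p.size)
    return floor_log((1.0 - severity) * p + severity * uniform)


def scale_precision(alpha: float, severity: float) -> float:
    """Attenuate action precision; severity 1 gives alpha = 0 (random acts)."""
    if alpha < 0:
        raise ConfigurationError("alpha must be nonnegative")
    return alpha * (1.0 - severity)


def apply_lesion(model: VisuomotorModel, spec: LesionSpec) -> VisuomotorModel:
    """Return a lesioned copy of the model; structures off-site are untouched."""
    spec = LesionSpec(spec.site, spec.severity)  # normalizes string sites
    lesioned = model.copy()
    s = spec.severity
    if spec.site is LesionSite.STRUCTURAL_A:
        lesioned.A_structural = [flatten_likelihood(a, s) for a in model.A_structural]
        for t, link in enumerate(lesioned.A_structural):
            lesioned.understanding.A[f"segment_pos{t}"] = link
    elif spec.site is LesionSite.FUNCTIONAL_A:
        lesioned.A_functional = flatten_likelihood(model.A_functional, s)
    elif spec.site is LesionSite.PROCEDURAL_E:
        # The motor program in memory is disconnected from procedural
        # control: the link informing E is severed, not E merely reweighted.
        lesioned.procedural_link_damage = s
    elif spec.site is LesionSite.DIRECT_C:
        # Sever the visuomotor conversion: the C informing G at the
        # execution level is flattened; ambiguity bookkeeping is retained.
        lesioned.direct_route_damage = s
    elif spec.site is LesionSite.PRECISION_ALPHA:
        lesioned.execution.alpha = scale_precision(model.execution.alpha, s)
    else:  # pragma: no cover - LesionSpec validates the site
        raise ConfigurationError(f"unknown lesion site {spec.site!r}")
    return lesioned
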