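"""Coupling between generative levels.

The visuomotor model stacks three levels that exchange messages in both
directions: posterior beliefs at a lower level become (soft) observations
for the level above, while posteriors at an upper level descend as
empirical priors for the level below.  Levels run at different timescales:
the action-understanding level integrates one step per ``timescale``
fast steps of the action-observation level.

Ascending messages are soft evidence, not sampled hard observations.  When
the message is the lower level's *bottom-up* posterior (likelihood times a
uniform prior), the product-of-messages update below is exact: it recovers
the same upper posterior as enumerating the flattened joint model.  This is
what makes the hierarchy testable against a brute-force oracle.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from apraxim.core import (
    EPS,
    Categorical,
    DegenerateEvidenceError,
    assert_column_stochastic,
    normalize,
)

__all__ = [
    "GenerativeLevel",
    "ascend",
    "soft_update",
    "descend",
    "filter_upper",
]


@dataclass
class GenerativeLevel:
    """One level of the hierarchy: its A/B/C/D/E structures and dynamics.

    Parameters
    ----------
    name : level identifier (``action_observation``, ``action_understanding``
        or ``action_execution``).
    A : one column-stochastic likelihood per observation modality.
    B : (n_actions, n_states, n_states) transition array, or None for
        levels whose hidden state is static within a trial.
    C : log-preferences per modality (empty for purely perceptual levels).
    D : initial-state prior.
    E : policy prior, or None.
    policies : (n_policies, horizon) integer array, or None.
    alpha : action precision (inverse temperature of the motor readout).
    timescale : number of lower-level steps per step of this level.
    """

    name: str
    A: dict[str, np.ndarray]
    D: Categorical
    B: np.ndarray | None = None
    C: dict[str, np.ndarray] = field(default_factory=dict)
    E: Categorical | None = None
    policies: np.ndarray | None = None
    alpha: float = 1.0
    timescale: int = 1

    def __post_init__(self) -> None:
        if self.timescale < 1:
            raise ValueError("timescale must be a positive integer")
        if self.alpha < 0:
            raise ValueError("alpha must be nonnegative")
        for modality, A in self.A.items():
            self.A[modality] = assert_column_stochastic(A, f"A[{modality}]")
        if self.B is not None:
            self.B = assert_column_stochastic(np.asarray(self.B, float), "B")

    @property
    def n_states(self) -> int:
        return len(self.D)


def ascend(lower_posterior: Categorical, link: np.ndarray) -> np.ndarray:
    """Soft observation evidence for the upper level.

    ``link[k, j]`` is the probability that upper state j emits lower-state
    observation k.  The returned message is the expected likelihood of the
    lower posterior under each upper state, normalized for numerical
    convenience (the scale cancels in the posterior update).

    A delta lower posterior on k reduces exactly to the hard observation
    ``obs = k`` (the message is row k of the link).
    """
    link = np.asarray(link, dtype=float)
    weights = link.T @ lower_posterior.probs
    return normalize(weights)


def soft_update(prior: Categorical, evidence: np.ndarray) -> Categorical:
    """Posterior from a prior and a soft-evidence weight vector."""
    evidence = np.asarray(evidence, dtype=float)
    joint = prior.probs * evidence
    if joint.sum() <= EPS:
        raise DegenerateEvidenceError("soft evidence has zero overlap with prior")
    return Categorical(normalize(joint), prior.labels)


def descend(upper_posterior: Categorical, link: np.ndarray,
            labels: tuple[str, ...] | None = None) -> Categorical:
    """Empirical prior for the lower level (Bayesian model average).

    The upper posterior is pushed through the link ``p(lower | upper)``:
    ``prior_lower = link @ q_upper``, renormalized.
    """
    link = np.asarray(link, dtype=float)
    return Categorical(normalize(link @ upper_posterior.probs), labels)


def filter_upper(
    D: Categorical,
    links: list[np.ndarray],
    A: np.ndarray,
    observations: list[int],
) -> tuple[Categorical, list[np.ndarray]]:
    """Upper-level posterior after a window of lower-level observations.

    For each fast step t the lower level forms a bottom-up posterior from
    its observation (likelihood row of ``A`` times a uniform prior); the
    ascending message is accumulated multiplicatively and applied to the
    upper prior at the slow-step boundary.  Equivalent to exact inference
    on the flattened joint model when lower states are conditionally
    independent across steps given the upper state.

    Returns the upper posterior and the list of bottom-up lower posteriors.
    """
    A = np.asarray(A, dtype=float)
    q = D
    bottom_up: list[np.ndarray] = []
    for t, obs in enumerate(observations):
        b = normalize(A[obs, :])
        bottom_up.append(b)
        q = soft_update(q, ascend(Categorical(b), links[t]))
    return q, bottom_up
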