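"""Single-level discrete active-inference machinery.

Beliefs, priors and inter-level messages are categorical distributions
over finite label sets.  A generative level is parameterized by
column-stochastic likelihood (A) and transition (B) arrays, log-preferences
over observations (C), an initial-state prior (D) and a policy prior (E).
Perception is exact Bayesian state inference scored by variational free
energy; planning scores candidate policies by expected free energy (risk
plus ambiguity); the policy posterior is read out into motor acts through a
precision-weighted softmax with inverse temperature ``alpha``.

All logarithms are floored at ``EPS`` so that degenerate (flat or delta)
structures produced by lesion operators remain well defined.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

__all__ = [
    "EPS",
    "Categorical",
    "DegenerateEvidenceError",
    "normalize",
    "floor_log",
    "softmax",
    "entropy",
    "kl_divergence",
    "assert_column_stochastic",
    "column_entropies",
    "infer_states",
    "variational_free_energy",
    "expected_free_energy",
    "policy_posterior",
    "action_marginal",
    "sample_action",
]

#: Probability floor applied before every logarithm (so log >= ~-36.8 nats).
EPS = 1e-16

_ATOL = 1e-8


class DegenerateEvidenceError(ValueError):
    """Raised when an observation carries zero likelihood under every state."""


def normalize(p: np.ndarray) -> np.ndarray:
    """Rescale a nonnegative vector to sum to one.

    Raises :class:`DegenerateEvidenceError` if the total mass is
    numerically zero, because the corresponding posterior is undefined.
    """
    p = np.asarray(p, dtype=float)
    total = p.sum()
    if not np.isfinite(total) or total <= EPS:
        raise DegenerateEvidenceError("cannot normalize a zero-mass vector")
    return p / total


def floor_log(p: np.ndarray | float) -> np.ndarray:
    """Elementwise natural log with probabilities floored at ``EPS``."""
    return np.log(np.maximum(p, EPS))


def softmax(x: np.ndarray) -> np.ndarray:
    x = np.asarray(x, dtype=float)
    x = x - x.max()
    e = np.exp(x)
    return e / e.sum()


def entropy(p: np.ndarray) -> float:
    """Shannon entropy in nats (0 * log 0 treated as 0)."""
    p = np.asarray(p, dtype=float)
    return float(-(p * floor_log(p)).sum())


def kl_divergence(p: np.ndarray, q: np.ndarray) -> float:
    """KL(p || q) in nats, with floored logs."""
    p = np.asarray(p, dtype=float)
    q = np.asarray(q, dtype=float)
    return float((p * (floor_log(p) - floor_log(q))).sum())


def assert_column_stochastic(A: np.ndarray, name: str = "A") -> np.ndarray:
    """Validate that every column (per trailing slice) sums to one."""
    A = np.asarray(A, dtype=float)
    if np.any(A < -_ATOL):
        raise ValueError(f"{name} has negative entries")
    sums = A.sum(axis=-2)
    if not np.allclose(sums, 1.0, atol=_ATOL):
        raise ValueError(f"{name} columns must sum to 1 (got {sums})")
    return A


def column_entropies(A: np.ndarray) -> np.ndarray:
    """Entropy of each state-conditional outcome distribution H[p(o|s)]."""
    A = np.asarray(A, dtype=float)
    return -(A * floor_log(A)).sum(axis=0)


@dataclass(frozen=True)
class Categorical:
    """Normalized probability vector over a finite, ordered label set.

    The universal currency of the model: variational posteriors q(s),
    priors D and E, policy posteriors and inter-level messages are all
    instances of this type.
    """

    probs: np.ndarray
    labels: tuple[str, ...] | None = field(default=None)

    def __post_init__(self) -> None:
        p = np.asarray(self.probs, dtype=float)
        if p.ndim != 1:
            raise ValueError("probs must be one-dimensional")
        if np.any(p < -_ATOL):
            raise ValueError("probabilities must be nonnegative")
        if abs(p.sum() - 1.0) > _ATOL:
            raise ValueError(f"probabilities must sum to 1 (got {p.sum()})")
        if self.labels is not None and len(self.labels) != p.size:
            raise ValueError("labels and probs must have the same length")
        object.__setattr__(self, "probs", p)
        if self.labels is not None:
            object.__setattr__(self, "labels", tuple(self.labels))

    # -- constructors ----------------------------------------------------
    @classmethod
    def uniform(cls, n: int, labels: tuple[str, ...] | None = None) -> "Categorical":
        return cls(np.full(n, 1.0 / n), labels)

    @classmethod
    def delta(cls, index: int, n: int, labels: tuple[str, ...] | None = None) -> "Categorical":
        p = np.zeros(n)
        p[index] = 1.0
        return cls(p, labels)

    @classmethod
    def from_unnormalized(
        cls, weights: np.ndarray, labels: tuple[str, ...] | None = None
    ) -> "Categorical":
        return cls(normalize(weights), labels)

    # -- conveniences ----------------------------------------------------
    def __len__(self) -> int:
        return self.probs.size

    def entropy(self) -> float:
        return entropy(self.probs)

    def kl_to(self, other: "Categorical") -> float:
        return kl_divergence(self.probs, other.probs)

    def mode(self) -> int:
        return int(np.argmax(self.probs))

    def label_of_mode(self) -> str:
        if self.labels is None:
            raise ValueError("distribution carries no labels")
        return self.labels[self.mode()]


# ---------------------------------------------------------------------------
# Perception
# ---------------------------------------------------------------------------


def infer_states(prior: Categorical, A: np.ndarray, obs: int) -> Categorical:
    """Exact Bayesian state posterior after a single observation.

    For a single state factor, the free-energy-minimizing variational
    posterior is the exact posterior ``prior(s) * A[obs, s] / p(o)``.

    Parameters
    ----------
    prior : Categorical over hidden states.
    A : (n_obs, n_states) column-stochastic likelihood mapping.
    obs : observed outcome index (row of ``A``).
    """
    A = np.asarray(A, dtype=float)
    evidence = A[obs, :]
    joint = prior.probs * evidence
    if joint.sum() <= EPS:
        raise DegenerateEvidenceError(
            f"observation {obs} has zero likelihood under the prior support"
        )
    return Categorical(normalize(joint), prior.labels)


def variational_free_energy(
    q: Categorical,
    prior: Categorical,
    A: np.ndarray,
    obs: int,
    *,
    form: str = "divergence",
) -> float:
    """Variational free energy F(q, o) in nats.

    Two algebraically equivalent decompositions are exposed:

    - ``form="divergence"``: KL[q(s) || p(s|o)] - ln p(o)
      (divergence from the exact posterior minus log evidence);
    - ``form="energy"``: E_q[ln q(s) - ln p(o, s)]
      (expected energy minus entropy).

    With ``q`` equal to the exact posterior, F = -ln p(o).
    """
    A = np.asarray(A, dtype=float)
    joint = prior.probs * A[obs, :]
    p_o = joint.sum()
    if form == "divergence":
        posterior = infer_states(prior, A, obs)
        return q.kl_to(posterior) - float(floor_log(p_o))
    if form == "energy":
        return float((q.probs * (floor_log(q.probs) - floor_log(joint))).sum())
    raise ValueError(f"unknown form {form!r}")


# ---------------------------------------------------------------------------
# Planning
# ---------------------------------------------------------------------------


def _preferences_per_step(C: np.ndarray, horizon: int, n_obs: int) -> np.ndarray:
    """Broadcast log-preferences to one preferred-outcome row per step."""
    C = np.asarray(C, dtype=float)
    if C.ndim == 1:
        C = np.tile(C, (horizon, 1))
    if C.shape != (horizon, n_obs):
        raise ValueError(f"C must have shape ({horizon}, {n_obs}); got {C.shape}")
    return C


def expected_free_energy(
    policy: np.ndarray,
    belief: Categorical,
    B: np.ndarray,
    A: np.ndarray,
    C: np.ndarray,
) -> float:
    """Expected free energy G(pi) of a policy, in nats.

    The per-step predicted state distribution q(s|pi) is rolled forward
    through the action-conditional transitions ``B``; at every step

        G += KL[q(o|pi) || sigma(C_t)]  +  E_{q(s|pi)}[H[p(o|s)]]

    i.e. risk (divergence of predicted from preferred outcomes) plus
    ambiguity (expected entropy of the likelihood).  G is additive over
    policy steps; a deterministic likelihood has zero ambiguity.

    Parameters
    ----------
    policy : 1-D integer array of action indices.
    belief : current state belief q(s).
    B : (n_actions, n_states, n_states) transitions, column-stochastic
        per action slice.
    A : (n_obs, n_states) likelihood mapping.
    C : log-preferences over observations; either a single row shared by
        all steps or one row per policy step.
    """
    policy = np.asarray(policy, dtype=int)
    A = np.asarray(A, dtype=float)
    B = np.asarray(B, dtype=float)
    C = _preferences_per_step(C, policy.size, A.shape[0])
    h_cols = column_entropies(A)
    q = belief.probs
    G = 0.0
    for t, a in enumerate(policy):
        q = B[a] @ q
        q_o = A @ q
        preferred = softmax(C[t])
        G += kl_divergence(q_o, preferred) + float(q @ h_cols)
    return float(G)


def policy_posterior(E: np.ndarray, F: np.ndarray | float, G: np.ndarray) -> Categorical:
    """Posterior over policies: sigma(ln E - F - G).

    ``E`` is the habitual policy prior (epsilon-floored before the log);
    ``F`` and ``G`` are per-policy variational and expected free energies
    (scalars broadcast).
    """
    E = np.asarray(E, dtype=float)
    logits = floor_log(E) - np.asarray(F, dtype=float) - np.asarray(G, dtype=float)
    return Categorical(softmax(logits))


def action_marginal(
    policy_post: Categorical, policies: np.ndarray, n_actions: int, step: int = 0
) -> np.ndarray:
    """Marginalize a policy posterior onto the actions taken at ``step``."""
    policies = np.asarray(policies, dtype=int)
    m = np.bincount(policies[:, step], weights=policy_post.probs, minlength=n_actions)
    return m


def sample_action(
    policy_post: Categorical,
    policies: np.ndarray,
    alpha: float,
    rng: np.random.Generator,
    n_actions: int | None = None,
) -> int:
    """Precision-weighted action selection.

    The policy posterior is marginalized onto first actions, giving m;
    the executed action is sampled from ``sigma(alpha * ln m)``.  At
    ``alpha = 0`` actions are uniform regardless of the plan; as alpha
    grows the modal planned action is selected almost surely.
    """
    if alpha < 0:
        raise ValueError("action precision alpha must be nonnegative")
    policies = np.asarray(policies, dtype=int)
    if n_actions is None:
        n_actions = int(policies.max()) + 1
    m = action_marginal(policy_post, policies, n_actions)
    p = softmax(alpha * floor_log(m))
    return int(rng.choice(n_actions, p=p))
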