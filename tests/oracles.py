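"""Independent brute-force oracles used by the test suite.

These deliberately avoid the package's vectorized code paths: posteriors
are obtained by explicit enumeration of joint states, and expected free
energy by a term-by-term loop.  They stay slow and obvious on purpose.
"""

import math

import numpy as np


def bayes_posterior_enumeration(prior, A, obs):
    """Exact single-factor posterior by enumerating the joint p(s, o)."""
    n_states = len(prior)
    joint = [prior[s] * A[obs][s] for s in range(n_states)]
    z = sum(joint)
    return np.array([j / z for j in joint])


def flattened_joint_posterior(D, links, A, observations):
    """Upper posterior by enumerating the flattened two-level joint.

    Generative model: upper state u ~ D; at each step t a lower state k_t
    ~ links[t][:, u]; an observation o_t ~ A[:, k_t].  Returns
    p(u | o_1..T) by summing the joint over all lower-state combinations.
    """
    n_upper = len(D)
    n_lower = links[0].shape[0]
    post = np.zeros(n_upper)
    for u in range(n_upper):
        total = 0.0
        # sum over every combination of lower states, one per step
        combos = [[k] for k in range(n_lower)]
        for _ in range(len(observations) - 1):
            combos = [c + [k] for c in combos for k in range(n_lower)]
        for combo in combos:
            p = D[u]
            for t, k in enumerate(combo):
                p *= links[t][k, u] * A[observations[t], k]
            total += p
        post[u] = total
    return post / post.sum()


def efe_terms(policy, belief, B, A, preferred_rows):
    """Risk and ambiguity of a policy by explicit per-step loops."""
    n_obs, n_states = np.asarray(A).shape
    q = list(belief)
    risk = 0.0
    ambiguity = 0.0
    for t, a in enumerate(policy):
        q = [sum(B[a][s2][s1] * q[s1] for s1 in range(n_states))
             for s2 in range(n_states)]
        q_o = [sum(A[o][s] * q[s] for s in range(n_states)) for o in range(n_obs)]
        for o in range(n_obs):
            if q_o[o] > 0:
                risk += q_o[o] * (math.log(q_o[o]) - math.log(max(preferred_rows[t][o], 1e-16)))
        for s in range(n_states):
            h = -sum(A[o][s] * math.log(max(A[o][s], 1e-16)) for o in range(n_obs))
            ambiguity += q[s] * h
    return risk, ambiguity


def random_stochastic_matrix(rng, n_rows, n_cols):
    """Column-stochastic matrix with Dirichlet(1) columns."""
    return rng.dirichlet(np.ones(n_rows), size=n_cols).T


def random_prior(rng, n):
    return rng.dirichlet(np.ones(n))
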