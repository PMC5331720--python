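"""Independent brute-force oracles used by several test modules.

These deliberately avoid the pruning/two-pass code paths: the Mk
likelihood is an exhaustive sum over all internal-state assignments and
the marginal posterior is the corresponding normalised partial sum.
"""

import itertools

import numpy as np
from scipy.linalg import expm


def enum_loglik(ta, tip_state_array, Q, root_prior=None):
    k = Q.shape[0]
    P = [expm(Q * t) for t in ta.edge_length]
    prior = np.full(k, 1.0 / k) if root_prior is None else np.asarray(root_prior)
    internals = list(range(ta.n_tips, ta.n_nodes))
    full = np.zeros(ta.n_nodes, dtype=int)
    full[: ta.n_tips] = tip_state_array
    total = 0.0
    for assign in itertools.product(range(k), repeat=len(internals)):
        for i, u in enumerate(internals):
            full[u] = assign[i]
        lik = prior[full[ta.root]]
        for v in range(ta.n_nodes - 1):
            lik *= P[v][full[ta.parent[v]], full[v]]
        total += lik
    return np.log(total)


def enum_marginals(ta, tip_state_array, Q):
    """Posterior state probabilities for every internal node, (n_nodes, k)."""
    k = Q.shape[0]
    P = [expm(Q * t) for t in ta.edge_length]
    internals = list(range(ta.n_tips, ta.n_nodes))
    full = np.zeros(ta.n_nodes, dtype=int)
    full[: ta.n_tips] = tip_state_array
    post = np.zeros((ta.n_nodes, k))
    for assign in itertools.product(range(k), repeat=len(internals)):
        for i, u in enumerate(internals):
            full[u] = assign[i]
        lik = 1.0 / k
        for v in range(ta.n_nodes - 1):
            lik *= P[v][full[ta.parent[v]], full[v]]
        for u in internals:
            post[u, full[u]] += lik
    post[internals] /= post[internals].sum(axis=1, keepdims=True)
    return post


def random_rate_matrix(rng, k, lo=0.05, hi=1.0):
    Q = rng.uniform(lo, hi, (k, k))
    np.fill_diagonal(Q, 0.0)
    np.fill_diagonal(Q, -Q.sum(axis=1))
    return Q
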