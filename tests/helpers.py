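"""Independent oracles used by the test suite.

Everything here recomputes expected values by brute force — exhaustive
enumeration over ancestral state assignments, exact rational hypergeometric
tails, dense quadrature, quaternion grid search — deliberately avoiding the
package's own algorithmic paths.
"""

from __future__ import annotations

import itertools
import math
from fractions import Fraction

import numpy as np

from paleoenrich.alphabet import N_STATES
from paleoenrich.trees import TreeIndex


# ---------------------------------------------------------------------------
# likelihood / posterior enumeration
# ---------------------------------------------------------------------------

def _site_enumeration(ti: TreeIndex, P_by_node, pi, leaf_states: dict[int, int]):
    """Yield (assignment, probability) over all internal-state assignments
    for one site under one rate category."""
    internal = [i for i in range(ti.n_nodes) if not ti.is_leaf[i]]
    for states in itertools.product(range(N_STATES), repeat=len(internal)):
        assign = dict(zip(internal, states))
        assign.update(leaf_states)
        prob = pi[assign[ti.root]]
        for i in range(ti.n_nodes):
            if i == ti.root:
                continue
            parent_state = assign[ti.parent[i]]
            child_state = assign.get(i)
            if child_state is None:  # missing leaf: sum over states = 1
                continue
            prob *= P_by_node[i][parent_state, child_state]
        yield assign, prob


def enum_site_likelihood_and_posteriors(tree, model, leaf_site_states: dict[str, int]):
    """Exact single-site likelihood and per-internal-node posteriors.

    ``leaf_site_states`` maps leaf label -> state index (or -1 for gap).
    Sums over every assignment of states to internal nodes and over rate
    categories.  Returns (site_likelihood, {node_label: posterior vector}).
    """
    ti = TreeIndex(tree)
    pi = model.frequencies
    leaf_states = {}
    for i in range(ti.n_nodes):
        if ti.is_leaf[i]:
            s = leaf_site_states[ti.labels[i]]
            if s >= 0:
                leaf_states[i] = s
    internal = [i for i in range(ti.n_nodes) if not ti.is_leaf[i]]
    lik = 0.0
    post = {i: np.zeros(N_STATES) for i in internal}
    for rate in model.category_rates:
        P_by_node = {
            i: model.transition_probs(ti.lengths[i], rate)
            for i in range(ti.n_nodes)
            if i != ti.root
        }
        for assign, prob in _site_enumeration(ti, P_by_node, pi, leaf_states):
            lik += prob / model.n_categories
            for i in internal:
                post[i][assign[i]] += prob / model.n_categories
    posteriors = {ti.labels[i]: post[i] / lik for i in internal}
    return lik, posteriors


def enum_log_likelihood(tree, model, leaf_sequences: dict[str, np.ndarray]) -> float:
    """Exact alignment log-likelihood by per-site enumeration."""
    L = len(next(iter(leaf_sequences.values())))
    total = 0.0
    for j in range(L):
        site = {name: int(seq[j]) for name, seq in leaf_sequences.items()}
        lik, _ = enum_site_likelihood_and_posteriors(tree, model, site)
        total += math.log(lik)
    return total


# ---------------------------------------------------------------------------
# Fitch parsimony brute force
# ---------------------------------------------------------------------------

def brute_force_parsimony(tree, leaf_presence: dict[str, bool]) -> int:
    """Minimum change count over all internal presence/absence assignments."""
    ti = TreeIndex(tree)
    internal = [i for i in range(ti.n_nodes) if not ti.is_leaf[i]]
    fixed = {
        i: bool(leaf_presence[ti.labels[i]])
        for i in range(ti.n_nodes)
        if ti.is_leaf[i]
    }
    best = math.inf
    for states in itertools.product((False, True), repeat=len(internal)):
        assign = dict(zip(internal, states))
        assign.update(fixed)
        changes = sum(
            assign[i] != assign[ti.parent[i]]
            for i in range(ti.n_nodes)
            if i != ti.root
        )
        best = min(best, changes)
    return int(best)


# ---------------------------------------------------------------------------
# exact Fisher enumeration (rational arithmetic)
# ---------------------------------------------------------------------------

def exact_fisher_two_sided(a: int, b: int, c: int, d: int) -> float:
    """Two-sided Fisher p by exact integer hypergeometric weights.

    Sums the probabilities of all tables with the observed margins whose
    point probability is at most the observed one (1 + 1e-7 relative slack),
    entirely in rational arithmetic.
    """
    n, r1, c1 = a + b + c + d, a + b, a + c
    amin, amax = max(0, r1 + c1 - n), min(r1, c1)
    weights = [
        math.comb(r1, x) * math.comb(n - r1, c1 - x) for x in range(amin, amax + 1)
    ]
    denom = math.comb(n, c1)
    w_obs = weights[a - amin]
    # integer-safe slack comparison: w <= w_obs * (1 + 1e-7)
    num = sum(w for w in weights if w * 10**7 <= w_obs * (10**7 + 1))
    return float(Fraction(num, denom))


def exact_fisher_greater(a: int, b: int, c: int, d: int) -> float:
    n, r1, c1 = a + b + c + d, a + b, a + c
    amax = min(r1, c1)
    num = sum(math.comb(r1, x) * math.comb(n - r1, c1 - x) for x in range(a, amax + 1))
    return float(Fraction(num, math.comb(n, c1)))


# ---------------------------------------------------------------------------
# rigid superposition brute force
# ---------------------------------------------------------------------------

def brute_force_min_rmsd(mobile: np.ndarray, reference: np.ndarray) -> float:
    """Minimum RMSD over rotations by quaternion grid + local refinement."""
    from scipy.optimize import minimize
    from scipy.spatial.transform import Rotation

    mob = mobile - mobile.mean(axis=0)
    ref = reference - reference.mean(axis=0)

    def rmsd_of(q):
        R = Rotation.from_quat(q / np.linalg.norm(q)).as_matrix()
        return float(np.sqrt(np.mean(np.sum((mob @ R.T - ref) ** 2, axis=1))))

    rng = np.random.default_rng(12345)
    best = math.inf
    for _ in range(400):
        q = rng.normal(size=4)
        best_q = q if rmsd_of(q) < best else None
        val = rmsd_of(q)
        if val < best:
            best, q0 = val, q
    res = minimize(lambda q: rmsd_of(q), q0, method="Nelder-Mead",
                   options={"xatol": 1e-10, "fatol": 1e-12, "maxiter": 5000})
    return min(best, float(res.fun))


# ---------------------------------------------------------------------------
# gamma band means by quadrature
# ---------------------------------------------------------------------------

def quadrature_gamma_band_means(alpha: float, K: int) -> np.ndarray:
    """Mean of x over each equal-probability band of Gamma(alpha, alpha)."""
    from scipy import integrate
    from scipy.stats import gamma

    edges = gamma.ppf(np.linspace(0, 1, K + 1), alpha, scale=1.0 / alpha)
    edges[-1] = gamma.ppf(1 - 1e-14, alpha, scale=1.0 / alpha)
    means = []
    for lo, hi in zip(edges[:-1], edges[1:]):
        val, _ = integrate.quad(
            lambda x: x * gamma.pdf(x, alpha, scale=1.0 / alpha), lo, hi, limit=200
        )
        means.append(val * K)
    return np.array(means)
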