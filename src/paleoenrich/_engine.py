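"""Felsenstein pruning and marginal ancestral posteriors.

Internal numerical core.  Works on a :class:`~paleoenrich.trees.TreeIndex`,
an encoded alignment (state indices, -1 for gap/missing) and a
:class:`~paleoenrich.substitution.SubstitutionModel`.  Site columns are
compressed to unique patterns; per-node partial likelihoods are max-scaled
with log accumulators so deep trees do not underflow.
"""

from __future__ import annotations

import numpy as np
from scipy.special import logsumexp

from .alphabet import N_STATES
from .substitution import SubstitutionModel
from .trees import TreeIndex


def compress_patterns(encoded: np.ndarray) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Unique alignment columns, weights, and column->pattern inverse map."""
    patterns, inverse, counts = np.unique(
        encoded.T, axis=0, return_inverse=True, return_counts=True
    )
    return patterns.T, counts.astype(float), inverse


def _leaf_partials(states: np.ndarray) -> np.ndarray:
    """(n_patterns, 20) indicator partials; all-ones where missing."""
    n = states.shape[0]
    F = np.zeros((n, N_STATES))
    missing = states < 0
    F[np.arange(n)[~missing], states[~missing]] = 1.0
    F[missing] = 1.0
    return F


class PruningEngine:
    """Caches tree/alignment/model structure for repeated evaluations."""

    def __init__(
        self,
        tree_index: TreeIndex,
        encoded: np.ndarray,
        taxon_rows: dict[str, int],
        model: SubstitutionModel,
    ):
        self.ti = tree_index
        self.model = model
        self.patterns, self.weights, self.inverse = compress_patterns(encoded)
        self.n_patterns = self.patterns.shape[1]
        # leaf partials are shared between categories and branch lengths
        self._leaf_F: dict[int, np.ndarray] = {}
        for i in np.flatnonzero(self.ti.is_leaf):
            label = self.ti.labels[i]
            if label not in taxon_rows:
                raise ValueError(f"leaf {label!r} has no row in the alignment")
            self._leaf_F[i] = _leaf_partials(self.patterns[taxon_rows[label]])

    # -- transition matrices ----------------------------------------------
    def _edge_matrices(self, lengths: np.ndarray) -> np.ndarray:
        """(K, n_nodes, 20, 20) transition matrices for the branch above
        each non-root node."""
        K = self.model.n_categories
        P = np.empty((K, self.ti.n_nodes, N_STATES, N_STATES))
        for i in range(self.ti.n_nodes - 1):
            for k, r in enumerate(self.model.category_rates):
                P[k, i] = self.model.transition_probs(lengths[i], r)
        return P

    # -- upward (pruning) pass --------------------------------------------
    def _up_pass(self, P: np.ndarray):
        """Per category: subtree partials F, their log-scalers, and the
        per-edge messages M (child partial propagated through its branch)."""
        ti = self.ti
        K = self.model.n_categories
        n, npat = ti.n_nodes, self.n_patterns
        F = np.empty((K, n, npat, N_STATES))
        logs = np.zeros((K, n, npat))
        M = np.empty((K, n, npat, N_STATES))
        for i in range(n):
            if ti.is_leaf[i]:
                for k in range(K):
                    F[k, i] = self._leaf_F[i]
            else:
                for k in range(K):
                    prod = np.ones((npat, N_STATES))
                    sc = np.zeros(npat)
                    for c in ti.children[i]:
                        prod *= M[k, c]
                        sc += logs[k, c]
                    norm = prod.max(axis=1)
                    norm[norm == 0.0] = 1.0
                    F[k, i] = prod / norm[:, None]
                    logs[k, i] = sc + np.log(norm)
            if i != ti.root:
                for k in range(K):
                    M[k, i] = F[k, i] @ P[k, i].T
        return F, logs, M

    def site_log_likelihoods(self, lengths: np.ndarray | None = None):
        """Per-pattern log-likelihood (mixed over categories) and per-category
        pattern log-likelihoods."""
        lengths = self.ti.lengths if lengths is None else lengths
        P = self._edge_matrices(lengths)
        F, logs, _ = self._up_pass(P)
        pi = self.model.frequencies
        K = self.model.n_categories
        percat = np.empty((K, self.n_patterns))
        for k in range(K):
            root_lik = F[k, self.ti.root] @ pi
            percat[k] = np.log(np.maximum(root_lik, 1e-300)) + logs[k, self.ti.root]
        mixed = logsumexp(percat, axis=0) - np.log(K)
        return mixed, percat

    def log_likelihood(self, lengths: np.ndarray | None = None) -> float:
        mixed, _ = self.site_log_likelihoods(lengths)
        return float(mixed @ self.weights)

    # -- marginal posteriors ----------------------------------------------
    def marginal_posteriors(self) -> tuple[dict[int, np.ndarray], float]:
        """Posterior state probabilities at every internal node.

        Returns a map from postorder node index to an ``(L, 20)`` array
        (expanded back to alignment columns) and the total log-likelihood.
        """
        ti = self.ti
        K = self.model.n_categories
        npat = self.n_patterns
        pi = self.model.frequencies
        P = self._edge_matrices(ti.lengths)
        F, logs, M = self._up_pass(P)

        percat = np.empty((K, npat))
        for k in range(K):
            root_lik = F[k, ti.root] @ pi
            percat[k] = np.log(np.maximum(root_lik, 1e-300)) + logs[k, ti.root]
        mixed = logsumexp(percat, axis=0) - np.log(K)
        total = float(mixed @ self.weights)
        # per-pattern category weights p(k | data); scalers cancel per column
        catw = np.exp(percat - logsumexp(percat, axis=0, keepdims=True))

        # outside ("above") partials B, computed root-to-tip
        B = np.empty((K, ti.n_nodes, npat, N_STATES))
        for k in range(K):
            B[k, ti.root] = pi[None, :]
        posteriors: dict[int, np.ndarray] = {}
        for i in range(ti.n_nodes - 1, -1, -1):
            if not ti.is_leaf[i]:
                post_pat = np.zeros((npat, N_STATES))
                for k in range(K):
                    joint = F[k, i] * B[k, i]
                    norm = joint.sum(axis=1, keepdims=True)
                    norm[norm == 0.0] = 1.0
                    post_pat += catw[k][:, None] * (joint / norm)
                posteriors[i] = post_pat[self.inverse]
            for c in ti.children[i]:
                for k in range(K):
                    pre = B[k, i].copy()
                    for s in ti.children[i]:
                        if s != c:
                            pre *= M[k, s]
                    out = pre @ P[k, c]
                    norm = out.max(axis=1)
                    norm[norm == 0.0] = 1.0
                    B[k, c] = out / norm[:, None]
        return posteriors, total
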