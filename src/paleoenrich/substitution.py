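"""Reversible amino-acid substitution models with discrete-gamma rates.

A model couples a symmetric exchangeability matrix ``S`` with stationary
frequencies ``pi``.  The instantaneous rate matrix is ``Q_ij = S_ij * pi_j``
for ``i != j``, with the diagonal set so rows sum to zero, and the whole
matrix rescaled so the expected substitution rate at stationarity,
``-sum_i pi_i Q_ii``, equals one.  Branch lengths are then expected
substitutions per site.

Site-rate heterogeneity uses the standard discrete-gamma construction: ``K``
equal-probability categories whose rates are the means of the Gamma(alpha,
alpha) distribution over its quantile bands, normalized to average one.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.special import gammainc
from scipy.stats import gamma as _gamma_dist

from ._wag import WAG_EXCHANGEABILITIES, WAG_FREQUENCIES
from .alphabet import N_STATES

__all__ = ["SubstitutionModel", "build_model", "discretize_gamma", "MODEL_NAMES"]

MODEL_NAMES = ("WAG", "Poisson")


class ModelError(ValueError):
    """Unknown model name or invalid model parameters."""


def discretize_gamma(alpha: float, K: int) -> np.ndarray:
    """Mean rates of ``K`` equal-probability gamma quantile bands.

    Rates are nonnegative, nondecreasing, and average exactly one.  With
    ``K == 1`` the single rate is one (rate homogeneity).

    Parameters
    ----------
    alpha : shape of the Gamma(alpha, alpha) site-rate distribution.
    K : number of categories.
    """
    if alpha <= 0:
        raise ValueError("gamma shape alpha must be positive")
    if K < 1:
        raise ValueError("need at least one rate category")
    if K == 1:
        return np.ones(1)
    # Band mean of x under Gamma(a, a) is the regularized incomplete gamma
    # of shape a+1 evaluated at the band edges (mean of the full
    # distribution is 1).
    edges = _gamma_dist.ppf(np.arange(1, K) / K, alpha, scale=1.0 / alpha)
    upper = np.concatenate([edges * alpha, [np.inf]])
    lower = np.concatenate([[0.0], edges * alpha])
    masses = gammainc(alpha + 1.0, upper) - gammainc(alpha + 1.0, lower)
    rates = K * masses
    rates /= rates.mean()
    return rates


@dataclass(frozen=True)
class SubstitutionModel:
    """A time-reversible 20-state substitution model with gamma rates.

    Attributes
    ----------
    name : model identifier ("WAG" or "Poisson").
    exchangeabilities : symmetric 20x20, zero diagonal.
    frequencies : stationary distribution pi (sums to 1).
    alpha : gamma shape of the site-rate distribution.
    n_categories : number of discrete-gamma categories K.
    """

    name: str
    exchangeabilities: np.ndarray
    frequencies: np.ndarray
    alpha: float = 1.0
    n_categories: int = 4
    rate_matrix: np.ndarray = field(init=False, repr=False)
    category_rates: np.ndarray = field(init=False, repr=False)
    # symmetric-eigendecomposition cache for transition probabilities
    _eigvals: np.ndarray = field(init=False, repr=False)
    _left: np.ndarray = field(init=False, repr=False)
    _right: np.ndarray = field(init=False, repr=False)

    def __post_init__(self) -> None:
        pi = np.asarray(self.frequencies, dtype=float)
        S = np.asarray(self.exchangeabilities, dtype=float)
        if pi.shape != (N_STATES,) or abs(pi.sum() - 1.0) > 1e-12:
            raise ModelError("frequencies must be 20 values summing to 1")
        if S.shape != (N_STATES, N_STATES) or not np.allclose(S, S.T):
            raise ModelError("exchangeability matrix must be symmetric 20x20")
        Q = S * pi[None, :]
        np.fill_diagonal(Q, 0.0)
        np.fill_diagonal(Q, -Q.sum(axis=1))
        scale = -np.dot(pi, np.diag(Q))
        Q = Q / scale
        object.__setattr__(self, "rate_matrix", Q)
        object.__setattr__(
            self, "category_rates", discretize_gamma(self.alpha, self.n_categories)
        )
        # Q = D^{-1/2} B D^{1/2} with B symmetric for a reversible model;
        # eigendecompose B once, reuse for every branch/category.
        d = np.sqrt(pi)
        B = (Q * d[:, None]) / d[None, :]
        B = 0.5 * (B + B.T)
        w, U = np.linalg.eigh(B)
        object.__setattr__(self, "_eigvals", w)
        object.__setattr__(self, "_right", U / d[:, None] * 1.0)
        object.__setattr__(self, "_left", (U * d[:, None]).T)

    @property
    def n_free_parameters(self) -> int:
        """Free parameters counted for AIC: alpha when rates vary."""
        return 1 if self.n_categories > 1 else 0

    def transition_probs(self, t: float, rate: float = 1.0) -> np.ndarray:
        """Transition probability matrix ``P = exp(Q * t * rate)``.

        Rows sum to one; tiny negative round-off is clamped to [0, 1].
        """
        if t < 0:
            raise ValueError("branch length must be nonnegative")
        ew = np.exp(self._eigvals * (t * rate))
        P = (self._right * ew[None, :]) @ self._left
        np.clip(P, 0.0, 1.0, out=P)
        P /= P.sum(axis=1, keepdims=True)
        return P

    def transition_probs_all_categories(self, t: float) -> np.ndarray:
        """Stacked ``(K, 20, 20)`` transition matrices, one per category."""
        return np.stack([self.transition_probs(t, r) for r in self.category_rates])


def build_model(name: str, alpha: float = 1.0, K: int = 4) -> SubstitutionModel:
    """Construct a named substitution model.

    "WAG" uses the published empirical exchangeabilities and frequencies;
    "Poisson" has equal exchangeabilities and uniform frequencies and admits
    closed-form transition probabilities, which makes it useful for exact
    tests.
    """
    key = name.strip().lower()
    if key == "wag":
        S, pi = WAG_EXCHANGEABILITIES, WAG_FREQUENCIES
    elif key == "poisson":
        S = np.ones((N_STATES, N_STATES)) - np.eye(N_STATES)
        pi = np.full(N_STATES, 1.0 / N_STATES)
    else:
        raise ModelError(f"unknown substitution model {name!r}")
    return SubstitutionModel(
        name=name, exchangeabilities=S, frequencies=pi, alpha=alpha, n_categories=K
    )
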