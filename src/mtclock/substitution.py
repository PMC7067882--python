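"""Tamura–Nei (TN93) substitution model with discrete-Gamma rate heterogeneity.

The TN93 model distinguishes the two transition exchange rates (A<->G among
purines, C<->T among pyrimidines) from a single shared transversion rate, on
top of arbitrary stationary base frequencies.  Rate heterogeneity across
sites uses Yang's equal-probability discretization of a Gamma(alpha, alpha)
distribution (mean 1), by default with 5 categories, the parameterisation
mtDNA coding-region analyses usually select.

The instantaneous rate matrix is normalised so the expected substitution
rate at stationarity is 1; branch lengths are therefore in expected
substitutions per site.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
from scipy.special import gammainc
from scipy.stats import gamma as gamma_dist

BASES = ("A", "C", "G", "T")
_A, _C, _G, _T = 0, 1, 2, 3


@dataclass(frozen=True)
class TN93GParams:
    """TN93 + discrete-Gamma model parameters.

    Parameters
    ----------
    base_freqs:
        Stationary frequencies (pi_A, pi_C, pi_G, pi_T); must be positive
        and sum to 1.
    rate_AG, rate_CT:
        Purine and pyrimidine transition exchange rates, expressed relative
        to the transversion rate.
    rate_transversion:
        Shared transversion exchange rate.  Only the ratios matter once the
        matrix is normalised; keeping it explicit makes configs readable.
    gamma_shape:
        Shape alpha of the Gamma(alpha, alpha) rates-across-sites
        distribution.
    n_categories:
        Number of equal-probability discrete Gamma categories.
    """

    base_freqs: tuple[float, float, float, float] = (0.25, 0.25, 0.25, 0.25)
    rate_AG: float = 1.0
    rate_CT: float = 1.0
    rate_transversion: float = 1.0
    gamma_shape: float = 1.0
    n_categories: int = 5

    def __post_init__(self) -> None:
        freqs = np.asarray(self.base_freqs, dtype=float)
        if freqs.shape != (4,):
            raise ValueError("base_freqs must have exactly 4 entries (A,C,G,T)")
        if np.any(freqs <= 0):
            raise ValueError("base_freqs must all be > 0")
        if abs(freqs.sum() - 1.0) > 1e-8:
            raise ValueError(f"base_freqs must sum to 1, got {freqs.sum():.10f}")
        for name in ("rate_AG", "rate_CT", "rate_transversion", "gamma_shape"):
            if getattr(self, name) <= 0 or not np.isfinite(getattr(self, name)):
                raise ValueError(f"{name} must be finite and > 0")
        if self.n_categories < 1:
            raise ValueError("n_categories must be >= 1")
        object.__setattr__(self, "base_freqs", tuple(float(f) for f in freqs))

    @property
    def freqs(self) -> np.ndarray:
        return np.asarray(self.base_freqs, dtype=float)

    def with_(self, **kwargs) -> "TN93GParams":
        return replace(self, **kwargs)

    # -- serialization (plain key=value block used by the CLI config) -----
    def to_config(self) -> dict:
        return {
            "base_freqs": list(self.base_freqs),
            "rate_AG": self.rate_AG,
            "rate_CT": self.rate_CT,
            "rate_transversion": self.rate_transversion,
            "gamma_shape": self.gamma_shape,
            "n_categories": self.n_categories,
        }

    @classmethod
    def from_config(cls, d: dict) -> "TN93GParams":
        return cls(
            base_freqs=tuple(d.get("base_freqs", (0.25, 0.25, 0.25, 0.25))),
            rate_AG=float(d.get("rate_AG", 1.0)),
            rate_CT=float(d.get("rate_CT", 1.0)),
            rate_transversion=float(d.get("rate_transversion", 1.0)),
            gamma_shape=float(d.get("gamma_shape", 1.0)),
            n_categories=int(d.get("n_categories", 5)),
        )


def build_rate_matrix(params: TN93GParams) -> np.ndarray:
    """Normalised TN93 instantaneous rate matrix Q.

    Off-diagonal Q[i, j] = r(i, j) * pi_j with r the exchange rate for the
    pair (transition or transversion); rows sum to zero and the matrix is
    scaled so that -sum_i pi_i Q[i, i] = 1.  Detailed balance
    pi_i Q[i, j] = pi_j Q[j, i] holds by construction (r is symmetric).
    """
    pi = params.freqs
    a1, a2, b = params.rate_AG, params.rate_CT, params.rate_transversion
    R = np.full((4, 4), b, dtype=float)
    R[_A, _G] = R[_G, _A] = a1
    R[_C, _T] = R[_T, _C] = a2
    np.fill_diagonal(R, 0.0)
    Q = R * pi[np.newaxis, :]
    np.fill_diagonal(Q, -Q.sum(axis=1))
    mu = -float(np.dot(pi, np.diag(Q)))
    if not np.isfinite(mu) or mu <= 0:
        raise ValueError("rate matrix is not normalizable")
    return Q / mu


def _eigen_system(params: TN93GParams):
    """Symmetric eigendecomposition of the reversible generator.

    Returns (w, A, B) with P(t) = A @ diag(exp(w t)) @ B, exploiting that
    D^{1/2} Q D^{-1/2} is symmetric for reversible Q (D = diag(pi)).
    """
    Q = build_rate_matrix(params)
    sq = np.sqrt(params.freqs)
    S = (Q * sq[:, np.newaxis]) / sq[np.newaxis, :]
    S = 0.5 * (S + S.T)  # symmetrize away rounding noise
    w, U = np.linalg.eigh(S)
    A = U / sq[:, np.newaxis]
    B = U.T * sq[np.newaxis, :]
    return w, A, B


def discretize_gamma(shape: float, n_categories: int) -> tuple[np.ndarray, np.ndarray]:
    """Equal-probability discrete Gamma categories with category-mean rates.

    The continuous distribution is Gamma(shape, scale=1/shape), mean 1.
    Category i covers the quantile band [i/n, (i+1)/n]; its representative
    rate is the conditional mean over the band, so the rates average to
    exactly 1.  Returns (rates, probabilities).
    """
    if shape <= 0:
        raise ValueError("gamma shape must be > 0")
    n = int(n_categories)
    if n < 1:
        raise ValueError("n_categories must be >= 1")
    if n == 1:
        return np.ones(1), np.ones(1)
    probs = np.full(n, 1.0 / n)
    cuts = gamma_dist.ppf(np.arange(1, n) / n, shape, scale=1.0 / shape)
    edges = np.concatenate([[0.0], cuts * shape, [np.inf]])  # in Gamma(shape,1) units
    # E[X | band] for X~Gamma(a,1/a): a/a * (I(a+1, upper) - I(a+1, lower)) / (1/n)
    upper = np.where(np.isinf(edges[1:]), 1.0, gammainc(shape + 1.0, edges[1:]))
    lower = gammainc(shape + 1.0, edges[:-1])
    rates = n * (upper - lower)
    return rates, probs


@dataclass
class TransitionMatrixCache:
    """Per-model cache of the eigen system and Gamma category rates.

    Repeated likelihood evaluations reuse the 4x4 eigendecomposition; only
    the exponential of the eigenvalues depends on branch length.
    """

    params: TN93GParams
    w: np.ndarray = field(init=False)
    A: np.ndarray = field(init=False)
    B: np.ndarray = field(init=False)
    category_rates: np.ndarray = field(init=False)
    category_probs: np.ndarray = field(init=False)

    def __post_init__(self) -> None:
        self.w, self.A, self.B = _eigen_system(self.params)
        self.category_rates, self.category_probs = discretize_gamma(
            self.params.gamma_shape, self.params.n_categories
        )

    def matrices(self, branch_length: float) -> np.ndarray:
        """Stack of per-category transition matrices, shape (n_cat, 4, 4)."""
        if branch_length < 0:
            raise ValueError("branch length must be >= 0")
        ew = np.exp(np.outer(self.category_rates * branch_length, self.w))
        P = np.matmul(self.A[np.newaxis, :, :] * ew[:, np.newaxis, :], self.B)
        np.maximum(P, 0.0, out=P)
        return P

    def matrices_batch(self, branch_lengths: np.ndarray) -> np.ndarray:
        """P matrices for many branches at once, shape (m, n_cat, 4, 4)."""
        t = np.asarray(branch_lengths, dtype=float)
        if np.any(t < 0):
            raise ValueError("branch lengths must be >= 0")
        ew = np.exp(
            t[:, np.newaxis, np.newaxis]
            * self.category_rates[np.newaxis, :, np.newaxis]
            * self.w[np.newaxis, np.newaxis, :]
        )  # (m, ncat, 4)
        P = np.matmul(
            self.A[np.newaxis, np.newaxis, :, :] * ew[..., np.newaxis, :], self.B
        )
        np.maximum(P, 0.0, out=P)
        return P


def transition_probabilities(params: TN93GParams, branch_length: float) -> np.ndarray:
    """Per-category transition probability matrices P_c(t), shape (n_cat, 4, 4)."""
    return TransitionMatrixCache(params).matrices(branch_length)
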