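"""GTR-family nucleotide substitution models with discrete-gamma rate heterogeneity.

The models used throughout the package are the reversible GTR family
restricted to the named sub-models:

* ``GTR``  — six free exchangeabilities, free base frequencies,
* ``TVM``  — transversion model: the two transition exchangeabilities are
  constrained equal (``s_AG == s_CT``), frequencies free (``+F``),
* ``SYM``  — six free exchangeabilities, frequencies fixed at 1/4,
* ``JC``   — all exchangeabilities equal, frequencies fixed at 1/4.

Rates across sites follow a discrete gamma with ``n_categories``
equal-probability categories (the ``+G4`` convention); category rates are
the conditional means of the gamma(alpha, alpha) density over each
quantile slice, so the mean rate is exactly 1.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
from scipy.special import gammainc
from scipy.stats import gamma as gamma_dist

#: canonical base order used for every 4-vector / 4x4 matrix in the package
BASES = "ACGT"
BASE_INDEX = {b: i for i, b in enumerate(BASES)}

#: exchangeability keys in (row, col) upper-triangle order
EXCH_KEYS = ("AC", "AG", "AT", "CG", "CT", "GT")

_UNIFORM = np.full(4, 0.25)


@dataclass(frozen=True)
class SubstitutionModel:
    """A reversible nucleotide model plus its among-site rate distribution.

    Parameters
    ----------
    kind:
        One of ``"GTR"``, ``"TVM"``, ``"SYM"``, ``"JC"``.
    exchangeabilities:
        The six symmetric rate multipliers ``(s_AC, s_AG, s_AT, s_CG,
        s_CT, s_GT)``.  Only their ratios matter; the generator is
        rescaled to one expected substitution per site per unit time.
    base_frequencies:
        Stationary frequencies ``(pi_A, pi_C, pi_G, pi_T)``; must sum
        to 1.  ``SYM`` and ``JC`` force the uniform vector.
    gamma_shape:
        Shape ``alpha`` of the discrete-gamma rate distribution, or
        ``None`` for rate homogeneity.
    n_categories:
        Number of equal-probability gamma categories (ignored when
        ``gamma_shape`` is ``None``).
    """

    kind: str = "GTR"
    exchangeabilities: tuple = (1.0,) * 6
    base_frequencies: tuple = (0.25, 0.25, 0.25, 0.25)
    gamma_shape: float | None = None
    n_categories: int = 4

    def __post_init__(self):
        if self.kind not in ("GTR", "TVM", "SYM", "JC"):
            raise ValueError(f"unknown model kind {self.kind!r}")
        s = np.asarray(self.exchangeabilities, dtype=float)
        pi = np.asarray(self.base_frequencies, dtype=float)
        if s.shape != (6,) or np.any(s <= 0):
            raise ValueError("need 6 positive exchangeabilities")
        if pi.shape != (4,) or np.any(pi <= 0):
            raise ValueError("need 4 positive base frequencies")
        if abs(pi.sum() - 1.0) > 1e-12:
            raise ValueError(f"base frequencies sum to {pi.sum()}, not 1")
        if self.kind == "TVM" and abs(s[1] - s[4]) > 1e-12:
            raise ValueError("TVM requires s_AG == s_CT")
        if self.kind in ("SYM", "JC") and np.any(np.abs(pi - 0.25) > 1e-12):
            raise ValueError(f"{self.kind} requires uniform base frequencies")
        if self.kind == "JC" and np.ptp(s) > 1e-12:
            raise ValueError("JC requires all exchangeabilities equal")
        if self.gamma_shape is not None and self.gamma_shape <= 0:
            raise ValueError("gamma shape must be positive")
        if self.n_categories < 1:
            raise ValueError("need at least one rate category")

    # -- convenience constructors -------------------------------------

    @classmethod
    def jc(cls, gamma_shape: float | None = None, n_categories: int = 4):
        return cls("JC", (1.0,) * 6, (0.25,) * 4, gamma_shape, n_categories)

    @classmethod
    def sym(cls, exchangeabilities, gamma_shape: float | None = None,
            n_categories: int = 4):
        return cls("SYM", tuple(exchangeabilities), (0.25,) * 4,
                   gamma_shape, n_categories)

    @classmethod
    def tvm(cls, s_AC, s_AG, s_AT, s_CG, s_GT, base_frequencies,
            gamma_shape: float | None = None, n_categories: int = 4):
        """TVM+F: five free exchangeabilities (s_CT is tied to s_AG)."""
        return cls("TVM", (s_AC, s_AG, s_AT, s_CG, s_AG, s_GT),
                   tuple(base_frequencies), gamma_shape, n_categories)

    # -- derived quantities -------------------------------------------

    @property
    def pi(self) -> np.ndarray:
        return np.asarray(self.base_frequencies, dtype=float)

    def rates(self) -> np.ndarray:
        """Discrete-gamma category rates (all 1.0 when homogeneous)."""
        if self.gamma_shape is None:
            return np.ones(1)
        return gamma_rates(self.gamma_shape, self.n_categories)

    def with_gamma(self, alpha: float, n_categories: int = 4) -> "SubstitutionModel":
        return replace(self, gamma_shape=alpha, n_categories=n_categories)


def build_rate_matrix(model: SubstitutionModel) -> np.ndarray:
    """Instantaneous rate matrix Q with q_ij = s_ij * pi_j (i != j).

    Rows sum to zero and the matrix is rescaled so that the expected
    substitution rate at stationarity, ``-sum_i pi_i q_ii``, equals 1 —
    i.e. branch lengths are in expected substitutions per site.
    """
    s = np.asarray(model.exchangeabilities, dtype=float)
    pi = model.pi
    S = np.zeros((4, 4))
    for (key, val) in zip(EXCH_KEYS, s):
        i, j = BASE_INDEX[key[0]], BASE_INDEX[key[1]]
        S[i, j] = S[j, i] = val
    Q = S * pi[None, :]
    np.fill_diagonal(Q, 0.0)
    np.fill_diagonal(Q, -Q.sum(axis=1))
    mu = -np.dot(pi, np.diag(Q))
    return Q / mu


def gamma_rates(alpha: float, n_categories: int) -> np.ndarray:
    """Mean rates of the equal-probability discrete gamma categories.

    The underlying density is gamma with shape ``alpha`` and rate
    ``alpha`` (mean 1).  Category c's rate is the conditional mean of
    the density over the quantile slice ((c-1)/C, c/C]; the rates
    therefore average exactly to 1.
    """
    if alpha <= 0:
        raise ValueError("alpha must be positive")
    C = int(n_categories)
    if C == 1:
        return np.ones(1)
    # slice boundaries on the rate axis
    probs = np.arange(1, C) / C
    cuts = gamma_dist.ppf(probs, a=alpha, scale=1.0 / alpha)
    edges = np.concatenate([[0.0], cuts, [np.inf]])
    # mean of gamma(a, rate b) over [x0, x1] * b equals the increment of the
    # regularized incomplete gamma with shape a+1 at b*x
    upper = gammainc(alpha + 1.0, alpha * edges[1:])
    lower = gammainc(alpha + 1.0, alpha * edges[:-1])
    rates = C * (np.where(np.isinf(edges[1:]), 1.0, upper) - lower)
    return rates


def _eigendecompose(Q: np.ndarray, pi: np.ndarray):
    """Symmetric eigendecomposition of a reversible generator."""
    sqrt_pi = np.sqrt(pi)
    # similarity transform D^{1/2} Q D^{-1/2} is symmetric for reversible Q
    B = (Q * sqrt_pi[:, None]) / sqrt_pi[None, :]
    B = 0.5 * (B + B.T)  # clean residual asymmetry to machine precision
    w, U = np.linalg.eigh(B)
    return w, U, sqrt_pi


def transition_probability(model: SubstitutionModel, t: float,
                           rate: float = 1.0) -> np.ndarray:
    """P(t) = exp(Q * t * rate) for one rate category."""
    Q = build_rate_matrix(model)
    w, U, sqrt_pi = _eigendecompose(Q, model.pi)
    E = U @ np.diag(np.exp(w * t * rate)) @ U.T
    P = E * sqrt_pi[None, :] / sqrt_pi[:, None]
    return np.clip(P, 0.0, None)


def transition_probabilities(model: SubstitutionModel, t: float) -> np.ndarray:
    """Stack of P(t * r_c) over the model's gamma categories, shape (C,4,4)."""
    Q = build_rate_matrix(model)
    w, U, sqrt_pi = _eigendecompose(Q, model.pi)
    rates = model.rates()
    out = np.empty((len(rates), 4, 4))
    for c, r in enumerate(rates):
        E = U @ np.diag(np.exp(w * t * r)) @ U.T
        out[c] = np.clip(E * sqrt_pi[None, :] / sqrt_pi[:, None], 0.0, None)
    return out
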