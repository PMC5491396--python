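"""General time-reversible (GTR) substitution model.

The rate matrix is built from six exchangeabilities and four stationary base
frequencies, normalised so that one unit of branch length corresponds to one
expected substitution per site at stationarity.  Optional discrete-gamma rate
variation uses equal-weight categories with the mean-of-quantile-bin rates.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.special import gammainc

#: order of states everywhere in the package
STATES = ("A", "C", "G", "T")
#: order of the exchangeability vector
PAIRS = (("A", "C"), ("A", "G"), ("A", "T"), ("C", "G"), ("C", "T"), ("G", "T"))


@dataclass
class GTRModel:
    """GTR model parameters.

    Parameters
    ----------
    exchangeabilities
        Six positive relative rates in the order AC, AG, AT, CG, CT, GT.
    base_freqs
        Stationary frequencies of A, C, G, T; must sum to 1.
    gamma_shape
        Shape of the discrete-gamma distribution of among-site rate
        variation; ``None`` disables rate variation.
    n_rate_categories
        Number of equal-weight gamma categories (used only when
        ``gamma_shape`` is set).
    """

    exchangeabilities: tuple[float, ...] = (1.0, 1.0, 1.0, 1.0, 1.0, 1.0)
    base_freqs: tuple[float, ...] = (0.25, 0.25, 0.25, 0.25)
    gamma_shape: float | None = None
    n_rate_categories: int = 4

    _eig: tuple[np.ndarray, np.ndarray, np.ndarray] | None = field(
        default=None, repr=False, compare=False
    )

    def __post_init__(self) -> None:
        ex = np.asarray(self.exchangeabilities, dtype=float)
        pi = np.asarray(self.base_freqs, dtype=float)
        if ex.shape != (6,) or (ex <= 0).any():
            raise ValueError("need 6 positive exchangeabilities")
        if pi.shape != (4,) or (pi <= 0).any() or abs(pi.sum() - 1.0) > 1e-8:
            raise ValueError("base frequencies must be 4 positive values summing to 1")
        if self.gamma_shape is not None and self.gamma_shape <= 0:
            raise ValueError("gamma shape must be positive")
        self.exchangeabilities = tuple(float(x) for x in ex)
        self.base_freqs = tuple(float(x) for x in pi / pi.sum())

    @classmethod
    def jukes_cantor(cls) -> "GTRModel":
        return cls()

    def rate_matrix(self) -> np.ndarray:
        """Normalised 4x4 rate matrix Q with rows summing to zero."""
        pi = np.asarray(self.base_freqs)
        Q = np.zeros((4, 4))
        for (a, b), s in zip(PAIRS, self.exchangeabilities):
            i, j = STATES.index(a), STATES.index(b)
            Q[i, j] = s * pi[j]
            Q[j, i] = s * pi[i]
        np.fill_diagonal(Q, -Q.sum(axis=1))
        mu = -(pi * np.diag(Q)).sum()  # expected rate at stationarity
        return Q / mu

    def _eigen(self) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
        # symmetric decomposition: S = diag(sqrt(pi)) Q diag(1/sqrt(pi))
        if self._eig is None:
            pi = np.asarray(self.base_freqs)
            sq = np.sqrt(pi)
            S = self.rate_matrix() * sq[:, None] / sq[None, :]
            S = (S + S.T) / 2.0
            w, U = np.linalg.eigh(S)
            left = U.T * sq[None, :]      # rows: U^T diag(sqrt(pi))
            right = (U.T / sq[None, :]).T  # diag(1/sqrt(pi)) U
            self._eig = (w, right, left)
        return self._eig

    def transition_probabilities(self, t: float) -> np.ndarray:
        """P(t) = exp(Qt): probability of state j after branch length t from i.

        Raises
        ------
        ValueError
            If ``t`` is negative.
        """
        if t < 0:
            raise ValueError("branch length must be non-negative")
        w, right, left = self._eigen()
        P = (right * np.exp(w * t)[None, :]) @ left
        np.clip(P, 0.0, None, out=P)
        P /= P.sum(axis=1, keepdims=True)
        return P

    def transition_probabilities_many(self, ts: np.ndarray) -> np.ndarray:
        """Stack of P(t) for an array of branch lengths, shape (len(ts), 4, 4)."""
        ts = np.asarray(ts, dtype=float)
        if (ts < 0).any():
            raise ValueError("branch lengths must be non-negative")
        w, right, left = self._eigen()
        P = np.einsum("ij,tj,jk->tik", right, np.exp(np.outer(ts, w)), left)
        np.clip(P, 0.0, None, out=P)
        P /= P.sum(axis=2, keepdims=True)
        return P

    def gamma_rates(self) -> np.ndarray:
        """Equal-weight discrete-gamma category rates (mean 1).

        Category c covers the quantile bin (c/K, (c+1)/K) of a
        Gamma(shape, scale=1/shape) distribution; its rate is the
        conditional mean over the bin, so the category rates average to 1.
        """
        if self.gamma_shape is None:
            return np.array([1.0])
        a = self.gamma_shape
        k = self.n_rate_categories
        from scipy.stats import gamma as gamma_dist

        edges = gamma_dist.ppf(np.linspace(0, 1, k + 1), a, scale=1.0 / a)
        # E[X ; X in (lo, hi)] / P(lo < X < hi) with X ~ Gamma(a, 1/a):
        # integral of x f(x) over a bin equals gammainc(a+1, a*hi) - gammainc(a+1, a*lo)
        upper = gammainc(a + 1, a * edges[1:])
        lower = gammainc(a + 1, a * np.where(np.isfinite(edges[:-1]), edges[:-1], 0))
        rates = (upper - lower) * k
        return rates / rates.mean()
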