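"""Substitution models: empirical amino-acid matrices + discrete gamma.

Protein models are general time-reversible processes built from a fixed
symmetric exchangeability matrix and stationary frequencies,
``Q_ij = s_ij * pi_j``, scaled so the expected substitution rate at
stationarity is one — branch lengths are then in expected substitutions
per site.  Rate heterogeneity uses Yang's discrete-gamma approximation
with mean category rates, which average to exactly one for any shape.

A small HKY nucleotide model is included for the sequence simulator.
"""

from __future__ import annotations

import numpy as np
from scipy.stats import gamma as _gamma_dist

from .aamatrices import AA_ORDER, EMPIRICAL_MODELS

AA_INDEX = {a: i for i, a in enumerate(AA_ORDER)}


def discrete_gamma_rates(alpha: float, ncat: int = 4) -> np.ndarray:
    """Mean rates of ``ncat`` equal-probability categories of a mean-one
    gamma distribution with shape ``alpha``."""
    if alpha <= 0:
        raise ValueError("gamma shape must be positive")
    if ncat == 1:
        return np.ones(1)
    edges = _gamma_dist.ppf(np.arange(ncat + 1) / ncat, a=alpha, scale=1.0 / alpha)
    upper = _gamma_dist.cdf(edges, a=alpha + 1, scale=1.0 / alpha)
    rates = ncat * np.diff(upper)
    return rates / rates.mean() * 1.0  # exact mean 1 up to fp noise


class SubstitutionModel:
    """Empirical amino-acid model with optional discrete-gamma rates.

    Parameters
    ----------
    name:
        One of ``WAG``, ``LG``, ``JTT``, ``Dayhoff``.
    alpha:
        Gamma shape; ``None`` disables rate heterogeneity.
    ncat:
        Number of discrete rate categories (default 4).
    freqs:
        Stationary frequencies; defaults to the model's published ones.
        Pass observed frequencies for the ``+F`` (empirical) variant.
    """

    n_states = 20

    def __init__(self, name: str = "WAG", alpha: float | None = None,
                 ncat: int = 4, freqs=None):
        if name not in EMPIRICAL_MODELS:
            raise ValueError(f"unknown model {name!r}; choose from "
                             f"{sorted(EMPIRICAL_MODELS)}")
        self.name = name
        self.alpha = alpha
        self.ncat = ncat if alpha is not None else 1
        rates, default_freqs = EMPIRICAL_MODELS[name]
        self.exchangeabilities = rates
        pi = np.asarray(default_freqs if freqs is None else freqs, float)
        pi = pi / pi.sum()
        if np.any(pi <= 0):
            raise ValueError("stationary frequencies must be positive")
        self.freqs = pi
        self.empirical_freqs = freqs is not None
        self._decompose()

    def _decompose(self):
        pi = self.freqs
        Q = self.exchangeabilities * pi[None, :]
        np.fill_diagonal(Q, 0.0)
        np.fill_diagonal(Q, -Q.sum(axis=1))
        mu = -(pi * np.diag(Q)).sum()
        Q /= mu
        self.Q = Q
        sq = np.sqrt(pi)
        B = (Q * sq[:, None]) / sq[None, :]
        B = (B + B.T) / 2
        w, V = np.linalg.eigh(B)
        self._eigval = w
        self._left = V.T * sq[None, :]          # V^T D^{1/2}
        self._right = V / sq[:, None]           # D^{-1/2} V

    @property
    def category_rates(self) -> np.ndarray:
        if self.alpha is None:
            return np.ones(1)
        return discrete_gamma_rates(self.alpha, self.ncat)

    def with_alpha(self, alpha: float) -> "SubstitutionModel":
        m = SubstitutionModel.__new__(SubstitutionModel)
        m.__dict__.update(self.__dict__)
        m.alpha = alpha
        m.ncat = self.ncat if self.ncat > 1 else 4
        return m

    def transition_matrix(self, t: float, rate: float = 1.0) -> np.ndarray:
        """P(t) for one branch at one relative rate."""
        if t < 0:
            raise ValueError("negative branch length")
        expw = np.exp(self._eigval * t * rate)
        P = (self._right * expw[None, :]) @ self._left
        np.clip(P, 0.0, None, out=P)
        P /= P.sum(axis=1, keepdims=True)
        return P

    def transition_matrices(self, t: float) -> np.ndarray:
        """Stack of P(t·r_c) over the gamma categories, shape (ncat, 20, 20)."""
        return np.stack([self.transition_matrix(t, r) for r in self.category_rates])

    @property
    def n_free_parameters(self) -> int:
        """Model parameters beyond branch lengths: gamma shape and,
        for +F variants, 19 free frequencies."""
        k = 0
        if self.alpha is not None:
            k += 1
        if self.empirical_freqs:
            k += 19
        return k

    def __repr__(self):
        gamma = f"+G{self.ncat}(a={self.alpha:.3g})" if self.alpha else ""
        f = "+F" if self.empirical_freqs else ""
        return f"SubstitutionModel({self.name}{gamma}{f})"


NT_ORDER = "ACGT"
NT_INDEX = {c: i for i, c in enumerate(NT_ORDER)}


class HKYModel:
    """HKY85 nucleotide model (transition/transversion ratio ``kappa``),
    scaled to one expected substitution per site per unit branch length."""

    n_states = 4

    def __init__(self, kappa: float = 2.0, freqs=(0.25, 0.25, 0.25, 0.25)):
        if kappa <= 0:
            raise ValueError("kappa must be positive")
        pi = np.asarray(freqs, float)
        pi = pi / pi.sum()
        self.kappa = kappa
        self.freqs = pi
        S = np.ones((4, 4))
        S[NT_INDEX["A"], NT_INDEX["G"]] = S[NT_INDEX["G"], NT_INDEX["A"]] = kappa
        S[NT_INDEX["C"], NT_INDEX["T"]] = S[NT_INDEX["T"], NT_INDEX["C"]] = kappa
        Q = S * pi[None, :]
        np.fill_diagonal(Q, 0.0)
        np.fill_diagonal(Q, -Q.sum(axis=1))
        Q /= -(pi * np.diag(Q)).sum()
        self.Q = Q
        sq = np.sqrt(pi)
        B = (Q * sq[:, None]) / sq[None, :]
        w, V = np.linalg.eigh((B + B.T) / 2)
        self._eigval, self._left, self._right = w, V.T * sq[None, :], V / sq[:, None]

    def transition_matrix(self, t: float) -> np.ndarray:
        if t < 0:
            raise ValueError("negative branch length")
        P = (self._right * np.exp(self._eigval * t)[None, :]) @ self._left
        np.clip(P, 0.0, None, out=P)
        P /= P.sum(axis=1, keepdims=True)
        return P
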