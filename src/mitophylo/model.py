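"""The Tamura–Nei (1993) nucleotide substitution model.

TN93 is a time-reversible model with arbitrary stationary base frequencies
``pi`` and three exchange rates: one for purine transitions (A<->G), one for
pyrimidine transitions (C<->T), and one for all transversions.  We
parameterize by the two transition/transversion rate ratios ``kappa1``
(purine) and ``kappa2`` (pyrimidine) with the transversion rate fixed at 1,
and express branch lengths ``d`` in expected substitutions per site (the
rate matrix is rescaled so that the mean rate at stationarity is 1).

Transition probabilities use the model's closed-form spectral decomposition
rather than a numerical matrix exponential; equal frequencies with
``kappa1 = kappa2 = 1`` recover Jukes–Cantor.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

__all__ = ["TN93Model", "BASE_ORDER"]

#: Index convention for all 4x4 matrices in this package.
BASE_ORDER = "ACGT"
_A, _C, _G, _T = 0, 1, 2, 3


@dataclass(frozen=True)
class TN93Model:
    """TN93 with frequencies ``pi`` (A,C,G,T order) and rate ratios.

    ``kappa1``: A<->G transition rate / transversion rate;
    ``kappa2``: C<->T transition rate / transversion rate.
    """

    pi: tuple[float, float, float, float]
    kappa1: float = 1.0
    kappa2: float = 1.0

    def __post_init__(self):
        pi = np.asarray(self.pi, dtype=float)
        if pi.shape != (4,) or np.any(pi <= 0):
            raise ValueError("pi must be 4 positive frequencies")
        if not np.isclose(pi.sum(), 1.0, atol=1e-8):
            raise ValueError(f"frequencies must sum to 1, got {pi.sum()}")
        if self.kappa1 <= 0 or self.kappa2 <= 0:
            raise ValueError("rate ratios must be positive")

    # -- derived quantities -------------------------------------------------

    @property
    def pi_array(self) -> np.ndarray:
        return np.asarray(self.pi, dtype=float)

    @property
    def pi_R(self) -> float:
        return self.pi[_A] + self.pi[_G]

    @property
    def pi_Y(self) -> float:
        return self.pi[_C] + self.pi[_T]

    @property
    def mean_rate(self) -> float:
        """Expected substitutions per site per unit time (unscaled rates)."""
        pi = self.pi
        return (
            2 * pi[_A] * pi[_G] * self.kappa1
            + 2 * pi[_C] * pi[_T] * self.kappa2
            + 2 * self.pi_R * self.pi_Y
        )

    def rate_matrix(self) -> np.ndarray:
        """Normalized generator Q (rows sum to 0, mean rate 1)."""
        pi = self.pi_array
        Q = np.empty((4, 4))
        for i in range(4):
            for j in range(4):
                if i == j:
                    continue
                purines = {_A, _G}
                if {i, j} == purines:
                    rate = self.kappa1
                elif {i, j} == {_C, _T}:
                    rate = self.kappa2
                else:
                    rate = 1.0
                Q[i, j] = rate * pi[j]
        np.fill_diagonal(Q, 0.0)
        np.fill_diagonal(Q, -Q.sum(axis=1))
        return Q / self.mean_rate

    def transition_matrix(self, d: float) -> np.ndarray:
        """P(d): transition probabilities after ``d`` substitutions/site.

        Closed form; rows sum to 1 and ``pi @ P = pi`` (stationarity).
        """
        if d < 0:
            raise ValueError("branch length must be non-negative")
        pi = self.pi_array
        piR, piY = self.pi_R, self.pi_Y
        t = d / self.mean_rate  # time under unscaled rates (transversion = 1)
        e1 = np.exp(-t)                                # transversion factor
        e2 = np.exp(-(piR * self.kappa1 + piY) * t)    # purine transitions
        e3 = np.exp(-(piY * self.kappa2 + piR) * t)    # pyrimidine transitions
        P = np.empty((4, 4))
        A, C, G, T = pi
        P[_A, _A] = A + A * piY / piR * e1 + G / piR * e2
        P[_A, _G] = G + G * piY / piR * e1 - G / piR * e2
        P[_G, _A] = A + A * piY / piR * e1 - A / piR * e2
        P[_G, _G] = G + G * piY / piR * e1 + A / piR * e2
        P[_C, _C] = C + C * piR / piY * e1 + T / piY * e3
        P[_C, _T] = T + T * piR / piY * e1 - T / piY * e3
        P[_T, _C] = C + C * piR / piY * e1 - C / piY * e3
        P[_T, _T] = T + T * piR / piY * e1 + C / piY * e3
        for i in (_A, _G):
            P[i, _C] = C * (1 - e1)
            P[i, _T] = T * (1 - e1)
        for i in (_C, _T):
            P[i, _A] = A * (1 - e1)
            P[i, _G] = G * (1 - e1)
        return P

    def expected_pair_distribution(self, d: float) -> np.ndarray:
        """Joint distribution of bases at the two ends of a branch of length d."""
        return self.pi_array[:, None] * self.transition_matrix(d)
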