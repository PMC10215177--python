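"""Pairwise genetic distances: p, closed-form TN93, and composite-likelihood.

Three estimators over gapped nucleotide alignments, all under pairwise
deletion (per pair, only columns where both sequences have an unambiguous
A/C/G/T are used):

``p``
    Proportion of differing valid sites.
``tn93``
    The Tamura–Nei (1993) closed-form correction computed per pair from the
    two transition proportions, the transversion proportion, and base
    frequencies pooled over the pair.
``mcl``
    Maximum composite likelihood: the two TN93 transition/transversion rate
    ratios are shared across all pairs and estimated by maximizing the sum of
    pairwise log-likelihoods; each pair's distance is then the maximizer of
    its own pair likelihood under the shared rates, with base frequencies
    pooled over the whole alignment.  This is the "maximum composite
    likelihood" distance popularized by MEGA.  For a 2-taxon alignment it
    reduces to the single-pair TN93 maximum-likelihood distance.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional

import numpy as np
import pandas as pd
from scipy.optimize import minimize, minimize_scalar

from .alignment import Alignment
from .model import TN93Model

__all__ = [
    "DistanceMatrix",
    "SaturationWarning",
    "p_distance",
    "tn93_distance",
    "p_distances",
    "tn93_distances",
    "mcl_distances",
    "write_phylip",
    "combined_triangle_table",
]

logger = logging.getLogger(__name__)

_A, _C, _G, _T = 0, 1, 2, 3


class SaturationWarning(UserWarning):
    """A pairwise distance was undefined (saturated or no valid sites)."""


@dataclass
class DistanceMatrix:
    """Labelled symmetric distance matrix with estimator provenance.

    ``values`` is symmetric with a zero diagonal; undefined distances are
    NaN.  ``n_sites_used`` records the per-pair count of valid (pairwise
    deletion) sites.  ``params`` carries estimator-level metadata such as the
    fitted shared TN93 rate ratios of the composite-likelihood estimator.
    """

    labels: list[str]
    values: np.ndarray
    estimator: str
    n_sites_used: Optional[np.ndarray] = None
    params: dict = field(default_factory=dict)

    def __post_init__(self):
        self.values = np.asarray(self.values, dtype=float)
        n = len(self.labels)
        if self.values.shape != (n, n):
            raise ValueError("matrix shape does not match labels")
        if not np.allclose(np.nan_to_num(self.values),
                           np.nan_to_num(self.values.T)):
            raise ValueError("distance matrix must be symmetric")
        if not np.allclose(np.diag(self.values), 0.0):
            raise ValueError("diagonal must be zero")

    def get(self, a: str, b: str) -> float:
        return float(self.values[self.labels.index(a), self.labels.index(b)])

    def has_missing(self) -> bool:
        return bool(np.isnan(self.values).any())

    def to_dataframe(self) -> pd.DataFrame:
        return pd.DataFrame(self.values, index=self.labels, columns=self.labels)


# ---------------------------------------------------------------------------
# per-pair machinery
# ---------------------------------------------------------------------------

def _encode(row: str) -> np.ndarray:
    aln = Alignment(labels=["x"], rows=[row.upper()])
    return aln.matrix[0]


def pair_counts(a: np.ndarray, b: np.ndarray) -> np.ndarray:
    """4x4 joint base-count matrix over valid (both unambiguous) columns."""
    valid = (a < 4) & (b < 4)
    return np.bincount(
        (a[valid].astype(np.int64) * 4 + b[valid]), minlength=16
    ).reshape(4, 4).astype(float)


def _p_from_counts(N: np.ndarray) -> float:
    n = N.sum()
    if n == 0:
        return np.nan
    return float((n - np.trace(N)) / n)


def _tn93_from_counts(N: np.ndarray) -> float:
    n = N.sum()
    if n == 0:
        return np.nan
    # frequencies pooled over the two sequences of the pair
    pi = (N.sum(axis=0) + N.sum(axis=1)) / (2 * n)
    if np.any(pi == 0):
        return np.nan
    piA, piC, piG, piT = pi
    piR, piY = piA + piG, piC + piT
    P1 = (N[_A, _G] + N[_G, _A]) / n          # purine transitions
    P2 = (N[_C, _T] + N[_T, _C]) / n          # pyrimidine transitions
    p_total = (n - np.trace(N)) / n
    Q = p_total - P1 - P2                      # transversions
    k1 = 2 * piA * piG / piR
    k2 = 2 * piC * piT / piY
    k3 = 2 * (piR * piY - piA * piG * piY / piR - piC * piT * piR / piY)
    w1 = 1 - piR * P1 / (2 * piA * piG) - Q / (2 * piR)
    w2 = 1 - piY * P2 / (2 * piC * piT) - Q / (2 * piY)
    w3 = 1 - Q / (2 * piR * piY)
    if w1 <= 0 or w2 <= 0 or w3 <= 0:
        return np.nan
    return float(-k1 * np.log(w1) - k2 * np.log(w2) - k3 * np.log(w3))


def p_distance(a: str, b: str) -> float:
    """p-distance between two aligned rows (pairwise deletion); NaN if no
    valid sites."""
    ea, eb = _encode(a), _encode(b)
    if ea.shape != eb.shape:
        raise ValueError("rows have unequal lengths")
    return _p_from_counts(pair_counts(ea, eb))


def tn93_distance(a: str, b: str) -> float:
    """Closed-form TN93 distance between two aligned rows.

    Returns NaN (with a warning) when a logarithm argument is non-positive
    (saturation) or when valid sites are absent.
    """
    ea, eb = _encode(a), _encode(b)
    if ea.shape != eb.shape:
        raise ValueError("rows have unequal lengths")
    d = _tn93_from_counts(pair_counts(ea, eb))
    if np.isnan(d):
        warnings.warn(
            "TN93 distance undefined (saturated or no valid sites)",
            SaturationWarning, stacklevel=2,
        )
    return d


def _all_pair_counts(aln: Alignment):
    mat = aln.matrix
    n = aln.n_taxa
    counts = {}
    for i in range(n):
        for j in range(i + 1, n):
            counts[(i, j)] = pair_counts(mat[i], mat[j])
    return counts


def _matrix_from_pairfunc(aln: Alignment, func, estimator: str) -> DistanceMatrix:
    n = aln.n_taxa
    values = np.zeros((n, n))
    sites = np.zeros((n, n))
    counts = _all_pair_counts(aln)
    n_undef = 0
    for (i, j), N in counts.items():
        d = func(N)
        if np.isnan(d):
            n_undef += 1
        values[i, j] = values[j, i] = d
        sites[i, j] = sites[j, i] = N.sum()
    if n_undef:
        warnings.warn(
            f"{n_undef} pairwise {estimator} distance(s) undefined",
            SaturationWarning, stacklevel=2,
        )
    return DistanceMatrix(
        labels=list(aln.labels), values=values,
        estimator=estimator, n_sites_used=sites,
    )


def p_distances(aln: Alignment) -> DistanceMatrix:
    """All pairwise p-distances of an alignment."""
    return _matrix_from_pairfunc(aln, _p_from_counts, "p")


def tn93_distances(aln: Alignment) -> DistanceMatrix:
    """All pairwise closed-form TN93 distances of an alignment."""
    return _matrix_from_pairfunc(aln, _tn93_from_counts, "tn93")


# ---------------------------------------------------------------------------
# composite likelihood
# ---------------------------------------------------------------------------

def _pooled_frequencies(aln: Alignment) -> np.ndarray:
    mat = aln.matrix
    counts = np.bincount(mat[mat < 4], minlength=4).astype(float)
    if np.any(counts == 0):
        # keep the model non-degenerate on tiny inputs
        counts += 0.5
    return counts / counts.sum()


def _pair_loglik(N: np.ndarray, model: TN93Model, d: float) -> float:
    joint = model.expected_pair_distribution(d)
    mask = N > 0
    with np.errstate(divide="ignore"):
        logj = np.log(np.where(joint > 0, joint, np.nan))
    if np.any(mask & ~np.isfinite(logj)):
        return -np.inf
    return float(np.sum(N[mask] * logj[mask]))


def _optimal_pair_distance(
    N: np.ndarray, model: TN93Model, d_max: float = 20.0
) -> float:
    n = N.sum()
    if n == 0:
        return np.nan
    if np.trace(N) == n:
        return 0.0
    res = minimize_scalar(
        lambda d: -_pair_loglik(N, model, d),
        bounds=(1e-9, d_max), method="bounded",
        options={"xatol": 1e-10},
    )
    return float(res.x)


def _moment_kappas(counts: dict) -> tuple[float, float]:
    """Rough starting rate ratios from summed transition/transversion counts."""
    total = sum(counts.values())
    n = total.sum()
    pi = (total.sum(axis=0) + total.sum(axis=1)) / (2 * n)
    piA, piC, piG, piT = pi
    piR, piY = piA + piG, piC + piT
    P1 = (total[_A, _G] + total[_G, _A]) / n
    P2 = (total[_C, _T] + total[_T, _C]) / n
    Q = max((n - np.trace(total)) / n - P1 - P2, 1e-6)
    k1 = (P1 / Q) * (piR * piY) / max(piA * piG, 1e-6)
    k2 = (P2 / Q) * (piR * piY) / max(piC * piT, 1e-6)
    return float(np.clip(k1, 0.05, 100)), float(np.clip(k2, 0.05, 100))


def mcl_distances(
    aln: Alignment,
    xtol: float = 1e-6,
    max_distance: float = 20.0,
) -> DistanceMatrix:
    """Maximum composite likelihood TN93 distances for an alignment.

    The two transition/transversion rate ratios are shared across pairs and
    fitted by maximizing the summed pairwise log-likelihoods (Nelder–Mead on
    the log-ratios, inner 1-D bounded search per pair distance); base
    frequencies are pooled over the alignment.  Raises ``RuntimeError`` on
    optimizer non-convergence.
    """
    if aln.n_taxa < 2:
        raise ValueError("need at least 2 taxa")
    counts = _all_pair_counts(aln)
    pi = tuple(_pooled_frequencies(aln))

    def neg_cl(x: np.ndarray) -> float:
        model = TN93Model(pi=pi, kappa1=float(np.exp(x[0])),
                          kappa2=float(np.exp(x[1])))
        total = 0.0
        for N in counts.values():
            if N.sum() == 0:
                continue
            d = _optimal_pair_distance(N, model, max_distance)
            ll = _pair_loglik(N, model, d)
            if not np.isfinite(ll):
                return np.inf
            total += ll
        return -total

    k1_0, k2_0 = _moment_kappas(counts)
    res = minimize(
        neg_cl, x0=np.log([k1_0, k2_0]), method="Nelder-Mead",
        options={"xatol": xtol, "fatol": 1e-8, "maxiter": 400},
    )
    if not res.success:
        raise RuntimeError(
            f"composite-likelihood optimizer did not converge "
            f"(xatol={xtol}, fatol=1e-8): {res.message}"
        )
    kappa1, kappa2 = np.exp(res.x)
    model = TN93Model(pi=pi, kappa1=float(kappa1), kappa2=float(kappa2))

    n = aln.n_taxa
    values = np.zeros((n, n))
    sites = np.zeros((n, n))
    for (i, j), N in counts.items():
        d = _optimal_pair_distance(N, model, max_distance)
        values[i, j] = values[j, i] = d
        sites[i, j] = sites[j, i] = N.sum()
    logger.info(
        "composite-likelihood fit: kappa1=%.4f kappa2=%.4f over %d pairs",
        kappa1, kappa2, len(counts),
    )
    return DistanceMatrix(
        labels=list(aln.labels), values=values, estimator="mcl",
        n_sites_used=sites,
        params={"kappa1": float(kappa1), "kappa2": float(kappa2), "pi": pi},
    )


# ---------------------------------------------------------------------------
# output formats
# ---------------------------------------------------------------------------

def write_phylip(dm: DistanceMatrix, path: str | Path) -> None:
    """Square PHYLIP distance-matrix file (relaxed label width)."""
    width = max(10, max(len(l) for l in dm.labels) + 2)
    with open(path, "w") as fh:
        fh.write(f"{len(dm.labels)}\n")
        for label, row in zip(dm.labels, dm.values):
            cells = "  ".join(f"{v:.6f}" for v in row)
            fh.write(f"{label:<{width}}{cells}\n")


def combined_triangle_table(
    upper: DistanceMatrix, lower: DistanceMatrix, ndigits: int = 3
) -> pd.DataFrame:
    """Render two estimators in one table: ``upper`` above the diagonal,
    ``lower`` below, dashes on the diagonal — the usual presentation of
    model-corrected vs p-distances in one matrix."""
    if upper.labels != lower.labels:
        raise ValueError("label sets differ")
    n = len(upper.labels)
    cells = [["-"] * n for _ in range(n)]
    for i in range(n):
        for j in range(n):
            if i < j:
                cells[i][j] = f"{upper.values[i, j]:.{ndigits}f}"
            elif i > j:
                cells[i][j] = f"{lower.values[i, j]:.{ndigits}f}"
    return pd.DataFrame(cells, index=upper.labels, columns=upper.labels)
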