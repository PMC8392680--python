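"""Favourability transform and the two entropies of a distribution model.

Favourability removes the effect of species prevalence from the fitted
probability:

    F = [P / (1 - P)] / [(n1 / n0) + P / (1 - P)]

so F = 0.5 exactly where the local probability equals the prevalence
n1/(n1+n0), whatever the prevalence. F is a fuzzy membership degree of each
cell in the set of favourable sites, which licenses fuzzy-set operations.

Shannon entropy H is computed on fitted probabilities divided by the number
of presences n1 (so they sum to 1 at any intercept-model MLE):

    H = -sum p_i ln p_i,   p_i = P_i / n1,

with maximum ln(n) when all P_i are equal. Fuzzy entropy uses the min/max
(fuzzy intersection/union) of F with its complement:

    R = sum min(F_i, 1 - F_i) / sum max(F_i, 1 - F_i),

ranging from 1 (all F = 0.5, total disorder) to 0 (every F at 0 or 1), and
is commensurable across species and study areas.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np

from .glm import LogisticModel


@dataclass
class FavourabilityMap:
    """Per-cell favourability values with the prevalence that produced them."""

    values: np.ndarray = field(repr=False)
    n1: int = 0
    n0: int = 0
    source_model: LogisticModel | None = field(default=None, repr=False)

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.ndim != 1 or self.values.size == 0:
            raise ValueError("favourability map needs a non-empty 1-d vector")
        if np.any((self.values < 0) | (self.values > 1)):
            raise ValueError("favourability values must lie in [0, 1]")


@dataclass
class EntropyPair:
    """Shannon entropy H (nats) and fuzzy entropy R of one model."""

    shannon: float
    fuzzy: float


def favourability(P, n1: int, n0: int, source_model: LogisticModel | None = None) -> FavourabilityMap:
    """Apply the favourability transform to a probability vector."""
    if n1 <= 0 or n0 <= 0:
        raise ValueError("favourability needs n1 > 0 and n0 > 0")
    P = np.asarray(P, dtype=float)
    if np.any((P < 0) | (P > 1)):
        raise ValueError("probabilities must lie in [0, 1]")
    at_bound = (P == 0) | (P == 1)
    if np.any(at_bound):
        warnings.warn("probabilities exactly at 0 or 1 mapped to F = 0 or 1")
    with np.errstate(divide="ignore", invalid="ignore"):
        odds = P / (1.0 - P)
        F = odds / (n1 / n0 + odds)
    F = np.where(P == 1.0, 1.0, F)
    F = np.where(P == 0.0, 0.0, F)
    return FavourabilityMap(values=F, n1=int(n1), n0=int(n0), source_model=source_model)


def inverse_favourability(F, n1: int, n0: int) -> np.ndarray:
    """Probability whose favourability equals F (inverse of the transform)."""
    F = np.asarray(F, dtype=float)
    odds = (n1 / n0) * F / (1.0 - F)
    return odds / (1.0 + odds)


def shannon_entropy_normalized(P, n1: int) -> float:
    """Shannon entropy (nats) of fitted probabilities divided by n1.

    The division makes the vector a probability distribution over cells;
    this holds exactly when P are MLE fitted probabilities of a model with
    an intercept, for which sum(P) = n1 by the score equation.
    """
    P = np.asarray(P, dtype=float)
    if n1 <= 0:
        raise ValueError("n1 must be positive")
    if np.any(P < 0):
        raise ValueError("probabilities must be non-negative")
    p = P / n1
    total = p.sum()
    if abs(total - 1.0) > 1e-3:
        raise ValueError(
            f"sum(P)/n1 = {total:.6f} is not 1: P must be MLE fitted "
            "probabilities of a model containing an intercept"
        )
    nz = p[p > 0]
    return float(-np.sum(nz * np.log(nz)))


def fuzzy_entropy(F) -> float:
    """Fuzzy entropy R = sum min(F, 1-F) / sum max(F, 1-F), in [0, 1]."""
    values = F.values if isinstance(F, FavourabilityMap) else np.asarray(F, dtype=float)
    if values.size == 0:
        raise ValueError("fuzzy entropy of an empty vector is undefined")
    comp = 1.0 - values
    return float(np.minimum(values, comp).sum() / np.maximum(values, comp).sum())


def entropy_pair(P, F, n1: int) -> EntropyPair:
    return EntropyPair(shannon=shannon_entropy_normalized(P, n1), fuzzy=fuzzy_entropy(F))
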