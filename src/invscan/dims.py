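"""Johnson-Lindenstrauss heuristic for choosing the hashed dimensionality.

The JL lemma bounds the number of dimensions k of a random projection
needed so that all pairwise squared distances among n points are preserved
within a relative distortion epsilon:

    k >= 4 ln(n) / (eps^2/2 - eps^3/3)

For inversion detection the tolerable distortion is tied to the geometry of
the genotype clusters: if l SNPs are inversion-linked and m are background,
the relative distance excess between samples of different inversion
genotypes is at least l/m, so any eps strictly below l/m keeps the clusters
separated after projection. l and m may be SNP counts or genomic spans —
only their ratio matters.

The bound is evaluated with the natural logarithm and truncated toward
zero; a strict reading of "k >= bound" would round up, but truncation is
what reproduces the reference dimensionality of 4,532 for n = 198 at
eps = 0.1 (raw bound 4532.8), so that convention is kept and documented.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

from .errors import ParameterError


@dataclass(frozen=True)
class JLQuery:
    """Inputs of the dimension heuristic (l and m in the same units)."""

    n: int
    epsilon: float
    l: float = 0.0
    m: float = 0.0

    def __post_init__(self) -> None:
        if self.n < 2:
            raise ParameterError(f"sample count must be >= 2, got {self.n}")
        if not 0.0 < self.epsilon < 1.0:
            raise ParameterError(f"epsilon must lie in (0, 1), got {self.epsilon}")


def epsilon_bound(l: float, m: float) -> float:
    """Strict upper bound l/m on the distortion eps that keeps inversion
    genotype clusters separable; callers must choose eps < min(l/m, 1)."""
    if l <= 0 or m <= 0:
        raise ParameterError(f"l and m must be positive, got l={l}, m={m}")
    return l / m


def choose_epsilon(l: float, m: float, delta: float = 0.01) -> float:
    """Pick an eps satisfying the strict inequality: min(l/m, 0.999)*(1-delta)."""
    if not 0.0 < delta < 1.0:
        raise ParameterError(f"delta must lie in (0, 1), got {delta}")
    return min(epsilon_bound(l, m), 0.999) * (1.0 - delta)


def min_dimensions(n: int, epsilon: float) -> int:
    """Minimal hashed dimensionality for n samples at distortion epsilon.

    Evaluates 4*ln(n)/(eps^2/2 - eps^3/3), truncates toward zero, and never
    returns less than 1. Monotone non-decreasing in n and non-increasing in
    epsilon.
    """
    if n < 2:
        raise ParameterError(f"sample count must be >= 2, got {n}")
    if not 0.0 < epsilon < 1.0:
        raise ParameterError(f"epsilon must lie in (0, 1), got {epsilon}")
    denom = epsilon**2 / 2.0 - epsilon**3 / 3.0
    raw = 4.0 * math.log(n) / denom
    return max(1, int(raw))
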