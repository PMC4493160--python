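"""Closed-form solution of the constant-coefficient age-class system.

When the egg-laying rate E0, the per-age survivals S_i and the aging rates
are all constant (no seasonality, pheromones or scarcity), the 55 coupled
equations dB_i/dt = S_{i-1} B_{i-1} - B_i form a linear cascade with the
explicit solution

    B_i(t) = E0 * prod_{j<i} S_j
             + sum_{k=0}^{i-1} [ prod_{j=i-k}^{i-1} S_j ]
                               * (B_{i-k}(0) - E0 * prod_{j<i-k} S_j)
                               * f_k(t),
    f_k(t) = t**k * exp(-t) / k!

— the steady profile plus Poisson-weighted relaxation of every upstream
initial deviation.  This module is the correctness oracle for the Euler
integrator.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np

__all__ = ["LinearSolutionSpec", "analytic_B", "analytic_solution"]


@dataclass(frozen=True)
class LinearSolutionSpec:
    """Inputs of the linear cascade: laying rate, survivals, initial state."""

    E0: float
    S: tuple[float, ...]
    B_init: tuple[float, ...] = field(default=())

    def __post_init__(self) -> None:
        if any(not 0.0 < s <= 1.0 for s in self.S):
            raise ValueError("survivals must lie in (0, 1]")
        binit = self.B_init if self.B_init else tuple(0.0 for _ in self.S)
        if len(binit) != len(self.S):
            raise ValueError("B_init length must match S")
        if any(b < 0.0 for b in binit):
            raise ValueError("B_init must be non-negative")
        object.__setattr__(self, "B_init", tuple(float(b) for b in binit))

    @property
    def n(self) -> int:
        return len(self.S)


def analytic_solution(spec: LinearSolutionSpec, t: float) -> np.ndarray:
    """All age-class abundances B_1..B_n at time t (days).

    The Poisson weights f_k(t) are accumulated incrementally
    (f_k = f_{k-1} * t / k) to stay finite at large t, and the survival
    suffix products prod_{j=i-k}^{i-1} S_j are built by extending one factor
    per k.
    """
    if t < 0:
        raise ValueError("t must be non-negative")
    n = spec.n
    S = spec.S
    # steady[i] = E0 * prod_{j<=i} S_j with steady[0] = E0 (empty product)
    steady = np.empty(n + 1)
    steady[0] = spec.E0
    for j in range(1, n + 1):
        steady[j] = steady[j - 1] * S[j - 1]

    out = np.empty(n)
    exp_neg_t = np.exp(-t)
    for i in range(1, n + 1):
        total = steady[i - 1]  # E0 * prod_{j=1}^{i-1} S_j
        fk = exp_neg_t  # f_0(t)
        suffix = 1.0  # prod_{j=i-k}^{i-1} S_j, empty at k=0
        for k in range(0, i):
            if k > 0:
                suffix *= S[i - k - 1]  # extend by S_{i-k}
                fk *= t / k
            dev = spec.B_init[i - k - 1] - steady[i - k - 1]
            total += suffix * dev * fk
        out[i - 1] = total
    return out


def analytic_B(spec: LinearSolutionSpec, i: int, t: float) -> float:
    """Abundance of age class ``i`` (1-based) at time ``t``."""
    if not 1 <= i <= spec.n:
        raise ValueError(f"age class {i} outside 1..{spec.n}")
    return float(analytic_solution(spec, t)[i - 1])
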