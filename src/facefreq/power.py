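"""A priori power for the within-between interaction of a 2 x 4 mixed ANOVA.

The target design crosses k = 2 groups with m = 4 repeated measures;
under compound symmetry (common correlation rho among the repeated
measures) with nonsphericity epsilon, the group x condition interaction
F test has

    df1 = (k - 1)(m - 1) epsilon
    df2 = (N - k)(m - 1) epsilon
    lambda = f^2 N m epsilon / (1 - rho)

with Cohen's f^2 = eta^2 / (1 - eta^2) from the partial eta squared, and
power = P(F'(df1, df2, lambda) > F_crit(1 - alpha)).  This is the
convention standard power calculators use for repeated-measures
interactions; rho and epsilon default to 0.5 and 1 (the calculator
defaults — the assumed correlation is rarely reported).  Minimum sample
size is found by monotone search, by default rounding N up so groups
can be equal, as sample-size calculators do.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import stats

__all__ = ["PowerSpec", "interaction_power", "min_sample_size"]


@dataclass
class PowerSpec:
    """Assumptions for the interaction power computation.

    eta2 : partial eta squared of the interaction (Cohen's f^2 =
        eta2 / (1 - eta2)); ``f`` may be given directly instead.
    alpha : significance level.
    target_power : desired 1 - beta (used by :func:`min_sample_size`).
    k_groups, m_levels : between and within factor levels.
    rho : assumed correlation among repeated measures, in [0, 1).
    epsilon : nonsphericity correction in (0, 1].
    """

    eta2: float | None = 0.06
    f: float | None = None
    alpha: float = 0.05
    target_power: float = 0.95
    k_groups: int = 2
    m_levels: int = 4
    rho: float = 0.5
    epsilon: float = 1.0

    def __post_init__(self) -> None:
        if (self.eta2 is None) == (self.f is None):
            raise ValueError("specify exactly one of eta2 or f")
        if self.eta2 is not None and not 0.0 <= self.eta2 < 1.0:
            raise ValueError("eta2 must lie in [0, 1)")
        if self.f is not None and self.f < 0:
            raise ValueError("f must be >= 0")
        if not 0.0 < self.alpha < 1.0:
            raise ValueError("alpha must lie in (0, 1)")
        if not 0.0 <= self.rho < 1.0:
            raise ValueError("rho must lie in [0, 1); rho -> 1 diverges")
        if not 0.0 < self.epsilon <= 1.0:
            raise ValueError("epsilon must lie in (0, 1]")
        if self.k_groups < 2 or self.m_levels < 2:
            raise ValueError("need k_groups >= 2 and m_levels >= 2")

    @property
    def f2(self) -> float:
        if self.f is not None:
            return self.f ** 2
        return self.eta2 / (1.0 - self.eta2)


def interaction_power(spec: PowerSpec, n_total: int) -> float:
    """Power of the group x condition interaction at total sample size N."""
    k, m = spec.k_groups, spec.m_levels
    if n_total <= k:
        raise ValueError("N must exceed the number of groups")
    df1 = (k - 1) * (m - 1) * spec.epsilon
    df2 = (n_total - k) * (m - 1) * spec.epsilon
    lam = spec.f2 * n_total * m * spec.epsilon / (1.0 - spec.rho)
    fcrit = stats.f.isf(spec.alpha, df1, df2)
    if lam == 0.0:  # central case (scipy's ncf is unreliable at lambda = 0)
        return float(spec.alpha)
    return float(stats.ncf.sf(fcrit, df1, df2, lam))


def min_sample_size(
    spec: PowerSpec, round_to_groups: bool = True, n_max: int = 100_000
) -> int:
    """Smallest total N whose interaction power reaches ``target_power``.

    With ``round_to_groups`` the result is rounded up to a multiple of
    the number of groups (equal allocation).  Raises if the target is
    unreachable below ``n_max``.
    """
    if not spec.alpha < spec.target_power < 1.0:
        raise ValueError("target_power must lie in (alpha, 1)")
    if spec.f2 == 0.0:
        raise ValueError("zero effect size: target power unreachable")
    n = spec.k_groups + 1
    while n <= n_max:
        if interaction_power(spec, n) >= spec.target_power:
            if round_to_groups and n % spec.k_groups:
                n += spec.k_groups - n % spec.k_groups
            return n
        n += 1
    raise ValueError(f"target power {spec.target_power} not reached by N={n_max}")
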