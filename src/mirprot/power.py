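"""Two-sample design calculations.

Minimal detectable effect size (Cohen's d) for a two-sided, unpaired
two-sample t-test with equal group sizes, solved from the noncentral t
distribution, and the raw-scale fold change that effect size implies for
log-normal data with a given coefficient of variation.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
from scipy import optimize, stats

from .containers import ConfigurationError

__all__ = [
    "DesignSpec",
    "power_at_effect",
    "min_detectable_effect",
    "required_fold_change",
    "effect_from_fold_change",
    "monte_carlo_power",
]


@dataclass
class DesignSpec:
    """Two-group design: n per group, two-sided alpha, target power."""

    n_per_group: int = 5
    alpha: float = 0.05
    power: float = 0.9
    cv: float | None = None

    def __post_init__(self) -> None:
        if not 0.0 < self.alpha < 1.0:
            raise ConfigurationError("alpha must lie in (0, 1)")
        if not 0.0 < self.power < 1.0:
            raise ConfigurationError("power must lie in (0, 1)")
        if self.n_per_group < 2:
            raise ConfigurationError("n_per_group must be at least 2")
        if self.alpha >= self.power:
            raise ConfigurationError(
                "target power must exceed alpha (otherwise d -> 0)")


def power_at_effect(d: float, n_per_group: int, alpha: float) -> float:
    """Exact power of the two-sided two-sample t-test at effect size d.

    df = 2n - 2, noncentrality d*sqrt(n/2); both rejection tails counted.
    """
    df = 2 * n_per_group - 2
    nc = d * math.sqrt(n_per_group / 2.0)
    tcrit = stats.t.ppf(1.0 - alpha / 2.0, df)
    return float(stats.nct.sf(tcrit, df, nc) + stats.nct.cdf(-tcrit, df, nc))


def min_detectable_effect(spec: DesignSpec) -> float:
    """Smallest Cohen's d reaching the target power (solved to |dd| < 1e-6)."""
    n, alpha, target = spec.n_per_group, spec.alpha, spec.power

    def gap(d: float) -> float:
        return power_at_effect(d, n, alpha) - target

    hi = 1.0
    while gap(hi) < 0.0:
        hi *= 2.0
        if hi > 1e4:
            raise ConfigurationError("requested power is unattainable")
    return float(optimize.brentq(gap, 1e-12, hi, xtol=1e-9))


def required_fold_change(d: float, cv: float) -> float:
    """Raw-scale fold change corresponding to Cohen's d at a given CV.

    Uses the exact log-normal relation FC = exp(d * sdln) with
    sdln = sqrt(ln(1 + cv^2)); for small cv, sdln ~ cv. Strictly
    increasing in both arguments.
    """
    if d <= 0:
        raise ConfigurationError("effect size must be positive")
    if cv <= 0:
        raise ConfigurationError("cv must be positive")
    return math.exp(d * math.sqrt(math.log1p(cv * cv)))


def effect_from_fold_change(fc: float, cv: float) -> float:
    """Inverse of :func:`required_fold_change`."""
    if fc <= 1.0:
        raise ConfigurationError("fold change must exceed 1")
    return math.log(fc) / math.sqrt(math.log1p(cv * cv))


def monte_carlo_power(d: float, n_per_group: int, alpha: float,
                      n_reps: int = 100_000, seed: int = 0) -> float:
    """Estimate two-sample t-test power by simulation (equal-variance test).

    Used as an independent check on the noncentral-t solution.
    """
    rng = np.random.default_rng(seed)
    a = rng.standard_normal((n_reps, n_per_group))
    b = rng.standard_normal((n_reps, n_per_group)) + d
    res = stats.ttest_ind(b, a, axis=1)
    return float(np.mean(res.pvalue < alpha))
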