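"""Discovery/replication combination, significance tiers, and power.

Stage estimates are combined by fixed-effect inverse-variance meta-analysis.
Associations are tiered against a Bonferroni threshold 0.05/n_exposures
(strict `<` for significance; p in [threshold, 0.05] is "suggestive").
Power for a binary outcome uses the standard summary-level MR
approximation: with N = cases + controls, case fraction P and instrument
variance explained R^2,

    power = Phi(|ln OR| * sqrt(N * R^2 * P(1-P)) - z_{1-alpha/2})

and the detectable OR at a target power inverts this closed form.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
from scipy import stats

__all__ = ["PowerSpec", "fixed_effect_meta", "classify_association",
           "detectable_or", "power_at_or"]


@dataclass
class PowerSpec:
    n_cases: int
    n_controls: int
    r2: float
    alpha: float = 0.05
    target_power: float = 0.80

    def __post_init__(self) -> None:
        if self.n_cases <= 0 or self.n_controls <= 0:
            raise ValueError("case and control counts must be positive")
        if not (0 < self.r2 < 1):
            raise ValueError("r2 must be in (0, 1)")
        if not (0 < self.alpha < 1) or not (0 < self.target_power < 1):
            raise ValueError("alpha and target_power must be in (0, 1)")

    @property
    def n(self) -> int:
        return self.n_cases + self.n_controls

    @property
    def case_fraction(self) -> float:
        return self.n_cases / self.n


def fixed_effect_meta(estimates: list[tuple[float, float]]
                      ) -> tuple[float, float, float]:
    """Inverse-variance fixed-effect combination of (estimate, se) pairs."""
    if not estimates:
        raise ValueError("nothing to combine")
    b = np.array([e for e, _ in estimates], dtype=float)
    s = np.array([s for _, s in estimates], dtype=float)
    if np.any(s <= 0):
        raise ValueError("all standard errors must be positive")
    w = s**-2
    combined = float(np.sum(w * b) / np.sum(w))
    se = float(np.sum(w) ** -0.5)
    p = min(1.0, max(float(np.finfo(float).tiny),
                     2 * float(stats.norm.sf(abs(combined / se)))))
    return combined, se, p


def classify_association(pvalue: float, n_exposures: int) -> tuple[str, float]:
    """Tier a p-value: 'significant' below 0.05/n_exposures (strict),
    'suggestive' in [threshold, 0.05], else 'none'. Returns (tier, threshold)."""
    if not (0 < pvalue <= 1):
        raise ValueError("pvalue must be in (0, 1]")
    if n_exposures < 1:
        raise ValueError("n_exposures must be >= 1")
    threshold = 0.05 / n_exposures
    if pvalue < threshold:
        return "significant", threshold
    if pvalue <= 0.05:
        return "suggestive", threshold
    return "none", threshold


def _ncp_scale(spec: PowerSpec) -> float:
    p = spec.case_fraction
    return math.sqrt(spec.n * spec.r2 * p * (1.0 - p))


def detectable_or(spec: PowerSpec) -> tuple[float, float]:
    """Smallest odds ratios detectable at the target power: (above 1, below 1)."""
    b = (stats.norm.ppf(spec.target_power)
         + stats.norm.ppf(1 - spec.alpha / 2)) / _ncp_scale(spec)
    return float(math.exp(b)), float(math.exp(-b))


def power_at_or(spec: PowerSpec, odds_ratio: float) -> float:
    """Power to detect ``odds_ratio`` at the spec's alpha (two-sided)."""
    if odds_ratio <= 0:
        raise ValueError("odds_ratio must be positive")
    z = abs(math.log(odds_ratio)) * _ncp_scale(spec) - stats.norm.ppf(1 - spec.alpha / 2)
    return float(stats.norm.cdf(z))
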