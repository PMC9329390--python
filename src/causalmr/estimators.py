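"""Univariable two-sample MR estimators and their diagnostics.

Each instrument j contributes a Wald ratio theta_j = beta_out_j / beta_exp_j
with first-order standard error sigma_j = se_out_j / |beta_exp_j|. The main
estimator is the inverse-variance-weighted (IVW) mean of the ratios, with a
multiplicative random-effects variance inflation max(1, sqrt(Q/(L-1))) by
default because moderate-to-high heterogeneity is the norm in practice.
Sensitivity estimators relax the no-pleiotropy assumption in different ways:

* MR-Egger: weighted regression of outcome on exposure effects with a free
  intercept; a non-zero intercept indicates directional pleiotropy, the
  slope stays consistent under the InSIDE assumption.
* Weighted median: consistent when >= 50% of the weight lies on valid
  instruments; SE by parametric bootstrap.
* Contamination mixture: each instrument is modelled as valid
  (ratio ~ N(theta, sigma_j^2)) or invalid (ratio ~ N(0, sigma_j^2 + psi^2));
  the estimate maximizes the profile log-likelihood over a grid, and the 95%
  confidence set is the likelihood-ratio region (possibly multimodal).

Cochran's Q (with df = L - 1) quantifies ratio heterogeneity. All p-values
are two-sided from the normal reference.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
from scipy import stats

from .summary_io import HarmonizedSet

__all__ = [
    "MRResult",
    "QResult",
    "EggerResult",
    "ConMixResult",
    "wald_ratio",
    "ivw",
    "cochran_q",
    "egger",
    "weighted_median",
    "contamination_mixture",
]

Z975 = stats.norm.ppf(0.975)


@dataclass
class MRResult:
    method: str
    estimate: float
    se: float
    ci_low: float
    ci_high: float
    pvalue: float
    n_snps: int
    notes: str = ""

    @property
    def odds_ratio(self) -> float:
        """exp(estimate): odds ratio per exposure unit for a binary outcome."""
        return math.exp(self.estimate)

    @classmethod
    def from_normal(cls, method: str, estimate: float, se: float, n_snps: int,
                    notes: str = "") -> "MRResult":
        z = estimate / se
        p = min(1.0, max(np.finfo(float).tiny, 2 * stats.norm.sf(abs(z))))
        return cls(method=method, estimate=float(estimate), se=float(se),
                   ci_low=float(estimate - Z975 * se),
                   ci_high=float(estimate + Z975 * se),
                   pvalue=float(p), n_snps=int(n_snps), notes=notes)


@dataclass
class QResult:
    q: float
    df: int
    pvalue: float


@dataclass
class EggerResult:
    slope: MRResult
    intercept: float
    intercept_se: float
    intercept_pvalue: float


@dataclass
class ConMixResult:
    estimate: float
    ci_low: float
    ci_high: float
    multimodal: bool
    valid_set: list = field(default_factory=list)
    psi: float = float("nan")
    n_snps: int = 0


def _ratios(hs: HarmonizedSet) -> tuple[np.ndarray, np.ndarray]:
    bx, _, by, sy = hs.arrays()
    if np.any(bx == 0):
        raise ZeroDivisionError("wald ratio undefined: beta_exp = 0 for some instrument")
    return by / bx, sy / np.abs(bx)


def wald_ratio(beta_exp: float, se_exp: float, beta_out: float, se_out: float
               ) -> tuple[float, float]:
    """Single-instrument causal ratio and its first-order standard error."""
    if beta_exp == 0:
        raise ZeroDivisionError("wald ratio undefined for beta_exp = 0")
    return beta_out / beta_exp, se_out / abs(beta_exp)


def cochran_q(hs: HarmonizedSet) -> QResult:
    """Heterogeneity of the per-instrument ratios about the IVW mean."""
    theta, sigma = _ratios(hs)
    if theta.size < 2:
        raise ValueError("Cochran's Q needs at least 2 instruments")
    w = sigma**-2
    est = np.sum(w * theta) / np.sum(w)
    q = float(np.sum(w * (theta - est) ** 2))
    df = theta.size - 1
    return QResult(q=q, df=df, pvalue=float(stats.chi2.sf(q, df)))


def ivw(hs: HarmonizedSet, model: str = "multiplicative_random"
        ) -> tuple[MRResult, QResult | None]:
    """Inverse-variance-weighted estimate (the main analysis).

    ``model`` is ``"fixed"`` or ``"multiplicative_random"``; the latter
    inflates the fixed-effect SE by max(1, sqrt(Q/(L-1))).
    """
    if model not in {"fixed", "multiplicative_random"}:
        raise ValueError(f"unknown IVW model {model!r}")
    theta, sigma = _ratios(hs)
    if theta.size == 0:
        raise ValueError("IVW needs at least one instrument")
    w = sigma**-2
    est = float(np.sum(w * theta) / np.sum(w))
    se_fixed = float(np.sum(w) ** -0.5)
    qres = None
    se = se_fixed
    if theta.size >= 2:
        q = float(np.sum(w * (theta - est) ** 2))
        df = theta.size - 1
        qres = QResult(q=q, df=df, pvalue=float(stats.chi2.sf(q, df)))
        if model == "multiplicative_random":
            se = se_fixed * max(1.0, math.sqrt(q / df))
    return MRResult.from_normal(f"ivw_{model}", est, se, theta.size), qres


def egger(hs: HarmonizedSet) -> EggerResult:
    """MR-Egger regression: pleiotropy-robust slope plus intercept test.

    Instruments are oriented so every exposure effect is positive (negating
    both betas where needed; results are invariant to the input orientation),
    then outcome effects are regressed on exposure effects with weights
    se_out^-2 and a free intercept. SEs carry the multiplicative
    overdispersion max(1, sqrt(RSS_w / (L - 2))).
    """
    bx, _, by, sy = hs.arrays()
    L = bx.size
    if L < 3:
        raise ValueError("MR-Egger needs at least 3 instruments")
    sign = np.where(bx < 0, -1.0, 1.0)
    x = bx * sign
    y = by * sign
    w = sy**-2

    X = np.column_stack([np.ones(L), x])
    XtW = X.T * w
    cov_unscaled = np.linalg.inv(XtW @ X)
    coef = cov_unscaled @ (XtW @ y)
    resid = y - X @ coef
    rss_w = float(np.sum(w * resid**2))
    phi = max(1.0, math.sqrt(rss_w / (L - 2)))
    se_coef = np.sqrt(np.diag(cov_unscaled)) * phi

    slope = MRResult.from_normal("egger", coef[1], se_coef[1], L)
    zp = min(1.0, max(np.finfo(float).tiny,
                      2 * stats.norm.sf(abs(coef[0] / se_coef[0]))))
    return EggerResult(slope=slope, intercept=float(coef[0]),
                       intercept_se=float(se_coef[0]), intercept_pvalue=float(zp))


def _weighted_median_point(theta: np.ndarray, w: np.ndarray) -> float:
    order = np.argsort(theta)
    t = theta[order]
    wn = w[order] / np.sum(w)
    p = np.cumsum(wn) - wn / 2.0
    return float(np.interp(0.5, p, t))


def weighted_median(hs: HarmonizedSet, n_boot: int = 1000, *, seed: int) -> MRResult:
    """Weighted-median estimator; SE from a seeded parametric bootstrap
    (theta_j* ~ N(theta_j, sigma_j^2), n_boot re-estimates)."""
    theta, sigma = _ratios(hs)
    if theta.size < 3:
        raise ValueError("weighted median needs at least 3 instruments")
    w = sigma**-2
    est = _weighted_median_point(theta, w)
    rng = np.random.default_rng(seed)
    draws = rng.normal(theta, sigma, size=(n_boot, theta.size))
    boots = np.empty(n_boot)
    for b in range(n_boot):
        boots[b] = _weighted_median_point(draws[b], w)
    se = float(np.std(boots, ddof=1))
    return MRResult.from_normal("weighted_median", est, se, theta.size)


def contamination_mixture(hs: HarmonizedSet, psi: float | None = None,
                          grid_size: int = 10001) -> ConMixResult:
    """Contamination-mixture estimator over a profile-likelihood grid.

    ``psi`` is the scale of invalid (pleiotropic) ratio effects; the default
    is 1.5x the standard deviation of the observed ratio estimates. The 95%
    confidence set collects grid points within chi2_1(0.95)/2 log-likelihood
    units of the maximum and is reported as its envelope plus a
    multimodality flag.
    """
    theta, sigma = _ratios(hs)
    if theta.size < 2:
        raise ValueError("contamination mixture needs at least 2 instruments")
    if psi is None:
        psi = 1.5 * float(np.std(theta, ddof=1))
        if psi <= 0:
            psi = 1.0  # all ratios identical; any positive scale gives consensus
    if psi <= 0:
        raise ValueError("psi must be positive")
    if grid_size < 3:
        raise ValueError("degenerate grid")

    pad = 3.0 * float(np.max(sigma))
    grid = np.linspace(theta.min() - pad, theta.max() + pad, grid_size)

    # log-density of each instrument under the valid model at every t
    valid_ll = (-0.5 * ((theta[None, :] - grid[:, None]) / sigma[None, :]) ** 2
                - np.log(sigma)[None, :])
    s_inv = np.sqrt(sigma**2 + psi**2)
    invalid_ll = (-0.5 * (theta / s_inv) ** 2 - np.log(s_inv))[None, :]
    profile = np.maximum(valid_ll, invalid_ll).sum(axis=1)

    best = int(np.argmax(profile))
    est = float(grid[best])
    cut = profile[best] - stats.chi2.ppf(0.95, 1) / 2.0
    in_region = profile >= cut
    idx = np.flatnonzero(in_region)
    ci_low, ci_high = float(grid[idx[0]]), float(grid[idx[-1]])
    multimodal = bool(np.any(np.diff(idx) > 1))

    ids = hs.data["variant_id"].tolist()
    valid_at_best = valid_ll[best] >= invalid_ll[0]
    valid_set = [ids[j] for j in range(theta.size) if valid_at_best[j]]
    return ConMixResult(estimate=est, ci_low=ci_low, ci_high=ci_high,
                        multimodal=multimodal, valid_set=valid_set,
                        psi=float(psi), n_snps=theta.size)
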