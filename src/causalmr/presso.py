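"""MR-PRESSO: residual-based global pleiotropy test, per-instrument outlier
test, and distortion test with outlier-corrected re-estimation.

The observed statistic is the weighted residual sum of squares
RSS = sum_j w_j (beta_out_j - theta_hat_{-j} * beta_exp_j)^2 with
w_j = se_out_j^-2 and theta_hat_{-j} the leave-one-out IVW slope. Its null
distribution is built by parametric simulation of outcome effects around the
leave-one-out fitted values. The per-instrument test compares each observed
residual contribution with its simulated null and Bonferroni-adjusts across
instruments; the distortion test asks whether removing the flagged outliers
shifts the causal estimate more than removing random subsets of the same
size would.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np

from .estimators import MRResult, ivw
from .summary_io import HarmonizedSet

__all__ = ["PressoConfig", "PressoResult", "presso_global", "presso_outliers",
           "presso_distortion", "mr_presso"]


@dataclass
class PressoConfig:
    n_sim: int = 1000
    outlier_alpha: float = 0.05
    n_distortion: int = 500
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_sim < 100:
            raise ValueError("n_sim must be >= 100")
        if not (0 < self.outlier_alpha < 1):
            raise ValueError("outlier_alpha must be in (0, 1)")


@dataclass
class PressoResult:
    rss_obs: float
    global_p: float
    outlier_pvalues: dict = field(default_factory=dict)  # variant_id -> adjusted p
    outlier_ids: list = field(default_factory=list)
    raw_estimate: MRResult | None = None
    corrected_estimate: MRResult | None = None
    distortion_p: float = float("nan")


def _loo_slopes(bx, by, w):
    """Leave-one-out weighted zero-intercept slopes, vectorized.

    Accepts ``by`` of shape (L,) or (n_sim, L); returns matching shape.
    """
    sxx = np.sum(w * bx * bx)
    sxy = (w * bx * by).sum(axis=-1, keepdims=True)
    return (sxy - w * bx * by) / (sxx - w * bx * bx)


def _residual_contributions(bx, by, w):
    loo = _loo_slopes(bx, by, w)
    return w * (by - loo * bx) ** 2


def _check(hs: HarmonizedSet):
    bx, _, by, sy = hs.arrays()
    if bx.size < 4:
        raise ValueError("MR-PRESSO needs at least 4 instruments")
    return bx, by, sy**-2, sy


def presso_global(hs: HarmonizedSet, cfg: PressoConfig) -> tuple[float, float]:
    """Global heterogeneity test: (rss_obs, global_p) with add-one smoothing,
    so global_p is always in [1/(n_sim+1), 1]."""
    bx, by, w, sy = _check(hs)
    contrib = _residual_contributions(bx, by, w)
    rss_obs = float(contrib.sum())

    rng = np.random.default_rng([cfg.seed, 0x67])
    loo = _loo_slopes(bx, by, w)
    sims = loo * bx + rng.normal(size=(cfg.n_sim, bx.size)) * sy
    rss_sim = _residual_contributions(bx, sims, w).sum(axis=1)
    global_p = (1 + int(np.sum(rss_sim >= rss_obs))) / (cfg.n_sim + 1)
    return rss_obs, float(global_p)


def presso_outliers(hs: HarmonizedSet, cfg: PressoConfig
                    ) -> tuple[dict, list]:
    """Per-instrument outlier test.

    Returns (adjusted p-values by variant, flagged variant ids). The
    simulation count is raised to ceil(L / outlier_alpha) when the
    configured ``n_sim`` is too small for the Bonferroni-adjusted empirical
    p-value floor L/(n_sim+1) to reach ``outlier_alpha``.
    """
    bx, by, w, sy = _check(hs)
    L = bx.size
    n_sim = max(cfg.n_sim, math.ceil(L / cfg.outlier_alpha))
    contrib_obs = _residual_contributions(bx, by, w)

    rng = np.random.default_rng([cfg.seed, 0x6F])
    loo = _loo_slopes(bx, by, w)
    sims = loo * bx + rng.normal(size=(n_sim, L)) * sy
    contrib_sim = _residual_contributions(bx, sims, w)

    exceed = (contrib_sim >= contrib_obs[None, :]).sum(axis=0)
    p_raw = (1 + exceed) / (n_sim + 1)
    p_adj = np.minimum(1.0, p_raw * L)

    ids = hs.data["variant_id"].tolist()
    pvalues = {ids[j]: float(p_adj[j]) for j in range(L)}
    outliers = [ids[j] for j in range(L) if p_adj[j] < cfg.outlier_alpha]
    return pvalues, outliers


def presso_distortion(hs: HarmonizedSet, outlier_ids: list, cfg: PressoConfig
                      ) -> tuple[MRResult, float]:
    """Outlier-corrected IVW and the distortion-test p-value.

    The distortion statistic (raw - corrected)/|corrected| is compared with
    the distribution obtained by deleting random instrument subsets of the
    same size. With no outliers the corrected estimate equals the raw one
    and the p-value is undefined (NaN).
    """
    raw, _ = ivw(hs)
    if not outlier_ids:
        return raw, float("nan")
    keep = [v for v in hs.data["variant_id"] if v not in set(outlier_ids)]
    if len(keep) < 2:
        raise ValueError("all (or nearly all) instruments flagged as outliers")
    corrected, _ = ivw(hs.select(keep))
    d_obs = (raw.estimate - corrected.estimate) / abs(corrected.estimate)

    ids = np.asarray(hs.data["variant_id"])
    rng = np.random.default_rng([cfg.seed, 0xD1])
    k = len(outlier_ids)
    d_sim = np.empty(cfg.n_distortion)
    for b in range(cfg.n_distortion):
        drop = set(rng.choice(ids, size=k, replace=False))
        est_b, _ = ivw(hs.select([v for v in ids if v not in drop]))
        d_sim[b] = (raw.estimate - est_b.estimate) / abs(est_b.estimate)
    p = (1 + int(np.sum(np.abs(d_sim) >= abs(d_obs)))) / (cfg.n_distortion + 1)
    return corrected, float(p)


def mr_presso(hs: HarmonizedSet, cfg: PressoConfig | None = None) -> PressoResult:
    """Run the global, outlier, and distortion tests in sequence."""
    cfg = cfg or PressoConfig()
    rss_obs, global_p = presso_global(hs, cfg)
    pvalues, outlier_ids = presso_outliers(hs, cfg)
    raw, _ = ivw(hs)
    corrected, distortion_p = presso_distortion(hs, outlier_ids, cfg)
    return PressoResult(rss_obs=rss_obs, global_p=global_p,
                        outlier_pvalues=pvalues, outlier_ids=outlier_ids,
                        raw_estimate=raw, corrected_estimate=corrected,
                        distortion_p=distortion_p)
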