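"""Multivariable MR and mediation decomposition.

Multivariable MR regresses outcome effects jointly on several exposures'
effects (no intercept, weights se_out^-2) to estimate each exposure's
*direct* effect holding the others fixed — e.g. the BMI-independent effect
of a metabolic trait. The mediation (difference-method) proportion for a
mediator M on the path exposure -> M -> outcome is

    proportion = (total - direct) / total = 1 - direct / total

on the log-odds scale, with SE by propagation of error (delta method).
By default the covariance between the total and direct estimates is taken
as zero; a ``covariance`` argument lets callers supply one, and a seeded
parametric bootstrap is provided as an independent cross-check of the SE.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .estimators import MRResult, Z975
from .summary_io import AssociationTable, HarmonizationPolicy, HarmonizedSet, harmonize

__all__ = ["MultiHarmonizedSet", "MediationResult", "multi_harmonize",
           "mvmr_ivw", "mediation", "mediation_se_bootstrap", "mediation_study"]


@dataclass
class MultiHarmonizedSet:
    """Instrument effects on m >= 2 exposures plus one outcome, aligned to a
    common effect allele per variant."""

    variant_ids: list
    beta_exp: np.ndarray   # (L, m)
    se_exp: np.ndarray     # (L, m)
    beta_out: np.ndarray   # (L,)
    se_out: np.ndarray     # (L,)
    exposure_labels: list
    outcome_label: str = ""

    def __post_init__(self) -> None:
        self.beta_exp = np.atleast_2d(np.asarray(self.beta_exp, dtype=float))
        self.se_exp = np.atleast_2d(np.asarray(self.se_exp, dtype=float))
        self.beta_out = np.asarray(self.beta_out, dtype=float)
        self.se_out = np.asarray(self.se_out, dtype=float)
        if self.beta_exp.shape[0] == 1 and len(self.beta_out) > 1:
            self.beta_exp = self.beta_exp.T
            self.se_exp = self.se_exp.T
        L, m = self.beta_exp.shape
        # m = 1 is allowed as the degenerate reduction to univariable IVW
        if L <= m:
            raise ValueError(f"need more instruments ({L}) than exposures ({m})")
        if np.any(np.all(self.beta_exp == 0, axis=1)):
            raise ValueError("some instrument has zero effect on every exposure")

    @property
    def n_snps(self) -> int:
        return self.beta_exp.shape[0]

    @property
    def n_exposures(self) -> int:
        return self.beta_exp.shape[1]


def multi_harmonize(exposures: list[AssociationTable], outcome: AssociationTable,
                    policy: HarmonizationPolicy | None = None,
                    outcome_label: str = "") -> MultiHarmonizedSet:
    """Align several exposure tables and one outcome table to the first
    exposure's allele coding, keeping variants retained in every pairwise
    harmonization."""
    if len(exposures) < 2:
        raise ValueError("need at least 2 exposure tables")
    ref = exposures[0]
    pair_sets: list[HarmonizedSet] = [harmonize(ref, t, policy)
                                      for t in exposures[1:] + [outcome]]
    common = set(ref.data["variant_id"])
    for hs in pair_sets:
        common &= set(hs.data["variant_id"])
    if not common:
        raise ValueError("no variant shared by all exposure and outcome tables")
    order = [v for v in ref.data["variant_id"] if v in common]

    ref_idx = ref.data.set_index("variant_id")
    beta_cols = [ref_idx.loc[order, "beta"].to_numpy(float)]
    se_cols = [ref_idx.loc[order, "se"].to_numpy(float)]
    for hs in pair_sets[:-1]:
        d = hs.data.set_index("variant_id").loc[order]
        beta_cols.append(d["beta_out"].to_numpy(float))
        se_cols.append(d["se_out"].to_numpy(float))
    dout = pair_sets[-1].data.set_index("variant_id").loc[order]
    return MultiHarmonizedSet(
        variant_ids=order,
        beta_exp=np.column_stack(beta_cols),
        se_exp=np.column_stack(se_cols),
        beta_out=dout["beta_out"].to_numpy(float),
        se_out=dout["se_out"].to_numpy(float),
        exposure_labels=[t.trait_label for t in exposures],
        outcome_label=outcome_label or outcome.trait_label)


def mvmr_ivw(mset: MultiHarmonizedSet) -> list[MRResult]:
    """Per-exposure direct effects by weighted zero-intercept least squares
    of outcome effects on the exposure-effect matrix (weights se_out^-2),
    with multiplicative overdispersion max(1, sqrt(RSS_w / (L - m)))."""
    X = mset.beta_exp
    y = mset.beta_out
    w = mset.se_out**-2.0
    L, m = X.shape
    if np.linalg.matrix_rank(X) < m:
        raise np.linalg.LinAlgError("exposure-effect matrix is rank deficient")
    XtW = X.T * w
    cov_unscaled = np.linalg.inv(XtW @ X)
    coef = cov_unscaled @ (XtW @ y)
    resid = y - X @ coef
    rss_w = float(np.sum(w * resid**2))
    phi = max(1.0, math.sqrt(rss_w / (L - m)))
    ses = np.sqrt(np.diag(cov_unscaled)) * phi
    return [MRResult.from_normal(f"mvmr_ivw[{lab}]", coef[i], ses[i], L)
            for i, lab in enumerate(mset.exposure_labels)]


@dataclass
class MediationResult:
    total: tuple
    direct: tuple
    proportion: float
    proportion_se: float
    ci_low: float
    ci_high: float


def mediation(total: tuple[float, float], direct: tuple[float, float],
              covariance: float = 0.0) -> MediationResult:
    """Difference-method mediated proportion with delta-method SE.

    ``total`` and ``direct`` are (estimate, se) pairs on the log-odds scale.
    proportion = 1 - direct/total; its variance follows from the delta
    method on the ratio direct/total, using ``covariance`` between the two
    estimates (0 unless supplied).
    """
    t, st = total
    d, sd = direct
    if t == 0:
        raise ZeroDivisionError("mediated proportion undefined for total effect 0")
    prop = 1.0 - d / t
    # delta method on f(d, t) = 1 - d/t: grad = (-1/t, d/t^2)
    var = (sd / t) ** 2 + (d * st / t**2) ** 2 - 2.0 * d * covariance / t**3
    se = math.sqrt(max(var, 0.0))
    return MediationResult(total=(float(t), float(st)), direct=(float(d), float(sd)),
                           proportion=float(prop), proportion_se=float(se),
                           ci_low=float(prop - Z975 * se),
                           ci_high=float(prop + Z975 * se))


def mediation_study(exposure: AssociationTable, mediator: AssociationTable,
                    outcome: AssociationTable,
                    policy: HarmonizationPolicy | None = None,
                    p_threshold: float = 5e-8,
                    covariance: float | None = None) -> MediationResult:
    """End-to-end difference-method mediation from three summary tables.

    Total effect: univariable IVW of outcome on the exposure's
    genome-wide-significant instruments. Direct effect: the exposure
    coefficient from multivariable MR over the union of exposure and
    mediator instruments, adjusting for the mediator.

    Because both fits reuse the same outcome summary statistics, their
    estimates are positively correlated; ``covariance=None`` (the default
    here) plugs in the analytic covariance — both estimators are linear in
    the outcome betas, so cov = sum_j a_j c_j se_out_j^2 over shared
    instruments, rescaled by each fit's overdispersion factor. Pass a
    number to override (0 reproduces the independence approximation).
    """
    from .estimators import ivw
    from .instruments import SelectionConfig, select_instruments

    sel = SelectionConfig(p_threshold=p_threshold)
    exp_instr = select_instruments(exposure, sel)
    med_instr = select_instruments(mediator, sel)
    if len(exp_instr) == 0 or len(med_instr) == 0:
        raise ValueError("no instruments pass selection for exposure or mediator")

    hs = harmonize(exp_instr, outcome, policy)
    total_res, _ = ivw(hs)

    union = sorted(set(exp_instr.data["variant_id"])
                   | set(med_instr.data["variant_id"]))
    exp_sub = exposure.subset(exposure.data["variant_id"].isin(union))
    med_sub = mediator.subset(mediator.data["variant_id"].isin(union))
    mset = multi_harmonize([exp_sub, med_sub], outcome, policy)
    direct_res = mvmr_ivw(mset)[0]

    if covariance is None:
        covariance = _total_direct_covariance(hs, mset, total_res.se,
                                              direct_res.se)
    return mediation((total_res.estimate, total_res.se),
                     (direct_res.estimate, direct_res.se),
                     covariance=covariance)


def _total_direct_covariance(hs: HarmonizedSet, mset: MultiHarmonizedSet,
                             total_se: float, direct_se: float) -> float:
    """Analytic covariance of the total-effect IVW and the MVMR direct
    effect, both linear in the shared outcome betas."""
    bx, _, _, sy = hs.arrays()
    wt = bx / sy**2
    a = pd.Series(wt / np.sum(bx * wt), index=hs.data["variant_id"].tolist())

    X = mset.beta_exp
    w = mset.se_out**-2.0
    XtW = X.T * w
    cinv = np.linalg.inv(XtW @ X)
    c = pd.Series((cinv @ XtW)[0, :], index=mset.variant_ids)
    sy2 = pd.Series(mset.se_out**2, index=mset.variant_ids)

    shared = a.index.intersection(c.index)
    cov = float((a[shared] * c[shared] * sy2[shared]).sum())
    # rescale to match the overdispersion-inflated SEs actually reported
    se_fixed_t = float(np.sum(bx * wt)) ** -0.5
    se_fixed_d = math.sqrt(cinv[0, 0])
    return cov * (total_se / se_fixed_t) * (direct_se / se_fixed_d)


def mediation_se_bootstrap(total: tuple[float, float], direct: tuple[float, float],
                           n_draws: int = 100_000, *, seed: int) -> float:
    """Monte-Carlo cross-check of the delta-method SE: draw (total*, direct*)
    from independent normals and return the SD of 1 - direct*/total*."""
    t, st = total
    d, sd = direct
    if t == 0:
        raise ZeroDivisionError("mediated proportion undefined for total effect 0")
    if st == 0 and sd == 0:
        return 0.0
    rng = np.random.default_rng(seed)
    ts = rng.normal(t, st, n_draws)
    ds = rng.normal(d, sd, n_draws)
    return float(np.std(1.0 - ds / ts, ddof=1))
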