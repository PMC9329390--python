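"""Synthetic two-sample GWAS summary statistics with known ground truth.

The generator emulates the data regime of a well-powered exposure GWAS
(hundreds of thousands of participants) paired with a binary-outcome GWAS
whose effective size is set by its case fraction — the situation in which
two-sample MR of a disease endpoint such as NAFLD actually operates. For
each of ``n_snps`` independent variants it draws a minor-allele frequency,
a true per-allele instrument effect gamma_j, and emits

    beta_exp_j = gamma_j + e_x,   e_x ~ N(0, se_x^2),
    beta_out_j = theta * gamma_j + alpha_j + outlier shift + e_y,

with standard errors following the large-sample approximations
se_x = 1/sqrt(2 f (1-f) n_exp) and, for a binary outcome on the log-odds
scale, se_y = 1/sqrt(2 f (1-f) n_out P(1-P)). The two samples' noise terms
are independent. Pleiotropy regimes for alpha_j: ``none`` (0), ``balanced``
(mean-zero normal), ``directional`` (mean ``pleio_mean``), and
``inside_violating`` (alpha correlated with gamma, breaking the InSIDE
assumption that MR-Egger relies on).

Allele bookkeeping is realistic but never statistically load-bearing: a
small fraction of variants is palindromic (with frequencies clear of the
ambiguity window, so frequency alignment can resolve them), and the outcome
table re-codes a fraction of rows (allele swap and/or strand flip) that
harmonization must undo.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from pathlib import Path

import numpy as np
import pandas as pd
from scipy import stats

from .summary_io import AssociationTable, COMPLEMENT

__all__ = ["SimConfig", "SimTruth", "simulate_two_sample",
           "simulate_replication", "simulate_mediation", "simulate_ld_blocks"]

#: discovery-stage outcome GWAS shape: 8434 cases / 770180 non-cases
DEFAULT_N_OUTCOME = 778_614
DEFAULT_CASE_FRACTION = 8434 / 778_614

_NONPAL_PAIRS = [("A", "G"), ("A", "C"), ("T", "G"), ("T", "C"),
                 ("G", "A"), ("C", "A"), ("G", "T"), ("C", "T")]
_PAL_PAIRS = [("A", "T"), ("T", "A"), ("C", "G"), ("G", "C")]


@dataclass
class SimConfig:
    """Study conditions for one simulated exposure-outcome pair."""

    seed: int
    n_snps: int = 100
    true_effect: float = 0.2
    gamma_dist: tuple = ("uniform", 0.03, 0.10)
    maf_dist: tuple = ("uniform", 0.05, 0.50)
    n_exposure: int = 500_000
    n_outcome: int = DEFAULT_N_OUTCOME
    case_fraction: float | None = DEFAULT_CASE_FRACTION
    pleiotropy_mode: str = "none"
    pleio_sd: float = 0.01
    pleio_mean: float = 0.05
    inside_rho: float = 0.5
    outlier_frac: float = 0.0
    outlier_shift: float = 0.0   # in units of the outcome SE
    palindrome_fraction: float = 0.05
    swap_fraction: float = 0.30  # outcome rows re-coded with swapped alleles
    strand_fraction: float = 0.10

    def __post_init__(self) -> None:
        if self.n_snps < 1:
            raise ValueError("n_snps must be >= 1")
        if self.pleiotropy_mode not in {"none", "balanced", "directional",
                                        "inside_violating"}:
            raise ValueError(f"unknown pleiotropy_mode {self.pleiotropy_mode!r}")
        if not (0 <= self.outlier_frac < 1):
            raise ValueError("outlier_frac must be in [0, 1)")
        if self.pleio_sd < 0:
            raise ValueError("pleio_sd must be >= 0")
        if self.case_fraction is not None and not (0 < self.case_fraction < 1):
            raise ValueError("case_fraction must be in (0, 1)")


@dataclass
class SimTruth:
    """Ground truth paired with the emitted tables."""

    theta: float
    gamma: np.ndarray
    alpha: np.ndarray
    maf: np.ndarray
    variant_ids: list
    outlier_ids: list = field(default_factory=list)
    # mediation scenarios only:
    path_a: float = float("nan")
    path_b: float = float("nan")
    path_c: float = float("nan")
    mediated_proportion: float = float("nan")

    def to_tsv(self, path: str | Path) -> None:
        scalars = {k: getattr(self, k) for k in
                   ("theta", "path_a", "path_b", "path_c", "mediated_proportion")}
        with open(path, "w") as fh:
            for k, v in scalars.items():
                fh.write(f"# {k}={v!r}\n")
            fh.write(f"# outlier_ids={','.join(self.outlier_ids)}\n")
            # default float formatting is the shortest round-trippable repr
            pd.DataFrame({"variant_id": self.variant_ids,
                          "gamma": self.gamma, "alpha": self.alpha,
                          "maf": self.maf}).to_csv(fh, sep="\t", index=False)

    @classmethod
    def from_tsv(cls, path: str | Path) -> "SimTruth":
        scalars: dict = {}
        outliers: list = []
        with open(path) as fh:
            lines = fh.readlines()
        body = []
        for line in lines:
            if line.startswith("# "):
                key, _, val = line[2:].strip().partition("=")
                if key == "outlier_ids":
                    outliers = [v for v in val.split(",") if v]
                else:
                    scalars[key] = float(val)
            else:
                body.append(line)
        from io import StringIO
        df = pd.read_csv(StringIO("".join(body)), sep="\t",
                         float_precision="round_trip")
        return cls(theta=scalars["theta"],
                   gamma=df["gamma"].to_numpy(float),
                   alpha=df["alpha"].to_numpy(float),
                   maf=df["maf"].to_numpy(float),
                   variant_ids=df["variant_id"].astype(str).tolist(),
                   outlier_ids=outliers,
                   path_a=scalars.get("path_a", float("nan")),
                   path_b=scalars.get("path_b", float("nan")),
                   path_c=scalars.get("path_c", float("nan")),
                   mediated_proportion=scalars.get("mediated_proportion",
                                                   float("nan")))


def _draw(rng: np.random.Generator, dist: tuple, size: int) -> np.ndarray:
    kind = dist[0]
    if kind == "uniform":
        return rng.uniform(dist[1], dist[2], size)
    if kind == "normal":
        return rng.normal(dist[1], dist[2], size)
    raise ValueError(f"unknown distribution {dist!r}")


def _standard_errors(maf: np.ndarray, n: int, case_fraction: float | None
                     ) -> np.ndarray:
    eff = float(n) if case_fraction is None else \
        n * case_fraction * (1.0 - case_fraction)
    return 1.0 / np.sqrt(2.0 * maf * (1.0 - maf) * eff)


def _pvalues(beta: np.ndarray, se: np.ndarray) -> np.ndarray:
    return np.clip(2 * stats.norm.sf(np.abs(beta / se)),
                   np.finfo(float).tiny, 1.0)


def _alleles(rng: np.random.Generator, n: int, pal_frac: float):
    pal = rng.random(n) < pal_frac
    ea = np.empty(n, dtype=object)
    oa = np.empty(n, dtype=object)
    for i in range(n):
        pairs = _PAL_PAIRS if pal[i] else _NONPAL_PAIRS
        ea[i], oa[i] = pairs[rng.integers(len(pairs))]
    return ea, oa, pal


def _table(ids, ea, oa, eaf, beta, se, n, label) -> AssociationTable:
    return AssociationTable(pd.DataFrame({
        "variant_id": ids, "effect_allele": ea, "other_allele": oa,
        "eaf": eaf, "beta": beta, "se": se,
        "pvalue": _pvalues(beta, se), "n": n}), trait_label=label)


def _recode_outcome(df: pd.DataFrame, rng: np.random.Generator,
                    swap_frac: float, strand_frac: float) -> pd.DataFrame:
    """Re-express a fraction of outcome rows with swapped and/or
    strand-complemented alleles (palindromes keep their strand)."""
    df = df.copy()
    swap = rng.random(len(df)) < swap_frac
    strand = rng.random(len(df)) < strand_frac
    for i in range(len(df)):
        ea, oa = df.at[i, "effect_allele"], df.at[i, "other_allele"]
        if swap[i]:
            ea, oa = oa, ea
            df.at[i, "beta"] = -df.at[i, "beta"]
            df.at[i, "eaf"] = 1.0 - df.at[i, "eaf"]
        if strand[i] and COMPLEMENT[ea] != oa:
            ea, oa = COMPLEMENT[ea], COMPLEMENT[oa]
        df.at[i, "effect_allele"], df.at[i, "other_allele"] = ea, oa
    return df


def _pleiotropy(rng: np.random.Generator, cfg: SimConfig, gamma: np.ndarray
                ) -> np.ndarray:
    L = gamma.size
    if cfg.pleiotropy_mode == "none":
        return np.zeros(L)
    if cfg.pleiotropy_mode == "balanced":
        return rng.normal(0.0, cfg.pleio_sd, L)
    if cfg.pleiotropy_mode == "directional":
        return rng.normal(cfg.pleio_mean, cfg.pleio_sd, L)
    # inside_violating: alpha correlated with instrument strength
    g_std = (gamma - gamma.mean()) / (gamma.std() or 1.0)
    rho = cfg.inside_rho
    return cfg.pleio_sd * (rho * g_std
                           + math.sqrt(max(0.0, 1 - rho**2)) * rng.standard_normal(L))


def simulate_two_sample(cfg: SimConfig
                        ) -> tuple[AssociationTable, AssociationTable, SimTruth]:
    """Draw one (exposure, outcome) summary-statistic pair plus its truth."""
    rng = np.random.default_rng(cfg.seed)
    L = cfg.n_snps
    ids = [f"rs{i + 1:06d}" for i in range(L)]

    maf = _draw(rng, cfg.maf_dist, L)
    ea, oa, pal = _alleles(rng, L, cfg.palindrome_fraction)
    # keep palindromes resolvable: frequency clear of the ambiguity window
    maf[pal] = np.minimum(maf[pal], 0.40)

    gamma = _draw(rng, cfg.gamma_dist, L)
    se_x = _standard_errors(maf, cfg.n_exposure, None)
    se_y = _standard_errors(maf, cfg.n_outcome, cfg.case_fraction)

    alpha = _pleiotropy(rng, cfg, gamma)
    shift = np.zeros(L)
    n_out = int(round(cfg.outlier_frac * L))
    outlier_idx = np.sort(rng.choice(L, size=n_out, replace=False)) if n_out else []
    shift[outlier_idx] = cfg.outlier_shift * se_y[outlier_idx]

    beta_x = gamma + rng.normal(0.0, 1.0, L) * se_x
    beta_y = cfg.true_effect * gamma + alpha + shift + rng.normal(0.0, 1.0, L) * se_y

    exposure = _table(ids, ea, oa, maf, beta_x, se_x, cfg.n_exposure, "exposure")
    out_df = _table(ids, ea, oa, maf, beta_y, se_y, cfg.n_outcome, "outcome").data
    out_df = _recode_outcome(out_df, rng, cfg.swap_fraction, cfg.strand_fraction)
    outcome = AssociationTable(out_df, trait_label="outcome")

    truth = SimTruth(theta=cfg.true_effect, gamma=gamma, alpha=alpha, maf=maf,
                     variant_ids=ids,
                     outlier_ids=[ids[i] for i in outlier_idx])
    return exposure, outcome, truth


def simulate_replication(exposure: AssociationTable, truth: SimTruth,
                         n_outcome: int, case_fraction: float | None,
                         seed: int, swap_fraction: float = 0.30,
                         strand_fraction: float = 0.10) -> AssociationTable:
    """An independent outcome cohort remeasuring the same variants.

    The variants keep their alleles and frequencies (they are population
    properties, as are the true effects gamma, theta and the pleiotropic
    alpha); only the sampling noise, the cohort size and the allele coding
    of the emitted table are new.
    """
    rng = np.random.default_rng(seed)
    order = {v: i for i, v in enumerate(truth.variant_ids)}
    idx = [order[v] for v in exposure.data["variant_id"]]
    maf = truth.maf[idx]
    se_y = _standard_errors(maf, n_outcome, case_fraction)
    beta_y = (truth.theta * truth.gamma[idx] + truth.alpha[idx]
              + rng.normal(0.0, 1.0, len(idx)) * se_y)
    df = _table(list(exposure.data["variant_id"]),
                exposure.data["effect_allele"].to_numpy(),
                exposure.data["other_allele"].to_numpy(),
                maf, beta_y, se_y, n_outcome, "outcome_replication").data
    df = _recode_outcome(df, rng, swap_fraction, strand_fraction)
    return AssociationTable(df, trait_label="outcome_replication")


def simulate_mediation(cfg: SimConfig, path_a: float, path_b: float, path_c: float,
                       n_snps_mediator: int | None = None,
                       ) -> tuple[AssociationTable, AssociationTable,
                                  AssociationTable, SimTruth]:
    """Exposure -> mediator -> outcome design with known mediated share.

    The exposure has ``cfg.n_snps`` own instruments (effects gamma), the
    mediator ``n_snps_mediator`` own instruments (effects delta). True
    effects: exposure on mediator ``path_a``, mediator on outcome
    ``path_b``, direct exposure on outcome ``path_c``; total effect
    c + a*b and mediated proportion a*b / (c + a*b).
    """
    total = path_c + path_a * path_b
    if total == 0:
        raise ValueError("total effect c + a*b must be nonzero")
    rng = np.random.default_rng(cfg.seed)
    Lx = cfg.n_snps
    Lm = n_snps_mediator if n_snps_mediator is not None else cfg.n_snps
    L = Lx + Lm
    ids = [f"rs{i + 1:06d}" for i in range(L)]

    maf = _draw(rng, cfg.maf_dist, L)
    ea, oa, pal = _alleles(rng, L, cfg.palindrome_fraction)
    maf[pal] = np.minimum(maf[pal], 0.40)

    gamma = np.zeros(L)
    delta = np.zeros(L)
    gamma[:Lx] = _draw(rng, cfg.gamma_dist, Lx)
    delta[Lx:] = _draw(rng, cfg.gamma_dist, Lm)

    se_g = _standard_errors(maf, cfg.n_exposure, None)
    se_y = _standard_errors(maf, cfg.n_outcome, cfg.case_fraction)

    bx = gamma + rng.normal(0.0, 1.0, L) * se_g
    bm = path_a * gamma + delta + rng.normal(0.0, 1.0, L) * se_g
    by = ((path_c + path_a * path_b) * gamma + path_b * delta
          + rng.normal(0.0, 1.0, L) * se_y)

    exposure = _table(ids, ea, oa, maf, bx, se_g, cfg.n_exposure, "exposure")
    mediator = _table(ids, ea, oa, maf, bm, se_g, cfg.n_exposure, "mediator")
    out_df = _recode_outcome(
        _table(ids, ea, oa, maf, by, se_y, cfg.n_outcome, "outcome").data,
        rng, cfg.swap_fraction, cfg.strand_fraction)
    outcome = AssociationTable(out_df, trait_label="outcome")

    truth = SimTruth(theta=total, gamma=gamma, alpha=path_b * delta, maf=maf,
                     variant_ids=ids, path_a=path_a, path_b=path_b, path_c=path_c,
                     mediated_proportion=path_a * path_b / total)
    return exposure, mediator, outcome, truth


def simulate_ld_blocks(n_blocks: int, block_size: int, within_r2: float,
                       cfg: SimConfig):
    """Exposure associations in LD blocks plus the matching r^2 table.

    Variants within a block share pairwise ``within_r2``; cross-block r^2
    is 0. Non-lead members inherit the lead's effect scaled by
    sqrt(within_r2), mimicking tagging of a single causal signal.
    """
    from .instruments import LDTable

    if n_blocks < 0 or block_size < 1:
        raise ValueError("invalid block sizes")
    if not (0 <= within_r2 <= 1):
        raise ValueError("within_r2 must be in [0, 1]")
    empty_cfg = replace(cfg, n_snps=1)
    if n_blocks == 0:
        cols = ["variant_id", "effect_allele", "other_allele", "eaf", "beta",
                "se", "pvalue", "n"]
        return (AssociationTable(pd.DataFrame(columns=cols), "exposure"), LDTable())

    rng = np.random.default_rng(cfg.seed)
    L = n_blocks * block_size
    ids = [f"rs{b + 1:03d}_{k}" for b in range(n_blocks) for k in range(block_size)]
    maf = _draw(rng, cfg.maf_dist, L)
    ea, oa, pal = _alleles(rng, L, cfg.palindrome_fraction)
    maf[pal] = np.minimum(maf[pal], 0.40)
    se_x = _standard_errors(maf, cfg.n_exposure, None)

    lead_gamma = _draw(rng, cfg.gamma_dist, n_blocks)
    gamma = np.repeat(lead_gamma, block_size)
    tag = np.tile(np.concatenate([[1.0], np.full(block_size - 1,
                                                 math.sqrt(within_r2))]), n_blocks)
    beta = gamma * tag + rng.normal(0.0, 1.0, L) * se_x

    table = _table(ids, ea, oa, maf, beta, se_x, cfg.n_exposure, "exposure")
    ld = LDTable()
    for b in range(n_blocks):
        members = ids[b * block_size:(b + 1) * block_size]
        for i in range(len(members)):
            for j in range(i + 1, len(members)):
                ld.set(members[i], members[j], within_r2)
    return table, ld
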