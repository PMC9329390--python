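"""GWAS summary-statistic tables and allele harmonization.

Two-sample Mendelian randomization works from per-variant association
summaries (beta, SE, allele frequency, p-value) published by independent
exposure and outcome GWAS. Before any causal estimation the two tables must
be *harmonized*: effects re-expressed for a shared effect allele, with
strand flips reconciled by base complement and palindromic variants (A/T,
C/G pairs, whose strand cannot be read off the allele labels) either
resolved by allele-frequency agreement or dropped when the minor-allele
frequency is too close to 0.5 to disambiguate.

Instruments absent from the outcome study are dropped, never replaced by
LD proxies. Every dropped variant is kept in an audit list with a reason,
so that |intersection| = |retained| + |dropped| always holds.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping

import numpy as np
import pandas as pd

__all__ = [
    "AssociationTable",
    "HarmonizationPolicy",
    "HarmonizedSet",
    "read_association_table",
    "is_palindromic",
    "harmonize",
]

VALID_ALLELES = frozenset("ACGT")
COMPLEMENT = {"A": "T", "T": "A", "C": "G", "G": "C"}

#: canonical column roles of an association table, in output order
STANDARD_COLUMNS = [
    "variant_id",
    "effect_allele",
    "other_allele",
    "eaf",
    "beta",
    "se",
    "pvalue",
    "n",
]

_REQUIRED = ["variant_id", "effect_allele", "other_allele", "beta", "se", "pvalue"]


@dataclass
class AssociationTable:
    """Per-variant summary statistics for one trait from one GWAS.

    ``data`` holds one row per variant with columns ``variant_id``,
    ``effect_allele``, ``other_allele``, ``eaf`` (effect-allele frequency,
    may be NaN), ``beta``, ``se``, ``pvalue`` and ``n`` (may be NaN).
    Alleles are upper-cased single bases; ``se`` must be positive and
    ``variant_id`` unique.
    """

    data: pd.DataFrame
    trait_label: str = ""

    def __post_init__(self) -> None:
        self.data = _validate_frame(self.data)

    def __len__(self) -> int:
        return len(self.data)

    def subset(self, mask) -> "AssociationTable":
        return AssociationTable(self.data.loc[mask].reset_index(drop=True),
                                trait_label=self.trait_label)

    def to_tsv(self, path: str | Path) -> None:
        self.data.to_csv(path, sep="\t", index=False, float_format="%.10g")


def _validate_frame(df: pd.DataFrame) -> pd.DataFrame:
    missing = [c for c in _REQUIRED if c not in df.columns]
    if missing:
        raise ValueError(f"association table missing required columns: {missing}")
    df = df.copy()
    for col in ("eaf", "n"):
        if col not in df.columns:
            df[col] = np.nan
    df = df[STANDARD_COLUMNS].reset_index(drop=True)

    df["variant_id"] = df["variant_id"].astype(str)
    for col in ("effect_allele", "other_allele"):
        df[col] = df[col].astype(str).str.upper().str.strip()
    for col in ("eaf", "beta", "se", "pvalue", "n"):
        try:
            df[col] = pd.to_numeric(df[col])
        except (ValueError, TypeError) as exc:
            raise ValueError(f"non-numeric values in column '{col}': {exc}") from None

    problems: list[str] = []
    for i, row in df.iterrows():
        if row.effect_allele not in VALID_ALLELES or row.other_allele not in VALID_ALLELES:
            problems.append(f"row {i}: invalid allele "
                            f"{row.effect_allele}/{row.other_allele}")
        elif row.effect_allele == row.other_allele:
            problems.append(f"row {i}: effect and other allele identical")
        if not (row.se > 0):
            problems.append(f"row {i}: se must be > 0 (got {row.se})")
        if not (0 < row.pvalue <= 1):
            problems.append(f"row {i}: pvalue must be in (0, 1] (got {row.pvalue})")
        if not math.isnan(row.eaf) and not (0 <= row.eaf <= 1):
            problems.append(f"row {i}: eaf outside [0, 1] (got {row.eaf})")
        if math.isnan(row.beta):
            problems.append(f"row {i}: beta is missing")
    dup = df["variant_id"][df["variant_id"].duplicated()]
    if len(dup):
        problems.append(f"duplicate variant_id: {sorted(set(dup))}")
    if problems:
        raise ValueError("invalid association table:\n  " + "\n  ".join(problems))
    return df


def read_association_table(
    path: str | Path,
    column_map: Mapping[str, str] | None = None,
    trait_label: str = "",
    sep: str = "\t",
) -> AssociationTable:
    """Read a delimited summary-statistics file into an :class:`AssociationTable`.

    ``column_map`` maps standard roles (``variant_id``, ``beta``, ...) to the
    file's column names; roles absent from the map are taken verbatim.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    raw = pd.read_csv(path, sep=sep)
    column_map = dict(column_map or {})
    rename = {}
    for role in STANDARD_COLUMNS:
        src = column_map.get(role, role)
        if src in raw.columns:
            rename[src] = role
        elif role in _REQUIRED:
            raise ValueError(f"column '{src}' (role '{role}') not found in {path}")
    table = raw.rename(columns=rename)
    return AssociationTable(table[[c for c in STANDARD_COLUMNS if c in table.columns]],
                            trait_label=trait_label or path.stem)


def is_palindromic(effect_allele: str, other_allele: str) -> bool:
    """True iff the allele pair is strand-ambiguous ({A,T} or {C,G})."""
    ea = effect_allele.upper()
    oa = other_allele.upper()
    if ea not in VALID_ALLELES or oa not in VALID_ALLELES:
        raise ValueError(f"invalid allele symbol: {effect_allele}/{other_allele}")
    if ea == oa:
        raise ValueError("effect and other allele must differ")
    return COMPLEMENT[ea] == oa


@dataclass
class HarmonizationPolicy:
    """How to treat palindromic variants during harmonization.

    ``drop_ambiguous`` (default, the study's main analysis) drops palindromes
    whose exposure effect-allele frequency lies strictly inside
    (``maf_low``, ``maf_high``) and aligns the rest by frequency agreement;
    ``drop_all`` drops every palindrome (the sensitivity analysis);
    ``align_by_frequency`` keeps all, aligned by frequency side.
    """

    maf_low: float = 0.45
    maf_high: float = 0.55
    palindrome_mode: str = "drop_ambiguous"

    def __post_init__(self) -> None:
        if not (0 <= self.maf_low < self.maf_high <= 1):
            raise ValueError("require 0 <= maf_low < maf_high <= 1")
        if self.palindrome_mode not in {"drop_ambiguous", "drop_all", "align_by_frequency"}:
            raise ValueError(f"unknown palindrome_mode {self.palindrome_mode!r}")


_HARMONIZED_COLUMNS = [
    "variant_id", "effect_allele", "other_allele",
    "beta_exp", "se_exp", "eaf_exp",
    "beta_out", "se_out", "eaf_out",
    "palindromic", "strand_flipped",
]


@dataclass
class HarmonizedSet:
    """Exposure and outcome effects aligned to a shared effect allele.

    ``data`` has one row per retained instrument (exposure allele coding);
    ``dropped`` is the audit list with a ``reason`` per excluded variant.
    """

    data: pd.DataFrame
    dropped: pd.DataFrame = field(
        default_factory=lambda: pd.DataFrame(columns=["variant_id", "reason"]))
    exposure_label: str = ""
    outcome_label: str = ""

    def __post_init__(self) -> None:
        self.data = self.data.reset_index(drop=True)
        self.dropped = self.dropped.reset_index(drop=True)
        if len(self.data):
            if not (self.data["se_exp"] > 0).all() or not (self.data["se_out"] > 0).all():
                raise ValueError("harmonized rows must have positive standard errors")

    @classmethod
    def from_arrays(cls, beta_exp, se_exp, beta_out, se_out,
                    variant_ids=None, eaf=None,
                    exposure_label: str = "", outcome_label: str = "") -> "HarmonizedSet":
        """Build directly from effect arrays (synthetic / already-aligned data)."""
        beta_exp = np.asarray(beta_exp, dtype=float)
        L = beta_exp.size
        if variant_ids is None:
            variant_ids = [f"v{i}" for i in range(L)]
        eaf = np.full(L, np.nan) if eaf is None else np.asarray(eaf, dtype=float)
        df = pd.DataFrame({
            "variant_id": list(variant_ids),
            "effect_allele": "A", "other_allele": "G",
            "beta_exp": beta_exp, "se_exp": np.asarray(se_exp, dtype=float),
            "eaf_exp": eaf,
            "beta_out": np.asarray(beta_out, dtype=float),
            "se_out": np.asarray(se_out, dtype=float),
            "eaf_out": eaf,
            "palindromic": False, "strand_flipped": False,
        })
        return cls(df, exposure_label=exposure_label, outcome_label=outcome_label)

    @property
    def n_snps(self) -> int:
        return len(self.data)

    def select(self, variant_ids) -> "HarmonizedSet":
        keep = self.data["variant_id"].isin(set(variant_ids))
        return HarmonizedSet(self.data.loc[keep], self.dropped.copy(),
                             self.exposure_label, self.outcome_label)

    def arrays(self):
        d = self.data
        return (d["beta_exp"].to_numpy(float), d["se_exp"].to_numpy(float),
                d["beta_out"].to_numpy(float), d["se_out"].to_numpy(float))

    def as_tables(self) -> tuple[AssociationTable, AssociationTable]:
        """Re-export aligned exposure/outcome tables (both in exposure coding)."""
        d = self.data
        base = {"variant_id": d["variant_id"], "effect_allele": d["effect_allele"],
                "other_allele": d["other_allele"]}
        exp = pd.DataFrame({**base, "eaf": d["eaf_exp"], "beta": d["beta_exp"],
                            "se": d["se_exp"]})
        out = pd.DataFrame({**base, "eaf": d["eaf_out"], "beta": d["beta_out"],
                            "se": d["se_out"]})
        for frame, which in ((exp, "exp"), (out, "out")):
            z = np.abs(frame["beta"] / frame["se"])
            from scipy.stats import norm
            frame["pvalue"] = np.clip(2 * norm.sf(z), np.finfo(float).tiny, 1.0)
        return (AssociationTable(exp, trait_label=self.exposure_label),
                AssociationTable(out, trait_label=self.outcome_label))

    def write_audit(self, path: str | Path) -> None:
        self.dropped.to_csv(path, sep="\t", index=False)

    def to_tsv(self, path: str | Path) -> None:
        self.data.to_csv(path, sep="\t", index=False, float_format="%.10g")


def harmonize(
    exposure: AssociationTable,
    outcome: AssociationTable,
    policy: HarmonizationPolicy | None = None,
) -> HarmonizedSet:
    """Align outcome effects to the exposure's effect allele.

    Shared variants are intersected on ``variant_id`` (no proxy lookup).
    Outcome rows whose coding is swapped get their beta negated and eaf
    complemented; alleles reported on the opposite strand are rescued by
    base complement; palindromic variants are handled per ``policy``.
    """
    policy = policy or HarmonizationPolicy()
    merged = exposure.data.merge(outcome.data, on="variant_id",
                                 suffixes=("_exp", "_out"), how="inner")
    if merged.empty:
        raise ValueError("exposure and outcome tables share no variants")

    kept_rows: list[dict] = []
    dropped: list[dict] = []
    for _, r in merged.iterrows():
        ea_e, oa_e = r["effect_allele_exp"], r["other_allele_exp"]
        ea_o, oa_o = r["effect_allele_out"], r["other_allele_out"]
        beta_out, eaf_out = r["beta_out"], r["eaf_out"]
        pal = is_palindromic(ea_e, oa_e)
        flipped = strand = False

        if pal:
            if {ea_o, oa_o} != {ea_e, oa_e}:
                dropped.append({"variant_id": r["variant_id"],
                                "reason": "irreconcilable alleles"})
                continue
            if policy.palindrome_mode == "drop_all":
                dropped.append({"variant_id": r["variant_id"],
                                "reason": "palindromic (drop_all policy)"})
                continue
            eaf_e = r["eaf_exp"]
            if math.isnan(eaf_e) or math.isnan(eaf_out):
                if policy.palindrome_mode == "align_by_frequency":
                    raise ValueError(
                        f"variant {r['variant_id']}: frequency alignment requested "
                        "but eaf missing")
                dropped.append({"variant_id": r["variant_id"],
                                "reason": "palindromic with missing eaf"})
                continue
            if policy.palindrome_mode == "drop_ambiguous" and \
                    policy.maf_low < eaf_e < policy.maf_high:
                dropped.append({"variant_id": r["variant_id"],
                                "reason": "ambiguous palindrome"})
                continue
            if eaf_e == 0.5 or eaf_out == 0.5:
                dropped.append({"variant_id": r["variant_id"],
                                "reason": "palindrome frequency uninformative"})
                continue
            # orientation chosen purely by minor-allele side agreement:
            # allele labels carry no strand information for a palindrome
            if (eaf_e < 0.5) != (eaf_out < 0.5):
                beta_out = -beta_out
                eaf_out = 1.0 - eaf_out
                flipped = True
        else:
            pair = (ea_e, oa_e)
            comp = (COMPLEMENT[ea_o], COMPLEMENT[oa_o])
            if (ea_o, oa_o) == pair:
                pass
            elif (oa_o, ea_o) == pair:
                flipped = True
            elif comp == pair:
                strand = True
            elif (comp[1], comp[0]) == pair:
                flipped = strand = True
            else:
                dropped.append({"variant_id": r["variant_id"],
                                "reason": "irreconcilable alleles"})
                continue
            if flipped:
                beta_out = -beta_out
                if not math.isnan(eaf_out):
                    eaf_out = 1.0 - eaf_out

        kept_rows.append({
            "variant_id": r["variant_id"],
            "effect_allele": ea_e, "other_allele": oa_e,
            "beta_exp": r["beta_exp"], "se_exp": r["se_exp"], "eaf_exp": r["eaf_exp"],
            "beta_out": beta_out, "se_out": r["se_out"], "eaf_out": eaf_out,
            "palindromic": pal, "strand_flipped": strand,
        })

    data = pd.DataFrame(kept_rows, columns=_HARMONIZED_COLUMNS)
    audit = pd.DataFrame(dropped, columns=["variant_id", "reason"])
    return HarmonizedSet(data, audit,
                         exposure_label=exposure.trait_label,
                         outcome_label=outcome.trait_label)
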