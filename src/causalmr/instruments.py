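"""Genetic instrument selection, LD clumping, and instrument strength.

Instruments are variants associated with the exposure at genome-wide
significance (p <= 5e-8) and mutually independent after greedy LD clumping
(pairwise r^2 below 0.01, keeping the smallest association p-value per
cluster). Strength is summarised by the variance explained
sum_j 2 f_j (1 - f_j) beta_j^2 and the F statistic
F = R^2 (n - k - 1) / ((1 - R^2) k); F <= 10 flags a weak instrument set.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd

from .summary_io import AssociationTable

__all__ = [
    "SelectionConfig",
    "LDTable",
    "StrengthReport",
    "select_instruments",
    "greedy_clump",
    "variance_explained",
    "f_statistic",
]


@dataclass
class SelectionConfig:
    p_threshold: float = 5e-8
    r2_threshold: float = 0.01

    def __post_init__(self) -> None:
        if not (0 < self.p_threshold < 1):
            raise ValueError("p_threshold must be in (0, 1)")
        if not (0 <= self.r2_threshold <= 1):
            raise ValueError("r2_threshold must be in [0, 1]")


class LDTable:
    """Symmetric pairwise r^2 lookup; absent pairs mean r^2 = 0."""

    def __init__(self, pairs: dict[frozenset, float] | None = None):
        self._r2: dict[frozenset, float] = {}
        for key, val in (pairs or {}).items():
            a, b = tuple(key)
            self.set(a, b, val)

    def set(self, a: str, b: str, r2: float) -> None:
        if a == b:
            return
        if not (0 <= r2 <= 1):
            raise ValueError(f"r2 outside [0, 1] for pair ({a}, {b}): {r2}")
        self._r2[frozenset((a, b))] = float(r2)

    def r2(self, a: str, b: str) -> float:
        if a == b:
            return 1.0
        return self._r2.get(frozenset((a, b)), 0.0)

    def __len__(self) -> int:
        return len(self._r2)

    @classmethod
    def from_tsv(cls, path: str | Path) -> "LDTable":
        df = pd.read_csv(path, sep="\t")
        if df.shape[1] < 3:
            raise ValueError("LD table needs 3 columns: id1, id2, r2")
        table = cls()
        c1, c2, c3 = df.columns[:3]
        for _, row in df.iterrows():
            table.set(str(row[c1]), str(row[c2]), float(row[c3]))
        return table

    def to_tsv(self, path: str | Path) -> None:
        rows = [{"id1": a, "id2": b, "r2": v}
                for key, v in self._r2.items() for a, b in [sorted(key)]]
        pd.DataFrame(rows, columns=["id1", "id2", "r2"]).sort_values(
            ["id1", "id2"]).to_csv(path, sep="\t", index=False)


@dataclass
class StrengthReport:
    r2_total: float
    f_stat: float
    n: int
    k: int
    weak_flag: bool


def select_instruments(table: AssociationTable, cfg: SelectionConfig | None = None
                       ) -> AssociationTable:
    """Keep rows reaching the significance threshold (inclusive), order kept."""
    cfg = cfg or SelectionConfig()
    return table.subset(table.data["pvalue"] <= cfg.p_threshold)


def greedy_clump(table: AssociationTable, ld: LDTable | None,
                 cfg: SelectionConfig | None = None) -> AssociationTable:
    """Greedy LD clumping: repeatedly keep the most significant remaining
    variant and discard everything correlated with it at r^2 >= threshold.

    Ties on p-value break by lexicographic variant_id for determinism.
    """
    cfg = cfg or SelectionConfig()
    if ld is None or len(table) == 0:
        return table.subset(np.ones(len(table), dtype=bool))
    df = table.data
    remaining = sorted(range(len(df)),
                       key=lambda i: (df["pvalue"].iat[i], df["variant_id"].iat[i]))
    ids = df["variant_id"].tolist()
    kept: set[int] = set()
    remaining = list(remaining)
    while remaining:
        lead = remaining.pop(0)
        kept.add(lead)
        remaining = [i for i in remaining
                     if ld.r2(ids[lead], ids[i]) < cfg.r2_threshold]
    mask = np.zeros(len(df), dtype=bool)
    mask[list(kept)] = True
    return table.subset(mask)  # original row order preserved


def variance_explained(instruments: AssociationTable) -> float:
    """Variance in the (standardized) exposure explained by the instrument set,
    sum_j 2 f_j (1 - f_j) beta_j^2, clamped to [0, 1]."""
    df = instruments.data
    if df["eaf"].isna().any():
        bad = df.index[df["eaf"].isna()].tolist()
        raise ValueError(f"eaf missing for rows {bad}; cannot compute variance explained")
    f = df["eaf"].to_numpy(float)
    b = df["beta"].to_numpy(float)
    return float(np.clip(np.sum(2.0 * f * (1.0 - f) * b * b), 0.0, 1.0))


def f_statistic(r2_total: float, n: int, k: int) -> StrengthReport:
    """Multi-instrument F statistic F = R^2 (n - k - 1) / ((1 - R^2) k)."""
    if not (0 <= r2_total < 1):
        raise ValueError("r2_total must be in [0, 1)")
    if k < 1:
        raise ValueError("need at least one instrument")
    if n <= k + 1:
        raise ValueError(f"sample size n={n} must exceed k+1={k + 1}")
    f = r2_total * (n - k - 1) / ((1.0 - r2_total) * k)
    return StrengthReport(r2_total=float(r2_total), f_stat=float(f),
                          n=int(n), k=int(k), weak_flag=bool(f <= 10))
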