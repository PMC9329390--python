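import numpy as np
import pandas as pd
import pytest

from causalmr import AssociationTable, HarmonizedSet


def make_table(rows, label="trait"):
    """Build an AssociationTable from a list of row dicts, filling defaults."""
    defaults = {"eaf": 0.3, "beta": 0.05, "se": 0.01, "pvalue": 1e-10, "n": 10000}
    full = []
    for i, r in enumerate(rows):
        row = {"variant_id": f"rs{i + 1}", "effect_allele": "A",
               "other_allele": "G", **defaults, **r}
        full.append(row)
    return AssociationTable(pd.DataFrame(full), trait_label=label)


@pytest.fixture
def three_row_table():
    return make_table([
        {"variant_id": "rs1", "beta": 0.10, "se": 0.01, "pvalue": 1e-20},
        {"variant_id": "rs2", "beta": 0.05, "se": 0.01, "pvalue": 1e-12},
        {"variant_id": "rs3", "beta": 0.08, "se": 0.02, "pvalue": 1e-9},
    ])


@pytest.fixture
def two_ratio_set():
    """Two instruments with Wald ratios (0.5, 0.3) and ratio SEs (0.1, 0.2)."""
    return HarmonizedSet.from_arrays(
        beta_exp=[1.0, 1.0], se_exp=[0.01, 0.01],
        beta_out=[0.5, 0.3], se_out=[0.1, 0.2])
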