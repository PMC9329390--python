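import numpy as np
import pandas as pd
import pytest

from causalmr import (AssociationTable, HarmonizationPolicy, harmonize,
                      is_palindromic, read_association_table)
from conftest import make_table


class TestAssociationTable:
    def test_roundtrip_read(self, three_row_table, tmp_path):
        path = tmp_path / "t.tsv"
        three_row_table.to_tsv(path)
        back = read_association_table(path)
        assert len(back) == 3
        pd.testing.assert_frame_equal(back.data, three_row_table.data)

    def test_column_map(self, three_row_table, tmp_path):
        df = three_row_table.data.rename(columns={"variant_id": "SNP", "beta": "b"})
        path = tmp_path / "t.tsv"
        df.to_csv(path, sep="\t", index=False)
        back = read_association_table(path, column_map={"variant_id": "SNP",
                                                        "beta": "b"})
        assert list(back.data["variant_id"]) == ["rs1", "rs2", "rs3"]

    def test_zero_se_names_row(self):
        with pytest.raises(ValueError, match="row 1"):
            make_table([{"se": 0.01}, {"se": 0.0}])

    def test_lowercase_alleles_normalized(self):
        t = make_table([{"effect_allele": "a", "other_allele": "g"}])
        assert t.data.loc[0, "effect_allele"] == "A"
        assert t.data.loc[0, "other_allele"] == "G"

    @pytest.mark.parametrize("bad,match", [
        ({"effect_allele": "A", "other_allele": "A"}, "identical"),
        ({"effect_allele": "N"}, "invalid allele"),
        ({"eaf": 1.5}, "eaf"),
        ({"pvalue": 0.0}, "pvalue"),
    ])
    def test_invariant_violations(self, bad, match):
        with pytest.raises(ValueError, match=match):
            make_table([bad])

    def test_duplicate_variant_id(self):
        with pytest.raises(ValueError, match="duplicate"):
            make_table([{"variant_id": "rs1"}, {"variant_id": "rs1"}])

    def test_missing_file(self, tmp_path):
        with pytest.raises(FileNotFoundError):
            read_association_table(tmp_path / "absent.tsv")


@pytest.mark.parametrize("ea,oa,expected", [
    ("A", "T", True), ("T", "A", True), ("C", "G", True), ("G", "C", True),
    ("A", "G", False), ("A", "C", False), ("G", "T", False),
])
def test_is_palindromic(ea, oa, expected):
    assert is_palindromic(ea, oa) is expected


def test_is_palindromic_rejects_bad_symbols():
    with pytest.raises(ValueError):
        is_palindromic("A", "N")
    with pytest.raises(ValueError):
        is_palindromic("A", "A")


class TestHarmonize:
    def test_swapped_coding_flips_beta(self):
        exp = make_table([{"effect_allele": "A", "other_allele": "G",
                           "beta": 0.10, "eaf": 0.3}])
        out = make_table([{"effect_allele": "G", "other_allele": "A",
                           "beta": -0.05, "eaf": 0.7}])
        hs = harmonize(exp, out)
        assert hs.n_snps == 1
        assert hs.data.loc[0, "beta_out"] == pytest.approx(0.05)
        assert hs.data.loc[0, "eaf_out"] == pytest.approx(0.3)

    def test_strand_flip_rescued(self):
        exp = make_table([{"effect_allele": "A", "other_allele": "G",
                           "beta": 0.10}])
        out = make_table([{"effect_allele": "T", "other_allele": "C",
                           "beta": 0.04}])
        hs = harmonize(exp, out)
        assert hs.n_snps == 1
        assert hs.data.loc[0, "beta_out"] == pytest.approx(0.04)
        assert bool(hs.data.loc[0, "strand_flipped"])

    def test_irreconcilable_dropped_with_reason(self):
        exp = make_table([{"effect_allele": "A", "other_allele": "G"}])
        out = make_table([{"effect_allele": "A", "other_allele": "C"}])
        hs = harmonize(exp, out)
        assert hs.n_snps == 0
        assert list(hs.dropped["reason"]) == ["irreconcilable alleles"]

    def test_ambiguous_palindrome_dropped_in_window(self):
        # exposure eaf exactly 0.50 sits strictly inside (0.45, 0.55)
        exp = make_table([{"effect_allele": "A", "other_allele": "T",
                           "eaf": 0.50}])
        out = make_table([{"effect_allele": "A", "other_allele": "T",
                           "eaf": 0.52}])
        hs = harmonize(exp, out)
        assert hs.n_snps == 0
        assert list(hs.dropped["reason"]) == ["ambiguous palindrome"]

    def test_window_boundary_is_strict(self):
        exp = make_table([{"effect_allele": "A", "other_allele": "T",
                           "eaf": 0.45}])
        out = make_table([{"effect_allele": "A", "other_allele": "T",
                           "eaf": 0.44}])
        assert harmonize(exp, out).n_snps == 1

    def test_palindrome_aligned_by_frequency(self):
        # eaf 0.10 vs 0.88: opposite minor-allele sides, so flip
        exp = make_table([{"effect_allele": "A", "other_allele": "T",
                           "eaf": 0.10, "beta": 0.1}])
        out = make_table([{"effect_allele": "A", "other_allele": "T",
                           "eaf": 0.88, "beta": 0.03}])
        hs = harmonize(exp, out)
        assert hs.n_snps == 1
        assert hs.data.loc[0, "beta_out"] == pytest.approx(-0.03)
        assert hs.data.loc[0, "eaf_out"] == pytest.approx(0.12)

    def test_drop_all_policy(self):
        exp = make_table([{"effect_allele": "A", "other_allele": "T", "eaf": 0.1},
                          {"variant_id": "rsX", "effect_allele": "A",
                           "other_allele": "G"}])
        out = make_table([{"effect_allele": "A", "other_allele": "T", "eaf": 0.1},
                          {"variant_id": "rsX", "effect_allele": "A",
                           "other_allele": "G"}])
        hs = harmonize(exp, out, HarmonizationPolicy(palindrome_mode="drop_all"))
        assert hs.n_snps == 1
        assert "palindromic" in hs.dropped.loc[0, "reason"]

    def test_palindrome_missing_eaf_dropped(self):
        exp = make_table([{"effect_allele": "A", "other_allele": "T",
                           "eaf": np.nan}])
        out = make_table([{"effect_allele": "A", "other_allele": "T",
                           "eaf": 0.2}])
        hs = harmonize(exp, out)
        assert hs.n_snps == 0
        assert "missing eaf" in hs.dropped.loc[0, "reason"]

    def test_align_by_frequency_missing_eaf_errors(self):
        exp = make_table([{"effect_allele": "A", "other_allele": "T",
                           "eaf": np.nan}])
        out = make_table([{"effect_allele": "A", "other_allele": "T",
                           "eaf": 0.2}])
        with pytest.raises(ValueError, match="eaf missing"):
            harmonize(exp, out,
                      HarmonizationPolicy(palindrome_mode="align_by_frequency"))

    def test_empty_intersection_errors(self):
        exp = make_table([{"variant_id": "rsA"}])
        out = make_table([{"variant_id": "rsB"}])
        with pytest.raises(ValueError, match="share no variants"):
            harmonize(exp, out)

    def test_idempotence(self):
        from causalmr import SimConfig, simulate_two_sample
        exp, out, _ = simulate_two_sample(SimConfig(seed=7, n_snps=40))
        hs1 = harmonize(exp, out)
        exp2, out2 = hs1.as_tables()
        hs2 = harmonize(exp2, out2)
        assert hs2.n_snps == hs1.n_snps
        np.testing.assert_allclose(hs2.data["beta_out"], hs1.data["beta_out"])
        np.testing.assert_allclose(hs2.data["beta_exp"], hs1.data["beta_exp"])

    def test_orientation_equivalence(self):
        """Recoding every outcome row (swap alleles, negate beta, complement
        eaf) before harmonization yields an identical harmonized set."""
        from causalmr import SimConfig, simulate_two_sample
        exp, out, _ = simulate_two_sample(SimConfig(seed=11, n_snps=40))
        flipped = out.data.copy()
        flipped[["effect_allele", "other_allele"]] = \
            flipped[["other_allele", "effect_allele"]].to_numpy()
        flipped["beta"] = -flipped["beta"]
        flipped["eaf"] = 1.0 - flipped["eaf"]
        hs_a = harmonize(exp, out)
        hs_b = harmonize(exp, AssociationTable(flipped, out.trait_label))
        assert list(hs_a.data["variant_id"]) == list(hs_b.data["variant_id"])
        np.testing.assert_allclose(hs_a.data["beta_out"], hs_b.data["beta_out"])
        np.testing.assert_allclose(hs_a.data["eaf_out"], hs_b.data["eaf_out"])

    def test_audit_completeness(self):
        from causalmr import SimConfig, simulate_two_sample
        exp, out, _ = simulate_two_sample(
            SimConfig(seed=13, n_snps=60, palindrome_fraction=0.4))
        # push some palindromes into the ambiguity window to force drops
        df = exp.data.copy()
        pal = df.apply(lambda r: is_palindromic(r.effect_allele, r.other_allele),
                       axis=1)
        df.loc[pal[pal].index[:3], "eaf"] = 0.5
        hs = harmonize(AssociationTable(df, "exposure"), out)
        n_shared = len(set(df["variant_id"]) & set(out.data["variant_id"]))
        assert hs.n_snps + len(hs.dropped) == n_shared
        assert (hs.dropped["reason"].str.len() > 0).all()
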