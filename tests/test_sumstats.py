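"""Reading, validation, round-trip and harmonization of summary statistics."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given
from hypothesis import strategies as st

from mrpipe.sumstats import (
    HarmonizationError,
    SumStatsFormatError,
    SumStatsTable,
    harmonize,
    read_sumstats,
    write_sumstats,
)

from conftest import make_table

ROWS = [
    ("rs1", "A", "G", 0.3, 0.10, 0.01, 1e-10, 10000),
    ("rs2", "T", "C", 0.2, -0.05, 0.02, 1e-9, 10000),
    ("rs3", "G", "A", 0.45, 0.02, 0.015, 5e-8, 10000),
]


class TestReadWrite:
    def test_round_trip_is_lossless(self, tmp_path):
        t = make_table(ROWS)
        path = write_sumstats(t, tmp_path / "t.tsv")
        back = read_sumstats(path, trait_label="trait")
        pd.testing.assert_frame_equal(t.df, back.df)

    def test_nonpositive_se_row_rejected_with_reason(self):
        t = make_table(ROWS + [("rs4", "A", "C", 0.1, 0.1, 0.0, 0.5, 10000)])
        assert len(t) == 3
        assert list(t.rejected["reason"]) == ["nonpositive_se"]

    def test_missing_beta_column_is_format_error(self, tmp_path):
        df = pd.DataFrame({"variant_id": ["rs1"], "se": [0.1]})
        df.to_csv(tmp_path / "bad.tsv", sep="\t", index=False)
        with pytest.raises(SumStatsFormatError, match="beta"):
            read_sumstats(tmp_path / "bad.tsv")

    def test_duplicate_variant_id_is_error_naming_it(self):
        with pytest.raises(SumStatsFormatError, match="rs1"):
            make_table([ROWS[0], ROWS[0]])

    def test_column_map_adapts_foreign_headers(self, tmp_path):
        df = pd.DataFrame(
            {
                "rsid": ["rs1"], "EA": ["A"], "OA": ["G"], "freq": [0.3],
                "effect": [0.1], "stderr": [0.01], "p": [1e-10], "N": [10000],
            }
        )
        df.to_csv(tmp_path / "foreign.tsv", sep="\t", index=False)
        t = read_sumstats(
            tmp_path / "foreign.tsv",
            column_map={
                "variant_id": "rsid", "effect_allele": "EA", "other_allele": "OA",
                "eaf": "freq", "beta": "effect", "se": "stderr", "pval": "p", "n": "N",
            },
        )
        assert t.df.loc[0, "beta"] == 0.1

    @pytest.mark.parametrize(
        "row,reason",
        [
            (("rsx", "A", "A", 0.3, 0.1, 0.01, 0.5, 100), "identical_alleles"),
            (("rsx", "A", "N", 0.3, 0.1, 0.01, 0.5, 100), "invalid_alleles"),
            (("rsx", "A", "G", 0.3, 0.1, 0.01, 0.0, 100), "invalid_pval"),
            (("rsx", "A", "G", 0.3, 0.1, 0.01, 1.5, 100), "invalid_pval"),
            (("rsx", "A", "G", 1.2, 0.1, 0.01, 0.5, 100), "invalid_eaf"),
            (("rsx", "A", "G", 0.3, 0.1, 0.01, 0.5, 0), "invalid_n"),
        ],
    )
    def test_invariant_violations_are_rejected(self, row, reason):
        t = make_table(ROWS + [row])
        assert list(t.rejected["reason"]) == [reason]


class TestHarmonize:
    def test_swapped_alleles_flip_outcome_sign(self):
        exp = make_table([("rs1", "A", "G", 0.3, 0.1, 0.01, 1e-10, 1000)])
        out = make_table([("rs1", "G", "A", 0.7, 0.05, 0.02, 0.5, 1000)])
        h = harmonize(exp, out)
        assert h.beta_x[0] == pytest.approx(0.1)
        assert h.beta_y[0] == pytest.approx(-0.05)

    def test_palindrome_with_uninformative_eaf_dropped(self):
        exp = make_table([("rs1", "A", "T", 0.50, 0.1, 0.01, 1e-10, 1000),
                          ("rs2", "A", "G", 0.3, 0.1, 0.01, 1e-10, 1000)])
        out = make_table([("rs1", "A", "T", 0.50, 0.05, 0.02, 0.5, 1000),
                          ("rs2", "A", "G", 0.3, 0.02, 0.02, 0.5, 1000)])
        h = harmonize(exp, out)
        assert h.variant_ids == ["rs2"]
        assert ("rs1", "ambiguous_palindrome") in h.dropped

    def test_informative_palindrome_kept(self):
        exp = make_table([("rs1", "A", "T", 0.10, 0.1, 0.01, 1e-10, 1000)])
        out = make_table([("rs1", "A", "T", 0.12, 0.05, 0.02, 0.5, 1000)])
        h = harmonize(exp, out)
        assert h.variant_ids == ["rs1"]
        assert h.beta_y[0] == pytest.approx(0.05)

    def test_negative_exposure_beta_reorients_both(self):
        exp = make_table([("rs1", "A", "G", 0.3, -0.1, 0.01, 1e-10, 1000)])
        out = make_table([("rs1", "A", "G", 0.3, 0.02, 0.02, 0.5, 1000)])
        h = harmonize(exp, out)
        assert h.beta_x[0] == pytest.approx(0.1)
        assert h.beta_y[0] == pytest.approx(-0.02)
        assert h.eaf[0] == pytest.approx(0.7)

    def test_strand_complement_rescued_and_logged(self):
        exp = make_table([("rs1", "A", "G", 0.3, 0.1, 0.01, 1e-10, 1000)])
        out = make_table([("rs1", "T", "C", 0.3, 0.05, 0.02, 0.5, 1000)])
        h = harmonize(exp, out)
        assert h.variant_ids == ["rs1"]
        assert h.strand_rescued == ["rs1"]
        assert h.beta_y[0] == pytest.approx(0.05)

    def test_irreconcilable_alleles_dropped(self):
        exp = make_table([("rs1", "A", "G", 0.3, 0.1, 0.01, 1e-10, 1000),
                          ("rs2", "A", "G", 0.3, 0.1, 0.01, 1e-10, 1000)])
        out = make_table([("rs1", "A", "C", 0.3, 0.05, 0.02, 0.5, 1000),
                          ("rs2", "A", "G", 0.3, 0.05, 0.02, 0.5, 1000)])
        h = harmonize(exp, out)
        assert ("rs1", "allele_mismatch") in h.dropped
        assert h.variant_ids == ["rs2"]

    def test_no_shared_variants_raises(self):
        exp = make_table([("rs1", "A", "G", 0.3, 0.1, 0.01, 1e-10, 1000)])
        out = make_table([("rs2", "A", "G", 0.3, 0.05, 0.02, 0.5, 1000)])
        with pytest.raises(HarmonizationError, match="no shared"):
            harmonize(exp, out)

    def test_idempotence_on_aligned_input(self):
        exp = make_table(ROWS)
        out = make_table(
            [("rs1", "A", "G", 0.3, 0.05, 0.01, 0.5, 1000),
             ("rs2", "T", "C", 0.2, 0.01, 0.02, 0.5, 1000),
             ("rs3", "G", "A", 0.45, -0.03, 0.015, 0.5, 1000)]
        )
        h1 = harmonize(exp, out)
        # rebuild tables already oriented to the exposure-increasing allele
        exp2 = make_table(
            [(v, "A", "G", e, b, s, 1e-10, 1000)
             for v, e, b, s in zip(h1.variant_ids, h1.eaf, h1.beta_x, h1.se_x)]
        )
        out2 = make_table(
            [(v, "A", "G", e, b, s, 0.5, 1000)
             for v, e, b, s in zip(h1.variant_ids, h1.eaf, h1.beta_y, h1.se_y)]
        )
        h2 = harmonize(exp2, out2)
        np.testing.assert_allclose(h2.beta_x, h1.beta_x)
        np.testing.assert_allclose(h2.beta_y, h1.beta_y)

    @given(
        flip_exp=st.booleans(),
        flip_out=st.booleans(),
        bx=st.floats(0.01, 0.5),
        by=st.floats(-0.5, 0.5),
    )
    def test_wald_ratio_invariant_to_input_allele_choice(self, flip_exp, flip_out, bx, by):
        """The ratio beta_y/beta_x must not depend on which allele either
        table chose as the effect allele."""
        def row(flip, beta):
            if flip:
                return ("rs1", "G", "A", 0.7, -beta, 0.01, 1e-10, 1000)
            return ("rs1", "A", "G", 0.3, beta, 0.01, 1e-10, 1000)

        exp = make_table([row(flip_exp, bx)])
        out = make_table([row(flip_out, by)])
        h = harmonize(exp, out)
        assert h.beta_y[0] / h.beta_x[0] == pytest.approx(by / bx, rel=1e-12)
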