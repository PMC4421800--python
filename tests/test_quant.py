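"""Expression statistics: RPM conservation, the exact two-library test
against a closed-form oracle, specificity classes, isomiR and arm
bookkeeping, and first-nucleotide bias matrices."""

import math
from fractions import Fraction

import numpy as np
import pandas as pd
import pytest

from mirgonad.preprocess import SequenceTag
from mirgonad.quant import (PrecursorRecord, arm_usage, assign_tags_to_precursors,
                            diff_expression, exact_count_test, first_nt_bias,
                            isomir_stats, rpm_normalize, specificity_class,
                            specificity_table)


class TestRpm:
    def test_unit_total(self):
        df = pd.DataFrame({"a": [5]}, index=["x"])
        assert rpm_normalize(df, {"a": 1_000_000}).loc["x", "a"] == 5

    def test_arithmetic(self):
        df = pd.DataFrame({"a": [3]}, index=["x"])
        assert rpm_normalize(df, {"a": 500_000}).loc["x", "a"] == 6

    def test_zero_total_rejected(self):
        with pytest.raises(ValueError):
            rpm_normalize(pd.DataFrame({"a": [1]}), {"a": 0})

    def test_column_sums_conserved(self, pipeline_result):
        rpm = rpm_normalize(pipeline_result.counts, pipeline_result.totals)
        for col in rpm.columns:
            assert rpm[col].sum() == pytest.approx(1e6, rel=1e-9)


def oracle_exact_p(a, b, na, nb):
    """Closed-form two-sided conditional-binomial p-value via exact
    rational arithmetic."""
    n = a + b
    if n == 0:
        return 1.0
    p = Fraction(na, na + nb)
    pmf = [math.comb(n, k) * p**k * (1 - p) ** (n - k) for k in range(n + 1)]
    obs = pmf[a]
    return float(min(Fraction(1), sum(x for x in pmf if x <= obs)))


class TestExactTest:
    def test_matches_closed_form_at_small_counts(self):
        rng = np.random.default_rng(0)
        for _ in range(120):
            a, b = int(rng.integers(0, 51)), int(rng.integers(0, 51))
            na, nb = int(rng.integers(1000, 20_000)), int(rng.integers(1000, 20_000))
            assert exact_count_test(a, b, na, nb) == pytest.approx(
                oracle_exact_p(a, b, na, nb), rel=1e-8, abs=1e-12
            )

    def test_identical_counts_null(self):
        df = pd.DataFrame({"a": [7], "b": [7]}, index=["x"])
        de = diff_expression(df, "a", "b", {"a": 10_000, "b": 10_000})
        assert de.loc["x", "fold_change"] == pytest.approx(1.0)
        assert de.loc["x", "p_value"] == pytest.approx(1.0)

    def test_swap_symmetry(self):
        df = pd.DataFrame({"a": [30, 4], "b": [5, 4]}, index=["x", "y"])
        totals = {"a": 9_000, "b": 11_000}
        ab = diff_expression(df, "a", "b", totals)
        ba = diff_expression(df, "b", "a", totals)
        assert np.allclose(ab["p_value"], ba["p_value"])
        assert np.allclose(ab["fold_change"], 1 / ba["fold_change"])

    def test_bh_adjustment_monotone(self, pipeline_result):
        res = pipeline_result
        de = diff_expression(res.mirna_counts, "ovary", "testis", res.totals)
        assert (de["p_adj"] >= de["p_value"] - 1e-12).all()
        s = de.sort_values("p_value")
        assert (np.diff(s["p_adj"]) >= -1e-12).all()


class TestSpecificity:
    def test_single_stage(self):
        row = pd.Series({"ovary": 10.0, "ovotestis": 0.0, "testis": 0.0})
        assert specificity_class(row, 1.0) == "ovary"

    def test_three_stage(self):
        row = pd.Series({"ovary": 10.0, "ovotestis": 12.0, "testis": 9.0})
        assert specificity_class(row, 1.0) == "all"

    def test_all_zero(self):
        row = pd.Series({"ovary": 0.0, "ovotestis": 0.0, "testis": 0.0})
        assert specificity_class(row, 1.0) == "none"

    def test_pair(self):
        row = pd.Series({"ovary": 10.0, "ovotestis": 0.0, "testis": 5.0})
        assert specificity_class(row, 1.0) == "ovary+testis"


PREC = PrecursorRecord(
    "prec1",
    "GGACGTACGG" + "TAGCTTATCAGACTGATGTTGA" + "GTGAAACT"
    + "TCAACATCAGTCTGATAAGCTA" + "CCATGACGTA",
    {"5p": (10, 32), "3p": (40, 62)},
)


class TestIsomirAssignment:
    def test_canonical_and_shifted_variants(self):
        seq = PREC.sequence
        tags = [
            SequenceTag("t1", seq[10:32], {"ovary": 50}),          # canonical 5p
            SequenceTag("t2", seq[9:32], {"ovary": 5}),            # 5' -1
            SequenceTag("t3", seq[10:34], {"ovary": 4}),           # 3' +2
            SequenceTag("t4", seq[40:62], {"ovary": 9}),           # canonical 3p
        ]
        asg, unassigned = assign_tags_to_precursors(tags, [PREC])
        assert unassigned == 0
        by_tag = {a.tag_id: a for a in asg}
        assert (by_tag["t1"].off5, by_tag["t1"].off3) == (0, 0)
        assert (by_tag["t2"].off5, by_tag["t2"].off3) == (-1, 0)
        assert (by_tag["t3"].off5, by_tag["t3"].off3) == (0, 2)
        assert by_tag["t4"].parent == "prec1:3p"

    def test_non_templated_addition_flagged(self):
        seq = PREC.sequence
        nxt = seq[32]
        add = "T" if nxt != "T" else "A"
        tag = SequenceTag("t1", seq[10:32] + add, {"ovary": 3})
        asg, _ = assign_tags_to_precursors([tag], [PREC])
        assert asg[0].nta == add and asg[0].off3 == 0

    def test_unrelated_tag_unassigned(self):
        tag = SequenceTag("t1", "ACGT" * 6, {"ovary": 1})
        asg, unassigned = assign_tags_to_precursors([tag], [PREC])
        assert not asg and unassigned == 1

    def test_one_mirna_three_variants_one_stage(self):
        seq = PREC.sequence
        tags = [
            SequenceTag("t1", seq[10:32], {"ovary": 5, "testis": 0}),
            SequenceTag("t2", seq[9:32], {"ovary": 2, "testis": 0}),
            SequenceTag("t3", seq[10:33], {"ovary": 1, "testis": 0}),
        ]
        sets, means, _ = isomir_stats(tags, [PREC], ["ovary", "testis"])
        assert len(sets["prec1:5p"].variants("ovary")) == 3
        assert means["ovary"] == 3.0
        assert means["testis"] == 0.0


class TestArmUsage:
    def test_single_arm_and_guide_calls(self):
        seq = PREC.sequence
        tags5 = [SequenceTag("t1", seq[10:32], {"o": 100})]
        tags3 = [SequenceTag("t2", seq[40:62], {"o": 8})]
        asg, _ = assign_tags_to_precursors(tags5, [PREC])
        only5 = arm_usage(asg)
        assert only5.iloc[0]["label"] == "5p"
        asg, _ = assign_tags_to_precursors(tags5 + tags3, [PREC])
        both = arm_usage(asg)
        assert both.iloc[0]["label"] == "both"
        assert both.iloc[0]["guide"] == "5p"

    def test_equal_counts_co_dominant(self):
        seq = PREC.sequence
        tags = [SequenceTag("t1", seq[10:32], {"o": 10}),
                SequenceTag("t2", seq[40:62], {"o": 10})]
        asg, _ = assign_tags_to_precursors(tags, [PREC])
        assert arm_usage(asg).iloc[0]["guide"] == "co-dominant"


class TestFirstNtBias:
    def test_all_u_reads(self):
        tags = [SequenceTag("t1", "T" * 22, {"o": 10}), SequenceTag("t2", "TACG" * 6, {"o": 5})]
        bias = first_nt_bias(tags, ["o"])
        for _, row in bias["o"].iterrows():
            assert row["U"] == 1.0

    def test_rows_sum_to_one(self, pipeline_result):
        bias = first_nt_bias(pipeline_result.tags, ["ovary", "ovotestis", "testis"])
        for df in bias.values():
            assert np.allclose(df.sum(axis=1), 1.0, atol=1e-9)

    def test_uniform_random_reads_near_quarter(self):
        rng = np.random.default_rng(0)
        tags = [
            SequenceTag(f"t{i}", "".join("ACGT"[b] for b in rng.integers(0, 4, 22)), {"o": 1})
            for i in range(8000)
        ]
        bias = first_nt_bias(tags, ["o"])
        sd = math.sqrt(0.25 * 0.75 / 8000)
        row = bias["o"].loc[22]
        for b in "ACGU":
            assert abs(row[b] - 0.25) < 3 * sd + 1e-9
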