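import math

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy import stats as sps

from nephroflow.stats import (
    NephronRecord,
    anova_sidak,
    paired_t,
    percent_change,
    records_from_table,
    sidak_adjust,
    summarize_groups,
)


class TestPairedT:
    def test_identity_pairs_convention(self):
        res = paired_t([1.0, 2.0, 3.0], [1.0, 2.0, 3.0])
        assert res.t == 0.0
        assert res.p == 1.0
        assert "zero_variance" in res.flags

    def test_constant_shift_flagged(self):
        res = paired_t([1.0, 2.0, 3.0], [2.0, 3.0, 4.0])
        assert "zero_variance" in res.flags
        assert res.p == 0.0
        assert math.isinf(res.t)

    def test_equals_one_sample_t_on_differences(self):
        rng = np.random.default_rng(1)
        for _ in range(20):
            n = int(rng.integers(3, 30))
            before = rng.normal(5, 2, n)
            after = before + rng.normal(0.5, 1, n)
            res = paired_t(before, after)
            oracle = sps.ttest_1samp(after - before, 0.0)
            assert res.t == pytest.approx(oracle.statistic, rel=1e-12)
            assert res.p == pytest.approx(oracle.pvalue, rel=1e-12)
            rel = sps.ttest_rel(after, before)
            assert res.p == pytest.approx(rel.pvalue, rel=1e-12)
            assert res.df == n - 1

    def test_too_few_pairs(self):
        with pytest.raises(ValueError, match="2 pairs"):
            paired_t([1.0], [2.0])

    def test_type_one_error_rate(self):
        # 10,000 null cohorts of 10 pairs: rejection rate 0.05 +/- 0.01
        rng = np.random.default_rng(2024)
        before = rng.normal(0, 1, size=(10_000, 10))
        after = before + rng.normal(0, 1, size=(10_000, 10))
        rejections = sum(paired_t(b, a).p < 0.05 for b, a in zip(before, after))
        assert abs(rejections / 10_000 - 0.05) <= 0.01


class TestSidak:
    def test_closed_form_example(self):
        assert sidak_adjust(0.01, 3) == pytest.approx(1 - 0.99**3, abs=1e-12)
        assert sidak_adjust(0.01, 3) == pytest.approx(0.029701, abs=1e-9)

    @given(st.floats(min_value=0.0, max_value=1.0))
    def test_single_comparison_identity(self, p):
        assert sidak_adjust(p, 1) == pytest.approx(p, abs=1e-15)

    @given(st.floats(min_value=0.0, max_value=1.0),
           st.integers(min_value=1, max_value=20))
    @settings(max_examples=200)
    def test_sidak_below_bonferroni(self, p, m):
        adj = sidak_adjust(p, m)
        assert 0.0 <= adj <= 1.0
        assert adj >= p - 1e-15          # adjusted >= raw
        assert adj <= min(1.0, m * p) + 1e-12  # Sidak <= Bonferroni

    def test_invalid_inputs(self):
        with pytest.raises(ValueError):
            sidak_adjust(1.5, 2)
        with pytest.raises(ValueError):
            sidak_adjust(0.5, 0)


class TestAnova:
    def test_two_groups_f_equals_t_squared(self):
        rng = np.random.default_rng(3)
        a, b = rng.normal(0, 1, 12), rng.normal(0.8, 1, 15)
        res = anova_sidak({"a": a, "b": b})
        t = sps.ttest_ind(a, b).statistic
        assert res.f == pytest.approx(t**2, rel=1e-10)
        assert res.comparisons.loc[0, "p"] == pytest.approx(res.p, rel=1e-10)

    def test_requested_comparisons_and_adjustment(self):
        rng = np.random.default_rng(4)
        groups = {k: rng.normal(i, 1, 10) for i, k in enumerate("abcd")}
        pairs = [("a", "b"), ("a", "c"), ("a", "d")]
        res = anova_sidak(groups, comparisons=pairs)
        assert len(res.comparisons) == 3
        for _, row in res.comparisons.iterrows():
            assert row.p_adj == pytest.approx(1 - (1 - row.p) ** 3, abs=1e-12)
            assert row.p_adj >= row.p

    def test_empty_group_error(self):
        with pytest.raises(ValueError, match="empty"):
            anova_sidak({"a": [1.0, 2.0], "b": []})

    def test_welch_toggle_changes_df(self):
        a = [1.0, 2.0, 3.0, 4.0]
        b = [10.0, 30.0, 50.0, 2.0, 4.0]
        classical = anova_sidak({"a": a, "b": b}, equal_var=True)
        welch = anova_sidak({"a": a, "b": b}, equal_var=False)
        assert classical.comparisons.loc[0, "df"] != welch.comparisons.loc[0, "df"]


class TestPercentChange:
    @pytest.mark.parametrize(
        "before,after,expected,tilde",
        [(4.24, 2.36, 44.34, 44),   # enalapril group means
         (4.12, 1.60, 61.17, 61),   # empagliflozin group means
         (6.03, 2.07, 65.67, 65)],  # combination group means
    )
    def test_group_mean_reductions(self, before, after, expected, tilde):
        assert percent_change(before, after) == pytest.approx(expected, abs=0.005)
        assert percent_change(before, after, mode="tilde") == tilde

    def test_no_change(self):
        assert percent_change(3.3, 3.3) == 0.0

    @given(st.floats(min_value=0.01, max_value=1e3),
           st.floats(min_value=0.0, max_value=1e3))
    def test_complement_identity(self, a, b):
        assert percent_change(a, b) == pytest.approx(100.0 - 100.0 * b / a, abs=1e-9)

    def test_truncation_toward_zero(self):
        assert percent_change(1.0, 0.5566, mode="tilde") == 44  # 44.34 -> 44
        assert percent_change(1.0, 1.5, mode="tilde") == -50
        assert percent_change(1.0, 1.005, mode="tilde") == 0   # -0.5 -> 0

    def test_nonpositive_before_error(self):
        with pytest.raises(ValueError):
            percent_change(0.0, 1.0)


def build_cohort(group_sizes, means, rng, measure="sngfr_nl_min"):
    """group_sizes: {group: (n_animals, n_units)}; means: {group: (before, after)}."""
    records = []
    for group, (n_animals, n_units) in group_sizes.items():
        mb, ma = means[group]
        for i in range(n_units):
            records.append(NephronRecord(
                animal_id=f"{group}_an{i % n_animals}",
                unit_id=f"{group}_u{i}",
                group=group,
                measure=measure,
                value_before=float(rng.normal(mb, 0.5)),
                value_after=float(rng.normal(ma, 0.5)),
            ))
    return records


class TestSummaries:
    def test_design_sizes_roundtrip(self):
        # the published design: placebo 8 animals / 13 nephrons
        rng = np.random.default_rng(5)
        records = build_cohort({"placebo": (8, 13)}, {"placebo": (4.0, 4.0)}, rng)
        out = summarize_groups(records)
        assert int(out.loc[0, "n_animals"]) == 8
        assert int(out.loc[0, "n_measurements"]) == 13

    def test_single_record_sd_flagged(self):
        rec = NephronRecord("a1", "u1", "placebo", "sngfr_nl_min", 4.2, 4.0)
        out = summarize_groups([rec])
        assert math.isnan(out.loc[0, "sd_before"])
        assert "sd_undefined" in out.loc[0, "flags"]
        assert out.loc[0, "mean_before"] == pytest.approx(4.2)

    def test_sampling_oracle_means_within_3se(self):
        rng = np.random.default_rng(6)
        n = 200
        records = build_cohort({"enalapril": (10, n)}, {"enalapril": (4.0, 2.2)}, rng)
        out = summarize_groups(records)
        se = 0.5 / math.sqrt(n)
        assert abs(out.loc[0, "mean_before"] - 4.0) < 3 * se
        assert abs(out.loc[0, "mean_after"] - 2.2) < 3 * se
        assert abs(out.loc[0, "percent_change"] - 45.0) < 5.0

    def test_animal_level_sensitivity(self):
        rng = np.random.default_rng(7)
        records = build_cohort({"placebo": (4, 12)}, {"placebo": (4.0, 4.0)}, rng)
        out = summarize_groups(records, unit="animal")
        assert int(out.loc[0, "n_measurements"]) == 4

    def test_record_validation(self):
        with pytest.raises(ValueError, match="group"):
            NephronRecord("a", "u", "aspirin", "sngfr_nl_min", 1.0, 2.0)
        with pytest.raises(ValueError, match="measure"):
            NephronRecord("a", "u", "placebo", "weight", 1.0, 2.0)
        with pytest.raises(ValueError, match="finite"):
            NephronRecord("a", "u", "placebo", "sngfr_nl_min", float("nan"), 2.0)

    def test_records_from_table(self):
        df = pd.DataFrame(
            {"animal_id": ["a1"], "unit_id": ["u1"], "group": ["placebo"],
             "measure": ["aff_diam_um"], "value_before": [12.1], "value_after": [11.0]}
        )
        recs = records_from_table(df)
        assert recs[0].measure == "aff_diam_um"
        with pytest.raises(ValueError, match="missing columns"):
            records_from_table(df.drop(columns=["group"]))
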