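"""Cohort I/O, inclusion filtering, zero-imputation, and flow accounting."""

import numpy as np
import pandas as pd
import pytest

from promval.cohort import (
    CohortValidationError,
    apply_inclusion_filter,
    compute_flow,
    impute_zero_scores,
    read_cohort,
    write_cohort,
)
from promval.datasets import make_flow_cohort

from conftest import blank_row, make_cohort


class TestReadWrite:
    def test_round_trip_preserves_fields(self, tmp_path, default_cohort):
        path = tmp_path / "cohort.csv"
        write_cohort(default_cohort, path)
        back = read_cohort(path)
        pd.testing.assert_frame_equal(back.data, default_cohort.data)

    def test_three_row_file(self, tmp_path):
        cohort = make_cohort(
            [blank_row(f"P{i}", enrs_t0=5) for i in range(3)]
        )
        path = tmp_path / "three.csv"
        write_cohort(cohort, path)
        assert len(read_cohort(path)) == 3

    def test_out_of_range_score_names_participant(self, tmp_path):
        cohort = make_cohort([blank_row("P0", enrs_t0=5)])
        df = cohort.data.copy()
        df.loc[0, "enrs_t0"] = 11
        path = tmp_path / "bad.csv"
        df.to_csv(path, index=False)
        with pytest.raises(CohortValidationError, match="P0.*enrs_t0"):
            read_cohort(path)

    def test_bad_transition_rejected(self):
        with pytest.raises(CohortValidationError, match="transition"):
            make_cohort([blank_row("P0", transition_t1w=8)])

    def test_duplicate_ids_rejected(self):
        with pytest.raises(CohortValidationError, match="duplicate"):
            make_cohort([blank_row("P0"), blank_row("P0")])


class TestInclusionFilter:
    def test_flow_conservation(self):
        cohort = make_cohort(
            [blank_row(f"P{i}", has_low_back_pain=i % 3 != 0) for i in range(20)]
        )
        kept, frag = apply_inclusion_filter(cohort)
        assert frag.n_included + frag.n_excluded == frag.n_enrolled == 20
        assert len(kept) == frag.n_included

    def test_enrolment_scale_percentage(self):
        cohort = make_flow_cohort(575, 442, {}, {})
        _, frag = apply_inclusion_filter(cohort)
        assert (frag.n_enrolled, frag.n_included) == (575, 442)
        assert frag.pct_included == 76.9

    def test_all_flagged_is_identity(self, default_cohort):
        kept, frag = apply_inclusion_filter(default_cohort)
        assert len(kept) == len(default_cohort) == frag.n_included

    def test_none_flagged_gives_empty(self):
        cohort = make_cohort(
            [blank_row(f"P{i}", has_low_back_pain=0) for i in range(4)]
        )
        kept, frag = apply_inclusion_filter(cohort)
        assert len(kept) == 0 and frag.pct_included == 0.0


class TestImputation:
    @pytest.mark.parametrize(
        "overrides,field,expected",
        [
            # pre-none-box blank baseline with submission -> 0 (rule a)
            (dict(none_box_available=0), "ermdq_t0", 0.0),
            # follow-up blank + submission + baseline>0 -> 0 (rule b)
            (
                dict(none_box_available=0, ermdq_t0=6, submitted_t1w=1),
                "ermdq_t1w",
                0.0,
            ),
            # baseline==0 fails rule (b): stays missing
            (
                dict(none_box_available=0, ermdq_t0=0, submitted_t1w=1),
                "ermdq_t1w",
                np.nan,
            ),
            # post-none-box blank never imputed
            (dict(none_box_available=1), "ermdq_t0", np.nan),
            # no submission at follow-up: stays missing
            (
                dict(none_box_available=0, ermdq_t0=6, submitted_t1w=0),
                "ermdq_t1w",
                np.nan,
            ),
        ],
    )
    def test_rule_table(self, overrides, field, expected):
        cohort = make_cohort([blank_row("P0", **overrides)])
        out, _ = impute_zero_scores(cohort)
        got = out.data.loc[0, field]
        if np.isnan(expected):
            assert np.isnan(got)
        else:
            assert got == expected

    def test_explicit_zero_not_logged(self):
        cohort = make_cohort([blank_row("P0", ermdq_t0=0)])
        out, log = impute_zero_scores(cohort)
        assert out.data.loc[0, "ermdq_t0"] == 0
        assert not [e for e in log if not e.rule.startswith("anomaly")]

    def test_enrs_never_imputed_but_anomaly_logged(self):
        cohort = make_cohort([blank_row("P0", none_box_available=0)])
        out, log = impute_zero_scores(cohort)
        assert np.isnan(out.data.loc[0, "enrs_t0"])
        assert any(e.rule == "anomaly:required-missing" for e in log)

    def test_idempotent(self, default_cohort):
        pre = default_cohort.copy()
        pre.data["none_box_available"] = 0
        once, _ = impute_zero_scores(pre)
        twice, log2 = impute_zero_scores(once)
        pd.testing.assert_frame_equal(once.data, twice.data)
        assert not [e for e in log2 if not e.rule.startswith("anomaly")]


class TestFlow:
    def test_published_style_counts(self):
        cohort = make_flow_cohort(
            575, 442, {"t1w": 187, "t6w": 91}, {"t1w": 101, "t6w": 69}
        )
        included, _ = apply_inclusion_filter(cohort)
        flow = compute_flow(included)
        assert flow.n_recovered == {"t1w": 101, "t6w": 69}
        assert flow.pct_recovered("t1w") == 54
        assert flow.pct_recovered("t6w") == 76
        assert flow.n_cumulative_recovered["t6w"] == 170
        assert flow.pct_cumulative_recovered("t6w") == 38

    def test_cumulative_is_sum_of_period_recoveries(self, default_cohort):
        flow = compute_flow(default_cohort)
        assert (
            flow.n_cumulative_recovered["t6w"]
            == flow.n_recovered["t1w"] + flow.n_recovered["t6w"]
        )
        for p in ("t1w", "t6w"):
            assert flow.n_recovered[p] <= flow.n_transition_respondents[p]

    def test_zero_respondents_reports_missing_pct(self):
        cohort = make_cohort([blank_row("P0", enrs_t0=5)])
        flow = compute_flow(cohort)
        assert flow.n_transition_respondents == {"t1w": 0, "t6w": 0}
        assert np.isnan(flow.pct_recovered("t1w"))

    def test_summary_text_contains_counts(self):
        cohort = make_flow_cohort(10, 10, {"t1w": 4}, {"t1w": 2})
        text = compute_flow(cohort).summary_text()
        assert "2 (50)" in text
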