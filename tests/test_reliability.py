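"""Agreement ICC, SEM/MDC95, stable selection, and the precision planner."""

import numpy as np
import pytest

from promval.reliability import (
    MDC_FACTOR,
    TestRetestSet as RetestSet,
    icc_agreement,
    icc_precision_halfwidth,
    interpret_icc,
    select_stable,
)
from promval.simulate import SyntheticConfig, generate_test_retest

from conftest import blank_row, make_cohort

# fixed 6x2 test-retest table for the hand-ANOVA oracle
SIX_BY_TWO = np.array(
    [[3, 5], [7, 8], [2, 2], [10, 9], [6, 8], [4, 5]], dtype=float
)


def hand_anova_icc(x):
    """Variance-component ICC(A,1) from explicit sums of squares."""
    n, k = x.shape
    grand = x.mean()
    ss_rows = k * ((x.mean(axis=1) - grand) ** 2).sum()
    ss_cols = n * ((x.mean(axis=0) - grand) ** 2).sum()
    ss_err = ((x - grand) ** 2).sum() - ss_rows - ss_cols
    msr = ss_rows / (n - 1)
    msc = ss_cols / (k - 1)
    mse = ss_err / ((n - 1) * (k - 1))
    return (msr - mse) / (msr + (k - 1) * mse + k * (msc - mse) / n)


def retest_set(x, instrument="enrs", mode="per_protocol"):
    return RetestSet(
        instrument=instrument, mode=mode, test=x[:, 0], retest=x[:, 1]
    )


class TestSelectStable:
    def test_mode_membership(self):
        rows = [
            blank_row(f"P{t}", enrs_t0=5, enrs_t1w=5, transition_t1w=t)
            for t in range(1, 8)
        ]
        cohort = make_cohort(rows)
        pp = select_stable(cohort, "enrs", "per_protocol")
        wide = select_stable(cohort, "enrs", "about_the_same")
        assert pp.n == 1  # category 4 only
        assert wide.n == 3  # categories 3, 4, 5

    def test_requires_both_scores(self):
        rows = [
            blank_row("P0", enrs_t0=5, transition_t1w=4),  # no retest
            blank_row("P1", enrs_t1w=5, transition_t1w=4),  # no test
            blank_row("P2", enrs_t0=5, enrs_t1w=4, transition_t1w=4),
        ]
        assert select_stable(make_cohort(rows), "enrs").n == 1

    def test_empty_cohort(self):
        cohort = make_cohort([blank_row("P0")])
        assert select_stable(cohort, "enrs").n == 0

    def test_unknown_mode(self):
        with pytest.raises(ValueError, match="mode"):
            select_stable(make_cohort([blank_row("P0")]), "enrs", "stable?")


class TestICCAgreement:
    def test_perfect_agreement(self):
        x = np.column_stack([SIX_BY_TWO[:, 0], SIX_BY_TWO[:, 0]])
        r = icc_agreement(retest_set(x))
        assert r.icc_agreement == pytest.approx(1.0)
        assert r.sem_agreement == pytest.approx(0.0, abs=1e-6)
        assert r.mdc95 == pytest.approx(0.0, abs=1e-6)

    def test_hand_anova_oracle(self):
        r = icc_agreement(retest_set(SIX_BY_TWO))
        assert r.icc_agreement == pytest.approx(hand_anova_icc(SIX_BY_TWO))

    def test_matches_pingouin(self):
        import pandas as pd
        import pingouin as pg

        n = len(SIX_BY_TWO)
        long = pd.DataFrame(
            {
                "subject": np.repeat(np.arange(n), 2),
                "occasion": np.tile([0, 1], n),
                "score": SIX_BY_TWO.ravel(),
            }
        )
        icc = pg.intraclass_corr(
            long, targets="subject", raters="occasion", ratings="score"
        ).set_index("Type")
        r = icc_agreement(retest_set(SIX_BY_TWO))
        assert r.icc_agreement == pytest.approx(icc.loc["ICC(A,1)", "ICC"])
        lo, hi = icc.loc["ICC(A,1)", "CI95"]  # pingouin rounds to 2 dp
        assert r.ci_low == pytest.approx(lo, abs=0.0051)
        assert r.ci_high == pytest.approx(hi, abs=0.0051)

    def test_mdc_sem_identity(self, default_cohort):
        for inst in ("ermdq", "evas", "enrs"):
            pairs = select_stable(default_cohort, inst, "about_the_same")
            r = icc_agreement(pairs)
            assert r.mdc95 == pytest.approx(MDC_FACTOR * r.sem_agreement)

    def test_occasion_shift_lowers_agreement_not_consistency(self):
        shifted = SIX_BY_TWO.copy()
        shifted[:, 1] += 3.0
        base = icc_agreement(retest_set(SIX_BY_TWO))
        shift = icc_agreement(retest_set(shifted))
        assert shift.icc_agreement < base.icc_agreement
        assert shift.icc_consistency == pytest.approx(base.icc_consistency)
        assert shift.icc_agreement <= shift.icc_consistency

    def test_negative_occasion_component_truncated(self):
        # occasion mean square below error mean square -> negative estimate
        rng = np.random.default_rng(0)
        for _ in range(20):
            x = rng.normal(size=(5, 2))
            r = icc_agreement(retest_set(x))
            assert r.var_occasion >= 0 and r.var_subject >= 0
            if "var_occasion" in r.truncated_components:
                assert r.var_occasion == 0.0
                break
        else:
            pytest.fail("no negative occasion component in 20 draws")

    def test_zero_variance_undefined(self):
        x = np.full((4, 2), 3.0)
        with pytest.raises(ValueError, match="undefined"):
            icc_agreement(retest_set(x))

    def test_too_few_pairs(self):
        with pytest.raises(ValueError, match="at least 3"):
            icc_agreement(retest_set(SIX_BY_TWO[:2]))

    def test_ci_coverage_near_nominal(self):
        """F-based 95% CI covers the true ICC at close to nominal rate."""
        rho, n, covered, n_sim = 0.7, 50, 0, 400
        rng = np.random.default_rng(42)
        sigma_e = np.sqrt((1 - rho) / rho)
        for _ in range(n_sim):
            b = rng.standard_normal(n)
            x = b[:, None] + sigma_e * rng.standard_normal((n, 2))
            r = icc_agreement(retest_set(x))
            covered += r.ci_low <= rho <= r.ci_high
        assert 0.93 <= covered / n_sim <= 0.97


class TestPrecisionPlanner:
    @pytest.mark.parametrize("rho,expected", [(0.7, 0.14), (0.8, 0.10)])
    def test_design_values(self, rho, expected):
        assert icc_precision_halfwidth(rho, 50, 2) == pytest.approx(
            expected, abs=0.005
        )

    def test_vanishes_as_rho_approaches_one(self):
        assert icc_precision_halfwidth(0.9999, 50, 2) < 1e-3

    def test_domain(self):
        with pytest.raises(ValueError):
            icc_precision_halfwidth(1.2, 50)


class TestInterpretation:
    @pytest.mark.parametrize(
        "icc,band",
        [
            (0.87, "excellent"),
            (0.75, "excellent"),
            (0.40, "poor-to-fair"),
            (0.52, "poor-to-fair"),
            (0.31, "poor"),
        ],
    )
    def test_bands(self, icc, band):
        assert interpret_icc(icc) == band
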