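"""Synthetic cohort generator: determinism, bounds, and anchor structure."""

import numpy as np
import pandas as pd
import pytest

from promval.cohort import score_column
from promval.instruments import DEFAULT_INSTRUMENTS, TIMEPOINTS
from promval.reliability import icc_agreement, select_stable
from promval.responsiveness import build_change_pairs
from promval.simulate import (
    ConfigError,
    SyntheticConfig,
    generate_cohort,
    generate_test_retest,
)


def quiet_config(**kw):
    """No true change, no noise, no attrition: retest == test."""
    base = dict(
        n_participants=40,
        true_change_mean={
            "acute_subacute": {"t1w": 0.0, "t6w": 0.0},
            "chronic": {"t1w": 0.0, "t6w": 0.0},
        },
        true_change_sd=0.0,
        change_baseline_loading=0.0,
        measurement_error_sd={"ermdq": 0.0, "evas": 0.0, "enrs": 0.0},
        attrition_prob={"t1w": 0.0, "t6w": 0.0},
        seed=5,
    )
    base.update(kw)
    return SyntheticConfig(**base)


class TestConfig:
    @pytest.mark.parametrize(
        "bad",
        [
            dict(n_participants=0),
            dict(prop_chronic=1.5),
            dict(anchor_weight_followup=0.9, anchor_weight_change=0.3),
            dict(anchor_thresholds=(0, 1, 2, 3, 4, 4)),
            dict(anchor_thresholds=(0, 1, 2)),
            dict(icc_target=1.2),
            dict(attrition_prob={"t1w": -0.1, "t6w": 0.5}),
        ],
    )
    def test_invalid_config_rejected_before_sampling(self, bad):
        with pytest.raises(ConfigError):
            generate_cohort(SyntheticConfig(**bad))

    def test_json_round_trip(self, tmp_path):
        cfg = SyntheticConfig(seed=9, prop_chronic=0.3)
        path = tmp_path / "cfg.json"
        cfg.to_json(path)
        assert SyntheticConfig.from_json(path) == cfg


class TestGenerateCohort:
    def test_same_seed_identical(self):
        a = generate_cohort(SyntheticConfig(n_participants=100, seed=3))
        b = generate_cohort(SyntheticConfig(n_participants=100, seed=3))
        pd.testing.assert_frame_equal(a.cohort.data, b.cohort.data)
        pd.testing.assert_frame_equal(a.truth, b.truth)

    def test_different_seed_differs(self):
        a = generate_cohort(SyntheticConfig(n_participants=100, seed=3))
        b = generate_cohort(SyntheticConfig(n_participants=100, seed=4))
        assert not a.cohort.data.equals(b.cohort.data)

    def test_scores_on_grid_within_bounds(self, default_cohort):
        for spec in DEFAULT_INSTRUMENTS:
            for t in TIMEPOINTS:
                vals = default_cohort.data[score_column(spec.name, t)].dropna()
                assert vals.between(spec.min_score, spec.max_score).all()
                assert (np.mod(vals, spec.resolution) == 0).all()

    def test_quiet_config_scores_identical_across_occasions(self):
        gen = generate_cohort(quiet_config())
        df = gen.cohort.data
        for spec in DEFAULT_INSTRUMENTS:
            for t in ("t1w", "t6w"):
                pd.testing.assert_series_equal(
                    df[score_column(spec.name, t)],
                    df[score_column(spec.name, "t0")],
                    check_names=False,
                )

    def test_truth_aligned_with_cohort(self, default_cohort, default_truth):
        # truth rows correspond 1:1 to the pre-filter cohort
        gen = generate_cohort(SyntheticConfig(seed=7))
        assert list(gen.truth["participant_id"]) == list(
            gen.cohort.data["participant_id"]
        )

    def test_recovery_fraction_monotone_in_change_mean(self):
        fracs = []
        for shift in (0.0, 0.6, 1.2):
            cfg = SyntheticConfig(
                n_participants=4000,
                seed=21,
                true_change_mean={
                    "acute_subacute": {"t1w": shift, "t6w": shift},
                    "chronic": {"t1w": shift, "t6w": shift},
                },
            )
            gen = generate_cohort(cfg)
            trans = gen.cohort.data["transition_t1w"].dropna()
            fracs.append((trans <= 2).mean())
        assert fracs[0] < fracs[1] < fracs[2]

    def test_anchor_tracks_followup_not_baseline_when_pure_followup(self):
        # with no change component the anchor must decouple from baseline
        cfg = SyntheticConfig(
            n_participants=6000,
            seed=13,
            anchor_weight_followup=0.8,
            anchor_weight_change=0.0,
            attrition_prob={"t1w": 0.0, "t6w": 0.0},
        )
        gen = generate_cohort(cfg)
        df = gen.cohort.data
        trans = df["transition_t1w"]
        r_base = np.corrcoef(trans, df["enrs_t0"])[0, 1]
        r_fup = np.corrcoef(trans, df["enrs_t1w"])[0, 1]
        assert abs(r_base) < 0.05
        assert r_fup > 0.4

    def test_attrition_blanks_scores_and_transition(self):
        cfg = SyntheticConfig(
            n_participants=2000, seed=2,
            attrition_prob={"t1w": 0.5, "t6w": 0.9},
        )
        df = generate_cohort(cfg).cohort.data
        missing_t1w = df["submitted_t1w"] == 0
        assert 0.4 < missing_t1w.mean() < 0.6
        assert df.loc[missing_t1w, "transition_t1w"].isna().all()
        assert df.loc[missing_t1w, "enrs_t1w"].isna().all()

    def test_paper_like_shares(self, default_cohort):
        """Recovery, chronic mix, and pair counts sit near the design targets."""
        df = default_cohort.data
        trans = df["transition_t1w"].dropna()
        assert 0.45 < (trans <= 2).mean() < 0.63
        stable = df["transition_t1w"].isin([3, 4, 5])
        chronic_share = (df.loc[stable, "chronicity"] == "chronic").mean()
        assert 0.5 < chronic_share < 0.75
        pairs = build_change_pairs(default_cohort, "enrs", "t1w")
        assert 120 < pairs.n < 260  # 185-scale


class TestTestRetest:
    def test_requires_icc_target(self):
        with pytest.raises(ConfigError, match="icc_target"):
            generate_test_retest(SyntheticConfig(icc_target=None))

    def test_near_one_target_gives_near_one_icc(self):
        cfg = SyntheticConfig(n_participants=300, icc_target=0.999, seed=8)
        gen = generate_test_retest(cfg)
        pairs = select_stable(gen.cohort, "evas", "per_protocol")
        assert icc_agreement(pairs).icc_agreement > 0.99

    def test_parameter_recovery(self):
        cfg = SyntheticConfig(n_participants=2000, icc_target=0.85, seed=3)
        gen = generate_test_retest(cfg)
        pairs = select_stable(gen.cohort, "evas", "per_protocol")
        assert abs(icc_agreement(pairs).icc_agreement - 0.85) < 0.02

    def test_all_participants_rate_no_change(self):
        gen = generate_test_retest(
            SyntheticConfig(n_participants=50, icc_target=0.7, seed=1)
        )
        assert (gen.cohort.data["transition_t1w"] == 4).all()
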